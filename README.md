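# minecomplex

Protein complex prediction from a **multi-relationship protein interaction
network** (MPIN). The package is for computational biologists who have a
physical protein–protein interaction (PPI) network and Gene Ontology (GO)
annotations, and want to detect complexes as subgraphs that are densely and
reliably connected inside (high cohesion) and weakly attached to the rest of
the network (low coupling).

## The model

Starting from a PPI graph *G = (V, E)* and per-protein GO term sets for the
three aspects (BP, MF, CC), the MPIN overlays up to four typed weighted
edges on each protein pair:

* **Physical edge**, weighted by the edge clustering coefficient

  ECC(v_i, v_j) = |N_i ∩ N_j|² / ((|N_i| − 1)(|N_j| − 1))

  when both degrees exceed 1, else 0 (N_i is the PPI neighbour set of v_i).
  Edges with ECC = 0 are removed as likely false positives.

* **Shared-annotation edge** per GO aspect, weighted by the squared overlap

  W_A(v_i, v_j) = |A_i ∩ A_j|² / (|A_i| · |A_j|),  A ∈ {BP, MF, CC},

  created only when the pair shares **≥ 2 terms** of the aspect *and* has
  **≥ 1 common neighbour** in the original PPI graph.

The MPIN is decomposed into four single-relation networks (PPIN, BPN, MFN,
CCN), each mined independently. From every vertex a candidate complex grows
over the seed's neighbourhood, keeping a neighbour only while the weighted
density

  WD(G) = 2 Σ w(e) / (max w(e) · |V|(|V| − 1))

stays at or above the threshold WDT (default 0.05). Members whose weighted
degree into the candidate is smaller than into the external neighbour set
are pruned (low coupling). Candidates that are subsets of complexes already
found are dropped, and a final redundancy filter discards the smaller /
less dense member of any pair whose matching score

  MS(A, B) = |A ∩ B|² / (|A| · |B|)

reaches 0.8. Evaluation against a benchmark uses the standard MS ≥ 0.2
match convention (precision, recall, F-measure, perfect matches) plus
hypergeometric GO term enrichment with the p < 0.01 significance cutoff and
the p-score (mean −log₁₀ p over significant complexes).

## Worked example

Generate a synthetic benchmark with ten planted complexes, run the
detector, and score it against the planted truth:

```bash
mine synth --seed 7 --out-dir demo
mine run  --ppi demo/ppi.tsv --go demo/go_annotations.tsv --out demo/predicted.tsv
mine eval --predicted demo/predicted.tsv --benchmark demo/complexes_truth.txt \
          --go demo/go_annotations.tsv --ppi demo/ppi.tsv --report demo/report.tsv
```

This prints:

```
INFO minecomplex: wrote 276 edges, 104 annotated proteins, 10 planted complexes to demo
INFO minecomplex: detected 25 complexes -> demo/predicted.tsv
complex prediction evaluation
  matching-score threshold : 0.2
  PC        : 25
  N_cp      : 25
  N_cb      : 10
  N_pcp     : 2
  precision : 1.0000
  recall    : 1.0000
  F         : 1.0000
  SC        : 25
  proportion: 100.00
  p_score   : 8.0882
```

All 25 predicted complexes match a planted complex (precision 1.0) and all
10 planted complexes are recovered (recall 1.0); two predictions match a
planted complex exactly. Every prediction is significantly enriched for a
GO term (SC = PC), with a mean −log₁₀ p of about 8.1 — expected, since the
generator annotates complex members with shared terms. The prediction table
(`demo/predicted.tsv`) lists each complex with its size, weighted density
and the relation network it was mined from; a `*.manifest.json` beside it
records parameters and input checksums so runs are bit-reproducible.

The same pipeline is available as a library (`minecomplex.build_mpin`,
`decompose`, `mine`, `match_counts`, `enrichment_report`), and a YAML config
can replace the `run` flags (`mine run --config run.yaml`).

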