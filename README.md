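# consortium-net

Ensemble co-occurrence network inference and keystone scoring for
compositional microbiome feature tables, built around the analysis of a
crude-oil-degrading bacterial consortium followed over serial transfer
passages (generations G1–G4, triplicate sampling).

## The problem

Enrichment cultures for complex pollutants like crude oil are unstable:
degradation efficiency can fade over successive transfers as the
community re-organises. Understanding why requires knowing (i) which
genera interact, (ii) which are structurally *keystone*, and (iii) which
track the degradation efficiency of specific oil fractions (TPH,
saturates, aromatics). All three questions must be answered on relative
abundances, where closure to 1 per sample induces spurious negative
correlations that a naive correlation network mistakes for competition.

## The method

For every taxon pair, five association measures — Bray–Curtis
dissimilarity, Pearson, Spearman, mutual information (equal-frequency
bins, nats) and a generalized boosted linear model (componentwise
L2-boosting) — are tested against a *compositionality-preserving*
permutation null: one taxon is permuted, every sample is re-closed to
sum 1, and the measure is recomputed, so the null carries the same
closure bias as the data (a ReBoot-style scheme, with a bootstrap over
samples stabilising the observed score). Per-measure p-values are merged
with Brown's method using the empirical dependence across shared
permutation draws, BH-corrected per generation, and significant pairs
form a signed weighted network (sign by majority vote of the directional
measures).

Keystone candidates are ranked by the key-score on homogenized
(sum-to-one) centralities,

    key_score = Degree + Closeness − Betweenness,

high for well-connected, central, non-bottleneck nodes. Taxon–function
links are the sum of the five measures' permutation-standardized signed
z-statistics between a taxon's abundance and an oil fraction's
degradation efficiency, `eff = (control − treatment) / control` on
residual masses.

A synthetic-data module simulates the whole study shape (log-normal
latents with planted correlations, multinomial counts, keystone-driven
efficiency responses) so every stage is testable against ground truth
without any sequencing download.

## Worked example

```python
from consortium_net import (PipelineConfig, association_scan, build_network,
                            recovery_report, simulate_study, study_spec)

spec = study_spec(seed=11, n_generations=1, replicates=40,
                  keystone_effects=[], generation_drift={})
table, _, truth = simulate_study(spec)          # 40 samples x 30 genera
results = association_scan(table.to_relative(),
                           PipelineConfig(permutations=200, bootstraps=100, seed=111))
net = build_network(results, q_threshold=0.05, nodes=table.taxon_ids)
print(recovery_report(truth, net))
```

prints

```
{'edge_precision': 0.75, 'edge_recall': 0.9, 'sign_accuracy': 1.0,
 'n_edges': 12, 'n_true_edges': 10}
```

meaning: of the ten planted associations (|ρ| = 0.8 on the latent log
scale), nine were recovered at q ≤ 0.05, every recovered edge carried
the correct sign, and three of twelve reported edges were spurious.
Longer narrative scripts live in `examples/` (simulation, network
inference, keystone ranking, function linking, full pipeline); the same
stages are available from the shell via the thin `consortium-net` CLI
(`simulate`, `scores`, `network`, `keystones`, `function-link`,
`diversity`, `run`).

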