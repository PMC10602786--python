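"""Infer a signed co-occurrence network and recover the planted edges.

Simulates one 40-sample community with ten planted |rho| = 0.8
associations, runs the five-measure ensemble with the
compositionality-preserving permutation null (P = 200, B = 100), builds
the BH-thresholded signed network, and scores it against ground truth.
"""

from consortium_net import (
    PipelineConfig,
    build_network,
    association_scan,
    recovery_report,
    study_spec,
    simulate_study,
)

spec = study_spec(seed=11, n_generations=1, replicates=40,
                  keystone_effects=[], generation_drift={})
table, _, truth = simulate_study(spec)

config = PipelineConfig(permutations=200, bootstraps=100, seed=111)
results = association_scan(table.to_relative(), config)
net = build_network(results, q_threshold=0.05, nodes=table.taxon_ids)

print(f"{len(net.nodes)} nodes, {net.graph.number_of_edges()} edges at q <= 0.05")
for a, b, sign, weight, q in net.edge_records():
    print(f"  {a} {sign} {b}   weight={weight:.2f}  q={q:.4f}")

report = recovery_report(truth, net)
print(f"edge precision {report['edge_precision']:.2f}, "
      f"recall {report['edge_recall']:.2f}, "
      f"sign accuracy {report['sign_accuracy']:.2f}")
# precision/recall near 1 mean the ensemble separates planted structure
# from closure-induced spurious correlation at this sample size
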