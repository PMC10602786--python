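"""Rank keystone candidates of a network by key-score.

key_score = degree + closeness - betweenness on homogenized centralities:
high for well-connected, central, non-bottleneck nodes.  The worked
example uses a hand-built network whose hub dominates strength and
closeness while sitting on no shortest path.
"""

import itertools

from consortium_net import ConsortiumNetwork, keystone_table, rank_keystones

rim = [f"genus_{i}" for i in range(5)]
edges = [("hub_genus", v, "+", 1.9, 0.01) for v in rim]
edges += [(a, b, "+", 1.0, 0.02) for a, b in itertools.combinations(rim, 2)]
edges += [("genus_0", "satellite", "-", 0.5, 0.03)]

net = ConsortiumNetwork.from_edges(["hub_genus", "satellite"] + rim, edges)
ks = keystone_table(net)

print(ks.frame[["betweenness", "closeness", "degree", "key_score"]].round(4))
print("\nkeystone ranking:", rank_keystones(ks))
# the hub ranks first: homogenized degree and closeness are maximal while
# its betweenness is zero (every rim pair has a direct shortest path)
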