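"""Participation coefficient and within-module degree z-score on a toy graph.

Builds a two-community weighted network with one integrator node (edges
spread across both communities) and one provincial node (edges confined to
its own community) and evaluates both per-node metrics.
"""

import numpy as np

from painflow import CommunityPartition, participation_coefficient, within_module_z

labels = ["hub", "a1", "a2", "b1", "b2", "b3"]
comm = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
part = CommunityPartition(labels, comm)

W = np.zeros((6, 6))
# "hub" spreads strength evenly over both communities -> integrator
for j, w in [(1, 1.0), (2, 1.0), (3, 1.0), (4, 1.0)]:
    W[0, j] = W[j, 0] = w
# "a1" keeps all strength inside community A -> provincial
W[1, 2] = W[2, 1] = 2.0
# some structure inside B
W[3, 4] = W[4, 3] = 1.0
W[4, 5] = W[5, 4] = 0.5

pc = participation_coefficient(W, part)
z = within_module_z(W, part)

print(f"{'node':>5} {'community':>9} {'PC':>7} {'z':>7}")
for i, lab in enumerate(labels):
    print(f"{lab:>5} {comm[i]:>9} {pc[i]:7.3f} {z[i]:7.3f}")
print()
print("PC = 0 means all positive strength stays within one community;")
print("PC -> 1 - 1/M for a uniform spread over M communities (here M = 2,")
print("so the ceiling is 0.5). z compares a node's within-community strength")
print("with its community's distribution; each community's z averages to 0:")
for lab in part.community_labels:
    print(f"  mean z in {lab}: {z[comm == lab].mean():+.2e}")
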