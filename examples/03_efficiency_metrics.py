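"""Weighted efficiency metrics and small-world normalization on toy graphs.

Edge length is 1/weight, so stronger connections are shorter.  Global
efficiency averages 1/d over node pairs; local efficiency measures the
interconnection of each node's neighborhood; gamma and lambda compare
clustering and path length against degree-preserving random networks.
"""

import numpy as np

import effconn as ec

# a 3-node path A-B-C with unit weights
path = ec.WeightedGraph(
    np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float), sparsity=0.67
)
gm = ec.global_metrics(path)
eg, el = ec.nodal_efficiencies(path)
print(f"path A-B-C: E_glob={gm.e_glob:.4f}, C_w={gm.c_w:.1f}, L_w={gm.l_w:.2f}")
print(f"  nodal global efficiency: {eg}  (middle node reaches both ends directly)")
print(f"  L_w * E_glob = {gm.l_w * gm.e_glob:.1f}  (harmonic path length is 1/E_glob)")

# a ring lattice: high clustering, long paths -> gamma >> 1
n = 24
w = np.zeros((n, n))
for i in range(n):
    for d in (1, 2):
        w[i, (i + d) % n] = w[(i + d) % n, i] = 1.0
ring = ec.WeightedGraph(w, sparsity=2 * 2 / (n - 1))
sw = ec.null_model_metrics(ring, n_rand=100, seed=0)
print(f"ring lattice: gamma={sw.gamma:.2f}, lambda={sw.lam:.2f}, sigma={sw.sigma:.2f}")
print("-> gamma far above 1: the lattice is much more clustered than its")
print("   degree-matched random rewirings, the signature probed in brain networks.")
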