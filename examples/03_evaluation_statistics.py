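"""The evaluation statistics on a worked toy: UniFrac, Mantel, ICC.

Small closed-form cases make the definitions visible before they are
used at scale: a three-leaf tree for unweighted UniFrac, a distance
matrix compared against itself for the Mantel permutation test, and a
replicate design with known variance components for the one-way ICC.
"""

import numpy as np
import pandas as pd
from skbio import TreeNode

import hybridotu as h

# unweighted UniFrac on ((A:1,B:1):1,C:2); sample1 holds only A, sample2
# only B: unique branch length 2 over observed branch length 3
tree = TreeNode.read(["((A:1,B:1):1,C:2);"])
table = h.OTUTable(pd.DataFrame([[4, 0, 0], [0, 6, 0]],
                                index=["s1", "s2"], columns=list("ABC")))
d = h.unifrac(table, tree, weighted=False)
print(f"unweighted UniFrac(s1, s2) = {d['s1', 's2']:.4f}   (expected 2/3)")

# Mantel of a matrix with itself: r = 1 and the smallest achievable p
rng = np.random.default_rng(0)
x = rng.random((12, 2))
from skbio import DistanceMatrix
D = DistanceMatrix(np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)),
                   [f"s{i}" for i in range(12)])
res = h.mantel(D, D, n_perm=1000, seed=1)
print(f"Mantel(D, D): r = {res.r:.3f}, p = {res.p:.6f}   (p floor = 1/1001)")

# one-way ICC: between-subject variance 3, replicate noise 1 -> 0.75
entries, values = {}, {}
for g in range(200):
    mu = rng.normal(0, np.sqrt(3))
    for rep in range(3):
        sid = f"subj{g}_rep{rep}"
        entries[sid] = (f"subj{g}", "frozen", rep)
        values[sid] = mu + rng.normal(0, 1)
icc = h.icc_oneway(values, h.ReplicateDesign(entries))
print(f"ICC at sigma_b^2=3, sigma_w^2=1: {icc:.3f}   (target 0.75)")
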