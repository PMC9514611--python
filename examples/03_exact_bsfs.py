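"""Tabulate exact block-wise mutation-configuration (bSFS) probabilities.

For a single population of two lineages the distribution of the number of
pairwise differences in a block is the geometric mixture
P(k) = θ^k / (1+θ)^(k+1); the same machinery then tabulates the full
4-dimensional bSFS of the two-population IM benchmark model.
"""

from coalgf import DemographicModel, bsfs_probabilities
from coalgf.presets import im_benchmark

pair = DemographicModel(["A"], samples={"A": 2})
theta = 1.0
arr = bsfs_probabilities(pair, theta, (3,))
print(f"pairwise differences, theta={theta}:")
for k in range(4):
    closed = theta ** k / (1 + theta) ** (k + 1)
    print(f"  P({k}) = {arr[(k,)]:.10f}   closed form {closed:.10f}")
print(f"  P(>3) = {arr[(4,)]:.10f}   (residual bin)")

model, theta = im_benchmark(2)
im = bsfs_probabilities(model, theta, 2)
print(f"\nIM benchmark bSFS (theta={theta}), branch types "
      f"{im.bts.header()}:")
print(f"  total probability: {im.total():.12f}")
print(f"  P(no mutations)          = {im[(0, 0, 0, 0)]:.6f}")
print(f"  P(one private b-mutation) = {im[(1, 0, 0, 0)]:.6f}")
print(f"  P(one shared a/b branch mutation) = {im[(0, 0, 0, 1)]:.6f}")
# a structural zero: a population-spanning ('fixed') branch and a
# cross-population branch cannot occur in the same genealogy
print(f"  P(fixed & shared jointly) = {im[(0, 1, 0, 1)]:.1f}  (structural zero)")
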