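"""Evaluate the Laplace transform of the joint branch-length distribution.

The transform at a point ω is the probability that independent Poisson
marking processes with intensities ω_k (one per branch type) leave the
genealogy unmarked; its derivatives at 0 give branch-length moments.
"""

import numpy as np

from coalgf import DemographicModel, evaluate_laplace
from coalgf.presets import im_model

# a single population of two samples: the transform is 1/(1 + 2ω)
pair = DemographicModel(["A"], samples={"A": 2})
for w in (0.0, 0.5, 1.0):
    print(f"pairwise transform at omega={w}: {evaluate_laplace(pair, [w]):.6f}")

# mean total branch length from a central finite difference at 0:
h = 1e-6
mean_len = -(evaluate_laplace(pair, [h]) - evaluate_laplace(pair, [-h])) / (2 * h)
print(f"mean total branch length (expect 2.0): {mean_len:.6f}")

# the IM model: transform evaluated at the split time T; at omega = 0 the
# value is the total probability, 1, for any T
im = im_model(2, migration_rate=0.8, split_time=1.5, size_b=0.5, size_anc=1.2)
print(f"IM transform at omega=0: {evaluate_laplace(im, np.zeros(4)):.12f}")
print(f"IM transform at omega=0.3: {evaluate_laplace(im, np.full(4, 0.3)):.6f}")
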