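"""Mutual-nearest-neighbor batch alignment between two sessions.

Simulates the day-to-day measurement offset between two sessions'
feature distributions and removes it with the MNN correction
(K=100 neighbors, Gaussian-kernel weighting, 15th-order median filter).
"""

import numpy as np
from sklearn.neighbors import NearestNeighbors

from ethokit import align_to_reference

rng = np.random.default_rng(0)
n, n_postures = 5000, 49
centers = rng.uniform(0.1, 0.9, (n_postures, 23))
labels = []
while len(labels) < n:
    labels += [int(rng.integers(n_postures))] * int(rng.geometric(1 / 18))
labels = np.asarray(labels[:n])

X1 = centers[labels] + rng.normal(0, 0.02, (n, 23))   # reference session
v = rng.normal(size=23)
v *= 0.3 / np.linalg.norm(v)                          # planted batch offset
X2 = X1 + v                                           # shifted session

X2_aligned, corr = align_to_reference(X1, X2, K=100)

recovered = corr.C.mean(axis=0)
print(f"planted offset norm:   {np.linalg.norm(v):.3f}")
print(f"recovered offset norm: {np.linalg.norm(recovered):.3f}")
print(f"relative recovery error: "
      f"{np.linalg.norm(recovered - v) / np.linalg.norm(v):.1%}")

nn = NearestNeighbors(n_neighbors=1).fit(X1)
before = nn.kneighbors(X2)[0].mean()
after = nn.kneighbors(X2_aligned)[0].mean()
print(f"cross-session NN distance: {before:.3f} -> {after:.3f} "
      f"({1 - after / before:.1%} reduction)")
# The correction matrix C captures the session-level shift; subtracting
# it makes corresponding postures from the two sessions overlap again.
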