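"""Centroid cloud analysis: per-axis permutation tests and ODR line fits.

Computes per-subject centers of mass of a sulcus for two groups, tests
their mean location per axis, fits the orthogonal-distance-regression line
P = p0 + t*d to each cloud by SVD, and compares the direction parameters
with a paired t-test.
"""

import numpy as np

from mtlatlas import (
    center_of_mass,
    centroid_permutation_test,
    compare_directions,
    fit_odr_line,
    sample_structure_masks,
)

g1 = sample_structure_masks(15, rng=np.random.default_rng(10))
g2 = sample_structure_masks(15, rng=np.random.default_rng(11))
pts = np.array([center_of_mass(v) for v in g1 + g2])
labels = np.array([1] * 15 + [2] * 15)

for ax in "xyz":
    res = centroid_permutation_test(pts, labels, axis=ax, n_perm=500, seed=3)
    lo, hi = res.interval
    print(
        f"{ax}-centroid difference {res.observed:+.2f} mm, "
        f"null [{lo:+.2f}, {hi:+.2f}], significant: {res.significant}"
    )

fit1 = fit_odr_line(pts[labels == 1])
fit2 = fit_odr_line(pts[labels == 2])
cmp = compare_directions(fit1, fit2)
print(f"\ngroup-1 direction d = {np.round(fit1.d, 3)}")
print(f"group-2 direction d = {np.round(fit2.d, 3)}")
print(f"paired t on direction components: t = {cmp.statistic:.3f}, p = {cmp.p_value:.3f}")
print()
print("Both groups come from one template: each axis has a ~5% chance of a")
print("false-positive centroid flag. Centroid clouds under near-isotropic")
print("jitter have a weakly determined principal direction, and the paired t")
print("over 3 direction components (df = 2) has very low power, so the")
print("direction comparison should stay non-significant.")
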