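"""Permutation test of blob bounding-box extrema between two mask groups.

Draws two groups of rhinal-sulcus masks, injects a known +6 mm rostrocaudal
shift into the second, and tests every extremum difference at the 5% blob
threshold against a 500-permutation relabeling null.
"""

import numpy as np

from mtlatlas import extrema_permutation_test, sample_structure_masks

grid = (48, 64, 48)
g1 = sample_structure_masks(15, rng=np.random.default_rng(1), grid_shape=grid)
g2 = sample_structure_masks(
    15, shift=(0.0, 6.0, 0.0), rng=np.random.default_rng(2), grid_shape=grid
)
labels = np.array([1] * 15 + [2] * 15)

results = extrema_permutation_test(
    g1 + g2, fractions=(0.05,), smoothing_fwhm=3.0, n_perm=500, seed=7, labels=labels
)

print("statistic      observed   null 95% interval   significant")
for r in results:
    lo, hi = r.interval
    print(
        f"{r.statistic_name:<12} {r.observed:+9.1f}   [{lo:+5.1f}, {hi:+5.1f}]"
        f"        {'yes' if r.significant else 'no'}"
    )
print()
print("Observed = group1 extremum - group2 extremum (mm). Group 2 sits 6 mm")
print("rostral of group 1, so the y statistics land near -6 mm, outside the")
print("relabeling null; the x and z statistics stay inside their intervals.")
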