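"""Cohort-level statistics: type proportions, phi, morphometry t-tests.

Generates a full synthetic cohort and reproduces the classical analysis
battery: Type 1/2 frequencies with a proportion z-test against an adult
literature reference, the inter-hemispheric type correlation, and
depth/length comparisons between types with BH-FDR correction.
"""

from mtlatlas import (
    CohortConfig,
    generate_cohort,
    group_ttests,
    interhemispheric_type_correlation,
    proportion_test,
    summarize_types,
)

_, cohort, morphometry = generate_cohort(CohortConfig(n_subjects=38, seed=5))

s = summarize_types(cohort)
pct1, pct2 = s.printed()
print(f"{s.n_hemispheres} hemispheres: {s.n_type1} Type 1 ({pct1}%), "
      f"{s.n_type2} Type 2 ({pct2}%)")

z = proportion_test(s.n_type1, s.n_hemispheres, 0.28)
print(f"vs adult reference 28%: z = {z.statistic:.3f}, p = {z.p_value:.3f}")

phi = interhemispheric_type_correlation(cohort)
print(f"inter-hemispheric type correlation r = {phi.statistic:.2f}")

print("\nright rhinal sulcus morphometry, Type 1 vs Type 2 (BH-FDR):")
rs = morphometry[(morphometry.sulcus == "RS") & (morphometry.hemisphere == "R")]
for res in group_ttests(rs, "conformation_type", ["max_depth", "mean_depth", "length"]):
    col = res.comparison.split(":")[0]
    print(
        f"  {col:<11} t = {res.statistic:+.2f}, p = {res.p_value:.4f}, "
        f"p_adj = {res.p_adjusted:.4f}{'  *' if res.rejected else ''}"
    )
print()
print("t = mean(Type 1) - mean(Type 2), so positive t means Type 1 deeper.")
print("The generator draws Type-1 right RS depths from deeper distributions,")
print("so the depth contrasts should be flagged while length is not.")
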