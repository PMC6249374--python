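# mtlatlas

Probabilistic atlas construction and sulcal-morphotype statistics for
medial temporal lobe (MTL) structures.

## The problem

The folds bordering the MTL cortices — the rhinal sulcus (RS) and the
rostral and caudal segments of the collateral sulcus (CS proper, CS post) —
vary qualitatively between people: in some hemispheres the RS and CS proper
merge into one continuous fold (**Type 1**), in others they are separated
(**Type 2**). This binary morphotype shifts the boundaries of the
entorhinal, perirhinal and parahippocampal cortices, so anyone segmenting
MTL regions, placing electrodes, or interpreting fMRI activations near the
collateral sulcus needs to know where each structure *probably* is, and
whether the morphotype moves it.

`mtlatlas` implements the analysis machinery such a study runs, end to end,
on cohorts of co-registered binary structure masks:

* **Occurrence maps** — each subject's binary mask is optionally smoothed
  with a Gaussian kernel (FWHM = 3 mm; σ = FWHM / 2√(2 ln 2)), then averaged
  voxelwise: a voxel's value is the fraction of subjects whose structure
  covers it. Thresholding at a fraction *f* (5% for atlas display, 25% for
  a high-overlap sensitivity check, inclusive ≥) yields the **blob**, the
  group-level extent of the structure.
* **Extrema permutation tests** — the blob's per-axis bounding-box extrema
  (mediolateral x, rostrocaudal y, dorsoventral z, at voxel centers in mm)
  are compared between Type-1 and Type-2 groups. The observed difference
  (group 1 − group 2) is tested against a null of `n_perm` random
  relabelings preserving group sizes; it is significant when it falls
  outside the central 95% interval (2.5th–97.5th centiles) of the null.
* **Centroid tests and line fits** — per-subject centers of mass are
  compared per axis by the same permutation scheme, and each group's
  centroid cloud is summarized by the total-least-squares line
  **P = p0 + t·d** (p0 the cloud mean, d the dominant right singular vector
  of the centered cloud), with direction parameters compared by paired
  t-test over the three components.
* **Cohort statistics** — Type-1/Type-2 frequencies with one- and
  two-sample proportion z-tests, the inter-hemispheric type correlation
  (phi coefficient), and morphometry/covariate group t-tests with
  Benjamini–Hochberg FDR correction.
* **Synthetic cohorts** — because MRI-derived masks are not distributable,
  a first-class generator rasterizes tubular sulcal casts around smooth 3D
  template curves with realistic inter-subject variability (positional
  jitter, shape noise, rostrocaudal extent and thickness variation), builds
  Type-1 connections as explicit bridge tubes and Type-2 gaps by
  construction, and draws matching metadata and depth/length morphometry.

## Worked example

```python
from mtlatlas import (CohortConfig, generate_cohort, summarize_types,
                      proportion_test, interhemispheric_type_correlation)

_, cohort, _ = generate_cohort(CohortConfig(n_subjects=38, seed=5))
s = summarize_types(cohort)
pct1, pct2 = s.printed()
print(f"{s.n_hemispheres} hemispheres: {s.n_type1} Type 1 ({pct1}%), "
      f"{s.n_type2} Type 2 ({pct2}%)")
z = proportion_test(s.n_type1, s.n_hemispheres, 0.28)
print(f"vs adult reference 28%: z = {z.statistic:.3f}, p = {z.p_value:.3f}")
```

prints

```
76 hemispheres: 29 Type 1 (38.15%), 47 Type 2 (61.85%)
vs adult reference 28%: z = 1.823, p = 0.068
```

— 29 of 76 hemispheres carry the connected morphotype (38.15%), a
frequency statistically compatible (p = 0.068 against 28%) with the rates
reported for adults. The `examples/` directory holds one short script per
capability (occurrence maps, extrema tests, centroid lines, cohort
statistics), each printing its numbers with a note on what they mean.

A thin CLI mirrors the library:

```bash
mtlatlas simulate --config cohort.yaml --out sim/
mtlatlas build-map --masks 'sim/masks/*_R_RS.nii.gz' --fwhm 3 --out map.nii.gz
mtlatlas threshold --map map.nii.gz --fraction 0.05 --out blob.nii.gz
mtlatlas run --out results/          # full experiment behind one config
```

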