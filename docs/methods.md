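# Methods

## Coordinate model

All volumes are 3D scalar grids with a NIfTI-style 4×4 affine mapping
0-based voxel indices to world millimetres at voxel centers. The default
synthetic grid is 1 mm isotropic, RAS+, 72×96×72 voxels, positioned over
the medial temporal region of a stereotaxic space; masks entering any
group analysis must share grid shape and affine (the package performs no
registration — inputs are assumed co-registered). Axis semantics follow
the neuroimaging convention: x mediolateral, y rostrocaudal, z
dorsoventral. Medial/lateral wording depends on the hemisphere's x sign
and is applied at reporting time only; stored coordinates are raw mm.

## Occurrence maps

For a cohort of binary masks the probabilistic map is the voxelwise mean
of (optionally smoothed) per-subject masks. Without smoothing every value
is exactly k/N — the fraction of subjects covering the voxel. Smoothing is
a separable Gaussian with the kernel size given as FWHM in mm
(σ = FWHM/2√(2 ln 2) per axis, converted to voxels; 3 mm FWHM default for
sulci, none for the larger cortical/hippocampal blobs, switchable per
structure). The filter is truncated at 6σ and uses constant-zero padding,
conserving total mass to relative 1e-6 for structures lying ≥ 2·FWHM from
the grid edge; callers are expected to respect that margin.

Thresholding keeps voxels with value ≥ f (inclusive, matching the
"present in at least f of subjects" reading). A blob is that voxel set
with its affine and threshold. One documented ambiguity: a figure caption
in the source literature describes the 5% display threshold as keeping
voxels "present in at least 95% of subjects"; the Methods wording (at
least 5%) is followed here.

## Blob geometry

Bounding-box extrema are the per-axis min/max of member-voxel *center*
coordinates (the half-voxel face offset cancels in group differences).
Centers of mass use binary occupancy weighting — the blob is a voxel set,
not a weighted cloud; a probability-weighted variant would be easy to add
but is deliberately not the default, since the blob definition already
discards the weights. The ODR line fit computes p0 as the cloud mean and
d as the dominant right singular vector of the centered point matrix; this
minimizes the summed squared orthogonal distances among all 3D lines. The
SVD sign ambiguity is resolved by flipping d so its largest-magnitude
component is positive (ties broken x→y→z), making the fit a deterministic
function of the point set. A near-tie between the two leading singular
values (relative gap < 1e-9) sets `degenerate_direction`, flagging an
ill-determined direction — common for near-isotropic centroid clouds.

## Permutation inference

The observed statistic is the signed difference (group 1 − group 2) of a
blob extremum or of group-mean centroid coordinates. The null is built
from `n_perm` (default 1000) random relabelings sampled with replacement
from the relabeling space, preserving group sizes; per-subject smoothed
volumes are cached and group means recomputed per relabeling
(mathematically identical to re-smoothing inside each permutation, since
smoothing and averaging commute — verified to 1e-9). A relabeling whose
group blob is empty at a requested threshold is resampled, keeping the
null length exactly `n_perm`.

The decision rule is two-sided: significant iff the observed value lies
strictly outside the central 95% interval of the null (2.5th/97.5th
linear-interpolation centiles). A one-sided upper-tail variant
(`alternative="greater"`, 95th centile) is exposed. The reported interval
is the centile pair, not the null min/max. No multiple-testing correction
is applied across the 12 extrema statistics (min/max × 3 axes × 2
thresholds), mirroring the analysis battery the package reproduces.

Results are deterministic given (inputs, seed, n_perm), and invariant to
the input ordering of masks: inputs are canonically reordered internally
(by label, then content digest) before permutation.

On a 1 mm grid the extrema statistics are integer-valued, so their nulls
are discrete with large atoms and the strictly-outside rule is
conservative: simulated type-I error per extremum statistic is ≈
0.015–0.04 rather than 0.05 (the identical engine on the continuous
centroid statistic rejects at ≈ 0.05). This conservatism never inflates
false positives; it does cost power for statistics with narrow nulls.

The direction comparison is a paired t-test over the 3 paired components
of two sign-canonicalized unit directions (df = 2). Its power is very low
by construction, and it is blind to symmetric axis swaps (d1 = x̂ vs
d2 = ŷ gives t = 0); it can only flag gross, consistently signed
direction differences and is reported for completeness.

## Cohort statistics

The one-sample proportion z-test defaults to the sample-proportion
variance (the behavior of the standard statsmodels routine); a
null-variance score-test variant is selectable. The two-sample variant
uses the pooled proportion. Group comparisons are two-sided
pooled-variance (Student) t-tests; the brain-surface contrast reported as
F(1, n−2) elsewhere equals the squared t of this path, so only the t form
is implemented. FDR is Benjamini–Hochberg step-up with the family defined
as the columns tested in a single call. Dichotomous covariates (sex, and
the type coding itself) run through the same t path on 0/1 codings. The
inter-hemispheric type correlation is the Pearson correlation of the 0/1
type across L/R pairs, identical to the 2×2-table phi closed form. Type
percentages are displayed two ways: standard half-up rounding, and the
publication-table convention (Type-1 percentage truncated to 2 decimals,
Type-2 as its complement to 100), which is the convention the reference
numbers 38.15/61.85 follow.

## Synthetic cohorts

The generator emulates the *post-normalization* situation of a sulcal
morphotype study: per subject and hemisphere, binary casts of RS, CS
proper and CS post rasterized as tubes of radius ~2–3 mm around smooth
template curves in a shared space. What it reproduces: the two
conformation types (Type 1 via an explicit bridging tube joining the
caudal RS endpoint to the rostral CS proper endpoint, guaranteeing a
single 26-connected component; Type 2 with a minimum inter-voxel-center
gap, default 2 mm), the relative layout of the three sulci with a fixed
CS proper → CS post transition plane at y = −54 mm, inter-subject
variability, balanced metadata (ages uniform on 7–17 years, sexes
balanced), and per-type depth morphometry drawn from the group
means/SDs reported for the two morphotypes (Type-1 sulci deeper, most
markedly the right RS).

Inter-subject variability has four modes, all per structure:

| parameter   | default        | meaning                                      |
|-------------|----------------|----------------------------------------------|
| `jitter_sd` | 1.5 mm/axis    | rigid translation (residual misalignment)    |
| `shape_sd`  | (2.2, 2.2, 3.2) mm | control-point noise; depth axis largest  |
| `extent_sd` | 4.0 mm/end     | rostral/caudal arc-length extension or trim  |
| `radius_sd` | 0.7 mm         | cast thickness variation (floor 0.6 mm)      |

`jitter_sd` follows the conventional residual-misalignment scale. The
other three were calibrated once so that the permutation null intervals
of the extrema statistics span the few-millimetre ranges that published
group-difference tables show (wider on y than on x/z, wider for minima
than maxima at the 5% threshold), and so that group maps retain voxels
above the 25% threshold — both qualitative properties of the real data.
The depth axis gets the largest shape noise because between-subject depth
SDs (≈ 2.4–3.7 mm in the reference morphometry) exceed the tangential
ones. Sulcal lengths have no published dispersion to anchor on; their
surrogate distributions (30–45 ± 4–6 mm) are plausible but uncalibrated.

What the generator does **not** emulate: sheet-like (2D) sulcal geometry —
casts are tubes; nonlinear inter-subject warps; cortical folding
mechanics; MRI intensities or segmentation errors; any spatial coupling
between depth morphometry and mask geometry; inter-hemispheric
correlation of types (hemispheres are drawn independently, so the phi
statistic is near zero on synthetic cohorts by design). Passing tests
therefore validate the *analysis machinery* — map algebra, geometry,
resampling inference, statistics — under a controlled data-generating
process, not anatomical fidelity.

Tube rasterization defines the voxel set as all voxels whose center lies
within the tube radius of the dense curve sampling (spline through the
control points, chord-length parametrized, step ≤ 0.25 mm); every sampled
curve point also claims its nearest voxel, so sub-voxel radii still
produce connected tubes. Draws violating a constraint (off-grid after
jitter, broken Type-1 connectivity, violated Type-2 gap) are retried up
to 25 times, then raise.

## Pipeline and reproducibility

`run_experiment` derives one independent sub-seed per stage from the
top-level seed via `numpy.random.SeedSequence.spawn`, so stages can be
re-run in isolation; the manifest records the config snapshot, derived
seeds and content hashes of config, cohort table and report. Identical
config + seed gives byte-identical reports.

## Simulation sizes

The operating-characteristic studies run single-structure (right RS)
cohorts of 15 masks per group. Type-I error uses a compact 48³ 1 mm grid,
200 replicate cohorts and 200 permutations per test; the power study
(+6 mm rostrocaudal shift injected into the second group) uses a
48×64×48 grid — the extra rostrocaudal headroom keeps the shifted
group's extent draws from clipping at the grid edge, which would
silently attenuate the injected effect — with 100 replicates and 500
permutations. The acceptance script reports the same quantities at 60
and 50 replicates respectively.

## Known limitations

* Extrema inference on 1 mm grids is conservative (see above); at a 6 mm
  effect the rostral-tip (y-max) statistic of union-like 5% blobs retains
  ≈ 60–70% power under the calibrated variability, while the y-centroid
  test is near 100% — centroids aggregate over the whole mask and are
  continuous-valued, so they are the more sensitive location statistic.
* The 25% threshold is fragile for small groups (≲ 6 subjects) of
  smoothed thin structures: the group map may not reach 0.25 anywhere,
  which raises an explicit error rather than returning an empty blob.
* Binary masks are required on input; users resampling real masks into a
  common space must re-binarize first.
* The direction comparison (df = 2) should be treated as descriptive.
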