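"""Permutation inference on group blobs and centroids.

Two group-level blobs (e.g. Type-1 vs Type-2 hemispheres of one sulcus) are
compared through the per-axis extrema of their bounding boxes, or through
the group means of per-subject centers of mass.  Significance comes from a
permutation null: subjects are randomly relabeled into groups of the
original sizes ``n_perm`` times, the statistic recomputed each time, and the
observed difference declared significant when it falls outside the central
95% interval (2.5th-97.5th linear-interpolation centiles) of the null — a
two-sided rule; a one-sided upper-tail variant is available via
``alternative='greater'``.

Per-subject smoothed volumes are computed once and cached across
permutations (mathematically identical to re-smoothing inside each
permutation, since smoothing and averaging commute).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohortstats import StatResult
from .geometry import AXES, LineFit, canonical_sign
from .probmap import Blob, build_probability_map, smooth_mask, threshold_map
from .volume import LabeledVolume, SubjectMask

__all__ = [
    "PermutationResult",
    "group_blob",
    "extrema_permutation_test",
    "centroid_permutation_test",
    "compare_directions",
]

_MAX_EMPTY_RETRIES = 50


@dataclass
class PermutationResult:
    """An observed group difference against its permutation null."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    interval: tuple
    significant: bool
    n_perm: int
    seed: int
    group_sizes: tuple
    threshold: float | None = None
    alternative: str = "two-sided"

    @classmethod
    def from_null(
        cls,
        statistic_name: str,
        observed: float,
        null_values,
        seed: int,
        group_sizes,
        threshold: float | None = None,
        alternative: str = "two-sided",
    ) -> "PermutationResult":
        """Build the decision from an observed value and its null draws.

        Two-sided: significant iff observed lies strictly outside the
        central 95% interval of the null.  'greater': significant iff
        observed exceeds the null's 95th centile.
        """
        null_values = np.asarray(null_values, dtype=float)
        if alternative == "two-sided":
            lo, hi = np.quantile(null_values, [0.025, 0.975])
        elif alternative == "greater":
            lo, hi = -np.inf, float(np.quantile(null_values, 0.95))
        else:
            raise ValueError("alternative must be 'two-sided' or 'greater'")
        significant = bool(observed < lo or observed > hi)
        return cls(
            statistic_name,
            float(observed),
            null_values,
            (float(lo), float(hi)),
            significant,
            len(null_values),
            seed,
            tuple(group_sizes),
            threshold,
            alternative,
        )

    def as_dict(self, include_null: bool = True) -> dict:
        out = {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "interval": [self.interval[0], self.interval[1]],
            "significant": self.significant,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "group_sizes": list(self.group_sizes),
            "alternative": self.alternative,
        }
        if self.threshold is not None:
            out["threshold"] = self.threshold
        if include_null:
            out["null_values"] = np.asarray(self.null_values).tolist()
        return out


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def _as_volume(m) -> LabeledVolume:
    return m.volume if isinstance(m, SubjectMask) else m


def _labels_from(masks, labels):
    if labels is not None:
        lab = np.asarray(labels)
    else:
        lab = np.array(
            [m.conformation_type for m in masks if isinstance(m, SubjectMask)]
        )
        if len(lab) != len(masks):
            raise ValueError("labels required when masks are bare volumes")
    uniq = sorted(np.unique(lab).tolist())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two group labels, got {uniq}")
    return lab, uniq


def _canonical_order(X: np.ndarray, lab: np.ndarray) -> np.ndarray:
    """Order masks by (label, content digest) so results do not depend on
    input ordering (exchangeability of the API, not of the statistic)."""
    keys = [
        (lab[i], hashlib.sha1(np.ascontiguousarray(X[i]).tobytes()).hexdigest())
        for i in range(len(X))
    ]
    return np.array(sorted(range(len(X)), key=lambda i: keys[i]))


def _axis_extrema(mean_map: np.ndarray, fraction: float, affine: np.ndarray):
    """(min, max) world coordinate per axis of {v: map[v] >= fraction}.

    Returns None when the thresholded set is empty.  Requires an
    axis-aligned affine with positive scales (the package's grids).
    """
    mask = mean_map >= fraction
    if not mask.any():
        return None
    mins = np.empty(3)
    maxs = np.empty(3)
    for a in range(3):
        proj = mask.any(axis=tuple(i for i in range(3) if i != a))
        nz = np.flatnonzero(proj)
        scale = affine[a, a]
        t = affine[a, 3]
        mins[a] = nz[0] * scale + t
        maxs[a] = nz[-1] * scale + t
    return mins, maxs


def _is_axis_aligned(affine: np.ndarray) -> bool:
    off = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    return np.allclose(off, 0.0) and np.all(np.diag(affine[:3, :3]) > 0)


def group_blob(masks, fraction: float, smoothing_fwhm: float = 0.0) -> Blob:
    """Group-level blob: occurrence map of the group's masks thresholded at
    ``fraction``."""
    pmap = build_probability_map(masks, smoothing_fwhm=smoothing_fwhm)
    return threshold_map(pmap, fraction)


# ----------------------------------------------------------------------
# extrema permutation test
# ----------------------------------------------------------------------
def extrema_permutation_test(
    masks,
    fractions=(0.05, 0.25),
    smoothing_fwhm: float = 0.0,
    n_perm: int = 1000,
    seed: int = 0,
    labels=None,
    alternative: str = "two-sided",
) -> list[PermutationResult]:
    """Permutation test of per-axis blob-extrema differences between groups.

    For each threshold fraction and each of the six extremum statistics
    (min and max along x, y, z) the observed statistic is
    ``group1_extremum - group2_extremum`` in mm (group 1 = smaller label).
    The null is built from ``n_perm`` random relabelings preserving group
    sizes, recomputing both group blobs each time; relabelings yielding an
    empty blob at any requested fraction are resampled (bounded, logged via
    the result's seed/n_perm metadata staying exact).

    A single float ``fractions`` yields 6 results; the default pair of
    thresholds (5% and 25%) yields 12.  Deterministic given ``seed``.
    """
    if np.isscalar(fractions):
        fractions = (float(fractions),)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    lab, (g1, g2) = _labels_from(masks, labels)
    vols = [_as_volume(m) for m in masks]
    affine = vols[0].affine
    shape = vols[0].shape
    if not all(v.same_grid(vols[0]) for v in vols):
        raise ValueError("masks on mismatched grids")
    if not _is_axis_aligned(affine):
        raise ValueError("extrema test requires an axis-aligned affine")

    # per-subject smoothing cached once; averaging commutes with smoothing
    X = np.stack(
        [
            np.asarray(
                smooth_mask(v, smoothing_fwhm).data if smoothing_fwhm > 0 else v.data,
                dtype=np.float32,
            )
            for v in vols
        ]
    ).reshape(len(vols), -1)
    lab = np.asarray(lab)
    order = _canonical_order(X, lab)
    X, lab = X[order], lab[order]

    n = len(X)
    n1 = int(np.sum(lab == g1))
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    total = X.sum(axis=0)

    def extrema_pair(mean1_flat, mean2_flat, fraction):
        e1 = _axis_extrema(mean1_flat.reshape(shape), fraction, affine)
        e2 = _axis_extrema(mean2_flat.reshape(shape), fraction, affine)
        if e1 is None or e2 is None:
            return None
        return (e1[0] - e2[0], e1[1] - e2[1])  # (min diffs, max diffs)

    # observed
    m1 = X[lab == g1].mean(axis=0)
    m2 = X[lab == g2].mean(axis=0)
    observed = {}
    for f in fractions:
        pair = extrema_pair(m1, m2, f)
        if pair is None:
            raise ValueError(f"observed group blob empty at threshold {f}")
        observed[f] = pair

    # null: sample relabelings, batched matrix product
    rng = np.random.default_rng(seed)
    null = {f: np.empty((n_perm, 2, 3)) for f in fractions}

    def draw_rows(k):
        r = rng.random((k, n))
        sel = np.argpartition(r, n1 - 1, axis=1)[:, :n1]
        P = np.zeros((k, n), dtype=np.float32)
        np.put_along_axis(P, sel, 1.0, axis=1)
        return P

    filled = 0
    retries = 0
    chunk = 64  # bounds the (chunk, n_voxels) scratch of the batched product
    while filled < n_perm:
        k = min(n_perm - filled, chunk)
        P = draw_rows(k)
        S = P @ X  # (k, V) group-1 sums
        for row in range(k):
            mean1 = S[row] / n1
            mean2 = (total - S[row]) / n2
            ok = True
            vals = {}
            for f in fractions:
                pair = extrema_pair(mean1, mean2, f)
                if pair is None:
                    ok = False
                    break
                vals[f] = pair
            if ok:
                for f in fractions:
                    null[f][filled, 0] = vals[f][0]
                    null[f][filled, 1] = vals[f][1]
                filled += 1
            else:
                retries += 1
                if retries > _MAX_EMPTY_RETRIES * n_perm:
                    raise RuntimeError("too many empty-blob permutations")

    results = []
    for f in fractions:
        for ki, kind in enumerate(("min", "max")):
            for a, ax in enumerate(AXES):
                results.append(
                    PermutationResult.from_null(
                        f"{ax}_{kind}_diff",
                        observed[f][ki][a],
                        null[f][:, ki, a],
                        seed=seed,
                        group_sizes=(n1, n2),
                        threshold=f,
                        alternative=alternative,
                    )
                )
    return results


# ----------------------------------------------------------------------
# centroid permutation test
# ----------------------------------------------------------------------
def centroid_permutation_test(
    centroids,
    labels,
    axis: str = "y",
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Permutation test of the group-mean centroid coordinate on one axis.

    ``centroids`` is an (n, 3) array of per-subject world-mm centers of
    mass; the observed statistic is mean(group1) - mean(group2) of the
    chosen coordinate, with the null built by random relabeling.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    pts = np.asarray(centroids, dtype=float)
    lab = np.asarray(labels)
    if len(pts) != len(lab):
        raise ValueError("centroids and labels length mismatch")
    uniq = sorted(np.unique(lab).tolist())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two group labels, got {uniq}")
    g1, g2 = uniq
    x = pts[:, AXES.index(axis)]
    order = np.array(
        sorted(range(len(x)), key=lambda i: (lab[i], tuple(np.atleast_1d(pts[i]))))
    )
    x, lab = x[order], lab[order]
    n1 = int(np.sum(lab == g1))
    n2 = len(x) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    observed = x[lab == g1].mean() - x[lab == g2].mean()

    rng = np.random.default_rng(seed)
    total = x.sum()
    r = rng.random((n_perm, len(x)))
    sel = np.argpartition(r, n1 - 1, axis=1)[:, :n1]
    s1 = x[sel].sum(axis=1)
    null = s1 / n1 - (total - s1) / n2
    return PermutationResult.from_null(
        f"{axis}_centroid_diff",
        observed,
        null,
        seed=seed,
        group_sizes=(n1, n2),
        alternative=alternative,
    )


# ----------------------------------------------------------------------
# direction comparison
# ----------------------------------------------------------------------
def compare_directions(fit1: LineFit, fit2: LineFit) -> StatResult:
    """Paired t-test over the 3 paired direction components of two line fits.

    With only three pairs (df = 2) this test has very low power; it can only
    flag gross, consistently signed direction differences.  Both directions
    must be unit (sign-canonicalized) vectors.
    """
    for f in (fit1, fit2):
        if abs(np.linalg.norm(f.d) - 1.0) > 1e-9:
            raise ValueError("directions must be unit vectors")
    d1 = canonical_sign(fit1.d)
    d2 = canonical_sign(fit2.d)
    diffs = d1 - d2
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.sign(mean)) * np.inf
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / (sd / np.sqrt(3))
        p = 2 * stats.t.sf(abs(t), df=2)
    return StatResult(
        "paired_ttest_directions",
        float(t),
        float(p),
        comparison="direction components d1 vs d2",
        extra={"differences": diffs.tolist(), "df": 2},
    )
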