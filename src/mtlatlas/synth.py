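"""Synthetic cohorts of medial-temporal-lobe sulcal masks.

The generator emulates, directly in a shared stereotaxic space, the raw
material of an MTL sulcal-pattern study: per subject and hemisphere, binary
casts of the rhinal sulcus (RS), the collateral sulcus proper (CS proper)
and its caudal segment (CS post), rasterized as tubes around smooth 3D
curves, plus optional compact cortical/hippocampal blobs.  Each hemisphere
is assigned one of two sulcal morphotypes:

* Type 1 — RS and CS proper *connected*: an explicit bridging tube joins
  the caudal RS endpoint to the rostral CS proper endpoint, so their union
  is a single 26-connected component by construction.
* Type 2 — RS and CS proper *separated* by at least ``connection_gap`` mm
  (minimum inter-voxel-center distance).

Inter-subject variability is a rigid per-structure translation
(``jitter_sd`` mm per axis) plus small control-point noise, modelling the
residual misalignment left after spatial normalization.  Systematic
between-type effects can be injected via ``type_shift`` (a rigid mm offset
of every Type-2 template) for power studies.  Metadata (ages uniform on
7-17 years, balanced sexes) and surrogate depth/length morphometry are
drawn alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .volume import LabeledVolume, SubjectMask, default_affine

__all__ = [
    "SulcusTemplate",
    "CohortConfig",
    "default_templates",
    "rasterize_tube",
    "classify_conformation",
    "generate_cohort",
    "sample_structure_masks",
    "DEFAULT_DEPTH_PARAMS",
]

_CURVE_STEP_MM = 0.25  # dense polyline sampling step
_MAX_RETRIES = 25

DEFAULT_SHAPE_SD = (2.2, 2.2, 3.2)  # mm per axis; depth (z) varies most


@dataclass
class SulcusTemplate:
    """A smooth 3D curve (world mm) with a tube radius, defining one sulcus.

    ``extend`` holds per-end arc-length offsets in mm (rostral, caudal): a
    positive value prolongs the curve linearly along its end tangent, a
    negative one trims it — the generator's model of inter-subject variation
    in sulcal extent.
    """

    control_points: np.ndarray  # (k >= 3, 3) world mm
    tube_radius: float
    structure: str
    hemisphere: str
    extend: tuple = (0.0, 0.0)

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[1] != 3:
            raise ValueError("control_points must be (k, 3)")
        if len(self.control_points) < 3:
            raise ValueError("need at least 3 control points")
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be > 0")

    def translated(self, offset) -> "SulcusTemplate":
        return replace(self, control_points=self.control_points + np.asarray(offset))

    def sample_curve(self, step: float = _CURVE_STEP_MM) -> np.ndarray:
        """Dense (m, 3) polyline sampling of the spline through the control
        points, chord-length parametrized, sample spacing <= ``step`` mm.
        Per-end ``extend`` offsets are applied as linear tangent extensions
        (positive) or arc-length trims (negative), bounded so at least 20%
        of the curve survives."""
        pts = self.control_points
        chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        t = np.concatenate([[0.0], np.cumsum(chord)])
        length = t[-1]
        if length == 0:
            raise ValueError("degenerate curve: coincident control points")
        spline = CubicSpline(t, pts, axis=0)
        n = max(int(np.ceil(length / step)) + 1, 2)
        samples = spline(np.linspace(0.0, length, n))

        a, b = self.extend
        limit = 0.4 * length  # keep >= 20% of the curve
        a = float(np.clip(a, -limit, 3 * limit))
        b = float(np.clip(b, -limit, 3 * limit))
        if a or b:
            arc = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(samples, axis=0), axis=1))]
            )
            keep = (arc >= max(-a, 0.0)) & (arc <= arc[-1] - max(-b, 0.0))
            samples = samples[keep]
            if a > 0:
                tan = samples[0] - samples[1]
                tan /= np.linalg.norm(tan)
                k = np.arange(1, int(np.ceil(a / step)) + 1)[::-1]
                samples = np.vstack(
                    [samples[0] + np.outer(np.minimum(k * step, a), tan), samples]
                )
            if b > 0:
                tan = samples[-1] - samples[-2]
                tan /= np.linalg.norm(tan)
                k = np.arange(1, int(np.ceil(b / step)) + 1)
                samples = np.vstack(
                    [samples, samples[-1] + np.outer(np.minimum(k * step, b), tan)]
                )
        return samples


def default_templates(hemisphere: str, tube_radius: float = 2.8):
    """Canonical sulcal templates for one hemisphere, in MNI-like mm.

    The rhinal sulcus runs rostral and medial; the collateral sulcus proper
    caudal and lateral to it; CS post continues caudally past the fixed
    transition plane (y = -54 mm, echoing the caudal hippocampal-body
    landmark).  The mediolateral sign flips with hemisphere.
    """
    s = -1.0 if hemisphere == "L" else 1.0
    rs = [(s * 17, 2, -28), (s * 19, -6, -30), (s * 21, -14, -31), (s * 22, -21, -30)]
    cs = [(s * 25, -28, -28), (s * 27, -36, -26), (s * 28, -44, -24), (s * 29, -52, -22)]
    cspost = [(s * 28, -56, -18), (s * 26, -62, -15), (s * 24, -68, -12)]
    return {
        "RS": SulcusTemplate(rs, tube_radius, "RS", hemisphere),
        "CSproper": SulcusTemplate(cs, tube_radius * 1.07, "CSproper", hemisphere),
        "CSpost": SulcusTemplate(cspost, tube_radius * 0.93, "CSpost", hemisphere),
    }


def rasterize_tube(
    template: SulcusTemplate,
    shape=(72, 96, 72),
    affine=None,
) -> LabeledVolume:
    """Rasterize a tube: voxels whose world center lies within ``tube_radius``
    of the densely sampled curve (sampling step <= 0.25 mm).

    Every sampled curve point additionally claims its nearest voxel, so even
    a radius below half the voxel size yields a connected, nonempty tube.

    Raises
    ------
    ValueError
        If the dilated curve does not fit inside the grid.
    """
    if affine is None:
        affine = default_affine()
    grid = LabeledVolume(np.zeros(shape, dtype=np.uint8), affine)
    samples = template.sample_curve()
    r = template.tube_radius

    vox = grid.world_to_voxel(samples)
    lo = np.floor(vox.min(axis=0) - r / grid.voxel_size - 1).astype(int)
    hi = np.ceil(vox.max(axis=0) + r / grid.voxel_size + 1).astype(int)
    if np.any(lo < -1) or np.any(hi > np.asarray(shape)):
        raise ValueError(
            f"{template.structure} curve (dilated by {r} mm) leaves the grid"
        )
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)

    ranges = [np.arange(lo[a], hi[a]) for a in range(3)]
    cand = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    world = cand.astype(float) @ affine[:3, :3].T + affine[:3, 3]
    dist, _ = cKDTree(samples).query(world, k=1)
    inside = cand[dist <= r]

    data = np.zeros(shape, dtype=np.uint8)
    if len(inside):
        data[tuple(inside.T)] = 1
    # nearest-voxel guarantee per sample point
    nearest = np.round(grid.world_to_voxel(samples)).astype(int)
    nearest = np.clip(nearest, 0, np.asarray(shape) - 1)
    data[tuple(nearest.T)] = 1
    return LabeledVolume(data, affine)


_CONN26 = np.ones((3, 3, 3), dtype=int)


def classify_conformation(rs, cs_proper) -> int:
    """Sulcal morphotype of a hemisphere: 1 if the RS and CS proper voxel
    sets union to a single 26-connected component (connected fold), else 2."""
    rs_vol = rs.volume if isinstance(rs, SubjectMask) else rs
    cs_vol = cs_proper.volume if isinstance(cs_proper, SubjectMask) else cs_proper
    if not rs_vol.same_grid(cs_vol):
        raise ValueError("RS and CS proper masks are on mismatched grids")
    union = (rs_vol.data > 0) | (cs_vol.data > 0)
    _, n_components = ndimage.label(union, structure=_CONN26)
    return 1 if n_components == 1 else 2


# ----------------------------------------------------------------------
# cohort generation
# ----------------------------------------------------------------------

#: Per (sulcus, hemisphere, type) surrogate morphometry distributions:
#: (mean, sd) in mm.  Depths follow the group means/SDs reported for the two
#: morphotypes in each hemisphere (Type 1 sulci are deeper, most markedly the
#: right RS); lengths are plausible per-sulcus values (uncalibrated).
DEFAULT_DEPTH_PARAMS = {
    ("RS", "L", 1): {"max_depth": (15.27, 3.71), "mean_depth": (9.21, 1.54), "length": (30.0, 4.0)},
    ("RS", "L", 2): {"max_depth": (13.60, 2.58), "mean_depth": (8.00, 1.52), "length": (30.0, 4.0)},
    ("RS", "R", 1): {"max_depth": (16.17, 2.37), "mean_depth": (10.45, 1.24), "length": (30.0, 4.0)},
    ("RS", "R", 2): {"max_depth": (13.64, 2.50), "mean_depth": (8.06, 1.26), "length": (30.0, 4.0)},
    ("CSproper", "L", 1): {"max_depth": (16.48, 2.96), "mean_depth": (12.41, 2.18), "length": (45.0, 6.0)},
    ("CSproper", "L", 2): {"max_depth": (15.16, 3.01), "mean_depth": (10.11, 2.18), "length": (45.0, 6.0)},
    ("CSproper", "R", 1): {"max_depth": (16.93, 1.93), "mean_depth": (12.42, 2.16), "length": (45.0, 6.0)},
    ("CSproper", "R", 2): {"max_depth": (16.45, 2.15), "mean_depth": (10.96, 2.17), "length": (45.0, 6.0)},
    ("CSpost", "L", 1): {"max_depth": (16.15, 2.15), "mean_depth": (10.36, 1.10), "length": (35.0, 5.0)},
    ("CSpost", "L", 2): {"max_depth": (16.17, 1.50), "mean_depth": (10.23, 0.95), "length": (35.0, 5.0)},
    ("CSpost", "R", 1): {"max_depth": (16.40, 1.63), "mean_depth": (11.15, 1.43), "length": (35.0, 5.0)},
    ("CSpost", "R", 2): {"max_depth": (16.36, 1.81), "mean_depth": (10.74, 1.07), "length": (35.0, 5.0)},
}


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study conditions the analysis assumes: 38
    subjects aged 7-17 with balanced sexes, two hemispheres each, Type 1
    frequency 29/76, 1 mm isotropic grid, 1.5 mm positional jitter, no
    systematic between-type location shift.
    """

    n_subjects: int = 38
    p_type1: float = 29 / 76
    jitter_sd: float = 1.5
    shape_sd: tuple = DEFAULT_SHAPE_SD
    extent_sd: float = 4.0
    radius_sd: float = 0.7
    type_shift: tuple = (0.0, 0.0, 0.0)
    connection_gap: float = 2.0
    bridge_radius: float = 1.2
    tube_radius: float = 2.8
    depth_params: dict = field(default_factory=lambda: dict(DEFAULT_DEPTH_PARAMS))
    age_range: tuple = (7.0, 17.0)
    seed: int = 0
    grid_shape: tuple = (72, 96, 72)
    grid_translation: tuple = (-36.0, -76.0, -50.0)
    hemispheres: tuple = ("L", "R")
    structures: tuple = ("RS", "CSproper", "CSpost")

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 <= self.p_type1 <= 1:
            raise ValueError("p_type1 must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.connection_gap <= 0:
            raise ValueError("connection_gap must be > 0")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.grid_translation)


def _jittered(
    template,
    rng,
    jitter_sd,
    shape_sd=DEFAULT_SHAPE_SD,
    extent_sd: float = 4.0,
    radius_sd: float = 0.7,
):
    """One subject's realization of a sulcal template.

    Rigid per-structure translation (``jitter_sd`` mm/axis, the residual
    normalization misalignment), per-axis control-point shape noise
    (``shape_sd``; the depth axis gets the largest value, mirroring the
    between-subject depth dispersion of real sulci), per-end arc-length
    extent variation (``extent_sd``) and cast-thickness variation
    (``radius_sd``, floored at 0.6 mm).
    """
    offset = rng.normal(0.0, jitter_sd, size=3)
    sd = np.broadcast_to(np.asarray(shape_sd, dtype=float), (3,))
    noise = rng.normal(0.0, 1.0, size=template.control_points.shape) * sd
    ext = tuple(rng.normal(0.0, extent_sd, size=2))
    radius = max(0.6, template.tube_radius + rng.normal(0.0, radius_sd))
    return replace(
        template,
        control_points=template.control_points + offset + noise,
        extend=ext,
        tube_radius=radius,
    )


def _min_intermask_distance(a: LabeledVolume, b: LabeledVolume) -> float:
    pa = a.world_coordinates()
    pb = b.world_coordinates()
    d, _ = cKDTree(pa).query(pb, k=1)
    return float(d.min())


def _bridge(rs_t: SulcusTemplate, cs_t: SulcusTemplate, radius: float):
    """Connecting tube from the caudal RS endpoint to the rostral CS proper
    endpoint (the Type-1 junction)."""
    p, q = rs_t.control_points[-1], cs_t.control_points[0]
    mid = 0.5 * (p + q)
    return SulcusTemplate(np.array([p, mid, q]), radius, rs_t.structure, rs_t.hemisphere)


def _sample_hemisphere(cfg: CohortConfig, hemisphere: str, ctype: int, rng):
    """Rasterize one hemisphere's sulci honouring its conformation type.

    Retries the jitter draw (bounded) until Type-1 connectivity / Type-2
    separation holds and everything stays on the grid.
    """
    base = default_templates(hemisphere, cfg.tube_radius)
    shift = np.asarray(cfg.type_shift) if ctype == 2 else np.zeros(3)
    for _ in range(_MAX_RETRIES):
        try:
            vols = {}
            jt = {}
            for name in cfg.structures:
                t = base[name].translated(shift)
                t = _jittered(
                    t, rng, cfg.jitter_sd, cfg.shape_sd, cfg.extent_sd, cfg.radius_sd
                )
                jt[name] = t
                vols[name] = rasterize_tube(t, cfg.grid_shape, cfg.affine)
            if "RS" in vols and "CSproper" in vols:
                if ctype == 1:
                    bridge = _bridge(jt["RS"], jt["CSproper"], cfg.bridge_radius)
                    bvol = rasterize_tube(bridge, cfg.grid_shape, cfg.affine)
                    merged = LabeledVolume(
                        ((vols["RS"].data > 0) | (bvol.data > 0)).astype(np.uint8),
                        cfg.affine,
                    )
                    vols["RS"] = merged
                    if classify_conformation(vols["RS"], vols["CSproper"]) != 1:
                        continue
                else:
                    if (
                        _min_intermask_distance(vols["RS"], vols["CSproper"])
                        < cfg.connection_gap
                    ):
                        continue
            return vols
        except ValueError:
            continue
    raise RuntimeError(
        f"could not realize a type-{ctype} {hemisphere} hemisphere within "
        f"{_MAX_RETRIES} retries; check jitter_sd / grid size"
    )


def _draw_morphometry(params, rng):
    """Positive, internally consistent (mean <= max) depth/length draws."""
    for _ in range(100):
        mx = rng.normal(*params["max_depth"])
        mn = rng.normal(*params["mean_depth"])
        ln = rng.normal(*params["length"])
        if mx > 0.5 and 0 < mn <= mx and ln > 0:
            return mx, mn, ln
    raise RuntimeError("could not draw valid morphometry; check depth_params")


def generate_cohort(cfg: CohortConfig):
    """Generate a full synthetic cohort.

    Returns
    -------
    masks : list of SubjectMask
        One mask per subject x hemisphere x structure.
    cohort : pandas.DataFrame
        One row per subject x hemisphere (age, sex, hemisphere volume and
        surface, conformation type).
    morphometry : pandas.DataFrame
        Surrogate per-sulcus depth/length measurements.

    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    subjects = [f"sub{i + 1:03d}" for i in range(n)]
    ages = np.round(rng.uniform(*cfg.age_range, size=n), 2)
    sexes = np.array(["F", "M"] * ((n + 1) // 2))[:n]
    rng.shuffle(sexes)

    masks, cohort_rows, morph_rows = [], [], []
    for si, sid in enumerate(subjects):
        for hemi in cfg.hemispheres:
            ctype = 1 if rng.random() < cfg.p_type1 else 2
            vols = _sample_hemisphere(cfg, hemi, ctype, rng)
            for name in cfg.structures:
                masks.append(
                    SubjectMask(sid, hemi, name, vols[name], conformation_type=ctype)
                )
            cohort_rows.append(
                {
                    "subject_id": sid,
                    "age": ages[si],
                    "sex": sexes[si],
                    "hemisphere": hemi,
                    "hemisphere_volume": float(np.round(rng.normal(5.5e5, 4.5e4), 1)),
                    "hemisphere_surface": float(np.round(rng.normal(8.0e4, 8.0e3), 1)),
                    "conformation_type": ctype,
                }
            )
            for name in cfg.structures:
                key = (name, hemi, ctype)
                if key not in cfg.depth_params:
                    continue
                mx, mn, ln = _draw_morphometry(cfg.depth_params[key], rng)
                morph_rows.append(
                    {
                        "subject_id": sid,
                        "hemisphere": hemi,
                        "sulcus": name,
                        "max_depth": round(mx, 2),
                        "mean_depth": round(mn, 2),
                        "length": round(ln, 2),
                        "conformation_type": ctype,
                    }
                )
    return masks, pd.DataFrame(cohort_rows), pd.DataFrame(morph_rows)


def sample_structure_masks(
    n: int,
    structure: str = "RS",
    hemisphere: str = "R",
    jitter_sd: float = 1.5,
    shape_sd=DEFAULT_SHAPE_SD,
    extent_sd: float = 4.0,
    radius_sd: float = 0.7,
    shift=(0.0, 0.0, 0.0),
    grid_shape=(48, 48, 48),
    tube_radius: float = 2.8,
    rng=None,
) -> list[LabeledVolume]:
    """Draw ``n`` jittered rasterizations of one sulcal template.

    A lean path for resampling studies that need many replicate groups of a
    single structure rather than full cohorts.  The grid is a compact
    1 mm cube centered on the (possibly shifted) template.  ``shift`` is a
    systematic mm offset applied on top of the per-mask jitter.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    template = default_templates(hemisphere, tube_radius)[structure]
    center = template.control_points.mean(axis=0)
    translation = np.round(center) - np.asarray(grid_shape) / 2.0
    affine = default_affine(tuple(translation))
    shift = np.asarray(shift, dtype=float)
    out = []
    for _ in range(n):
        for _ in range(_MAX_RETRIES):
            t = _jittered(
                template.translated(shift), rng, jitter_sd, shape_sd, extent_sd, radius_sd
            )
            try:
                out.append(rasterize_tube(t, grid_shape, affine))
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("template repeatedly left the grid; enlarge grid_shape")
    return out
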