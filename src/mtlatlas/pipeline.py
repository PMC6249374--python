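"""End-to-end experiment orchestration.

``run_experiment`` composes the whole analysis behind one configuration:
simulate a cohort -> per-structure probabilistic maps and blobs (5% and 25%
thresholds) -> extrema and centroid permutation tests between conformation
types -> line-fit direction comparisons -> cohort-level classical
statistics; everything lands in one JSON report plus a run manifest with
config snapshot, derived seeds and content hashes for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohortstats import (
    group_ttests,
    interhemispheric_type_correlation,
    proportion_test,
    summarize_types,
)
from .geometry import AXES, bounding_box, center_of_mass, fit_odr_line
from .io import write_cohort_table, write_json, write_mask, write_morphometry_table
from .permstats import (
    centroid_permutation_test,
    compare_directions,
    extrema_permutation_test,
)
from .probmap import build_probability_map, threshold_map
from .synth import CohortConfig, generate_cohort

__all__ = ["DEFAULT_CONFIG", "derive_seeds", "run_experiment"]

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {},  # CohortConfig overrides
    "smoothing_fwhm": 3.0,  # mm, applied to sulcal occurrence maps
    "fractions": [0.05, 0.25],
    "n_perm": 1000,
    "write_masks": False,
    "adult_reference_proportion": 0.28,  # literature Type-1 rate to test against
    "adult_reference_n": 25,
    "fdr_alpha": 0.05,
}

_STAGES = ("simulate", "maps", "extrema", "centroids", "cohort_stats")


def derive_seeds(seed: int) -> dict:
    """Deterministically derive one independent sub-seed per stage from the
    top-level seed, so stages can be re-run in isolation."""
    ss = np.random.SeedSequence(seed)
    states = [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(len(_STAGES))]
    return dict(zip(_STAGES, states))


def _hash_obj(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_experiment(config: dict | None = None, out_dir=None):
    """Run the full pipeline; returns ``(report, manifest)`` dicts.

    When ``out_dir`` is given, writes ``report.json``, ``manifest.json``,
    ``cohort.tsv``, ``morphometry.tsv`` (and the NIfTI masks when
    ``write_masks`` is true).
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seeds = derive_seeds(int(cfg["seed"]))
    t0 = time.time()

    # --- simulate -----------------------------------------------------
    cohort_cfg = CohortConfig(seed=seeds["simulate"], **cfg["cohort"])
    masks, cohort, morphometry = generate_cohort(cohort_cfg)

    structures = cohort_cfg.structures
    hemis = cohort_cfg.hemispheres
    fwhm = float(cfg["smoothing_fwhm"])
    fractions = tuple(cfg["fractions"])
    n_perm = int(cfg["n_perm"])

    report = {"seed": cfg["seed"], "version": __version__}

    # --- probabilistic maps and blob geometry (all subjects pooled) ---
    maps_section = {}
    for hemi in hemis:
        for structure in structures:
            group = [m for m in masks if m.hemisphere == hemi and m.structure == structure]
            pmap = build_probability_map(group, smoothing_fwhm=fwhm,
                                         structure=structure, hemisphere=hemi)
            entry = {"n_subjects": pmap.n_subjects, "smoothing_fwhm": fwhm}
            for f in fractions:
                blob = threshold_map(pmap, f)
                bb = bounding_box(blob)
                entry[f"blob@{f}"] = {
                    "n_voxels": blob.n_voxels,
                    "bounding_box": bb.as_dict(),
                    "center_of_mass": center_of_mass(blob).tolist(),
                }
            maps_section[f"{structure}_{hemi}"] = entry
    report["probabilistic_maps"] = maps_section

    # --- extrema permutation tests (Type 1 vs Type 2) ------------------
    extrema_section = {}
    n_significant = 0
    n_tests = 0
    for hemi in hemis:
        for structure in structures:
            group = [m for m in masks if m.hemisphere == hemi and m.structure == structure]
            results = extrema_permutation_test(
                group,
                fractions=fractions,
                smoothing_fwhm=fwhm,
                n_perm=n_perm,
                seed=seeds["extrema"],
            )
            extrema_section[f"{structure}_{hemi}"] = [
                r.as_dict(include_null=False) for r in results
            ]
            n_significant += sum(r.significant for r in results)
            n_tests += len(results)
    report["extrema_tests"] = extrema_section
    report["extrema_tests_summary"] = {
        "n_tests": n_tests, "n_significant": n_significant,
    }

    # --- centroid tests and line-direction comparison ------------------
    centroid_section = {}
    for hemi in hemis:
        for structure in structures:
            group = [m for m in masks if m.hemisphere == hemi and m.structure == structure]
            pts = np.array([center_of_mass(m) for m in group])
            labels = np.array([m.conformation_type for m in group])
            entry = {}
            for ax in AXES:
                res = centroid_permutation_test(
                    pts, labels, axis=ax, n_perm=n_perm, seed=seeds["centroids"]
                )
                entry[ax] = res.as_dict(include_null=False)
            if np.sum(labels == 1) >= 2 and np.sum(labels == 2) >= 2:
                fit1 = fit_odr_line(pts[labels == 1])
                fit2 = fit_odr_line(pts[labels == 2])
                entry["direction_comparison"] = compare_directions(fit1, fit2).as_dict()
                entry["direction_comparison"]["d_type1"] = fit1.d.tolist()
                entry["direction_comparison"]["d_type2"] = fit2.d.tolist()
            centroid_section[f"{structure}_{hemi}"] = entry
    report["centroid_tests"] = centroid_section

    # --- cohort statistics ---------------------------------------------
    summary = summarize_types(cohort)
    pct1, pct2 = summary.printed()
    prop = proportion_test(
        summary.n_type1,
        summary.n_hemispheres,
        float(cfg["adult_reference_proportion"]),
    )
    cov = cohort.copy()
    cov["sex_code"] = (cov["sex"] == "M").astype(float)  # 0/1 coding for the t path
    covariate_tests = group_ttests(
        cov,
        "conformation_type",
        ["age", "sex_code", "hemisphere_volume", "hemisphere_surface"],
        fdr_alpha=float(cfg["fdr_alpha"]),
    )
    morph_results = []
    for sulcus in structures:
        sub = morphometry[morphometry.sulcus == sulcus]
        if sub.conformation_type.nunique() == 2:
            morph_results.extend(
                group_ttests(
                    sub,
                    "conformation_type",
                    ["max_depth", "mean_depth", "length"],
                    fdr_alpha=float(cfg["fdr_alpha"]),
                )
            )
    report["cohort_stats"] = {
        "type_proportions": {
            "n_hemispheres": summary.n_hemispheres,
            "n_type1": summary.n_type1,
            "n_type2": summary.n_type2,
            "pct_type1": pct1,
            "pct_type2": pct2,
        },
        "proportion_vs_adult_reference": prop.as_dict(),
        "interhemispheric_type_correlation": interhemispheric_type_correlation(
            cohort
        ).as_dict(),
        "covariate_ttests": [r.as_dict() for r in covariate_tests],
        "morphometry_ttests": [r.as_dict() for r in morph_results],
    }

    manifest = {
        "version": __version__,
        "config": cfg,
        "derived_seeds": seeds,
        "elapsed_s": round(time.time() - t0, 2),
        "hashes": {
            "config": _hash_obj(cfg),
            "cohort_table": _hash_obj(cohort.to_dict("records")),
            "report": _hash_obj(report),
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_table(cohort, out_dir / "cohort.tsv")
        write_morphometry_table(morphometry, out_dir / "morphometry.tsv")
        if cfg["write_masks"]:
            for m in masks:
                write_mask(m, out_dir / "masks")
        write_json(report, out_dir / "report.json")
        write_json(manifest, out_dir / "manifest.json")
    return report, manifest
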