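"""End-to-end validation experiments on synthetic ground truth.

These routines drive the whole pipeline over seeded synthetic scenes and
summarize how well it recovers what the generator planted: maxima-oracle
agreement, compartment bookkeeping, intensity-ratio and foci recovery,
statistical calibration under the null, and detection of the
menadione-like treatment effect.  They back both the test suite and the
reproduction script, so every reported number is recomputed from scratch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .foci import MaximaParams, brute_force_maxima_oracle, find_maxima, find_nuclear_foci
from .intensity import compartment_intensities
from .pipeline import analyze_groups, process_image
from .segmentation import Compartment, ThresholdConfig, compute_nuclear_mask, segment
from .stats import GroupSample, select_and_run
from .synthetic import (
    DEFAULT_MAXIMA,
    DEFAULT_THRESHOLDS,
    MENADIONE_LIKE_EFFECT,
    SceneParams,
    generate_experiment,
)

__all__ = [
    "maxima_oracle_agreement",
    "partition_and_monotonicity",
    "nc_ratio_recovery",
    "foci_recovery",
    "null_calibration",
    "lognormal_gate_rate",
    "treatment_effect_detection",
]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def maxima_oracle_agreement(
    seed: int, n_planes: int = 100, tolerances: tuple[float, ...] = (0.0, 5.0, 15.0)
) -> dict:
    """Fraction of random planes on which find_maxima equals the oracle."""
    rng = np.random.default_rng(seed)
    total = agree = 0
    for _ in range(n_planes):
        plane = rng.integers(0, 50, size=(12, 12)).astype(float)
        for tol in tolerances:
            params = MaximaParams(noise_tolerance=tol)
            total += 1
            agree += find_maxima(plane, params) == brute_force_maxima_oracle(plane, params)
    return {"agreement": agree / total, "n": total}


def partition_and_monotonicity(seed: int, n_scenes: int = 10) -> dict:
    """Partition conservation and threshold monotonicity over a sweep."""
    violations = 0
    checks = 0
    for s in _seeds(seed, n_scenes):
        img, _ = _default_scene(s)
        total = img.height * img.width
        prev_cyt = None
        for bg_t in (0, 20, 40, 80, 160, 255):
            cfg = ThresholdConfig(dapi_threshold=90, background_threshold=bg_t)
            cmap = segment(img.blue, img.green, cfg)
            counts = np.bincount(cmap.classes.ravel(), minlength=3)
            checks += 1
            if counts.sum() != total:
                violations += 1
            cyt = int(counts[Compartment.CYTOSOL])
            if prev_cyt is not None and cyt > prev_cyt:
                violations += 1
            prev_cyt = cyt
        prev_area = None
        for dapi_t in (30, 60, 90, 150, 220):
            cfg = ThresholdConfig(dapi_threshold=dapi_t, background_threshold=30,
                                  fill_holes=False, min_nucleus_area=0)
            area = int((compute_nuclear_mask(img.blue, cfg) > 0).sum())
            checks += 1
            if prev_area is not None and area > prev_area:
                violations += 1
            prev_area = area
    return {"violations": violations, "n": checks}


def _default_scene(seed: int):
    from .synthetic import generate_scene

    return generate_scene(SceneParams(seed=seed))


def nc_ratio_recovery(seed: int, n_scenes: int = 20) -> dict:
    """Mean relative error of the recovered nuclear:cytosolic ratio."""
    errors = []
    jaccards = []
    for s in _seeds(seed, n_scenes):
        img, truth = _default_scene(s)
        cmap = segment(img.blue, img.green, DEFAULT_THRESHOLDS)
        rep = compartment_intensities(img.green, cmap)
        errors.append(abs(rep.nc_ratio / truth.true_nc_ratio - 1.0))
        rec, gt = cmap.nucleus_labels > 0, truth.nucleus_labels > 0
        jaccards.append((rec & gt).sum() / (rec | gt).sum())
    return {
        "mean_rel_error": float(np.mean(errors)),
        "mean_mask_jaccard": float(np.mean(jaccards)),
        "n": n_scenes,
    }


def foci_recovery(seed: int, n_scenes: int = 20, match_radius: float = 2.0) -> dict:
    """Recall/precision of detected foci against planted coordinates."""
    tp = fp = fn = 0
    density_errors = []
    for s in _seeds(seed, n_scenes):
        img, truth = _default_scene(s)
        cmap = segment(img.blue, img.green, DEFAULT_THRESHOLDS)
        res = find_nuclear_foci(img.green, cmap, DEFAULT_MAXIMA)
        planted = [(r, c) for r, c, _ in truth.foci_coordinates]
        unmatched = set(range(len(planted)))
        r2 = match_radius**2
        for r, c in res.foci:
            best, best_d = None, r2 + 1
            for i in unmatched:
                d = (r - planted[i][0]) ** 2 + (c - planted[i][1]) ** 2
                if d <= r2 and d < best_d:
                    best, best_d = i, d
            if best is None:
                fp += 1
            else:
                tp += 1
                unmatched.discard(best)
        fn += len(unmatched)
        if truth.true_foci_density > 0 and res.foci_density is not None:
            density_errors.append(abs(res.foci_density / truth.true_foci_density - 1.0))
    return {
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "mean_density_rel_error": float(np.mean(density_errors)),
        "n": n_scenes,
    }


def null_calibration(seed: int, n_reps: int = 2000, n_per_group: int = 1000) -> dict:
    """Two-group null rejection rate through the full gated procedure."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        groups = [
            GroupSample("treated", rng.normal(100, 30, n_per_group)),
            GroupSample("control", rng.normal(100, 30, n_per_group), is_control=True),
        ]
        comp = select_and_run(groups)
        hits += comp.omnibus_p <= 0.05
    return {"rejection_rate": hits / n_reps, "n": n_reps}


def lognormal_gate_rate(seed: int, n_reps: int = 200, n_per_group: int = 1000) -> dict:
    """How often lognormal data are routed to the non-parametric branch."""
    rng = np.random.default_rng(seed)
    routed = 0
    for _ in range(n_reps):
        groups = [
            GroupSample("treated", rng.lognormal(0, 1, n_per_group)),
            GroupSample("control", rng.lognormal(0, 1, n_per_group), is_control=True),
        ]
        comp = select_and_run(groups)
        routed += comp.chosen_test.startswith("mann_whitney")
    return {"nonparametric_rate": routed / n_reps, "n": n_reps}


def treatment_effect_detection(
    seed: int,
    n_reps: int = 50,
    n_images_per_group: int = 20,
    effect: tuple[float, float] = MENADIONE_LIKE_EFFECT,
    scene_params: SceneParams | None = None,
) -> dict:
    """Full-pipeline detection rate of a planted treatment effect.

    Each repetition simulates a fresh control-vs-treated experiment,
    runs segmentation, intensity and foci measurement on every image,
    and asks the gated statistics whether treated exceeds control in
    relative nuclear intensity and in foci density.
    """
    params = scene_params if scene_params is not None else SceneParams()
    sig_intensity = sig_foci = 0
    density_ratios = []
    for s in _seeds(seed, n_reps):
        scenes = generate_experiment(
            dataclasses.replace(params), effect=effect,
            n_images_per_group=n_images_per_group, seed=s,
        )
        analyses = [
            process_image(img, DEFAULT_THRESHOLDS, DEFAULT_MAXIMA, iid, group)
            for iid, group, img, _ in scenes.items()
        ]
        results = analyze_groups(analyses, "control", unit="per_image")
        sig_intensity += results["relative_nuclear_intensity"].omnibus_p <= 0.05
        sig_foci += results["foci_density"].omnibus_p <= 0.05
        dens = {g: np.mean([a.foci.foci_density for a in analyses if a.group == g])
                for g in ("control", "treated")}
        if dens["control"] > 0:
            density_ratios.append(dens["treated"] / dens["control"])
    return {
        "intensity_detection_rate": sig_intensity / n_reps,
        "foci_detection_rate": sig_foci / n_reps,
        "mean_density_ratio": float(np.mean(density_ratios)),
        "n": n_reps,
    }
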