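"""Batch driver: segment, quantify, detect foci, compare groups.

One run = one configuration: per-series thresholds set on a reference
image and propagated unchanged, a maxima noise tolerance, the choice of
replication unit (per nucleus or per image), and the control group.
Outputs are deterministic CSV tables plus a machine-readable JSON
summary; identical configuration and inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .foci import FociResult, MaximaParams, find_nuclear_foci
from .intensity import (
    IntensityReport,
    NucleusIntensity,
    compartment_intensities,
    normalize_to_control,
    per_nucleus_intensities,
)
from .segmentation import (
    CompartmentMap,
    ThresholdConfig,
    compute_nuclear_mask,
    classify_compartments,
)
from .stats import GroupComparison, GroupSample, select_and_run

__all__ = [
    "RunConfig",
    "ImageAnalysis",
    "process_image",
    "analyze_groups",
    "run_pipeline",
    "audit_export",
]

log = logging.getLogger("fociquant")

AnalysisUnit = Literal["per_nucleus", "per_image"]


@dataclass
class RunConfig:
    """Everything one batch run needs.

    ``manifest`` is a YAML file naming image files per condition group
    and the control group; paths are relative to the manifest location.
    """

    manifest: str
    thresholds: ThresholdConfig
    maxima: MaximaParams
    output_dir: str
    unit: AnalysisUnit = "per_nucleus"
    alpha: float = 0.05
    combine: str = "all"
    channel_order: dict[int, str] | None = None
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class ImageAnalysis:
    """All per-image products of the measurement stages."""

    image_id: str
    group: str
    cmap: CompartmentMap
    intensity: IntensityReport
    nuclei: list[NucleusIntensity]
    foci: FociResult
    green: np.ndarray | None = None

    def record(self) -> dict:
        r = self.intensity
        return {
            "image_id": self.image_id,
            "group": self.group,
            "nuclear_mean": r.nuclear_mean,
            "cytosolic_mean": r.cytosolic_mean,
            "background_mean": r.background_mean,
            "nc_ratio": r.nc_ratio,
            "foci_count": self.foci.foci_count,
            "nuclear_area": r.nuclear_area,
            "foci_density": self.foci.foci_density,
        }


def process_image(
    image: fio.MultiChannelImage,
    thresholds: ThresholdConfig,
    maxima: MaximaParams,
    image_id: str = "",
    group: str = "",
) -> ImageAnalysis:
    """Mask, classify, quantify and count foci for one image."""
    image_id = image_id or image.source_id
    labels = compute_nuclear_mask(image.blue, thresholds)
    cmap = classify_compartments(image.green, labels, thresholds)
    report = compartment_intensities(image.green, cmap, image_id=image_id)
    nuclei = per_nucleus_intensities(image.green, cmap, image_id=image_id)
    foci = find_nuclear_foci(image.green, cmap, maxima, image_id=image_id)
    log.debug(
        "%s: %d nuclei, nuclear mean %s, %d foci",
        image_id, cmap.n_nuclei, report.nuclear_mean, foci.foci_count,
    )
    return ImageAnalysis(
        image_id=image_id, group=group, cmap=cmap,
        intensity=report, nuclei=nuclei, foci=foci, green=np.asarray(image.green),
    )


def _metric_samples(
    analyses: list[ImageAnalysis], unit: AnalysisUnit, control_group: str
) -> dict[str, list[GroupSample]]:
    """Assemble per-group samples of the two headline metrics.

    ``nuclear_intensity`` is the raw (not yet control-normalized) nuclear
    mean per replication unit; ``foci_density`` is foci per pixel of
    nuclear area per unit.  Units without a defined value are dropped.
    """
    by_group: dict[str, dict[str, list[float]]] = {}
    for a in analyses:
        g = by_group.setdefault(a.group, {"nuclear_intensity": [], "foci_density": []})
        if unit == "per_image":
            if a.intensity.nuclear_mean is not None:
                g["nuclear_intensity"].append(a.intensity.nuclear_mean)
            if a.foci.foci_density is not None:
                g["foci_density"].append(a.foci.foci_density)
        else:
            for nuc in a.nuclei:
                g["nuclear_intensity"].append(nuc.mean)
                count = a.foci.per_nucleus_counts.get(nuc.label, 0)
                g["foci_density"].append(count / nuc.area)
    out: dict[str, list[GroupSample]] = {}
    for metric in ("nuclear_intensity", "foci_density"):
        out[metric] = [
            GroupSample(
                label=group,
                values=np.array(vals[metric]),
                is_control=(group == control_group),
            )
            for group, vals in by_group.items()
            if vals[metric]
        ]
    return out


def analyze_groups(
    analyses: list[ImageAnalysis],
    control_group: str,
    unit: AnalysisUnit = "per_nucleus",
    alpha: float = 0.05,
    combine: str = "all",
) -> dict[str, GroupComparison]:
    """Gated statistics on nuclear intensity and foci density.

    Intensity enters the comparison as percentages of the control mean
    (control = 100 %); the normalization is a positive linear map, so
    p-values equal those on the raw scale while the reported group means
    are on the familiar relative scale.
    """
    samples = _metric_samples(analyses, unit, control_group)
    results: dict[str, GroupComparison] = {}
    for metric, groups in samples.items():
        if len(groups) < 2:
            continue
        if metric == "nuclear_intensity":
            control = next((g for g in groups if g.is_control), None)
            if control is not None:
                groups = [
                    GroupSample(
                        label=g.label,
                        values=normalize_to_control(g.values, control.values),
                        is_control=g.is_control,
                    )
                    for g in groups
                ]
                metric = "relative_nuclear_intensity"
        results[metric] = select_and_run(groups, alpha=alpha, combine=combine)
    return results


def _read_manifest(path: str) -> tuple[str, dict[str, list[str]]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "groups" not in doc or not doc["groups"]:
        raise ValueError(f"manifest {path} lists no groups")
    base = os.path.dirname(os.path.abspath(path))
    groups = {
        g: [os.path.join(base, f) for f in files]
        for g, files in doc["groups"].items()
    }
    for g, files in groups.items():
        if not files:
            raise ValueError(f"manifest group {g!r} lists no images")
    control = doc.get("control")
    if control is not None and control not in groups:
        raise ValueError(f"control group {control!r} not among groups {list(groups)}")
    return control, groups


def _comparison_rows(results: dict[str, GroupComparison]) -> list[dict]:
    rows = []
    for metric in sorted(results):
        comp = results[metric]
        for c in comp.comparisons:
            rows.append(
                {
                    "metric": metric,
                    "comparison": c.label,
                    "chosen_test": comp.chosen_test,
                    "p_value": c.p_value,
                    "adjusted": c.adjusted,
                    "stars": c.stars,
                }
            )
    return rows


def _summary_dict(
    config: RunConfig, analyses: list[ImageAnalysis], results: dict[str, GroupComparison]
) -> dict:
    per_group: dict[str, dict] = {}
    for a in analyses:
        g = per_group.setdefault(a.group, {"images": 0, "nuclei": 0, "foci": 0})
        g["images"] += 1
        g["nuclei"] += a.cmap.n_nuclei
        g["foci"] += a.foci.foci_count
    stats_block = {}
    for metric, comp in results.items():
        stats_block[metric] = {
            "chosen_test": comp.chosen_test,
            "comparisons": {
                c.label: {"p_value": c.p_value, "stars": c.stars}
                for c in comp.comparisons
            },
            "normality_p": {
                g: v.per_test_p for g, v in comp.normality.items()
            },
            "gaussian": {g: v.gaussian for g, v in comp.normality.items()},
        }
    return {
        "config": {
            "thresholds": dataclasses.asdict(config.thresholds),
            "noise_tolerance": config.maxima.noise_tolerance,
            "unit": config.unit,
            "alpha": config.alpha,
            "combine": config.combine,
        },
        "groups": per_group,
        "statistics": stats_block,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Process every image of the manifest and write all result tables.

    Writes ``per_image.csv``, ``per_nucleus.csv``, ``foci.csv``,
    ``comparisons.csv`` and ``summary.json`` into the output directory
    and returns the summary dict.  Any stage failure raises with the
    failing image named.
    """
    logging.basicConfig(level=config.log_level)
    control, groups = _read_manifest(config.manifest)
    os.makedirs(config.output_dir, exist_ok=True)
    log.info(
        "thresholds: dapi=%s background=%s tolerance=%s (propagated per series)",
        config.thresholds.dapi_threshold,
        config.thresholds.background_threshold,
        config.maxima.noise_tolerance,
    )

    analyses: list[ImageAnalysis] = []
    for group, files in groups.items():
        for path in files:
            image_id = os.path.basename(path)
            try:
                img = fio.load_image(path, channel_order=config.channel_order)
                analyses.append(
                    process_image(img, config.thresholds, config.maxima, image_id, group)
                )
            except Exception as exc:
                raise RuntimeError(f"failed processing image {path}: {exc}") from exc

    fio.write_results_table(
        [a.record() for a in analyses], os.path.join(config.output_dir, "per_image.csv")
    )
    nucleus_rows = [
        {
            "image_id": a.image_id,
            "group": a.group,
            "nucleus_label": nuc.label,
            "mean": nuc.mean,
            "total": nuc.total,
            "area": nuc.area,
            "foci_count": a.foci.per_nucleus_counts.get(nuc.label, 0),
            "foci_density": a.foci.per_nucleus_counts.get(nuc.label, 0) / nuc.area,
        }
        for a in analyses
        for nuc in a.nuclei
    ]
    fio.write_results_table(
        nucleus_rows,
        os.path.join(config.output_dir, "per_nucleus.csv"),
        columns=[
            "image_id", "group", "nucleus_label", "mean", "total",
            "area", "foci_count", "foci_density",
        ],
    )
    foci_rows = [
        {
            "image_id": a.image_id,
            "group": a.group,
            "row": r,
            "col": c,
            "nucleus_label": int(a.cmap.nucleus_labels[r, c]),
        }
        for a in analyses
        for r, c in a.foci.foci
    ]
    fio.write_results_table(
        foci_rows,
        os.path.join(config.output_dir, "foci.csv"),
        columns=["image_id", "group", "row", "col", "nucleus_label"],
    )

    results: dict[str, GroupComparison] = {}
    if control is not None and len(groups) >= 2:
        results = analyze_groups(
            analyses, control, unit=config.unit, alpha=config.alpha,
            combine=config.combine,
        )
        fio.write_results_table(
            _comparison_rows(results),
            os.path.join(config.output_dir, "comparisons.csv"),
            columns=["metric", "comparison", "chosen_test", "p_value", "adjusted", "stars"],
        )
        for metric, comp in results.items():
            for g, v in comp.normality.items():
                log.info("%s / %s normality p-values: %s", metric, g, v.per_test_p)
            log.info("%s: %s -> %s", metric, comp.chosen_test, comp.stars)

    summary = _summary_dict(config, analyses, results)
    with open(os.path.join(config.output_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def audit_export(
    analysis: ImageAnalysis, output_dir: str
) -> tuple[str, str]:
    """Write the visual-QC overlays for one processed image.

    The compartment mask PNG encodes background/cytosol/nucleus as
    0/85/170 — the manual check that the propagated threshold suits the
    image.  The foci overlay marks each detected focus as a red pixel on
    the grayscale green channel.
    """
    import imageio.v3 as iio

    os.makedirs(output_dir, exist_ok=True)
    mask_path = os.path.join(output_dir, f"{analysis.image_id}_compartments.png")
    iio.imwrite(mask_path, (analysis.cmap.classes.astype(np.uint8) * 85))

    overlay = np.zeros((*analysis.cmap.classes.shape, 3), dtype=np.uint8)
    if analysis.green is not None:
        # display-only rescale; measurements are never rescaled
        disp = (255.0 * analysis.green / max(float(analysis.green.max()), 1.0)).astype(
            np.uint8
        )
        overlay[:, :, 0] = disp
        overlay[:, :, 1] = disp
        overlay[:, :, 2] = disp
    for r, c in analysis.foci.foci:
        overlay[r, c] = (255, 0, 0)
    foci_path = os.path.join(output_dir, f"{analysis.image_id}_foci.png")
    iio.imwrite(foci_path, overlay)
    return mask_path, foci_path
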