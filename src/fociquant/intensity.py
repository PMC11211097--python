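"""Per-compartment intensity quantification and control normalization.

Means are computed over the raw green values of each compartment;
background is measured but never subtracted (the protocol thresholds it
away instead).  Group intensities are expressed relative to the control
group, whose mean is defined as 100 %.

Both per-image and per-nucleus summaries are provided; the choice of
replication unit is left to the statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Compartment, CompartmentMap

__all__ = [
    "IntensityReport",
    "NucleusIntensity",
    "compartment_intensities",
    "per_nucleus_intensities",
    "normalize_to_control",
]


@dataclass
class IntensityReport:
    """Per-image compartment intensity summary.

    A mean is ``None`` when its compartment has zero pixels; ``nc_ratio``
    (nuclear_mean / cytosolic_mean) is ``None`` when undefined.
    """

    image_id: str
    nuclear_mean: float | None
    cytosolic_mean: float | None
    background_mean: float | None
    nuclear_total: float
    nuclear_area: int
    cytosolic_area: int
    nc_ratio: float | None


@dataclass
class NucleusIntensity:
    """Green-channel summary of one labeled nuclear object."""

    image_id: str
    label: int
    mean: float
    total: float
    area: int


def _masked_mean(plane: np.ndarray, mask: np.ndarray) -> tuple[float | None, float, int]:
    area = int(mask.sum())
    if area == 0:
        return None, 0.0, 0
    total = float(plane[mask].sum(dtype=np.float64))
    return total / area, total, area


def compartment_intensities(
    green: np.ndarray, cmap: CompartmentMap, image_id: str = ""
) -> IntensityReport:
    """Mean green intensity of nucleus, cytosol and background.

    Raises ``ValueError`` on shape mismatch.  Compartments with zero
    pixels yield ``None`` means; the nuclear:cytosolic ratio is ``None``
    whenever either constituent is undefined.
    """
    green = np.asarray(green)
    if green.shape != cmap.classes.shape:
        raise ValueError(
            f"shape mismatch: green {green.shape} vs map {cmap.classes.shape}"
        )
    nuc_mean, nuc_total, nuc_area = _masked_mean(
        green, cmap.classes == Compartment.NUCLEUS
    )
    cyt_mean, _, cyt_area = _masked_mean(green, cmap.classes == Compartment.CYTOSOL)
    bg_mean, _, _ = _masked_mean(green, cmap.classes == Compartment.BACKGROUND)
    ratio = None
    if nuc_mean is not None and cyt_mean is not None and cyt_mean > 0:
        ratio = nuc_mean / cyt_mean
    return IntensityReport(
        image_id=image_id,
        nuclear_mean=nuc_mean,
        cytosolic_mean=cyt_mean,
        background_mean=bg_mean,
        nuclear_total=nuc_total,
        nuclear_area=nuc_area,
        cytosolic_area=cyt_area,
        nc_ratio=ratio,
    )


def per_nucleus_intensities(
    green: np.ndarray, cmap: CompartmentMap, image_id: str = ""
) -> list[NucleusIntensity]:
    """Green-channel mean/total/area for each labeled nucleus."""
    green = np.asarray(green, dtype=np.float64)
    if green.shape != cmap.nucleus_labels.shape:
        raise ValueError("shape mismatch between green plane and nucleus labels")
    n = cmap.n_nuclei
    if n == 0:
        return []
    labels = cmap.nucleus_labels
    totals = np.bincount(labels.ravel(), weights=green.ravel(), minlength=n + 1)
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    return [
        NucleusIntensity(
            image_id=image_id,
            label=k,
            mean=float(totals[k] / areas[k]),
            total=float(totals[k]),
            area=int(areas[k]),
        )
        for k in range(1, n + 1)
        if areas[k] > 0
    ]


def normalize_to_control(
    sample_values: np.ndarray | list[float], control_values: np.ndarray | list[float]
) -> np.ndarray:
    """Express values as percentages of the control mean (control = 100 %).

    Every value v maps to ``100 * v / mean(control_values)``; normalizing
    the control group against itself therefore gives a mean of exactly
    100.  Raises ``ValueError`` when the control mean is not positive.
    """
    control = np.asarray(control_values, dtype=np.float64)
    if control.size == 0:
        raise ValueError("control group is empty")
    cmean = control.mean()
    if cmean <= 0:
        raise ValueError(f"control mean must be positive, got {cmean}")
    return 100.0 * np.asarray(sample_values, dtype=np.float64) / cmean
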