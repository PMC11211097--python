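"""DAPI-driven nuclear masking and three-way pixel compartmentalization.

The blue (DAPI) channel defines the nuclear mask by a user-set global
threshold; on the green channel every non-nuclear pixel is classified as
cytosol ("not nucleus, but brighter than the background") or background.
Thresholds are set once on a reference image of a series and propagated
unchanged to the remaining images of that series — no per-image
adaptation.

Strictness convention: a pixel exactly at a threshold is *not* signal
(non-nucleus for DAPI, background for green).  Connected components use
8-connectivity.  Touching nuclei are not split; downstream foci density
is normalized by area, which is robust to merged nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "Compartment",
    "ThresholdConfig",
    "CompartmentMap",
    "compute_nuclear_mask",
    "classify_compartments",
    "segment",
    "propagate_threshold",
    "suggest_dapi_threshold",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


class Compartment(IntEnum):
    """Per-pixel class: every pixel is exactly one of the three."""

    BACKGROUND = 0
    CYTOSOL = 1
    NUCLEUS = 2


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-series segmentation thresholds on the native intensity scale.

    ``dapi_threshold`` binarizes the blue channel (pixels strictly above
    are nuclear candidates); ``background_threshold`` separates cytosol
    from background on the green channel; nuclear components smaller than
    ``min_nucleus_area`` pixels are discarded; ``fill_holes`` fills
    interior holes of each nuclear component.
    """

    dapi_threshold: float
    background_threshold: float
    min_nucleus_area: int = 50
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.dapi_threshold < 0 or self.background_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_nucleus_area < 0:
            raise ValueError("min_nucleus_area must be >= 0")


@dataclass
class CompartmentMap:
    """Pixel classes plus per-nucleus instance labels.

    ``nucleus_labels`` is 0 outside nuclei and ``k >= 1`` on the k-th
    connected nuclear object (top-left-first scan order).  Invariant:
    ``classes == NUCLEUS`` exactly where ``nucleus_labels >= 1``.
    """

    classes: np.ndarray
    nucleus_labels: np.ndarray
    n_nuclei: int

    @property
    def nuclear_area(self) -> int:
        return int((self.nucleus_labels > 0).sum())


def suggest_dapi_threshold(blue: np.ndarray) -> float:
    """Otsu auto-suggestion for the DAPI threshold (advisory only).

    The pipeline never applies it silently; the user sets the threshold
    on a reference image, as in the manual-threshold protocol.
    """
    return float(threshold_otsu(np.asarray(blue)))


def _relabel_scan_order(labels: np.ndarray, n: int) -> tuple[np.ndarray, int]:
    """Renumber labels 1..n by the scan-order position of each object's
    first (top-left-first) pixel."""
    if n == 0:
        return labels, 0
    flat = labels.ravel()
    first_pos = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier positions overwrite later ones
    first_pos[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_pos[1:], kind="stable")  # old label-1 -> rank
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    return remap[labels], n


def compute_nuclear_mask(blue: np.ndarray, config: ThresholdConfig) -> np.ndarray:
    """Binarize the DAPI plane and label nuclear objects.

    Mask = ``blue > dapi_threshold``; interior holes filled if configured;
    8-connected components below ``min_nucleus_area`` removed; survivors
    labeled 1..n in top-left-first scan order.  An all-zero plane is a
    valid input yielding zero nuclei.
    """
    blue = np.asarray(blue)
    mask = blue > config.dapi_threshold
    if config.fill_holes:
        mask = ndimage.binary_fill_holes(mask, structure=_STRUCT8)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n and config.min_nucleus_area > 0:
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        keep = np.flatnonzero(areas[1:] >= config.min_nucleus_area) + 1
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[keep] = np.arange(1, keep.size + 1)
        labels = remap[labels]
        n = keep.size
    labels, n = _relabel_scan_order(labels, n)
    return labels


def classify_compartments(
    green: np.ndarray, nucleus_labels: np.ndarray, config: ThresholdConfig
) -> CompartmentMap:
    """Three-way classification of every pixel.

    NUCLEUS where a nuclear label is present; elsewhere CYTOSOL if the
    green value is strictly above ``background_threshold``, else
    BACKGROUND.  The three classes partition the image.
    """
    green = np.asarray(green)
    nucleus_labels = np.asarray(nucleus_labels)
    if green.shape != nucleus_labels.shape:
        raise ValueError(
            f"shape mismatch: green {green.shape} vs labels {nucleus_labels.shape}"
        )
    classes = np.full(green.shape, Compartment.BACKGROUND, dtype=np.uint8)
    classes[green > config.background_threshold] = Compartment.CYTOSOL
    in_nucleus = nucleus_labels > 0
    classes[in_nucleus] = Compartment.NUCLEUS
    return CompartmentMap(
        classes=classes,
        nucleus_labels=nucleus_labels,
        n_nuclei=int(nucleus_labels.max()),
    )


def segment(blue: np.ndarray, green: np.ndarray, config: ThresholdConfig) -> CompartmentMap:
    """Convenience: nuclear mask from blue, then compartments on green."""
    return classify_compartments(green, compute_nuclear_mask(blue, config), config)


def propagate_threshold(
    reference_config: ThresholdConfig, series: Sequence[str]
) -> dict[str, ThresholdConfig]:
    """Copy one reference configuration to every image of a series.

    Each image receives an identical, independent copy — editing the
    reference afterwards cannot alter already-issued configs, and two
    series with distinct references never cross-contaminate.
    """
    series = list(series)
    if not series:
        raise ValueError("empty series: a series needs at least one image id")
    return {image_id: replace(reference_config) for image_id in series}
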