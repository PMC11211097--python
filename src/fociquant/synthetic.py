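"""Synthetic immunofluorescence scenes with known ground truth.

Scenes emulate fields of adherent cultured cells imaged in two channels:
bright elliptical nuclei on the blue (DAPI) channel, and on the green
(immunostain) channel a dark background, a diffuse cytosolic halo around
each nucleus, an elevated nuclear level, and punctate intranuclear foci
modeled as isotropic Gaussian bumps (a standard PSF-limited spot model).
Additive Gaussian read noise is applied to both channels and values are
clipped to the representable range of the chosen bit depth.

The oxidative-stress experiment is emulated at the data level by a named
"menadione-like" preset: treated scenes carry 1.5x the nuclear green
level and 3x the expected foci load of the control, mirroring the
direction (not any published magnitude) of the treatment effect the
pipeline is meant to detect.

Every generator draw flows from one integer seed; identical parameters
give bit-identical scenes.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import tifffile
import yaml

from .io import MultiChannelImage
from .segmentation import ThresholdConfig, _relabel_scan_order
from .foci import MaximaParams

__all__ = [
    "SceneParams",
    "GroundTruth",
    "ExperimentScenes",
    "MENADIONE_LIKE_EFFECT",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_MAXIMA",
    "generate_scene",
    "generate_experiment",
    "write_experiment",
]

#: (nuclear green multiplier, foci-load multiplier) of the treated group.
MENADIONE_LIKE_EFFECT = (1.5, 3.0)

#: Segmentation thresholds matched to the generator's default contrast:
#: DAPI 90 sits between the dark blue background (~0) and the nuclear
#: level (180); green background threshold 30 sits >3 noise sd above the
#: background level (10) and well below the cytosolic level (60).
DEFAULT_THRESHOLDS = ThresholdConfig(
    dapi_threshold=90, background_threshold=30, min_nucleus_area=50, fill_holes=True
)

#: Default noise tolerance 30 = one third of the focus amplitude and five
#: noise sd: noise excursions never survive, planted foci always do.
DEFAULT_MAXIMA = MaximaParams(noise_tolerance=30.0)


@dataclass(frozen=True)
class SceneParams:
    """Geometry, photometry and noise of one synthetic field of cells.

    Intensity levels are on the native scale of ``bit_depth``.
    ``foci_per_nucleus`` is the Poisson mean of the planted foci count.
    """

    width: int = 256
    height: int = 256
    n_nuclei: int = 6
    nucleus_axes: tuple[float, float] = (13.0, 19.0)
    nucleus_blue_level: float = 180.0
    nuclear_green_level: float = 120.0
    cytosol_green_level: float = 60.0
    cytosol_halo_width: int = 6
    background_green_level: float = 10.0
    foci_per_nucleus: float = 3.0
    focus_amplitude: float = 90.0
    focus_sigma: float = 1.5
    noise_sd: float = 6.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        limit = 2**self.bit_depth - 1
        levels = (
            self.nucleus_blue_level,
            self.nuclear_green_level,
            self.cytosol_green_level,
            self.background_green_level,
        )
        if any(not 0 <= lv <= limit for lv in levels):
            raise ValueError(f"intensity levels must lie in [0, {limit}]")
        if self.nuclear_green_level < self.background_green_level:
            raise ValueError("nuclear green level must be >= background level")
        if self.nucleus_axes[0] > self.nucleus_axes[1] or self.nucleus_axes[0] <= 0:
            raise ValueError("nucleus_axes must be (min, max) with min > 0")


@dataclass
class GroundTruth:
    """What the generator actually planted.

    ``true_nc_ratio`` and ``true_foci_density`` are computed from the
    noise-free expectation scene (foci bumps included, clipping applied),
    so they are exactly what an ideal measurement would recover.
    """

    nucleus_labels: np.ndarray
    foci_coordinates: list[tuple[int, int, int]]  # (row, col, nucleus label)
    true_nc_ratio: float
    true_foci_density: float

    @property
    def n_nuclei(self) -> int:
        return int(self.nucleus_labels.max())

    @property
    def foci_count(self) -> int:
        return len(self.foci_coordinates)


class PlacementError(RuntimeError):
    """Non-overlapping nucleus placement failed within the retry budget."""


def _ellipse_mask(h, w, cy, cx, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_nuclei(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping ellipses (>=2 px apart); labels
    are assigned in top-left-first scan order like the segmentation stage."""
    h, w = params.height, params.width
    a_min, a_max = params.nucleus_axes
    margin = a_max + params.cytosol_halo_width + 2
    if 2 * margin >= min(h, w):
        raise PlacementError("image too small for the requested nucleus size")
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    struct = np.ones((5, 5), dtype=bool)  # 2 px clearance
    placed = 0
    for _ in range(200 * params.n_nuclei):
        if placed == params.n_nuclei:
            break
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        a = rng.uniform(a_min, a_max)
        b = rng.uniform(a_min, a_max)
        theta = rng.uniform(0, math.pi)
        mask = _ellipse_mask(h, w, cy, cx, a, b, theta)
        if (mask & occupied).any():
            continue
        placed += 1
        labels[mask] = placed
        from scipy.ndimage import binary_dilation

        occupied |= binary_dilation(mask, structure=struct)
    if placed < params.n_nuclei:
        raise PlacementError(
            f"placed only {placed}/{params.n_nuclei} non-overlapping nuclei"
        )
    labels, _ = _relabel_scan_order(labels, placed)
    return labels


def _plant_foci(
    labels: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Poisson-sample foci per nucleus at interior positions.

    Foci model distinct damage puncta: centers keep a margin of
    ~2 focus sigmas from the nucleus boundary and a minimum mutual
    separation of ~4 sigmas so planted spots remain resolvable peaks.
    If a crowded nucleus cannot host its full draw, fewer are planted —
    the returned list is always the truth.
    """
    from scipy.ndimage import binary_erosion

    margin = max(2, math.ceil(2 * params.focus_sigma))
    min_sep = max(3.0, 4.0 * params.focus_sigma)
    struct = np.ones((2 * margin + 1, 2 * margin + 1), dtype=bool)
    foci: list[tuple[int, int, int]] = []
    for k in range(1, int(labels.max()) + 1):
        target = int(rng.poisson(params.foci_per_nucleus))
        if target == 0:
            continue
        interior = binary_erosion(labels == k, structure=struct)
        cand = np.argwhere(interior)
        if cand.size == 0:
            continue
        order = rng.permutation(len(cand))
        chosen: list[np.ndarray] = []
        for idx in order:
            p = cand[idx]
            if all(np.hypot(*(p - q)) >= min_sep for q in chosen):
                chosen.append(p)
                if len(chosen) == target:
                    break
        foci.extend((int(r), int(c), k) for r, c in chosen)
    return foci


def generate_scene(params: SceneParams) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one two-channel scene and its ground truth.

    Identical ``params`` (including the seed) give bit-identical output.
    """
    from scipy.ndimage import binary_dilation

    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    maxval = 2**params.bit_depth - 1
    labels = _place_nuclei(params, rng)
    nuclei = labels > 0
    halo_r = params.cytosol_halo_width
    yy, xx = np.mgrid[-halo_r : halo_r + 1, -halo_r : halo_r + 1]
    disk = yy**2 + xx**2 <= halo_r**2
    halo = binary_dilation(nuclei, structure=disk) & ~nuclei

    green = np.full((h, w), params.background_green_level, dtype=np.float64)
    green[halo] = params.cytosol_green_level
    green[nuclei] = params.nuclear_green_level

    foci = _plant_foci(labels, params, rng)
    sig = params.focus_sigma
    rad = math.ceil(4 * sig)
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    bump = params.focus_amplitude * np.exp(-(yy**2 + xx**2) / (2 * sig**2))
    for r, c, _ in foci:
        r0, r1 = max(r - rad, 0), min(r + rad + 1, h)
        c0, c1 = max(c - rad, 0), min(c + rad + 1, w)
        green[r0:r1, c0:c1] += bump[
            r0 - (r - rad) : bump.shape[0] - ((r + rad + 1) - r1),
            c0 - (c - rad) : bump.shape[1] - ((c + rad + 1) - c1),
        ]
    green_clean = np.clip(green, 0, maxval)

    nuc_area = int(nuclei.sum())
    true_nc = float(green_clean[nuclei].mean() / green_clean[halo].mean())
    true_density = len(foci) / nuc_area if nuc_area else float("nan")

    blue_clean = np.where(nuclei, params.nucleus_blue_level, 0.0)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    blue = np.clip(
        np.rint(blue_clean + rng.normal(0, params.noise_sd, (h, w))), 0, maxval
    ).astype(dtype)
    green_noisy = np.clip(
        np.rint(green_clean + rng.normal(0, params.noise_sd, (h, w))), 0, maxval
    ).astype(dtype)

    image = MultiChannelImage(
        channels={"blue": blue, "green": green_noisy},
        bit_depth=params.bit_depth,
        source_id=f"scene-{params.seed}",
    )
    truth = GroundTruth(
        nucleus_labels=labels,
        foci_coordinates=foci,
        true_nc_ratio=true_nc,
        true_foci_density=true_density,
    )
    return image, truth


@dataclass
class ExperimentScenes:
    """Two-group in-memory experiment: scenes plus their ground truths."""

    groups: dict[str, list[tuple[MultiChannelImage, GroundTruth]]]
    control_group: str = "control"

    def items(self) -> Iterator[tuple[str, str, MultiChannelImage, GroundTruth]]:
        for group, scenes in self.groups.items():
            for i, (img, truth) in enumerate(scenes):
                yield f"{group}_{i:03d}", group, img, truth


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def generate_experiment(
    control_params: SceneParams = SceneParams(),
    effect: tuple[float, float] = MENADIONE_LIKE_EFFECT,
    n_images_per_group: int = 20,
    seed: int = 0,
) -> ExperimentScenes:
    """Control and treated scene groups differing only by the effect.

    ``effect`` multiplies the treated group's nuclear green level and
    expected foci per nucleus; ``(1.0, 1.0)`` is the exchangeable null.
    The treated nuclear level is capped at the representable maximum.
    """
    if n_images_per_group < 1:
        raise ValueError("need at least 1 image per group")
    if effect[0] <= 0 or effect[1] <= 0:
        raise ValueError("effect multipliers must be positive")
    maxval = 2**control_params.bit_depth - 1
    treated_params = replace(
        control_params,
        nuclear_green_level=min(control_params.nuclear_green_level * effect[0], maxval),
        foci_per_nucleus=control_params.foci_per_nucleus * effect[1],
    )
    seeds = _child_seeds(seed, 2 * n_images_per_group)
    groups: dict[str, list] = {"control": [], "treated": []}
    for i in range(n_images_per_group):
        groups["control"].append(
            generate_scene(replace(control_params, seed=int(seeds[i])))
        )
        groups["treated"].append(
            generate_scene(
                replace(treated_params, seed=int(seeds[n_images_per_group + i]))
            )
        )
    return ExperimentScenes(groups=groups, control_group="control")


def write_experiment(scenes: ExperimentScenes, outdir: str | os.PathLike) -> str:
    """Write scenes as multi-plane TIFFs plus a YAML group manifest.

    Each TIFF holds the (red, green, blue) planes in that order (red is a
    zero plane, mirroring an RGB confocal export).  Ground-truth foci go
    to ``<image>_truth.csv``.  Returns the manifest path.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"control": scenes.control_group, "groups": {}}
    for image_id, group, img, truth in scenes.items():
        fname = f"{image_id}.tif"
        stack = np.stack(
            [np.zeros_like(img.green), img.green, img.blue]
        )  # R, G, B planes
        tifffile.imwrite(
            os.path.join(outdir, fname), stack,
            photometric="rgb", planarconfig="separate",
        )
        manifest["groups"].setdefault(group, []).append(fname)
        with open(os.path.join(outdir, f"{image_id}_truth.csv"), "w") as fh:
            fh.write("row,col,nucleus_label\n")
            for r, c, k in truth.foci_coordinates:
                fh.write(f"{r},{c},{k}\n")
    path = os.path.join(outdir, "manifest.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
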