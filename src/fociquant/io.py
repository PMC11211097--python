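"""Reading multichannel microscopy images and writing tabular results.

Confocal exports arrive either as a single RGB raster (one file, three
colour planes) or as one grayscale file per channel.  Both are supported;
pixel data are passed through unmodified — no rescaling, gamma or
denoising.  Coordinates are row-major, 0-based ``(row, col)`` throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile

__all__ = [
    "MultiChannelImage",
    "DEFAULT_CHANNEL_ORDER",
    "load_image",
    "load_planes",
    "write_results_table",
    "read_results_table",
    "RESULT_COLUMNS",
]

#: RGB plane index -> channel name, the usual microscope export order.
DEFAULT_CHANNEL_ORDER: dict[int, str] = {0: "red", 1: "green", 2: "blue"}

#: Deterministic column order of the per-image results table.
RESULT_COLUMNS = [
    "image_id",
    "group",
    "nuclear_mean",
    "cytosolic_mean",
    "background_mean",
    "nc_ratio",
    "foci_count",
    "nuclear_area",
    "foci_density",
]


@dataclass
class MultiChannelImage:
    """Registered 2-D intensity planes, one per named colour channel.

    Invariants: all planes share one shape; values lie in
    ``[0, 2**bit_depth - 1]``; ``"blue"`` and ``"green"`` are present
    after a successful load.
    """

    channels: dict[str, np.ndarray]
    bit_depth: int
    source_id: str = ""
    height: int = field(init=False)
    width: int = field(init=False)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel planes differ in shape: {sorted(shapes)}")
        self.height, self.width = next(iter(shapes))
        limit = 2**self.bit_depth - 1
        for name, plane in self.channels.items():
            if plane.ndim != 2:
                raise ValueError(f"channel {name!r} is not a 2-D plane")
            if plane.min() < 0 or plane.max() > limit:
                raise ValueError(
                    f"channel {name!r} has values outside [0, {limit}]"
                )

    @property
    def blue(self) -> np.ndarray:
        return self.channels["blue"]

    @property
    def green(self) -> np.ndarray:
        return self.channels["green"]


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ValueError(f"unsupported pixel dtype {arr.dtype} (expected uint8/uint16)")


def _read_raster(path: str | os.PathLike) -> np.ndarray:
    if not os.path.exists(path):
        raise IOError(f"cannot read image file: {path}")
    spath = str(path)
    try:
        if spath.lower().endswith((".tif", ".tiff")):
            return tifffile.imread(spath)
        return iio.imread(spath)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"cannot read image file: {path}: {exc}") from exc


def load_image(
    path: str | os.PathLike,
    channel_order: Mapping[int, str] | None = None,
) -> MultiChannelImage:
    """Load a single-file RGB (or multi-plane) raster and split channels.

    ``channel_order`` maps colour-plane index to channel name; override it
    for microscopes exporting BGR.  Pixel values are the file's values,
    bit-exact.

    Raises ``IOError`` for unreadable files and ``ValueError`` when the
    blue or green plane is missing after splitting.
    """
    order = dict(channel_order) if channel_order is not None else dict(DEFAULT_CHANNEL_ORDER)
    arr = _read_raster(path)
    if arr.ndim == 3 and arr.shape[0] <= 4 and arr.shape[0] < arr.shape[-1]:
        planes = {i: arr[i] for i in range(arr.shape[0])}  # C x H x W TIFF
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4):  # H x W x C
        planes = {i: arr[:, :, i] for i in range(min(arr.shape[-1], 3))}
    elif arr.ndim == 3 and arr.shape[0] <= 4:
        planes = {i: arr[i] for i in range(arr.shape[0])}
    elif arr.ndim == 2:
        raise ValueError(
            f"{path}: single grayscale plane; use load_planes() with an "
            "explicit channel name instead"
        )
    else:
        raise ValueError(f"{path}: unsupported raster shape {arr.shape}")

    channels = {}
    for idx, name in order.items():
        if idx in planes:
            channels[name] = np.ascontiguousarray(planes[idx])
    for required in ("blue", "green"):
        if required not in channels:
            raise ValueError(
                f"{path}: no {required!r} plane under channel order {order}"
            )
    depth = _bit_depth_of(next(iter(channels.values())))
    return MultiChannelImage(
        channels=channels, bit_depth=depth, source_id=os.path.basename(str(path))
    )


def load_planes(
    channel_paths: Mapping[str, str | os.PathLike],
    source_id: str | None = None,
) -> MultiChannelImage:
    """Load per-channel grayscale files, e.g. ``{"blue": ..., "green": ...}``.

    All planes must share one shape; a mismatch raises ``ValueError``.
    """
    channels: dict[str, np.ndarray] = {}
    for name, path in channel_paths.items():
        arr = _read_raster(path)
        if arr.ndim == 3 and arr.shape[-1] == 1:
            arr = arr[:, :, 0]
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a grayscale plane, got shape {arr.shape}")
        channels[name] = np.ascontiguousarray(arr)
    for required in ("blue", "green"):
        if required not in channels:
            raise ValueError(f"missing required channel {required!r}")
    shapes = {a.shape for a in channels.values()}
    if len(shapes) != 1:
        raise ValueError(f"channel files differ in shape: {sorted(shapes)}")
    depth = max(_bit_depth_of(a) for a in channels.values())
    sid = source_id or os.path.basename(str(next(iter(channel_paths.values()))))
    return MultiChannelImage(channels=channels, bit_depth=depth, source_id=sid)


def write_results_table(
    records: Sequence[Mapping], path: str | os.PathLike, columns: Sequence[str] | None = None
) -> None:
    """Write per-image result rows as RFC-4180 CSV with a header row.

    Column order is fixed (``RESULT_COLUMNS`` by default) so reruns are
    byte-identical.  An empty record list yields a header-only file.
    """
    cols = list(columns) if columns is not None else list(RESULT_COLUMNS)
    frame = pd.DataFrame(list(records), columns=cols)
    try:
        frame.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise IOError(f"cannot write results table: {path}: {exc}") from exc


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    return pd.read_csv(path)
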