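"""Image-stack I/O: multichannel TIFFs, pixel-size metadata, max projection.

The in-memory container is :class:`ImageStack`: an intensity array indexed
``(channel, row, col)`` or ``(channel, z, row, col)`` with square-pixel size
in µm.  Stacks written by this module carry their metadata (axes, channel
names, pixel size, z step, bit depth) in the TIFF description, and round-trip
exactly.  Foreign TIFFs are accepted when the pixel size can be recovered
from ImageJ/resolution tags or is supplied explicitly; the reader fails
rather than guessing, and rejects anisotropic pixels (all area measurements
assume square pixels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "MetadataError",
    "read_stack",
    "write_stack",
    "max_project",
    "read_manifest",
]

MANIFEST_COLUMNS = ("path", "group", "timepoint_h", "pixel_size_um")


class MetadataError(ValueError):
    """Required image metadata is missing or inconsistent."""


@dataclass
class ImageStack:
    """A multichannel, optionally z-stacked intensity image.

    ``data`` has axes ``(channel, row, col)`` (2-D) or
    ``(channel, z, row, col)`` (z-stacked).  Coordinates are row-major,
    0-based, with pixel centers at integer coordinates.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size: float            # µm per pixel, x == y
    z_step: float | None = None  # µm, None for 2-D stacks
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"data must have axes (channel, [z,] row, col); got ndim={self.data.ndim}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}") from None
        return self.data[idx]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF with self-describing metadata."""
    meta = {
        "axes": "CZYX" if stack.has_z else "CYX",
        "channel_names": list(stack.channel_names),
        "pixel_size_um": float(stack.pixel_size),
        "z_step_um": None if stack.z_step is None else float(stack.z_step),
        "bit_depth": int(stack.bit_depth),
    }
    tifffile.imwrite(str(path), stack.data, photometric="minisblack", metadata=meta)


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    """Recover µm pixel size from ImageJ metadata plus resolution tags."""
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is None or yres is None:
        return None
    def _value(tag):
        num, den = tag.value
        return num / den if den else None
    px_per_unit_x = _value(xres)
    px_per_unit_y = _value(yres)
    if not px_per_unit_x or not px_per_unit_y:
        return None
    unit = None
    if tif.imagej_metadata:
        unit = tif.imagej_metadata.get("unit")
    scale = {"um": 1.0, "micron": 1.0, "µm": 1.0, "µm": 1.0}.get(unit)
    if scale is None:
        return None
    size_x = scale / px_per_unit_x
    size_y = scale / px_per_unit_y
    if abs(size_x - size_y) > 1e-9 * max(size_x, size_y):
        raise MetadataError(
            f"anisotropic pixels ({size_x:.6g} x {size_y:.6g} µm) are not supported")
    return size_x


def _arrange_axes(data: np.ndarray, axes: str) -> tuple[np.ndarray, bool]:
    """Transpose a tifffile series to (C, [Z,] Y, X); returns (data, has_z)."""
    axes = axes.upper()
    # generic page axes count as channels
    axes = axes.replace("I", "C").replace("Q", "C").replace("S", "C")
    if len(set(axes)) != len(axes) or set(axes) - {"C", "Z", "Y", "X"}:
        raise MetadataError(f"cannot interpret TIFF axes {axes!r}")
    order = [ax for ax in ("C", "Z", "Y", "X") if ax in axes]
    data = np.transpose(data, [axes.index(ax) for ax in order])
    if "C" not in order:
        data = data[np.newaxis]
    return data, "Z" in order


def read_stack(path: str | Path, pixel_size_override: float | None = None) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Pixel size comes from this package's own metadata, then from
    ImageJ-style resolution tags, then from ``pixel_size_override``;
    a file with none of these raises :class:`MetadataError`.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        shaped = tif.shaped_metadata
        meta = dict(shaped[0]) if shaped else {}
        tag_pixel_size = None if meta else _pixel_size_from_tags(tif)

    if meta.get("pixel_size_um"):
        axes = meta.get("axes", series.axes)
        data, has_z = _arrange_axes(data, axes)
        names = list(meta.get("channel_names") or
                     [f"ch{i}" for i in range(data.shape[0])])
        z_step = meta.get("z_step_um")
        return ImageStack(
            data=data,
            channel_names=names,
            pixel_size=float(meta["pixel_size_um"]),
            z_step=None if z_step is None else float(z_step),
            bit_depth=int(meta.get("bit_depth", 8 if data.dtype == np.uint8 else 16)),
        )

    pixel_size = tag_pixel_size if tag_pixel_size is not None else pixel_size_override
    if pixel_size is None:
        raise MetadataError(
            f"{path}: no pixel size in TIFF metadata and no override given")
    data, has_z = _arrange_axes(data, series.axes if data.ndim > 2 else "YX")
    names = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(
        data=data,
        channel_names=names,
        pixel_size=float(pixel_size),
        bit_depth=8 if data.dtype == np.uint8 else 16,
    )


def max_project(stack: ImageStack) -> ImageStack:
    """Maximal projection over z: per channel, per pixel maximum.

    The standard reduction applied to confocal z-series before focus
    counting.  Requires a z axis; projecting an already-2-D stack is a
    precondition error.
    """
    if not stack.has_z:
        raise ValueError("max_project: stack has no z axis")
    return ImageStack(
        data=stack.data.max(axis=1),
        channel_names=list(stack.channel_names),
        pixel_size=stack.pixel_size,
        z_step=None,
        bit_depth=stack.bit_depth,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a CSV manifest with columns path, group, timepoint_h, pixel_size_um."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing columns {missing}")
    if (df["pixel_size_um"] <= 0).any():
        raise ValueError(f"manifest {path}: pixel_size_um must be > 0")
    return df
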