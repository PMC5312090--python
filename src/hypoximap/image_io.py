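"""Reading and writing of image stacks, label/region masks and blob tables.

Stacks are multi-page TIFFs. Two channel layouts are accepted: a single file
with channel-interleaved pages (page ``s * n_channels + c`` holds section
``s`` of channel ``c``) or one single-channel file per channel. Intensities
are carried at native depth and never rescaled on read.
"""

from __future__ import annotations

import dataclasses
import os
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Stack",
    "RegionMask",
    "read_stack",
    "write_stack",
    "read_region_mask",
    "write_region_mask",
    "read_label_image",
    "write_label_image",
    "write_rgb_stack",
    "write_blob_table",
    "read_blob_table",
]


@dataclass
class Stack:
    """A multi-channel confocal stack with anisotropic voxel spacing.

    Parameters
    ----------
    channels
        Ordered mapping of channel name to a 3D array (sections, rows, cols).
        Typical channels are the ``sensor`` (GFP-ODD) and the nuclear
        ``reference`` (mRFP-nls) signal.
    spacing_xy, spacing_z
        In-plane pixel size and section interval, in micrometres.
    bit_depth
        Sample depth of the source data (informational; arrays may be float).
    """

    channels: dict[str, np.ndarray]
    spacing_xy: float
    spacing_z: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        ref_shape = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError(f"channels must be 3D (sections, rows, cols); got {shapes}")
        if any(s != ref_shape for s in shapes.values()):
            raise ValueError(f"channels have mismatched dimensions: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.size and float(np.min(arr)) < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
        for label, v in (("spacing_xy", self.spacing_xy), ("spacing_z", self.spacing_z)):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{label} must be strictly positive and finite, got {v}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_sections(self) -> int:
        return self.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not in stack (have {self.channel_names})")
        return self.channels[name]

    def scaled(self, factors: Mapping[str, float]) -> "Stack":
        """Return a copy with each named channel multiplied by a constant."""
        chans = {
            name: np.asarray(arr, dtype=np.float64) * factors.get(name, 1.0)
            for name, arr in self.channels.items()
        }
        return dataclasses.replace(self, channels=chans)


@dataclass
class RegionMask:
    """Per-voxel anatomical region labelling (0 = unassigned).

    ``names`` maps every nonzero label to a region name, e.g.
    ``{1: "CB", 2: "OL"}`` for central brain and optic lobe.
    """

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    UNASSIGNED = "unassigned"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("region labels must be a 3D array")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = sorted(present - set(self.names))
        if missing:
            raise ValueError(f"unnamed region label {missing[0]}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def name_at(self, section: int, row: int, col: int) -> str:
        label = int(self.labels[section, row, col])
        return self.names.get(label, self.UNASSIGNED) if label else self.UNASSIGNED

    def region_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels).tolist()) - {0})


def _read_pages(path: str | os.PathLike) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"cannot read image file: {path}")
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def read_stack(
    path: str | os.PathLike | Mapping[str, str | os.PathLike],
    channel_map: Mapping[int, str] | None = None,
    spacing_xy: float = 1.0,
    spacing_z: float = 1.0,
    bit_depth: int | None = None,
) -> Stack:
    """Read a multi-channel stack from TIFF.

    ``path`` is either a single multi-page TIFF with interleaved channel
    pages (then ``channel_map`` maps channel index to channel name) or a
    mapping of channel name to a per-channel TIFF file.
    """
    if isinstance(path, Mapping):
        channels: dict[str, np.ndarray] = {}
        shape = None
        for name, p in path.items():
            arr = _read_pages(p)
            if shape is not None and arr.shape != shape:
                raise ValueError(
                    f"channel {name!r} has shape {arr.shape}, expected {shape}"
                )
            shape = arr.shape
            channels[name] = arr
    else:
        if not channel_map:
            raise ValueError("channel_map is required for a single-file stack")
        pages = _read_pages(path)
        n_chan = len(channel_map)
        if pages.shape[0] % n_chan:
            raise ValueError(
                f"page count {pages.shape[0]} is not a multiple of {n_chan} channels"
            )
        bad = [i for i in channel_map if not 0 <= i < n_chan]
        if bad:
            raise ValueError(f"channel index out of range: {bad[0]} (have {n_chan} channels)")
        n_sections = pages.shape[0] // n_chan
        interleaved = pages.reshape(n_sections, n_chan, *pages.shape[1:])
        channels = {name: interleaved[:, idx] for idx, name in sorted(channel_map.items())}
    if bit_depth is None:
        dt = next(iter(channels.values())).dtype
        bit_depth = dt.itemsize * 8 if dt.kind in "ui" else 16
    return Stack(channels, spacing_xy=spacing_xy, spacing_z=spacing_z, bit_depth=bit_depth)


def write_stack(stack: Stack, path: str | os.PathLike) -> None:
    """Write a stack as a channel-interleaved multi-page TIFF (deflate)."""
    arrs = list(stack.channels.values())
    inter = np.stack(arrs, axis=1)  # (sections, channels, rows, cols)
    pages = inter.reshape(-1, *inter.shape[2:])
    tifffile.imwrite(os.fspath(path), pages, compression="zlib", photometric="minisblack")


def read_label_image(path: str | os.PathLike) -> np.ndarray:
    """Read a 3D integer label image (nuclei or regions) from TIFF."""
    arr = _read_pages(path)
    if arr.dtype.kind not in "ui":
        raise ValueError(f"label image must be integer-typed, got {arr.dtype}")
    return arr.astype(np.int32)


def write_label_image(labels: np.ndarray, path: str | os.PathLike) -> None:
    labels = np.asarray(labels)
    dtype = np.uint16 if labels.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(os.fspath(path), labels.astype(dtype), compression="zlib", photometric="minisblack")


def read_region_mask(
    path: str | os.PathLike,
    names: Mapping[int, str],
    stack: Stack | None = None,
) -> RegionMask:
    """Read a region mask TIFF, validating names and (optionally) dimensions."""
    labels = read_label_image(path)
    mask = RegionMask(labels, dict(names))
    if stack is not None and mask.shape != stack.shape:
        raise ValueError(
            f"region mask shape {mask.shape} does not match stack shape {stack.shape}"
        )
    return mask


def write_region_mask(mask: RegionMask, path: str | os.PathLike) -> None:
    write_label_image(mask.labels, path)


def write_rgb_stack(rgb: np.ndarray, path: str | os.PathLike) -> None:
    """Write an (sections, rows, cols, 3) uint8 RGB rendering."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 4 or rgb.shape[-1] != 3:
        raise ValueError("expected an (S, H, W, 3) RGB array")
    tifffile.imwrite(os.fspath(path), rgb.astype(np.uint8), photometric="rgb", compression="zlib")


def write_blob_table(table, path: str | os.PathLike) -> None:
    """Write a BlobTable as CSV with metadata in ``#`` comment lines."""
    df = table.records
    if len(df) and not np.all(np.isfinite(df["ratio"].to_numpy()[df["valid"].to_numpy()])):
        raise ValueError("blob table contains non-finite ratios flagged as valid")
    with open(path, "w", newline="") as fh:
        fh.write(f"# specimen_id: {table.specimen_id}\n")
        norm = table.normalization
        if norm:
            fh.write(f"# normalization: {norm['scheme']} factor={norm['factor']!r}\n")
        else:
            fh.write("# normalization: none\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_blob_table(path: str | os.PathLike):
    """Read a blob-table CSV written by :func:`write_blob_table`."""
    from .ratiometrics import BlobTable

    specimen_id = ""
    normalization = None
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line[1:].strip()
            if body.startswith("specimen_id:"):
                specimen_id = body.split(":", 1)[1].strip()
            elif body.startswith("normalization:"):
                desc = body.split(":", 1)[1].strip()
                if not desc.startswith("none"):
                    scheme, factor = desc.split(" factor=")
                    normalization = {"scheme": scheme, "factor": float(factor)}
            pos = fh.tell()
        df = pd.read_csv(fh, float_precision="round_trip")
    return BlobTable(records=df, specimen_id=specimen_id, normalization=normalization)
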