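"""Volumetric image-stack containers and TIFF I/O.

All pipeline stages operate on :class:`VoxelGrid`: a 3D greyscale intensity
volume with an isotropic voxel edge length in micrometres and a fixed axis
convention ``(z, y, x)`` where ``z`` is the slice index along the flower
axis and ``z = 0`` is the flower base (peduncle end). Indexing is 0-based
and all index intervals are half-open.

Stacks scanned tip-first can be brought into this convention with
:func:`reorient` (or the ``--flip-z`` CLI flag).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

AXIS_ORDER = ("z", "y", "x")

MaskLabel = str  # semantic tag: tissue | air | nectary | nectar | bee


@dataclass
class VoxelGrid:
    """3D greyscale volume (16-bit intensity range) with isotropic spacing.

    Parameters
    ----------
    data
        Integer intensity array of shape ``(z, y, x)``.
    spacing_um
        Voxel edge length in micrometres (isotropic), > 0.
    """

    data: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("grid data must be 3D with all dimensions >= 1")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.data.dtype.kind not in "ui":
            raise TypeError("grid intensities must be integer-typed")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 65535):
            raise ValueError("intensities must lie in [0, 65535]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """Boolean voxel mask on the same grid as its source volume."""

    data: np.ndarray
    spacing_um: float
    label: MaskLabel = "tissue"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class CropBox:
    """Per-axis half-open index intervals ``[lo, hi)`` in (z, y, x) order."""

    z: tuple[int, int]
    y: tuple[int, int]
    x: tuple[int, int]

    def validate(self, shape: Sequence[int]) -> None:
        for (lo, hi), dim, name in zip((self.z, self.y, self.x), shape, AXIS_ORDER):
            if not (0 <= lo < hi <= dim):
                raise ValueError(
                    f"crop interval [{lo}, {hi}) out of bounds for axis {name} of size {dim}"
                )

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.z), slice(*self.y), slice(*self.x))


_NUMERAL = re.compile(r"\d+")


def _sorted_slice_files(directory: Path) -> list[Path]:
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff"))
    if not files:
        raise FileNotFoundError(f"no TIFF slices found in {directory}")
    # lexicographic order is slice order; warn when numerals are unpadded,
    # because then lexicographic != numeric order (slice_2 after slice_10)
    nums = [_NUMERAL.findall(p.stem) for p in files]
    widths = {len(n[-1]) for n in nums if n}
    if len(widths) > 1:
        logger.warning(
            "slice filenames in %s have unpadded numerals; "
            "lexicographic order may not match numeric slice order", directory,
        )
    return files


def read_stack(path: str | Path, spacing_um: float) -> VoxelGrid:
    """Read a multi-page TIFF or a directory of slice TIFFs into a VoxelGrid.

    Slice order is the page order for a multi-page file, or the
    lexicographic filename order for a directory; slice 0 becomes ``z = 0``.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist or the directory holds no TIFFs.
    ValueError
        On inconsistent slice shapes or non-8/16-bit samples, naming the
        offending file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if path.is_dir():
        files = _sorted_slice_files(path)
        slices = []
        first_shape = None
        for f in files:
            arr = tifffile.imread(f)
            if arr.ndim != 2:
                raise ValueError(f"slice {f} is not a single 2D image")
            if arr.dtype not in (np.dtype("uint8"), np.dtype("uint16")):
                raise ValueError(
                    f"slice {f} has dtype {arr.dtype}; only 8-bit or 16-bit "
                    "greyscale samples are supported"
                )
            if first_shape is None:
                first_shape = arr.shape
            elif arr.shape != first_shape:
                raise ValueError(
                    f"slice {f} has shape {arr.shape}, expected {first_shape}"
                )
            slices.append(arr)
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.dtype not in (np.dtype("uint8"), np.dtype("uint16")):
            raise ValueError(
                f"{path} has dtype {data.dtype}; only 8-bit or 16-bit "
                "greyscale samples are supported"
            )
    return VoxelGrid(data=data.astype(np.uint16, copy=False), spacing_um=spacing_um)


def write_stack(grid: VoxelGrid | BinaryMask, path: str | Path) -> Path:
    """Write a grid (16-bit) or mask (8-bit, 0/255) as a multi-page TIFF.

    A JSON sidecar ``<path>.json`` records the voxel spacing and the axis
    convention, so round-trips preserve metadata.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(grid, BinaryMask):
        data = np.where(grid.data, 255, 0).astype(np.uint8)
    else:
        data = grid.data.astype(np.uint16, copy=False)
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "spacing_um": float(grid.spacing_um),
        "axis_order": list(AXIS_ORDER),
        "z_base": "z=0 is the flower base (peduncle end)",
    }
    if isinstance(grid, BinaryMask):
        sidecar["label"] = grid.label
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_sidecar(path: str | Path) -> dict:
    """Read the JSON sidecar written next to a stack by :func:`write_stack`."""
    return json.loads(Path(str(path) + ".json").read_text())


def crop(grid: VoxelGrid, box: CropBox) -> VoxelGrid:
    """Extract the half-open sub-volume ``box``; spacing is unchanged."""
    box.validate(grid.shape)
    return VoxelGrid(data=grid.data[box.slices()].copy(), spacing_um=grid.spacing_um)


def reorient(
    grid: VoxelGrid,
    flips: tuple[bool, bool, bool] = (False, False, False),
    axis_permutation: tuple[int, int, int] = (0, 1, 2),
) -> VoxelGrid:
    """Axis-aligned reorientation: flip axes, then permute them.

    Only flips and axis permutations are supported — interpolating rotation
    would resample intensities and bias the volumes that are the primary
    measurand. The voxel multiset is preserved exactly, and applying the
    inverse (``reorient(g', inverse flips after permutation, inverse
    permutation)``) restores the original grid.
    """
    if sorted(axis_permutation) != [0, 1, 2]:
        raise ValueError(f"invalid axis permutation: {axis_permutation}")
    data = grid.data
    flip_axes = [i for i, f in enumerate(flips) if f]
    if flip_axes:
        data = np.flip(data, axis=flip_axes)
    data = np.transpose(data, axes=axis_permutation)
    return VoxelGrid(data=data.copy(), spacing_um=grid.spacing_um)


def inverse_reorient(
    grid: VoxelGrid,
    flips: tuple[bool, bool, bool] = (False, False, False),
    axis_permutation: tuple[int, int, int] = (0, 1, 2),
) -> VoxelGrid:
    """Undo a :func:`reorient` performed with the same arguments."""
    inv_perm = tuple(int(np.argsort(axis_permutation)[i]) for i in range(3))
    data = np.transpose(grid.data, axes=inv_perm)
    flip_axes = [i for i, f in enumerate(flips) if f]
    if flip_axes:
        data = np.flip(data, axis=flip_axes)
    return VoxelGrid(data=data.copy(), spacing_um=grid.spacing_um)
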