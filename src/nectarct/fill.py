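"""Nectar-level reconstruction from a measured nectar volume.

A glass-capillary nectar measurement gives a volume in µL; this module
projects that volume back into the flower: air voxels are accumulated
from the flower base upward, in deterministic (z, y, x) scan order, until
the accumulated voxel volume reaches the measured one. By default only
air 6-connected to the basal air component is eligible — nectar pools in
the nectar chamber, not in disconnected pockets. The result can be
exported as a mask stack plus per-slice tinted overlays on the greyscale
images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .volgrid import BinaryMask, VoxelGrid, write_stack


@dataclass
class FillResult:
    """Outcome of filling air with nectar up to a target volume.

    ``achieved_ul`` always satisfies
    ``0 <= achieved_ul - target_ul < voxel_volume_ul(spacing)`` unless the
    eligible air was exhausted first (``truncated``).
    """

    nectar_mask: BinaryMask
    target_ul: float
    achieved_ul: float
    voxels_used: int
    top_z: int            # highest filled slice index, -1 if none
    truncated: bool


def voxel_volume_ul(spacing_um: float) -> float:
    """Volume of one voxel in µL: spacing³ µm³ × 1e−9 (1 µL = 1e9 µm³).

    At the 5 µm scan resolution one voxel is 5×5×5 = 125 µm³ = 1.25e−7 µL.
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    return spacing_um**3 * 1e-9


def air_mask(grid: VoxelGrid, threshold: float) -> BinaryMask:
    """Air = the darker voxels: intensity strictly below the threshold.

    Complementary to the tissue mask at the same threshold, so the two
    partitions never overlap or leave gaps.
    """
    return BinaryMask(grid.data < threshold, grid.spacing_um, "air")


def _eligible_air(
    air: np.ndarray, base_seed_z: int | None
) -> tuple[np.ndarray, int]:
    """Air restricted to component(s) touching the basal air slice."""
    if base_seed_z is None:
        zs = np.nonzero(air.any(axis=(1, 2)))[0]
        if len(zs) == 0:
            return air.copy(), 0
        base_seed_z = int(zs[0])
    labels, n = ndimage.label(air)  # default structure = 6-connectivity
    seed_labels = np.unique(labels[base_seed_z])
    seed_labels = seed_labels[seed_labels != 0]
    return np.isin(labels, seed_labels), base_seed_z


def fill_to_volume(
    air: BinaryMask,
    target_ul: float,
    spacing_um: float | None = None,
    restrict_to_base_component: bool = True,
    base_seed_z: int | None = None,
) -> FillResult:
    """Accumulate air voxels base-upward until the target volume is reached.

    Voxels are visited in (z ascending, y ascending, x ascending) order;
    accumulation stops at the first voxel where the achieved volume
    reaches or exceeds the target, so the result is never under-filled and
    overshoots by less than one voxel. With
    ``restrict_to_base_component`` (default) only air 6-connected to the
    air component touching ``base_seed_z`` (default: the lowest slice
    containing air) is eligible. If the eligible air runs out first the
    result is flagged ``truncated``.
    """
    if target_ul < 0:
        raise ValueError("target volume must be non-negative")
    sp = air.spacing_um if spacing_um is None else spacing_um
    vox = voxel_volume_ul(sp)

    if restrict_to_base_component:
        eligible, _ = _eligible_air(air.data, base_seed_z)
    else:
        eligible = air.data

    # smallest n with n * vox >= target, robust to float rounding either way
    if target_ul <= 0:
        n_needed = 0
    else:
        n_needed = int(math.ceil(target_ul / vox))
        while n_needed > 0 and (n_needed - 1) * vox >= target_ul:
            n_needed -= 1
        while n_needed * vox < target_ul:
            n_needed += 1
    per_slice = eligible.sum(axis=(1, 2))
    cum = np.cumsum(per_slice)
    total = int(cum[-1]) if len(cum) else 0

    mask = np.zeros_like(eligible)
    if n_needed >= total:
        mask = eligible.copy()
        used = total
        truncated = n_needed > total
    else:
        # full slices below the waterline, then a partial slice in (y, x) order
        z_full = int(np.searchsorted(cum, n_needed, side="left"))
        below = int(cum[z_full - 1]) if z_full > 0 else 0
        mask[:z_full] = eligible[:z_full]
        remainder = n_needed - below
        if remainder > 0:
            ys, xs = np.nonzero(eligible[z_full])
            mask[z_full, ys[:remainder], xs[:remainder]] = True
        used = n_needed
        truncated = False

    zs = np.nonzero(mask.any(axis=(1, 2)))[0]
    return FillResult(
        nectar_mask=BinaryMask(mask, sp, "nectar"),
        target_ul=target_ul,
        achieved_ul=used * vox,
        voxels_used=used,
        top_z=int(zs[-1]) if len(zs) else -1,
        truncated=truncated,
    )


def overlay_export(
    grid: VoxelGrid,
    nectar_mask: BinaryMask,
    out_dir: str | Path,
    tint: tuple[int, int, int] = (255, 210, 0),
    alpha: float = 0.55,
) -> Path:
    """Write the nectar mask stack and per-slice tinted composites.

    The mask is saved as an 8-bit TIFF stack (``nectar_mask.tif``) and
    each slice as an RGB PNG with nectar voxels blended toward ``tint``
    (yellow, as nectar is usually rendered).
    """
    if grid.shape != nectar_mask.shape:
        raise ValueError("grid and nectar mask shapes differ")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_stack(nectar_mask, out_dir / "nectar_mask.tif")

    gmax = max(int(grid.data.max()), 1)
    for z in range(grid.shape[0]):
        grey = (grid.data[z].astype(np.float64) / gmax * 255.0)
        rgb = np.stack([grey] * 3, axis=-1)
        m = nectar_mask.data[z]
        for c in range(3):
            ch = rgb[..., c]
            ch[m] = (1 - alpha) * ch[m] + alpha * tint[c]
        Image.fromarray(np.clip(np.rint(rgb), 0, 255).astype(np.uint8)).save(
            out_dir / f"overlay_{z:04d}.png"
        )
    return out_dir
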