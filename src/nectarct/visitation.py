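"""Pollinator-accessibility modeling by rigid superposition.

Three voxel datasets — the flower tissue, the reconstructed nectar volume
and a bee-head solid — are superimposed on one grid. The original
flower-visit rendering was posed manually; this module defines a minimal
deterministic proxy instead: the head descends along the flower axis in
one-voxel steps, laterally centered on the corolla opening, and the
deepest collision-free position yields the accessibility measures (an
extension of the manual procedure, not a reproduction of it). Only
integer translations and axis-aligned flips are considered; rotational
pose search is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volgrid import BinaryMask

logger = logging.getLogger(__name__)

LABEL_BG, LABEL_TISSUE, LABEL_NECTAR, LABEL_BEE, LABEL_OVERLAP = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class RigidPlacement:
    """Integer voxel translation (dz, dy, dx) plus optional axis flips,
    applied to the bee mask before compositing onto the flower grid."""

    dz: int = 0
    dy: int = 0
    dx: int = 0
    flips: tuple[bool, bool, bool] = (False, False, False)


@dataclass
class VisitationReport:
    """Accessibility summary at the deepest collision-free head position."""

    max_depth_mm: float
    depth_vox: int
    overlap_voxels: int          # 0 at the reported placement
    rim_z: int
    head_bottom_z: int           # z of the head's lowest voxel when placed
    placement: RigidPlacement
    nectar_reachable: bool | None = None
    proboscis_length_mm: float | None = None


def place_mask(bee: BinaryMask, placement: RigidPlacement,
               shape: tuple[int, int, int]) -> np.ndarray:
    """Bee mask flipped, translated by integer voxels and clipped to shape."""
    m = bee.data
    flip_axes = [i for i, f in enumerate(placement.flips) if f]
    if flip_axes:
        m = np.flip(m, axis=flip_axes)
    out = np.zeros(shape, dtype=bool)
    src = []
    dst = []
    for axis, d in enumerate((placement.dz, placement.dy, placement.dx)):
        lo = max(0, -d)
        hi = min(m.shape[axis], shape[axis] - d)
        if hi <= lo:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo + d, hi + d))
    out[tuple(dst)] = m[tuple(src)]
    return out


def superimpose(
    flower_tissue: BinaryMask,
    nectar: BinaryMask,
    bee: BinaryMask,
    placement: RigidPlacement,
) -> np.ndarray:
    """Composite label volume: tissue=1, nectar=2, bee=3, bee∧tissue=4."""
    for other in (nectar, bee):
        if abs(other.spacing_um - flower_tissue.spacing_um) > 1e-9:
            raise ValueError("masks must share voxel spacing")
    if nectar.shape != flower_tissue.shape:
        raise ValueError("flower and nectar must share a grid")
    shape = flower_tissue.shape
    bee_arr = place_mask(bee, placement, shape)
    comp = np.zeros(shape, dtype=np.uint8)
    comp[flower_tissue.data] = LABEL_TISSUE
    comp[nectar.data] = LABEL_NECTAR
    comp[bee_arr] = LABEL_BEE
    comp[bee_arr & flower_tissue.data] = LABEL_OVERLAP
    return comp


def detect_rim(flower_tissue: BinaryMask) -> int:
    """Topmost slice whose tissue footprint is annular (encloses a hole) —
    the corolla rim where the tube opens."""
    m = flower_tissue.data
    for z in range(m.shape[0] - 1, -1, -1):
        sl = m[z]
        if not sl.any():
            continue
        filled = ndimage.binary_fill_holes(sl)
        if (filled & ~sl).any():
            return z
    raise ValueError("no annular slice found; supply rim_z explicitly")


def _opening_centroid(flower_tissue: np.ndarray, rim_z: int) -> tuple[float, float]:
    sl = flower_tissue[rim_z]
    holes = ndimage.binary_fill_holes(sl) & ~sl
    if not holes.any():
        raise ValueError("corolla opening not found at the rim slice")
    ys, xs = np.nonzero(holes)
    return float(ys.mean()), float(xs.mean())


def _bee_reference(bee: np.ndarray) -> tuple[int, float, float]:
    """(lowest z, lateral centroid) of the bee mask."""
    zz, yy, xx = np.nonzero(bee)
    if len(zz) == 0:
        raise ValueError("bee mask is empty")
    return int(zz.min()), float(yy.mean()), float(xx.mean())


def max_insertion_depth(
    flower_tissue: BinaryMask,
    bee: BinaryMask,
    rim_z: int | None = None,
    step: int = 1,
) -> VisitationReport:
    """Deepest collision-free axial insertion of the bee head.

    The head is laterally centered on the corolla-opening centroid and
    slides down from the rim in ``step``-voxel increments; the descent
    stops at the first position that collides with tissue (a head cannot
    pass through a constriction), and the last collision-free position is
    reported. Depth 0 means the head's lowest voxel sits at the rim; if
    even that collides (head wider than the opening) the report has depth
    0 with the head resting fully above the rim.
    """
    if not bee.data.any():
        raise ValueError("bee mask is empty")
    shape = flower_tissue.shape
    if rim_z is None:
        rim_z = detect_rim(flower_tissue)
    if not (0 <= rim_z < shape[0]):
        raise ValueError("rim_z out of bounds")
    oy, ox = _opening_centroid(flower_tissue.data, rim_z)
    bz, by, bx = _bee_reference(bee.data)
    min_lat = min(shape[1], shape[2])
    if max(bee.shape[1], bee.shape[2]) > max(shape[1], shape[2]) + 2 * min_lat:
        raise ValueError("bee mask is far wider than the flower grid")

    dy = int(round(oy - by))
    dx = int(round(ox - bx))

    def placement_at(depth: int) -> RigidPlacement:
        return RigidPlacement(dz=(rim_z - depth) - bz, dy=dy, dx=dx)

    best_depth = None
    depth = 0
    while rim_z - depth >= 0:
        arr = place_mask(bee, placement_at(depth), shape)
        if (arr & flower_tissue.data).any():
            break
        best_depth = depth
        depth += step

    if best_depth is None:
        logger.warning("head collides already at the rim; depth 0, head above rim")
        pl = placement_at(-1)
        depth_vox = 0
    else:
        pl = placement_at(best_depth)
        depth_vox = best_depth
    arr = place_mask(bee, pl, shape)
    overlap = int((arr & flower_tissue.data).sum())
    zz = np.nonzero(arr)[0]
    head_bottom = int(zz.min()) if len(zz) else rim_z + 1
    return VisitationReport(
        max_depth_mm=depth_vox * flower_tissue.spacing_um * 1e-3,
        depth_vox=depth_vox,
        overlap_voxels=overlap,
        rim_z=rim_z,
        head_bottom_z=head_bottom,
        placement=pl,
    )


def nectar_reachability(
    report: VisitationReport,
    nectar: BinaryMask,
    proboscis_length_mm: float,
) -> bool:
    """Can the proboscis reach the nectar surface from the deepest placement?

    True iff the top of the nectar is within ``proboscis_length_mm`` below
    the head's lowest voxel (nectar at or above the head bottom is always
    reachable). An empty nectar mask is unreachable and logs a warning.
    """
    if proboscis_length_mm < 0:
        raise ValueError("proboscis length must be non-negative")
    zs = np.nonzero(nectar.data)[0]
    if len(zs) == 0:
        logger.warning("empty nectar mask: nothing to reach")
        report.nectar_reachable = False
        report.proboscis_length_mm = proboscis_length_mm
        return False
    nectar_top = int(zs.max())
    gap_mm = (report.head_bottom_z - nectar_top) * nectar.spacing_um * 1e-3
    reachable = gap_mm <= proboscis_length_mm
    report.nectar_reachable = reachable
    report.proboscis_length_mm = proboscis_length_mm
    return reachable
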