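"""Nectary gland segmentation from a greyscale micro-CT stack.

The gland is extracted with a topographic pipeline: restrict to a volume
of interest (VOI) along z, threshold tissue from air, project each (y, x)
column to the height of its topmost tissue voxel, split the height map
into compartments by watershed, select the gland compartment, recover the
hidden lower surface by harmonic interpolation from the compartment's
external contour, and stack the voxels between the lower and upper
surfaces into a 3D gland mask whose volume and air-contact surface are
then quantified.

Conventions (used consistently across the package): height is measured
from the flower base (z = 0) upward; connectivity is 6-neighborhood in 3D
and 4-neighborhood in 2D; the air phase for surface contact is the global
complement of the tissue mask, so gland area pressed against other organs
is not counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from skimage import filters, morphology, segmentation as sk_seg

from .volgrid import BinaryMask, VoxelGrid

logger = logging.getLogger(__name__)

SurfaceEstimator = Literal["exposed_faces", "surface_voxels"]


@dataclass
class HeightMap:
    """2D Z-projection: per (y, x) column, the z index of the topmost
    tissue voxel measured from the flower base; −1 marks empty columns.

    ``z_offset`` records the VOI offset so values stay in original stack
    coordinates.
    """

    data: np.ndarray
    spacing_um: float
    z_offset: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValueError("height map must be 2D")


@dataclass
class LabelMap:
    """2D compartment labels over (y, x); 0 = background/ridge."""

    data: np.ndarray

    def labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.data) if v != 0]


@dataclass
class SelectedCompartment:
    """A chosen compartment: its id(s), footprint and external contour.

    The contour is the set of footprint pixels 4-adjacent to a pixel
    outside the footprint (for an annular footprint this includes the
    inner rim as well as the outer one).
    """

    ids: tuple[int, ...]
    footprint: np.ndarray
    contour: np.ndarray


@dataclass
class Voi:
    """Sub-stack of slices [z_first, z_last) with its offset recorded."""

    grid: VoxelGrid
    z_first: int
    z_last: int


@dataclass
class ThresholdResult:
    mask: BinaryMask
    threshold: float
    method: str


@dataclass
class NectaryModel:
    """Segmented gland: 3D mask, bounding surfaces and derived measures."""

    mask: BinaryMask
    upper_surface: HeightMap
    lower_surface: HeightMap
    volume_mm3: float
    surface_mm2: float
    threshold_used: float
    threshold_method: str
    surface_estimator: SurfaceEstimator
    params: dict = field(default_factory=dict)


def select_voi(grid: VoxelGrid, z_first: int, z_last: int) -> Voi:
    """Restrict to the slice range where the gland is observed."""
    nz = grid.shape[0]
    if not (0 <= z_first < z_last <= nz):
        raise ValueError(f"invalid VOI [{z_first}, {z_last}) for {nz} slices")
    return Voi(
        grid=VoxelGrid(grid.data[z_first:z_last].copy(), grid.spacing_um),
        z_first=z_first,
        z_last=z_last,
    )


def threshold_tissue(
    grid: VoxelGrid,
    method: Literal["otsu", "fixed"] = "otsu",
    value: float | None = None,
) -> ThresholdResult:
    """Separate tissue (bright) from air (dark) voxels.

    Tissue is every voxel with intensity >= the threshold. With ``otsu``
    the threshold is computed from the VOI histogram; a constant-intensity
    volume cannot be thresholded automatically and raises with advice to
    use a fixed value.
    """
    data = grid.data
    if method == "otsu":
        lo, hi = int(data.min()), int(data.max())
        if lo == hi:
            raise ValueError(
                "constant-intensity volume: Otsu is undefined; supply a "
                "fixed threshold instead"
            )
        # skimage's Otsu value is the last background bin (foreground is
        # "> thr"); place the reported threshold half a step above it so
        # the package-wide ">= threshold is tissue" convention holds
        thr = float(filters.threshold_otsu(data)) + 0.5
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed threshold requires a value")
        if not (0 <= value <= 65536):
            raise ValueError("fixed threshold outside the 16-bit range")
        thr = float(value)
    else:
        raise ValueError(f"unknown threshold method: {method}")
    logger.info("tissue threshold (%s): %g", method, thr)
    mask = BinaryMask(data >= thr, grid.spacing_um, "tissue")
    return ThresholdResult(mask=mask, threshold=thr, method=method)


def height_zproject(tissue: BinaryMask, z_offset: int = 0) -> HeightMap:
    """Topmost-tissue height of every (y, x) column; −1 where empty."""
    m = tissue.data
    nz = m.shape[0]
    any_tissue = m.any(axis=0)
    # argmax on the z-reversed stack finds the topmost True
    top = nz - 1 - np.argmax(m[::-1], axis=0)
    heights = np.where(any_tissue, top + z_offset, -1)
    return HeightMap(heights, tissue.spacing_um, z_offset=z_offset)


def watershed_compartments(hmap: HeightMap, h_min: float = 2.0) -> LabelMap:
    """Partition the height map into compartments by watershed.

    The map is treated as topography: seeds are its regional maxima after
    h-maxima suppression of depth ``h_min`` (shallow bumps below ``h_min``
    do not open their own compartment), and the negated map is flooded
    from those seeds. Empty (sentinel) columns are excluded, so footprints
    separated by air are always distinct compartments. The flood is
    deterministic; ties on ridge pixels follow the scan order of the
    underlying flood queue.
    """
    if h_min < 0:
        raise ValueError("h_min must be >= 0")
    h = hmap.data
    mask = h >= 0
    if not mask.any():
        return LabelMap(np.zeros_like(h, dtype=np.int32))
    f = h.astype(np.float64)
    f[~mask] = f[mask].min() - (h_min + 2.0)  # sentinel below all topography
    if h_min > 0:
        maxima = morphology.h_maxima(f, h_min)
    else:
        maxima = morphology.local_maxima(f)
    maxima &= mask
    markers, n_markers = ndimage.label(maxima)
    if n_markers == 0:
        # flat topography: each connected footprint is one compartment
        labels, _ = ndimage.label(mask)
        return LabelMap(labels.astype(np.int32))
    labels = sk_seg.watershed(-f, markers=markers, mask=mask, connectivity=1)
    return LabelMap(labels.astype(np.int32))


def _contour_of(footprint: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        footprint, structure=ndimage.generate_binary_structure(2, 1),
        border_value=0,
    )
    return footprint & ~eroded


def select_nectary_compartment(
    labels: LabelMap,
    hmap: HeightMap,
    strategy: Literal["centermost", "largest"] | int = "centermost",
    merge_ids: Sequence[int] | None = None,
) -> SelectedCompartment:
    """Pick the gland compartment and return its external contour.

    ``centermost`` chooses the compartment whose centroid is nearest the
    lateral image center — the nectary sits at the base of the corolla in
    the center of the flower. When several centroids tie within one pixel
    (e.g. a central dome inside a concentric wall ring: both centroids sit
    at the center), the compartment that actually contains the center
    pixel wins, then the smallest label. ``largest`` picks the biggest
    footprint; an integer selects that label directly, and ``merge_ids``
    merges several labels into one footprint (a gland split across
    compartments).
    """
    lab = labels.data
    ids = labels.labels()
    if not ids:
        raise ValueError("empty labeling: no compartments to select")

    if merge_ids is not None:
        missing = [i for i in merge_ids if i not in ids]
        if missing:
            raise ValueError(f"labels not present: {missing}")
        chosen: tuple[int, ...] = tuple(int(i) for i in merge_ids)
    elif isinstance(strategy, (int, np.integer)):
        if int(strategy) not in ids:
            raise ValueError(f"label {strategy} not present in labeling")
        chosen = (int(strategy),)
    elif strategy == "largest":
        sizes = {i: int((lab == i).sum()) for i in ids}
        chosen = (max(ids, key=lambda i: (sizes[i], -i)),)
    elif strategy == "centermost":
        # nearest-pixel distance to the lateral image center (0 when the
        # compartment contains the center); a plain centroid distance is
        # degenerate for annular compartments such as the corolla wall,
        # whose centroid falls at the center it does not occupy
        ny, nx = lab.shape
        center = np.array([(ny - 1) / 2.0, (nx - 1) / 2.0])
        key = {}
        for i in ids:
            ys, xs = np.nonzero(lab == i)
            d_pix = float(np.hypot(ys - center[0], xs - center[1]).min())
            d_cen = float(np.hypot(ys.mean() - center[0], xs.mean() - center[1]))
            key[i] = (d_pix, d_cen, i)
        chosen = (min(ids, key=lambda i: key[i]),)
    else:
        raise ValueError(f"unknown selection strategy: {strategy}")

    footprint = np.isin(lab, chosen)
    return SelectedCompartment(ids=chosen, footprint=footprint,
                               contour=_contour_of(footprint))


def interpolate_lower_surface(
    selection: SelectedCompartment,
    tissue: BinaryMask,
    upper: HeightMap | None = None,
    z_offset: int = 0,
) -> HeightMap:
    """Recover the gland's hidden base by harmonic interpolation.

    The lower contour cannot be obtained by thresholding (the gland merges
    with underlying tissue), so it is interpolated inward from the
    external contour: each contour pixel is assigned the z of the lowest
    tissue voxel in its column, and interior values solve the discrete
    Laplace equation with those Dirichlet boundary values — deterministic,
    parameter-free, and exact for flat or planar bases. Values are rounded
    to integer z and clamped to the upper surface where given.
    """
    m = tissue.data
    footprint = selection.footprint
    contour = selection.contour
    nz = m.shape[0]

    any_t = m.any(axis=0)
    lowest = np.argmax(m, axis=0)  # first True from the base

    bvals = {}
    for y, x in zip(*np.nonzero(contour)):
        if any_t[y, x]:
            bvals[(y, x)] = float(lowest[y, x])
    if not bvals:
        raise ValueError("no tissue beneath any contour pixel")

    lower = np.full(footprint.shape, -1, dtype=np.int64)
    interior = footprint & ~contour
    # contour pixels without tissue inherit the solved/neighbor values later;
    # treat them as interior unknowns so the system stays well-posed
    dirichlet = np.zeros(footprint.shape, bool)
    for (y, x), v in bvals.items():
        dirichlet[y, x] = True
    unknown = footprint & ~dirichlet

    if unknown.any():
        idx = -np.ones(footprint.shape, dtype=np.int64)
        uy, ux = np.nonzero(unknown)
        idx[uy, ux] = np.arange(len(uy))
        n = len(uy)
        rows, cols, vals = [], [], []
        rhs = np.zeros(n)
        ny, nx = footprint.shape
        for k, (y, x) in enumerate(zip(uy, ux)):
            deg = 0
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                yy, xx = y + dy, x + dx
                if not (0 <= yy < ny and 0 <= xx < nx) or not footprint[yy, xx]:
                    continue  # Neumann at footprint edge without boundary data
                deg += 1
                if dirichlet[yy, xx]:
                    rhs[k] += bvals[(yy, xx)]
                else:
                    rows.append(k)
                    cols.append(idx[yy, xx])
                    vals.append(-1.0)
            rows.append(k)
            cols.append(k)
            vals.append(float(max(deg, 1)))
        lap = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        sol = spsolve(lap, rhs)
        lower[uy, ux] = np.rint(sol).astype(np.int64)
    for (y, x), v in bvals.items():
        lower[y, x] = int(round(v))

    lower[footprint] = np.clip(lower[footprint], 0, nz - 1)
    if upper is not None:
        up_local = upper.data - upper.z_offset
        lower[footprint] = np.minimum(lower[footprint], up_local[footprint])
    lower[footprint] += z_offset
    return HeightMap(lower, tissue.spacing_um, z_offset=z_offset)


def build_nectary_mask(
    upper: HeightMap,
    lower: HeightMap,
    footprint: np.ndarray,
    nz: int,
    spacing_um: float,
) -> BinaryMask:
    """Stack voxels between the lower and upper surfaces into a 3D mask.

    Voxel (z, y, x) is gland iff (y, x) is in the footprint and
    ``lower(y, x) <= z <= upper(y, x)`` (heights in full-stack z
    coordinates).
    """
    up, lo = upper.data, lower.data
    valid = footprint & (up >= 0) & (lo >= 0)
    if np.any(lo[valid] > up[valid]):
        raise ValueError("lower surface exceeds upper surface on footprint")
    z = np.arange(nz)[:, None, None]
    mask = valid[None] & (z >= lo[None]) & (z <= up[None])
    return BinaryMask(mask, spacing_um, "nectary")


def mask_volume(mask: BinaryMask, spacing_um: float | None = None) -> float:
    """Voxel-count volume in mm³ (numerically equal to µL)."""
    sp = mask.spacing_um if spacing_um is None else spacing_um
    if sp <= 0:
        raise ValueError("spacing must be positive")
    return mask.voxel_count() * sp**3 * 1e-9


def mask_surface_area(
    mask: BinaryMask,
    spacing_um: float | None = None,
    estimator: SurfaceEstimator = "exposed_faces",
    air: BinaryMask | np.ndarray | None = None,
) -> float:
    """Air-contact surface of a mask in mm².

    ``exposed_faces`` (default) counts 6-neighbor faces between a gland
    voxel and an air voxel; ``surface_voxels`` counts gland voxels having
    at least one air 6-neighbor (the per-pixel reading). ``air`` defaults
    to the mask complement (an isolated solid); in the pipeline it is the
    global tissue-mask complement so area pressed against other organs is
    not counted. Voxels outside the grid count as air.
    """
    sp = mask.spacing_um if spacing_um is None else spacing_um
    obj = mask.data
    if air is None:
        air_arr = ~obj
    else:
        air_arr = air.data if isinstance(air, BinaryMask) else np.asarray(air, bool)
        if air_arr.shape != obj.shape:
            raise ValueError("air mask shape mismatch")
    obj_pad = np.pad(obj, 1, constant_values=False)
    air_pad = np.pad(air_arr, 1, constant_values=True)
    if estimator == "exposed_faces":
        faces = 0
        for axis in range(3):
            for shift in (1, -1):
                faces += int(np.count_nonzero(obj_pad & np.roll(air_pad, shift, axis=axis)))
        return faces * sp**2 * 1e-6
    if estimator == "surface_voxels":
        touches = np.zeros_like(obj_pad)
        for axis in range(3):
            for shift in (1, -1):
                touches |= obj_pad & np.roll(air_pad, shift, axis=axis)
        return int(touches.sum()) * sp**2 * 1e-6
    raise ValueError(f"unknown surface estimator: {estimator}")


def segment_nectary(
    grid: VoxelGrid,
    z_first: int | None = None,
    z_last: int | None = None,
    threshold: Literal["otsu"] | float = "otsu",
    h_min: float = 2.0,
    compartment: Literal["centermost", "largest"] | int = "centermost",
    merge_ids: Sequence[int] | None = None,
    surface_estimator: SurfaceEstimator = "exposed_faces",
) -> NectaryModel:
    """Full gland extraction pipeline on a greyscale stack.

    Composes VOI selection, thresholding, height Z-projection, watershed
    compartmentalization, compartment selection, lower-surface
    interpolation and mask construction; returns the gland model with its
    volume and air-contact surface. Identical inputs and parameters give a
    bit-identical result.
    """
    nz = grid.shape[0]
    z0 = 0 if z_first is None else z_first
    z1 = nz if z_last is None else z_last
    voi = select_voi(grid, z0, z1)

    if threshold == "otsu":
        thr_res = threshold_tissue(voi.grid, "otsu")
    else:
        thr_res = threshold_tissue(voi.grid, "fixed", float(threshold))

    hmap = height_zproject(thr_res.mask, z_offset=voi.z_first)
    labels = watershed_compartments(hmap, h_min=h_min)
    sel = select_nectary_compartment(labels, hmap, strategy=compartment,
                                     merge_ids=merge_ids)
    lower = interpolate_lower_surface(sel, thr_res.mask, upper=hmap,
                                      z_offset=voi.z_first)
    gland = build_nectary_mask(hmap, lower, sel.footprint, nz=nz,
                               spacing_um=grid.spacing_um)

    # air for surface contact: complement of the *global* tissue mask at
    # the same threshold, so contact with the style or receptacle is not
    # counted as air-exposed surface
    tissue_full = grid.data >= thr_res.threshold
    air_full = ~tissue_full
    vol = mask_volume(gland)
    surf = mask_surface_area(gland, estimator=surface_estimator, air=air_full)
    return NectaryModel(
        mask=gland,
        upper_surface=hmap,
        lower_surface=lower,
        volume_mm3=vol,
        surface_mm2=surf,
        threshold_used=thr_res.threshold,
        threshold_method=thr_res.method,
        surface_estimator=surface_estimator,
        params={
            "z_first": voi.z_first, "z_last": voi.z_last, "h_min": h_min,
            "compartment": str(compartment),
            "merge_ids": list(merge_ids) if merge_ids else None,
        },
    )
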