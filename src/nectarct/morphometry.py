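"""Per-flower geometric measures and the assembled phenotype record.

Two measures mirror classical 2D phenotyping inside the 3D volume: the
gland cross-sectional area is the mean over two perpendicular virtual
longitudinal sections, one pixel thick, taken through the center of the
flower; the flower width is a lateral extent of the tissue mask. The
``measure_flower`` composition runs the whole segmentation pipeline and
assembles one :class:`MeasurementRecord` with full provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .segmentation import NectaryModel, segment_nectary
from .volgrid import BinaryMask, VoxelGrid

logger = logging.getLogger(__name__)


@dataclass
class MeasurementRecord:
    """One flower's phenotype row.

    Areas in mm², volumes in mm³, widths in mm, nectar in µL (1 mm³ of
    nectar = 1 µL). ``provenance`` carries thresholds and estimator tags
    so records are reproducible.
    """

    flower_id: str
    sex: Literal["male", "female"] | None = None
    flower_width_mm: float | None = None
    cross_section_area_mm2: float | None = None
    nectary_surface_mm2: float | None = None
    nectary_volume_mm3: float | None = None
    nectar_volume_ul: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("flower_width_mm", "cross_section_area_mm2",
                     "nectary_surface_mm2", "nectary_volume_mm3",
                     "nectar_volume_ul"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


def cross_section_area(nectary_mask: BinaryMask, spacing_um: float | None = None) -> float:
    """Mean gland area over two perpendicular central longitudinal sections.

    The center is the lateral centroid of the gland mask (robust to
    off-center crops); section 1 is the plane ``x = centroid_x``, section
    2 the plane ``y = centroid_y``, each one voxel thick. Per section the
    area counts every gland voxel in the plane — for an annular (female-
    type) gland each section shows two lobes and both are included. The
    returned value is the mean of the two section areas in mm².
    """
    m = nectary_mask.data
    sp = nectary_mask.spacing_um if spacing_um is None else spacing_um
    zz, yy, xx = np.nonzero(m)
    if len(zz) == 0:
        raise ValueError("empty nectary mask")
    cy = int(round(yy.mean()))
    cx = int(round(xx.mean()))
    ny, nx = m.shape[1:]
    img_cy, img_cx = (ny - 1) // 2, (nx - 1) // 2
    if abs(cy - img_cy) > 5 or abs(cx - img_cx) > 5:
        logger.info(
            "gland centroid (%d, %d) is > 5 voxels from the image center "
            "(%d, %d); sections follow the gland", cy, cx, img_cy, img_cx,
        )
    a1 = int(np.count_nonzero(m[:, :, cx]))
    a2 = int(np.count_nonzero(m[:, cy, :]))
    return 0.5 * (a1 + a2) * sp**2 * 1e-6


def flower_width(
    tissue_mask: BinaryMask,
    spacing_um: float | None = None,
    mode: Literal["max_extent", "at_z"] = "max_extent",
    z: int | None = None,
) -> float:
    """Lateral flower width in mm.

    ``max_extent`` (default): the maximum per-axis extent of the tissue
    footprint over all slices. ``at_z`` evaluates the same extent at one
    slice (e.g. the corolla rim) — the anatomical level of "width" is a
    choice, so both are provided.
    """
    m = tissue_mask.data
    sp = tissue_mask.spacing_um if spacing_um is None else spacing_um
    if not m.any():
        raise ValueError("empty tissue mask")
    if mode == "at_z":
        if z is None or not (0 <= z < m.shape[0]):
            raise ValueError("at_z mode requires a valid slice index")
        slices = [m[z]]
    elif mode == "max_extent":
        slices = [m[k] for k in range(m.shape[0])]
    else:
        raise ValueError(f"unknown width mode: {mode}")
    best = 0
    for sl in slices:
        if not sl.any():
            continue
        ys, xs = np.nonzero(sl)
        best = max(best, int(np.ptp(ys)) + 1, int(np.ptp(xs)) + 1)
    if best == 0:
        raise ValueError("no tissue at the requested slice")
    return best * sp * 1e-3


def measure_flower(
    grid: VoxelGrid,
    nectar_ul: float | None = None,
    flower_id: str = "flower",
    sex: Literal["male", "female"] | None = None,
    width_mode: Literal["max_extent", "at_z"] = "max_extent",
    width_z: int | None = None,
    **segment_params,
) -> MeasurementRecord:
    """Run the full pipeline on a stack and assemble one phenotype record.

    ``segment_params`` are forwarded to
    :func:`nectarct.segmentation.segment_nectary` (VOI bounds, threshold,
    watershed depth, compartment strategy, surface estimator). The nectar
    volume is an external capillary measurement and is recorded as given;
    when absent the field stays empty and all geometry is still computed.
    """
    model: NectaryModel = segment_nectary(grid, **segment_params)
    tissue = BinaryMask(grid.data >= model.threshold_used, grid.spacing_um,
                        "tissue")
    record = MeasurementRecord(
        flower_id=flower_id,
        sex=sex,
        flower_width_mm=flower_width(tissue, mode=width_mode, z=width_z),
        cross_section_area_mm2=cross_section_area(model.mask),
        nectary_surface_mm2=model.surface_mm2,
        nectary_volume_mm3=model.volume_mm3,
        nectar_volume_ul=nectar_ul,
        provenance={
            "threshold_used": model.threshold_used,
            "threshold_method": model.threshold_method,
            "surface_estimator": model.surface_estimator,
            "width_mode": width_mode,
            **model.params,
        },
    )
    return record
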