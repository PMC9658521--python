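"""Synthetic micro-CT flower phantoms with analytic ground truth.

No scans are deposited with the study this package operates on, so every
pipeline stage is validated against generated volumes whose true geometry
is known exactly. The flower phantom emulates the anatomy relevant to
nectar phenotyping:

* a corolla tube (cylindrical bore) standing on a solid base cap,
* a nectary gland at the base of the tube — a **dome** for male flowers,
  or an **annulus** completely surrounding a central style for female
  flowers (in any single longitudinal section the annulus appears as two
  separate lobes; in 3D it is one organ — the 2D-vs-3D discrepancy the
  pipeline is meant to resolve),
* an interior air cavity 6-connected both to the corolla opening and to
  the nectar chamber at the base.

Everything outside the bore is tissue, so the interior cavity is the only
air in the volume; the phantom emulates a scan already cropped to the
flower, as reconstructed stacks are in practice.

Ground truth is defined on the ideal geometry *before* degradation.
Degradation is Gaussian blur (a partial-volume surrogate), then additive
Gaussian noise, then 16-bit quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .volgrid import BinaryMask, VoxelGrid

Sex = Literal["male", "female"]

BASE_CAP_VOX = 6  # thickness of the solid base below the nectar chamber


@dataclass
class FlowerPhantomSpec:
    """Parameters of a synthetic flower volume.

    Defaults give a male flower with a dome nectary of radius 20 voxels at
    5 µm spacing (0.1 mm), inside a corolla bore of radius 54 voxels. The
    female defaults (annulus 12/26 voxels, height 27) are chosen so the
    female/male true nectary-volume ratio is 2.7, the fold-change regime
    reported for melon flowers.
    """

    sex: Sex = "male"
    corolla_outer_radius_vox: int = 60
    corolla_wall_vox: int = 6
    corolla_depth_vox: int = 110
    dome_radius_vox: int = 20           # male nectary
    annulus_inner_radius_vox: int = 12  # female nectary
    annulus_outer_radius_vox: int = 26
    annulus_height_vox: int = 27
    style_radius_vox: int = 8
    spacing_um: float = 5.0
    tissue_intensity: int = 30000
    air_intensity: int = 10000
    blur_sigma_vox: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.tissue_intensity <= self.air_intensity:
            raise ValueError("tissue must be brighter than air")
        inner = self.corolla_outer_radius_vox - self.corolla_wall_vox
        if self.sex == "female":
            if not (self.style_radius_vox < self.annulus_inner_radius_vox
                    < self.annulus_outer_radius_vox < inner):
                raise ValueError(
                    "radii must nest: style < annulus inner < annulus outer "
                    "< corolla inner"
                )
        else:
            if not (0 < self.dome_radius_vox < inner):
                raise ValueError("dome radius must nest inside the corolla bore")
        if self.corolla_wall_vox < 1 or self.corolla_depth_vox < 2:
            raise ValueError("corolla wall and depth must be positive")


@dataclass
class GroundTruth:
    """Analytic/exact-geometry sidecar used as a test oracle.

    Scalar quantities carry units in their names. ``*_mask`` fields are
    the exact pre-degradation voxel sets. For calibration solids the
    continuum (analytic) value and the exact voxel-count value are both
    recorded; they differ by discretization.
    """

    spacing_um: float
    nectary_volume_mm3: float | None = None
    nectary_volume_analytic_mm3: float | None = None
    nectary_surface_mm2: float | None = None
    flower_width_mm: float | None = None
    cross_section_area_mm2: float | None = None
    air_cavity_volume_ul: float | None = None
    voxel_count: int | None = None
    voxel_volume_mm3: float | None = None
    analytic_volume_mm3: float | None = None
    analytic_surface_mm2: float | None = None
    central_section_area_vox: float | None = None
    voi: tuple[int, int] | None = None        # [z_first, z_last) of the gland
    nectary_probe_yx: tuple[int, int] | None = None  # pixel inside gland footprint
    nectary_mask: BinaryMask | None = None
    air_mask: BinaryMask | None = None
    tissue_mask: BinaryMask | None = None

    def scalars(self) -> dict:
        """Scalar fields as a plain dict (for truth.json export)."""
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, (int, float)) and v is not None:
                out[k] = float(v)
            elif isinstance(v, tuple):
                out[k] = list(v)
        return out


@dataclass
class CohortRow:
    """One synthetic per-flower phenotype row for regression fixtures."""

    flower_id: str
    sex: Sex
    nectar_volume_ul: float
    gland_volume_mm3: float
    gland_surface_mm2: float
    cross_section_mm2: float
    flower_width_mm: float
    clipped: bool = False  # negative simulated nectar clipped to zero


def _lateral_rho(shape_yx: tuple[int, int]) -> np.ndarray:
    """Distance of each (y, x) pixel from the lateral grid center."""
    ny, nx = shape_yx
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    return np.hypot(yy - cy, xx - cx)


def _degrade(ideal: np.ndarray, spec: FlowerPhantomSpec) -> np.ndarray:
    """Blur + noise + 16-bit quantization of an ideal intensity volume."""
    img = ideal.astype(np.float64)
    if spec.blur_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def _exposed_face_count(obj: np.ndarray, air: np.ndarray) -> int:
    """Faces shared by an object voxel and an air voxel (6-neighborhood).

    Voxels outside the grid count as air, so solids touching the array
    edge are closed off consistently.
    """
    obj = np.asarray(obj, bool)
    air_pad = np.pad(np.asarray(air, bool), 1, constant_values=True)
    obj_pad = np.pad(obj, 1, constant_values=False)
    faces = 0
    for axis in range(3):
        for shift in (1, -1):
            neighbor_air = np.roll(air_pad, shift, axis=axis)
            faces += int(np.count_nonzero(obj_pad & neighbor_air))
    return faces


def _mask_extent_mm(mask: np.ndarray, spacing_um: float) -> float:
    """Maximum per-axis lateral extent (voxels) over all slices, in mm."""
    best = 0
    for z in range(mask.shape[0]):
        sl = mask[z]
        if not sl.any():
            continue
        ys, xs = np.nonzero(sl)
        best = max(best, int(np.ptp(ys)) + 1, int(np.ptp(xs)) + 1)
    return best * spacing_um * 1e-3


def _central_section_area_mm2(mask: np.ndarray, spacing_um: float) -> float:
    """Mean of the two perpendicular central-plane areas of a mask, mm²."""
    zz, yy, xx = np.nonzero(mask)
    if len(zz) == 0:
        raise ValueError("empty mask")
    cy = int(round(yy.mean()))
    cx = int(round(xx.mean()))
    a1 = int(np.count_nonzero(mask[:, :, cx]))
    a2 = int(np.count_nonzero(mask[:, cy, :]))
    return 0.5 * (a1 + a2) * spacing_um**2 * 1e-6


def make_flower_phantom(spec: FlowerPhantomSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Build a synthetic flower volume and its exact ground truth.

    Deterministic for a given ``spec.seed``. Ground-truth masks are the
    ideal pre-blur, pre-noise geometry; the returned grid carries the
    degradation the spec requests.
    """
    spec.validate()
    r_out = spec.corolla_outer_radius_vox
    r_in = r_out - spec.corolla_wall_vox
    nyx = 2 * r_out + 1
    nz = BASE_CAP_VOX + spec.corolla_depth_vox
    rho = _lateral_rho((nyx, nyx))
    cy = cx = (nyx - 1) // 2

    tissue = np.zeros((nz, nyx, nyx), dtype=bool)
    tissue[:BASE_CAP_VOX] = True              # solid base cap
    tissue[BASE_CAP_VOX:, rho >= r_in] = True  # wall, solid out to grid edge

    nectary = np.zeros_like(tissue)
    z0 = BASE_CAP_VOX
    if spec.sex == "male":
        r = spec.dome_radius_vox
        zz = np.arange(nz)[:, None, None] - z0
        # layer k samples the slab [k, k+1) at its midpoint, so the voxel
        # count is an unbiased (midpoint-rule) discretization of the
        # continuum half-ball volume
        dome = (zz >= 0) & ((zz + 0.5)**2 + (rho**2)[None] <= r**2)
        nectary = dome
        gland_height = r
        analytic_vol_vox = (2.0 / 3.0) * math.pi * r**3
        probe = (cy, cx)
    else:
        ri, ro, h = (spec.annulus_inner_radius_vox,
                     spec.annulus_outer_radius_vox, spec.annulus_height_vox)
        ring = (rho >= ri) & (rho <= ro)
        nectary[z0:z0 + h, ring] = True
        # style: central cylinder running from the base to the corolla rim
        style = rho <= spec.style_radius_vox
        tissue[z0:, style] = True
        gland_height = h
        analytic_vol_vox = math.pi * (ro**2 - ri**2) * h
        probe = (cy, cx + (ri + ro) // 2)

    tissue |= nectary
    air = ~tissue

    sp = spec.spacing_um
    vox_mm3 = sp**3 * 1e-9
    ideal = np.where(tissue, spec.tissue_intensity, spec.air_intensity)
    grid = VoxelGrid(data=_degrade(ideal, spec), spacing_um=sp)

    truth = GroundTruth(
        spacing_um=sp,
        nectary_volume_mm3=float(nectary.sum()) * vox_mm3,
        nectary_volume_analytic_mm3=analytic_vol_vox * vox_mm3,
        nectary_surface_mm2=_exposed_face_count(nectary, air) * sp**2 * 1e-6,
        flower_width_mm=_mask_extent_mm(tissue, sp),
        cross_section_area_mm2=_central_section_area_mm2(nectary, sp),
        air_cavity_volume_ul=float(air.sum()) * vox_mm3,
        voxel_count=int(nectary.sum()),
        voi=(z0, z0 + gland_height + 1),
        nectary_probe_yx=probe,
        nectary_mask=BinaryMask(nectary, sp, "nectary"),
        air_mask=BinaryMask(air, sp, "air"),
        tissue_mask=BinaryMask(tissue, sp, "tissue"),
    )
    return grid, truth


def make_calibration_solid(
    shape: Literal["sphere", "cube", "cylinder"],
    size_vox: int,
    spacing_um: float = 5.0,
    tissue_intensity: int = 30000,
    air_intensity: int = 10000,
) -> tuple[VoxelGrid, GroundTruth]:
    """Binary-valued calibration solid with continuum and voxel-count truth.

    ``size_vox`` is the radius for sphere/cylinder and the edge length for
    the cube; the cylinder height equals twice its radius.
    """
    if size_vox < 3:
        raise ValueError("size must be at least 3 voxels")
    margin = 3
    sp = spacing_um
    vox_mm3 = sp**3 * 1e-9
    if shape == "cube":
        n = size_vox
        dim = n + 2 * margin
        mask = np.zeros((dim, dim, dim), bool)
        mask[margin:margin + n, margin:margin + n, margin:margin + n] = True
        analytic_vol = float(n**3)
        analytic_surf = 6.0 * n**2  # exact in exposed-face units
        section = float(n * n)
    elif shape == "sphere":
        r = size_vox
        dim = 2 * r + 1 + 2 * margin
        c = (dim - 1) / 2.0
        zz, yy, xx = np.mgrid[0:dim, 0:dim, 0:dim]
        mask = (zz - c)**2 + (yy - c)**2 + (xx - c)**2 <= r**2
        analytic_vol = (4.0 / 3.0) * math.pi * r**3
        analytic_surf = 4.0 * math.pi * r**2
        section = math.pi * r**2
    elif shape == "cylinder":
        r = size_vox
        h = 2 * r
        dimxy = 2 * r + 1 + 2 * margin
        dimz = h + 2 * margin
        rho = _lateral_rho((dimxy, dimxy))
        mask = np.zeros((dimz, dimxy, dimxy), bool)
        mask[margin:margin + h, rho <= r] = True
        analytic_vol = math.pi * r**2 * h
        analytic_surf = 2 * math.pi * r * h + 2 * math.pi * r**2
        section = float(2 * r * h)  # longitudinal central section
    else:
        raise ValueError(f"unknown calibration shape: {shape}")

    ideal = np.where(mask, tissue_intensity, air_intensity).astype(np.uint16)
    grid = VoxelGrid(data=ideal, spacing_um=sp)
    truth = GroundTruth(
        spacing_um=sp,
        voxel_count=int(mask.sum()),
        voxel_volume_mm3=float(mask.sum()) * vox_mm3,
        analytic_volume_mm3=analytic_vol * vox_mm3,
        analytic_surface_mm2=analytic_surf * sp**2 * 1e-6,
        central_section_area_vox=section,
        nectary_mask=BinaryMask(mask, sp, "nectary"),
        air_mask=BinaryMask(~mask, sp, "air"),
        tissue_mask=BinaryMask(mask, sp, "tissue"),
    )
    return grid, truth


def make_bee_head_phantom(
    head_width_vox: int,
    proboscis_length_vox: int,
    proboscis_radius_vox: int,
    spacing_um: float = 5.0,
) -> BinaryMask:
    """Simplified honey-bee head: ellipsoid plus a downward proboscis cylinder.

    The head is an ellipsoid whose lateral extent equals ``head_width_vox``
    exactly (z semi-axis 0.8× the lateral one); the proboscis is a cylinder
    of the given radius extending ``proboscis_length_vox`` voxels below the
    head center, so the solid is always a single 6-connected component.
    The proboscis tip is the lowest voxel (z = 0 side), matching the
    head-down insertion pose used for accessibility modeling.
    """
    if head_width_vox < 3 or proboscis_length_vox < 0 or proboscis_radius_vox < 1:
        raise ValueError("bee head dimensions must be positive")
    s_lat = (head_width_vox - 1) / 2.0
    s_z = max(1.0, 0.8 * s_lat)
    margin = 2
    nyx = head_width_vox + 2 * margin
    top_half = int(math.ceil(s_z))
    nz = proboscis_length_vox + 2 * top_half + 1 + 2 * margin
    c_z = margin + proboscis_length_vox + top_half
    c = (nyx - 1) / 2.0
    zz, yy, xx = np.mgrid[0:nz, 0:nyx, 0:nyx]
    ell = (((zz - c_z) / s_z)**2 + ((yy - c) / s_lat)**2
           + ((xx - c) / s_lat)**2) <= 1.0
    rho = np.hypot(yy - c, xx - c)
    cyl = (rho <= proboscis_radius_vox) & (zz <= c_z) \
        & (zz >= c_z - top_half - proboscis_length_vox)
    mask = ell | (cyl if proboscis_length_vox > 0 else np.zeros_like(ell))
    return BinaryMask(mask, spacing_um, "bee")


def noise_sd_for_r(slope: float, x_range: tuple[float, float], r: float) -> float:
    """Noise standard deviation giving population Pearson ``r`` for a linear
    relation with uniform x on ``x_range``."""
    if not 0 < abs(r) <= 1:
        raise ValueError("target r must be in (0, 1]")
    var_x = (x_range[1] - x_range[0])**2 / 12.0
    return abs(slope) * math.sqrt(var_x * (1.0 / r**2 - 1.0))


def make_synthetic_cohort(
    n: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    x_range: tuple[float, float],
    seed: int,
    sex: Sex = "male",
) -> list[CohortRow]:
    """Cohort of per-flower rows with a known linear nectar~gland relation.

    ``nectar_volume_ul = slope * gland_volume_mm3 + intercept + N(0, noise_sd)``
    with gland volume uniform on ``x_range``. Negative simulated nectar
    volumes are clipped to 0 and flagged. Secondary morphometric fields are
    deterministic allometric transforms of the gland volume (surface and
    cross-section scale as volume^(2/3)) so correlation plumbing has every
    column populated.
    """
    if n < 0 or noise_sd < 0:
        raise ValueError("n and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n)
    y = slope * x + intercept + (rng.normal(0.0, noise_sd, size=n)
                                 if noise_sd > 0 else 0.0)
    rows: list[CohortRow] = []
    for i in range(n):
        yi = float(y[i]) if np.ndim(y) else float(y)
        clipped = yi < 0
        rows.append(CohortRow(
            flower_id=f"{sex[0].upper()}{i + 1:03d}",
            sex=sex,
            nectar_volume_ul=max(yi, 0.0),
            gland_volume_mm3=float(x[i]),
            gland_surface_mm2=4.8 * float(x[i]) ** (2.0 / 3.0),
            cross_section_mm2=1.9 * float(x[i]) ** (2.0 / 3.0),
            flower_width_mm=4.0 + 0.5 * float(x[i]),
            clipped=clipped,
        ))
    return rows
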