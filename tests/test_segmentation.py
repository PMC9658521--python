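"""Height-map pipeline stages against brute-force and analytic oracles."""

import heapq
import math

import numpy as np
import pytest

from conftest import dice
from nectarct.phantom import FlowerPhantomSpec, make_flower_phantom
from nectarct.segmentation import (HeightMap, SelectedCompartment,
                                   build_nectary_mask, height_zproject,
                                   interpolate_lower_surface,
                                   mask_surface_area, mask_volume,
                                   segment_nectary,
                                   select_nectary_compartment, select_voi,
                                   threshold_tissue, watershed_compartments)
from nectarct.volgrid import BinaryMask, VoxelGrid

SP = 5.0


def _grid(arr):
    return VoxelGrid(np.asarray(arr, np.uint16), SP)


def _dome_grid(r=12, margin=4, air=1000, tissue=30000):
    """Isolated dome solid in air: z=0 is the dome base plane."""
    nyx = 2 * r + 1 + 2 * margin
    nz = r + margin
    c = (nyx - 1) / 2.0
    zz, yy, xx = np.mgrid[0:nz, 0:nyx, 0:nyx]
    dome = (zz + 0.5)**2 + (yy - c)**2 + (xx - c)**2 <= r**2
    return _grid(np.where(dome, tissue, air)), dome


# ---------------------------------------------------------------- thresholds

def test_otsu_separates_two_level_phantom_exactly():
    g, dome = _dome_grid()
    res = threshold_tissue(g, "otsu")
    np.testing.assert_array_equal(res.mask.data, dome)
    assert 1000 < res.threshold <= 30000


def test_fixed_threshold_above_max_gives_empty_mask():
    g, _ = _dome_grid()
    res = threshold_tissue(g, "fixed", 30001)
    assert res.mask.voxel_count() == 0


def test_otsu_on_constant_grid_instructs_fixed():
    g = _grid(np.full((4, 4, 4), 7))
    with pytest.raises(ValueError, match="fixed"):
        threshold_tissue(g, "otsu")


def test_noisy_phantom_tissue_dice(noisy_male_phantom):
    grid, truth = noisy_male_phantom
    res = threshold_tissue(grid, "otsu")
    assert dice(res.mask.data, truth.tissue_mask.data) >= 0.98


# ----------------------------------------------------------------- height map

def test_height_zproject_column_and_empty():
    m = np.zeros((10, 3, 3), bool)
    m[3:8, 1, 1] = True
    h = height_zproject(BinaryMask(m, SP))
    assert h.data[1, 1] == 7
    assert (h.data[0, 0] == -1) and (h.data[2, 2] == -1)
    empty = height_zproject(BinaryMask(np.zeros((4, 3, 3), bool), SP))
    assert (empty.data == -1).all()


def test_height_apex_on_dome_phantom():
    g, dome = _dome_grid(r=12)
    h = height_zproject(BinaryMask(dome, SP))
    # apex column reaches base_z + r - 1
    assert h.data.max() == 12 - 1


# ----------------------------------------------------------------- watershed

def _flood_oracle(height, markers, mask):
    """Priority-flood watershed: flood from markers in decreasing height."""
    lab = np.where(markers > 0, markers, 0)
    heap = []
    ny, nx = height.shape
    order = 0
    for y in range(ny):
        for x in range(nx):
            if lab[y, x] > 0:
                heapq.heappush(heap, (-height[y, x], order, y, x))
                order += 1
    while heap:
        _, _, y, x = heapq.heappop(heap)
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and lab[yy, xx] == 0:
                lab[yy, xx] = lab[y, x]
                heapq.heappush(heap, (-height[yy, xx], order, yy, xx))
                order += 1
    return lab


def _two_dome_map(n=20, sep=10):
    y, x = np.mgrid[0:n, 0:n]
    c1, c2 = (n // 2, n // 4), (n // 2, n // 4 + sep)
    h1 = np.maximum(8 - np.hypot(y - c1[0], x - c1[1]), 0)
    h2 = np.maximum(8 - np.hypot(y - c2[0], x - c2[1]), 0)
    return np.maximum(h1, h2).astype(int)


def test_single_dome_is_one_compartment():
    g, dome = _dome_grid(r=10)
    h = height_zproject(BinaryMask(dome, SP))
    labels = watershed_compartments(h, h_min=2)
    assert labels.labels() == [1]
    assert (labels.data > 0).sum() == dome.any(axis=0).sum()


def test_two_domes_split_along_the_valley():
    hm = _two_dome_map()
    labels = watershed_compartments(HeightMap(hm, SP), h_min=2)
    ids = labels.labels()
    assert len(ids) == 2
    # each dome core (strictly above the valley floor) lies in one compartment
    valley_level = hm[10, 10]
    for cx in (5, 15):
        core = np.zeros_like(hm, bool)
        core[hm > valley_level + 1] = True
        core[:, :10] = core[:, :10] if cx == 5 else False
        core[:, 10:] = core[:, 10:] if cx == 15 else False
        core_labels = set(labels.data[core].tolist())
        assert len(core_labels) == 1
    # boundary pixels between the two compartments sit in the valley column band
    a, b = ids
    la = labels.data == a
    boundary_cols = []
    for y in range(20):
        for x in range(19):
            if labels.data[y, x] != labels.data[y, x + 1] \
                    and labels.data[y, x] > 0 and labels.data[y, x + 1] > 0:
                boundary_cols.append(x)
    assert boundary_cols and all(7 <= c <= 13 for c in boundary_cols)
    # independent priority-flood oracle agrees on the two dome cores
    from nectarct.segmentation import LabelMap
    markers = np.zeros_like(hm)
    markers[10, 5], markers[10, 15] = 1, 2
    oracle = _flood_oracle(hm, markers, hm >= 0)
    for x, oid in ((5, 1), (15, 2)):
        core = hm > valley_level + 1
        side = np.zeros_like(core)
        side[:, :10] = core[:, :10] if x == 5 else False
        side[:, 10:] = core[:, 10:] if x == 15 else False
        assert set(oracle[side].tolist()) == {oid}


def test_flat_map_is_one_compartment_and_sentinel_map_is_empty():
    flat = HeightMap(np.full((6, 6), 4), SP)
    labels = watershed_compartments(flat, h_min=2)
    assert labels.labels() == [1]
    assert (labels.data == 1).all()
    empty = HeightMap(np.full((6, 6), -1), SP)
    assert watershed_compartments(empty).labels() == []


# ---------------------------------------------------------------- selection

def _dome_plus_lobe_labels():
    n = 41
    y, x = np.mgrid[0:n, 0:n]
    hm = np.full((n, n), -1)
    hm[np.hypot(y - 20, x - 20) <= 8] = 10   # central dome footprint
    hm[np.hypot(y - 6, x - 32) <= 4] = 12    # off-center lobe
    labels = watershed_compartments(HeightMap(hm, SP), h_min=1)
    return labels, HeightMap(hm, SP)


def test_centermost_prefers_the_central_compartment():
    labels, hm = _dome_plus_lobe_labels()
    sel = select_nectary_compartment(labels, hm, "centermost")
    assert labels.data[20, 20] in sel.ids
    sel_l = select_nectary_compartment(labels, hm, "largest")
    assert labels.data[20, 20] in sel_l.ids  # central dome is also larger


def test_single_compartment_chosen_under_any_strategy():
    g, dome = _dome_grid(r=8)
    h = height_zproject(BinaryMask(dome, SP))
    labels = watershed_compartments(h, h_min=1)
    for strategy in ("centermost", "largest", 1):
        sel = select_nectary_compartment(labels, h, strategy)
        assert sel.ids == (1,)
        assert sel.footprint.sum() == (labels.data == 1).sum()


def test_manual_id_absent_raises():
    labels, hm = _dome_plus_lobe_labels()
    with pytest.raises(ValueError, match="not present"):
        select_nectary_compartment(labels, hm, 99)
    from nectarct.segmentation import LabelMap
    with pytest.raises(ValueError, match="empty"):
        select_nectary_compartment(LabelMap(np.zeros((4, 4), np.int32)), hm)


# ------------------------------------------------------------- lower surface

def _selection_from_footprint(fp):
    from scipy import ndimage
    eroded = ndimage.binary_erosion(fp, border_value=0)
    return SelectedCompartment(ids=(1,), footprint=fp, contour=fp & ~eroded)


def test_flat_base_gives_constant_lower_surface():
    g, dome = _dome_grid(r=10)
    sel = _selection_from_footprint(dome.any(axis=0))
    lower = interpolate_lower_surface(sel, BinaryMask(dome, SP))
    assert (lower.data[sel.footprint] == 0).all()


def test_linear_ramp_boundary_reproduces_the_plane():
    # tissue occupying z >= 2 + y (a planar base), footprint a 9x9 square
    nz, n = 20, 9
    zz, yy, _ = np.mgrid[0:nz, 0:n, 0:n]
    tissue = zz >= 2 + yy
    fp = np.ones((n, n), bool)
    sel = _selection_from_footprint(fp)
    lower = interpolate_lower_surface(sel, BinaryMask(tissue, SP))
    expect = 2 + np.mgrid[0:n, 0:n][0]
    np.testing.assert_array_equal(lower.data[fp], expect[fp])


def test_gently_curved_hidden_base_recovered_within_two_voxels():
    """Gland with a shallow spherical-cap base (sagitta 4 over a 61-voxel
    footprint): harmonic interpolation from the rim recovers the hidden
    base with MAE <= 2 voxels."""
    r_fp, sag = 30, 4.0
    n = 2 * r_fp + 1
    nz = 25
    c = r_fp
    y, x = np.mgrid[0:n, 0:n]
    rho = np.hypot(y - c, x - c)
    fp = rho <= r_fp
    # spherical-cap base: z = sag * (1 - (rho/r_fp)^2) (paraboloid cap)
    base = np.where(fp, sag * (1 - (rho / r_fp)**2), 0)
    zz = np.mgrid[0:nz][:, None, None]
    tissue = fp[None] & (zz >= base[None]) & (zz <= 20)
    sel = _selection_from_footprint(fp)
    lower = interpolate_lower_surface(sel, BinaryMask(tissue, SP))
    true_lowest = np.ceil(base)[fp]
    mae = np.abs(lower.data[fp] - true_lowest).mean()
    assert mae <= 2.0


def test_lower_surface_errors_without_tissue():
    fp = np.ones((5, 5), bool)
    sel = _selection_from_footprint(fp)
    with pytest.raises(ValueError, match="no tissue"):
        interpolate_lower_surface(sel, BinaryMask(np.zeros((4, 5, 5), bool), SP))


# ----------------------------------------------------------------- 3D mask

def test_build_mask_slab_and_empty():
    fp = np.zeros((5, 5), bool)
    fp[1:4, 1:4] = True
    up = HeightMap(np.where(fp, 3, -1), SP)
    lo = HeightMap(np.where(fp, 3, -1), SP)
    mask = build_nectary_mask(up, lo, fp, nz=6, spacing_um=SP)
    assert mask.voxel_count() == 9
    assert mask.data[3].sum() == 9
    empty = build_nectary_mask(up, lo, np.zeros((5, 5), bool), 6, SP)
    assert empty.voxel_count() == 0
    with pytest.raises(ValueError):
        build_nectary_mask(lo, HeightMap(np.where(fp, 4, -1), SP), fp, 6, SP)


# ---------------------------------------------------------- volume & surface

def test_mask_volume_cube_sphere_and_empty(sphere_solid):
    cube = BinaryMask(np.ones((10, 10, 10), bool), 5)
    assert mask_volume(cube) == pytest.approx(1.25e-4, rel=1e-12)
    assert mask_volume(BinaryMask(np.zeros((2, 2, 2), bool), 5)) == 0
    _, truth = sphere_solid
    vol = mask_volume(truth.nectary_mask)
    assert vol == pytest.approx(4.18879e-3, rel=0.02)


def test_volume_additivity_for_disjoint_masks():
    rng = np.random.default_rng(3)
    a = rng.random((8, 8, 8)) < 0.3
    b = (rng.random((8, 8, 8)) < 0.3) & ~a
    u = BinaryMask(a | b, 5)
    assert mask_volume(u) == pytest.approx(
        mask_volume(BinaryMask(a, 5)) + mask_volume(BinaryMask(b, 5)))


def test_surface_cube_single_voxel_and_estimators():
    cube = np.zeros((16, 16, 16), bool)
    cube[3:13, 3:13, 3:13] = True
    m = BinaryMask(cube, 5)
    assert mask_surface_area(m, estimator="exposed_faces") == \
        pytest.approx(600 * 25e-6, rel=1e-12)  # 6n^2 faces
    one = np.zeros((3, 3, 3), bool)
    one[1, 1, 1] = True
    assert mask_surface_area(BinaryMask(one, 5)) == pytest.approx(1.5e-4)
    # surface_voxels counts boundary voxels, not faces
    assert mask_surface_area(m, estimator="surface_voxels") == \
        pytest.approx((1000 - 8**3) * 25e-6, rel=1e-12)
    with pytest.raises(ValueError):
        mask_surface_area(m, estimator="marching")


def test_exposed_faces_match_brute_force_scan():
    g, dome = _dome_grid(r=8)
    m = BinaryMask(dome, 5)
    fast = mask_surface_area(m, estimator="exposed_faces")
    faces = 0
    nz, ny, nx = dome.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not dome[z, y, x]:
                    continue
                for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    zz_, yy_, xx_ = z + dz, y + dy, x + dx
                    if not (0 <= zz_ < nz and 0 <= yy_ < ny and 0 <= xx_ < nx) \
                            or not dome[zz_, yy_, xx_]:
                        faces += 1
    assert fast == pytest.approx(faces * 25e-6, rel=1e-12)


def test_gland_surface_excludes_contact_with_other_organs():
    # gland slab pressed against a style wall: contact faces are not air
    gland = np.zeros((6, 6, 6), bool)
    gland[1:3, 1:5, 1:5] = True
    tissue = gland.copy()
    tissue[3, 1:5, 1:5] = True  # another organ resting on top
    air = ~tissue
    with_contact = mask_surface_area(BinaryMask(gland, 5), air=air)
    isolated = mask_surface_area(BinaryMask(gland, 5))
    assert with_contact < isolated


# ------------------------------------------------------------- full pipeline

def test_voi_bookkeeping_preserves_downstream_volume():
    g, dome = _dome_grid(r=12, margin=6)
    full = segment_nectary(g)
    voi = segment_nectary(g, z_first=0, z_last=13)
    assert voi.volume_mm3 == full.volume_mm3
    assert dice(voi.mask.data, full.mask.data) == 1.0
    with pytest.raises(ValueError):
        select_voi(g, 5, 3)
    single = select_voi(g, 3, 4)
    assert single.grid.shape[0] == 1


def test_pipeline_recovers_dome_within_tolerance(male_phantom):
    grid, truth = male_phantom
    model = segment_nectary(grid, z_first=truth.voi[0], z_last=truth.voi[1])
    assert dice(model.mask.data, truth.nectary_mask.data) >= 0.95
    err = abs(model.volume_mm3 - truth.nectary_volume_mm3)
    assert err / truth.nectary_volume_mm3 < 0.02
    # lower <= upper wherever the gland was found
    fp = model.mask.data.any(axis=0)
    assert (model.lower_surface.data[fp] <= model.upper_surface.data[fp]).all()


def test_pipeline_is_deterministic(male_phantom):
    grid, truth = male_phantom
    kw = dict(z_first=truth.voi[0], z_last=truth.voi[1])
    m1 = segment_nectary(grid, **kw)
    m2 = segment_nectary(grid, **kw)
    np.testing.assert_array_equal(m1.mask.data, m2.mask.data)
    assert m1.volume_mm3 == m2.volume_mm3
    assert m1.surface_mm2 == m2.surface_mm2


def test_resolution_consistency_volume_and_manhattan_surface():
    """Halving the spacing on the same continuum dome changes the measured
    volume by < 2%, while the face-count surface stays above the smooth
    continuum area (Manhattan voxel surface overestimates)."""
    vols, surfs = {}, {}
    for r, sp in ((10, 10.0), (20, 5.0)):
        nyx = 2 * r + 9
        c = (nyx - 1) / 2.0
        zz, yy, xx = np.mgrid[0:r + 4, 0:nyx, 0:nyx]
        dome = (zz + 0.5)**2 + (yy - c)**2 + (xx - c)**2 <= r**2
        m = BinaryMask(dome, sp)
        vols[sp] = mask_volume(m)
        surfs[sp] = mask_surface_area(m, estimator="exposed_faces")
    assert abs(vols[5.0] - vols[10.0]) / vols[10.0] < 0.02
    continuum_mm2 = (2 * math.pi * 0.1**2 + math.pi * 0.1**2)  # cap + base disc
    assert surfs[5.0] >= continuum_mm2


def test_2d_section_blind_to_3d_volume_difference():
    """Male and female glands built with near-equal central cross-sections
    still differ ~2.7x in volume; the pipeline resolves the 3D difference
    the 2D proxy misses."""
    from nectarct.morphometry import cross_section_area
    male = FlowerPhantomSpec(sex="male", dome_radius_vox=20)
    female = FlowerPhantomSpec(sex="female", annulus_inner_radius_vox=16,
                               annulus_outer_radius_vox=30,
                               annulus_height_vox=22)
    gm, tm = make_flower_phantom(male)
    gf, tf = make_flower_phantom(female)
    cs_m = cross_section_area(tm.nectary_mask)
    cs_f = cross_section_area(tf.nectary_mask)
    assert abs(cs_f - cs_m) / cs_m < 0.10
    true_ratio = tf.nectary_volume_mm3 / tm.nectary_volume_mm3
    mm = segment_nectary(gm, z_first=tm.voi[0], z_last=tm.voi[1])
    labels = watershed_compartments(
        height_zproject(threshold_tissue(
            select_voi(gf, *tf.voi).grid).mask, z_offset=tf.voi[0]))
    probe_label = int(labels.data[tf.nectary_probe_yx])
    mf = segment_nectary(gf, z_first=tf.voi[0], z_last=tf.voi[1],
                         compartment=probe_label)
    measured_ratio = mf.volume_mm3 / mm.volume_mm3
    assert abs(measured_ratio - true_ratio) / true_ratio < 0.05
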