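"""Droplet segmentation, particle measurement and per-cell counting."""

import numpy as np
import pytest
from skimage.draw import disk

from droplens.config import AnalysisConfig
from droplens.morphometry import (count_lds_per_cell, line_intensity_profile,
                                  max_project, measure_particles,
                                  measure_stack, passing_diameters, segment)


def disk_image(shape=(64, 64), centre=(32, 32), radius=10, value=100.0):
    img = np.zeros(shape)
    rr, cc = disk(centre, radius, shape=shape)
    img[rr, cc] = value
    return img


# ---------------------------------------------------------------------------
# projection

def test_single_plane_projection_is_identity():
    img = disk_image()
    np.testing.assert_array_equal(max_project(img[None]), img)


def test_projection_unions_disjoint_planes():
    a = disk_image(centre=(16, 16), radius=5)
    b = disk_image(centre=(48, 48), radius=5)
    proj = max_project(np.stack([a, b]))
    np.testing.assert_array_equal(proj, np.maximum(a, b))


def test_sphere_stack_projects_to_equatorial_disk():
    """A sphere sliced into 35 planes projects to a disk of its equatorial
    diameter."""
    from droplens.synthetic.imaging import ImagingPlant, _render_droplet
    plant = ImagingPlant(noise=False, blur_sigma_px=0.0,
                         field_shape=(64, 64))
    stack = np.zeros((35, 64, 64))
    _render_droplet(stack, plant, 1.6, 1.6, 4.2, 1.0)  # 1 µm sphere
    proj = max_project(stack)
    row = proj[32] > plant.amplitude / 2
    # 1 µm / 0.05 µm px = 20 px equatorial diameter (+- 1 px rasterisation)
    assert abs(row.sum() - 20) <= 1


def test_empty_stack_rejected():
    with pytest.raises(ValueError):
        max_project(np.zeros((0, 4, 4)))


# ---------------------------------------------------------------------------
# segmentation

def test_single_disk_single_label():
    labels = segment(disk_image() + np.random.default_rng(0).normal(
        0, 1e-3, (64, 64)))
    assert labels.max() == 1


def test_blank_image_zero_labels():
    assert segment(np.zeros((32, 32))).max() == 0


def test_watershed_splits_touching_disks():
    img = np.zeros((64, 96))
    rr, cc = disk((32, 34), 12, shape=img.shape)
    img[rr, cc] = 100.0
    rr, cc = disk((32, 52), 12, shape=img.shape)  # overlap < 1 radius
    img[rr, cc] = 100.0
    assert segment(img, do_watershed=False).max() == 1
    assert segment(img, do_watershed=True).max() == 2


# ---------------------------------------------------------------------------
# measurement

def test_disk_measurement_and_circularity(cfg):
    labels = (disk_image(radius=10) > 0).astype(int)
    table = measure_particles(labels, pixel_size=0.05, cfg=cfg)
    assert len(table) == 1
    row = table.iloc[0]
    assert row["major_um"] == pytest.approx(1.0, abs=0.05)
    assert row["circularity"] >= 0.95
    assert row["passed"]


def test_thin_bar_filtered_by_circularity(cfg):
    labels = np.zeros((32, 32), dtype=int)
    labels[10:12, 5:25] = 1  # 20 x 2 px bar: 4*pi*A/P^2 well below 0.8
    table = measure_particles(labels, pixel_size=0.05, cfg=cfg)
    assert not table.iloc[0]["pass_circularity"]
    assert len(passing_diameters(table)) == 0


def test_small_particle_filtered_by_area(cfg):
    labels = np.zeros((16, 16), dtype=int)
    labels[8, 8] = 1  # single pixel: 0.0025 um^2 < 0.01 um^2
    table = measure_particles(labels, pixel_size=0.05, cfg=cfg)
    assert not table.iloc[0]["pass_area"]


def test_filters_only_remove_rows(cfg):
    rng = np.random.default_rng(1)
    labels = segment(disk_image() + rng.normal(0, 2, (64, 64)))
    table = measure_particles(labels, pixel_size=0.05, cfg=cfg)
    sub = table[table["passed"]]
    assert set(sub.index).issubset(set(table.index))


def test_area_conservation_without_watershed(cfg):
    """Sum of particle areas equals foreground pixel count x pixel area."""
    img = disk_image() + disk_image(centre=(10, 50), radius=4)
    labels = segment(img, do_watershed=False)
    table = measure_particles(labels, pixel_size=0.05, cfg=cfg)
    assert table["area_um2"].sum() == pytest.approx(
        (labels > 0).sum() * 0.05 ** 2)


def test_bad_pixel_size_rejected():
    with pytest.raises(ValueError):
        measure_particles(np.ones((4, 4), dtype=int), pixel_size=0.0)


# ---------------------------------------------------------------------------
# per-cell counting

def test_three_droplets_in_one_cell():
    labels = np.zeros((64, 64), dtype=int)
    for k, c in enumerate([(20, 20), (30, 30), (40, 20)], start=1):
        rr, cc = disk(c, 4, shape=labels.shape)
        labels[rr, cc] = k
    mask = np.zeros((64, 64), dtype=int)
    rr, cc = disk((30, 25), 25, shape=mask.shape)
    mask[rr, cc] = 1
    per_cell, summary = count_lds_per_cell(labels, mask, pixel_size=1.0)
    assert per_cell.iloc[0]["n_lds"] == 3
    assert summary["frac_ge3"] == 1.0


def test_unassigned_particles_reported():
    labels = np.zeros((64, 64), dtype=int)
    rr, cc = disk((5, 5), 3, shape=labels.shape)
    labels[rr, cc] = 1
    mask = np.zeros((64, 64), dtype=int)
    rr, cc = disk((40, 40), 10, shape=mask.shape)
    mask[rr, cc] = 1
    _per_cell, summary = count_lds_per_cell(labels, mask, pixel_size=1.0)
    assert summary["unassigned"] == 1


def test_no_cells_rejected():
    with pytest.raises(ValueError):
        count_lds_per_cell(np.zeros((8, 8), dtype=int),
                           np.zeros((8, 8), dtype=int))


# ---------------------------------------------------------------------------
# line profiles

def _rim_image(spacing_px=16):
    img = np.zeros((64, 64))
    x = np.arange(64)
    c = 32
    for offset in (-spacing_px // 2, spacing_px // 2):
        img += 100 * np.exp(-((x - (c + offset)) ** 2) / 4.0)[None, :]
    return img


def test_rim_peak_spacing():
    img = _rim_image(16)  # 16 px * 0.05 µm = 0.8 µm
    prof = line_intensity_profile(img, (32, 4), (32, 60), width=3,
                                  pixel_size=0.05)
    assert not prof.flagged
    assert prof.spacing == pytest.approx(0.8, abs=0.05)  # within 1 px


def test_flat_profile_flagged():
    prof = line_intensity_profile(np.ones((32, 32)), (16, 2), (16, 30))
    assert prof.flagged
    assert prof.spacing is None


def test_spacing_invariant_under_reversal():
    img = _rim_image(12)
    a = line_intensity_profile(img, (32, 4), (32, 60), pixel_size=0.05)
    b = line_intensity_profile(img, (32, 60), (32, 4), pixel_size=0.05)
    assert a.spacing == pytest.approx(b.spacing, abs=1e-9)


def test_endpoint_outside_image_rejected():
    with pytest.raises(ValueError):
        line_intensity_profile(np.ones((16, 16)), (0, 0), (20, 20))
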