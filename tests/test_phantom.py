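"""Phantom generator: geometry, degradation model, determinism, sections."""

import numpy as np
import pytest
from scipy import ndimage

from petcontour import (
    Ellipsoid,
    PhantomConfig,
    cut_histology_section,
    generate_phantom,
)
from petcontour._utils import block_majority
from petcontour.dataio import AIR, NECROTIC, NORMAL, VIABLE
from conftest import small_config


def test_default_grid_is_scanner_matrix():
    """Default acquisition grid is 128 x 128 x 120 at 1 mm voxels."""
    config = PhantomConfig()
    assert config.grid_shape == (128, 128, 120)
    assert config.voxel_size_mm == 1.0
    assert 3 <= config.n_sections <= 5


def test_undegraded_phantom_paints_exact_class_means():
    """With no blur/noise/variability every voxel carries its class mean."""
    config = small_config(
        psf_fwhm_mm=0.0,
        noise_model="none",
        uptake_sd_fraction=0.0,
        fiducial_intensity=0.0,
        uptake_viable_mean=100.0,
        uptake_necrotic_mean=10.0,
    )
    volume, truth = generate_phantom(config)
    assert np.all(volume.counts[truth.label_volume == VIABLE] == 100.0)
    assert np.all(volume.counts[truth.label_volume == NECROTIC] == 10.0)
    assert np.all(volume.counts[truth.label_volume == AIR] == 0.0)


def test_same_seed_bit_identical():
    v1, t1 = generate_phantom(small_config(seed=5))
    v2, t2 = generate_phantom(small_config(seed=5))
    assert np.array_equal(v1.counts, v2.counts)
    assert np.array_equal(t1.label_volume, t2.label_volume)
    v3, _ = generate_phantom(small_config(seed=6))
    assert not np.array_equal(v1.counts, v3.counts)


def test_psf_matches_dense_convolution_oracle():
    """Blurred value at the tumor center equals a brute-force discrete
    Gaussian convolution sum over a 15^3 neighborhood."""
    config = small_config(
        psf_fwhm_mm=2.0, noise_model="none", uptake_sd_fraction=0.0,
        fiducial_intensity=0.0,
    )
    volume, truth = generate_phantom(config)
    # independent reconstruction of the unblurred class image
    means = np.zeros(4)
    means[NORMAL], means[NECROTIC], means[VIABLE] = (
        config.uptake_normal_mean, config.uptake_necrotic_mean,
        config.uptake_viable_mean,
    )
    img = means[truth.label_volume]
    img[truth.liver_mask] = config.uptake_liver_mean
    sigma = config.psf_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / config.voxel_size_mm
    r = 7
    offs = np.arange(-r, r + 1)
    w1 = np.exp(-(offs**2) / (2 * sigma**2))
    w1 /= w1.sum()
    cx, cy, cz = (int(c) for c in config.tumor_center_mm)
    patch = img[cx - r : cx + r + 1, cy - r : cy + r + 1, cz - r : cz + r + 1]
    expected = np.einsum("ijk,i,j,k->", patch, w1, w1, w1)
    assert volume.counts[cx, cy, cz] == pytest.approx(expected, rel=2e-3)


def test_fine_sections_match_rasterization_oracle_and_analytic_area():
    """Fine cut-surface labels equal an independent pixel-center
    rasterization; the viable pixel count matches the analytic
    annulus-minus-inclusions area to within one boundary-pixel layer."""
    config = small_config(psf_fwhm_mm=0.0, noise_model="none", uptake_sd_fraction=0.0)
    _, truth = generate_phantom(config)
    cut = truth.section_plane_indices["pos2-rostral"]
    section = cut_histology_section(truth, cut, "rostral")
    h = config.histology_pixel_mm
    n = section.labels.shape[0]
    xs = (np.arange(n) + 0.5) * h
    z = (cut + 0.5) * config.voxel_size_mm
    X, Y = np.meshgrid(xs, (np.arange(section.labels.shape[1]) + 0.5) * h, indexing="ij")

    def inside(ell):
        cx, cy, cz = ell.center_mm
        rx, ry, rz = ell.radii_mm
        return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1

    viable_oracle = inside(config.tumor)
    for nec in config.necrosis_spec:
        viable_oracle &= ~inside(nec)
    for cord in config.viable_cords:
        viable_oracle |= inside(cord) & inside(config.tumor)
    assert np.array_equal(section.labels == VIABLE, viable_oracle)

    # analytic in-plane area of the viable region at this z
    def disc_area(ell):
        cz, rz = ell.center_mm[2], ell.radii_mm[2]
        f = 1 - ((z - cz) / rz) ** 2
        return np.pi * ell.radii_mm[0] * ell.radii_mm[1] * max(f, 0.0)

    analytic = disc_area(config.tumor) - sum(disc_area(n) for n in config.necrosis_spec)
    analytic += sum(disc_area(c) for c in config.viable_cords)
    measured = (section.labels == VIABLE).sum() * h**2
    # one boundary-pixel layer along every curve boundary
    perimeter = sum(
        2 * np.pi * max(e.radii_mm[:2])
        for e in (config.tumor, *config.necrosis_spec, *config.viable_cords)
    )
    assert abs(measured - analytic) < perimeter * h


def test_label_conservation_at_section_planes(clean_small_phantom):
    """Block-downsampled fine sections reproduce the coarse truth exactly."""
    _, truth = clean_small_phantom
    factor = int(round(truth.config.voxel_size_mm / truth.config.histology_pixel_mm))
    for section in truth.fine_label_sections:
        plane = truth.section_plane_indices[section.section_id]
        coarse = block_majority(section.labels, factor)
        assert np.array_equal(coarse, truth.label_volume[:, :, plane])


def test_cluster_structure_two_surfaces_per_position(default_small_phantom):
    """Each sectioning position owns exactly a rostral and a caudal surface,
    each matched to one PET slice."""
    _, truth = default_small_phantom
    clusters = {}
    for s in truth.fine_label_sections:
        clusters.setdefault(s.cluster_id, []).append(s)
        assert s.section_id in truth.section_plane_indices
    for members in clusters.values():
        assert sorted(m.side for m in members) == ["caudal", "rostral"]
    manifest = truth.manifest()
    assert len(manifest.entries) == 2 * len(clusters)


def test_class_separation_without_degradation():
    """With no noise and no PSF, a moderate within-class CV keeps the
    dimmest viable voxel above the hottest necrotic voxel, so a perfectly
    separating threshold exists."""
    config = small_config(psf_fwhm_mm=0.0, noise_model="none")
    assert config.uptake_sd_fraction < 0.5 * (
        1 - config.uptake_necrotic_mean / config.uptake_viable_mean
    )
    volume, truth = generate_phantom(config)
    viable = volume.counts[truth.label_volume == VIABLE]
    necrotic = volume.counts[truth.label_volume == NECROTIC]
    assert viable.min() > necrotic.max()


def test_poisson_region_mean_within_3_se():
    """Poisson counts over a uniform region average to the painted mean."""
    config = small_config(
        psf_fwhm_mm=0.0, noise_model="poisson", uptake_sd_fraction=0.0,
        fiducial_intensity=0.0, seed=3,
    )
    volume, truth = generate_phantom(config)
    normal = (truth.label_volume == NORMAL) & ~truth.liver_mask
    vals = volume.counts[normal]
    assert vals.size >= 10_000
    se = np.sqrt(config.uptake_normal_mean / vals.size)
    assert abs(vals.mean() - config.uptake_normal_mean) < 3 * se


def test_geometry_errors():
    with pytest.raises(ValueError, match="outside the image grid"):
        generate_phantom(small_config(tumor_center_mm=(60.0, 40.0, 24.0)))
    with pytest.raises(ValueError, match="not inside the tumor"):
        generate_phantom(
            small_config(
                necrosis_spec=(Ellipsoid((40.0, 40.0, 24.0), (4.0, 4.0, 4.0)),)
            )
        )
    with pytest.raises(ValueError, match="uptake_viable_mean > uptake_necrotic"):
        small_config(uptake_necrotic_mean=500.0)


def test_cut_section_lookup_and_flags(clean_small_phantom):
    _, truth = clean_small_phantom
    planes = sorted(set(truth.section_plane_indices.values()))
    s = cut_histology_section(truth, planes[0], "rostral")
    assert s.has_tumor and s.pixel_size_mm == truth.config.histology_pixel_mm
    with pytest.raises(ValueError, match="not among"):
        cut_histology_section(truth, 1, "rostral")


def test_section_outside_tumor_has_no_tumor_pixels():
    """A sectioning plane through normal tissue only is flagged, not an error."""
    config = small_config(section_planes=(5, 24))
    _, truth = generate_phantom(config)
    s = cut_histology_section(truth, 5, "rostral")
    assert not s.has_tumor
    assert cut_histology_section(truth, 24, "rostral").has_tumor
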