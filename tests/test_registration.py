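"""Fiducial Procrustes fit, area-plurality resampling, pair assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petcontour import (
    HistologySection,
    ManifestEntry,
    RigidTransform2D,
    build_pair,
    fit_fiducial_transform,
    resample_labels,
)
from petcontour._utils import block_majority
from petcontour.dataio import AIR, NECROTIC, NORMAL, VIABLE


def _section(labels, h=0.125):
    return HistologySection(
        labels=np.asarray(labels), pixel_size_mm=h, cluster_id="c",
        side="rostral", section_id="s",
    )


class TestFiducialFit:
    def test_identity(self):
        pts = np.array([[1.0, 2.0], [5.0, 7.0], [3.0, 1.0]])
        tf, rms = fit_fiducial_transform(pts, pts)
        assert rms == pytest.approx(0.0, abs=1e-12)
        assert tf.rotation_rad == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.translation_mm, 0.0, atol=1e-12)

    def test_pure_translation(self):
        pts = np.array([[0.0, 0.0], [4.0, 1.0]])
        tf, rms = fit_fiducial_transform(pts, pts + [3.0, -2.0])
        assert np.allclose(tf.translation_mm, [3.0, -2.0], atol=1e-12)
        assert tf.rotation_rad == pytest.approx(0.0, abs=1e-12)
        assert rms < 1e-12

    def test_quarter_turn_about_centroid(self):
        pts = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0]]) + [5.0, 5.0]
        c = pts.mean(axis=0)
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        moved = (pts - c) @ R.T + c
        tf, _ = fit_fiducial_transform(pts, moved)
        assert tf.rotation_rad == pytest.approx(np.pi / 2, abs=1e-9)

    def test_degenerate_and_underdetermined(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_fiducial_transform([[1.0, 1.0], [1.0, 1.0]], [[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match=">= 2"):
            fit_fiducial_transform([[1.0, 1.0]], [[0.0, 0.0]])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        angle=st.floats(-np.pi, np.pi),
        tx=st.floats(-20, 20),
        ty=st.floats(-20, 20),
    )
    def test_recovery_of_random_rigid_transforms(self, angle, tx, ty):
        """Noise-free fiducials recover the true transform to < 0.1 px."""
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [4.0, 7.0]])
        true = RigidTransform2D(rotation_rad=angle, translation_mm=[tx, ty])
        tf, rms = fit_fiducial_transform(pts, true.apply(pts))
        probe = np.array([[2.0, 3.0]])
        assert np.max(np.abs(tf.apply(probe) - true.apply(probe))) < 0.1
        assert rms < 1e-9

    def test_similarity_fit_recovers_scale(self):
        pts = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 6.0]])
        true = RigidTransform2D(rotation_rad=0.3, translation_mm=[1.0, -2.0], scale=1.07)
        tf, rms = fit_fiducial_transform(pts, true.apply(pts), allow_scale=True)
        assert tf.scale == pytest.approx(1.07, abs=1e-9)
        assert rms < 1e-9


class TestResampleLabels:
    def test_uniform_block_collapses(self):
        section = _section(np.full((8, 8), VIABLE))
        out = resample_labels(section, RigidTransform2D(), 1.0, (1, 1))
        assert out.shape == (1, 1) and out[0, 0] == VIABLE

    def test_plurality_and_tie_rules(self):
        block = np.full((8, 8), NECROTIC)
        block.ravel()[:33] = VIABLE  # 33 viable vs 31 necrotic
        out = resample_labels(_section(block), RigidTransform2D(), 1.0, (1, 1))
        assert out[0, 0] == VIABLE
        block.ravel()[:32] = VIABLE
        block.ravel()[32:] = NECROTIC  # exact 32/32 tie
        out = resample_labels(_section(block), RigidTransform2D(), 1.0, (1, 1))
        assert out[0, 0] == VIABLE  # viable wins ties

    def test_matches_block_majority_oracle(self, rng):
        fine = rng.integers(0, 4, size=(64, 64))
        out = resample_labels(_section(fine), RigidTransform2D(), 1.0, (8, 8))
        assert np.array_equal(out, block_majority(fine, 8))

    def test_non_integer_factor_area_overlap(self):
        """0.127 mm pixels onto a 1 mm grid: coarse cell (0,0) is dominated
        by the labels covering most of its 1 mm^2 of area."""
        fine = np.full((16, 16), NORMAL)
        fine[:4, :] = VIABLE  # x in [0, 0.508) mm
        out = resample_labels(_section(fine, h=0.127), RigidTransform2D(), 1.0, (2, 2))
        # cell (0,0) covers x in [0,1): viable area 0.508 > normal 0.492
        assert out[0, 0] == VIABLE
        # cell (1,0) covers x in [1, 2.032): entirely normal
        assert out[1, 0] == NORMAL

    def test_rotated_transform_quarter_turn(self):
        fine = np.zeros((16, 16), dtype=int)
        fine[:8, :] = VIABLE  # left half viable
        tf = RigidTransform2D(rotation_rad=np.pi / 2, translation_mm=[2.0, 0.0])
        out = resample_labels(_section(fine), tf, 1.0, (2, 2))
        # left-half-in-x becomes bottom-half-in-y under a quarter turn
        assert out[0, 0] == VIABLE or out[1, 0] == VIABLE

    def test_errors(self):
        section = _section(np.zeros((8, 8), dtype=int))
        with pytest.raises(ValueError, match="entirely outside"):
            resample_labels(section, RigidTransform2D(translation_mm=[100.0, 0.0]),
                            1.0, (2, 2))
        with pytest.raises(ValueError, match="must be >="):
            resample_labels(section, RigidTransform2D(), 0.01, (2, 2))


class TestBuildPair:
    def test_phantom_pair_matches_downsampled_truth(self, clean_small_phantom):
        """With identity geometry the coarse labels equal the
        block-downsampled phantom truth exactly."""
        volume, truth = clean_small_phantom
        entry = truth.manifest().entries[0]
        pair = build_pair(volume, truth.section(entry.section_id), entry)
        plane = truth.section_plane_indices[entry.section_id]
        assert np.array_equal(pair.labels_coarse, truth.label_volume[:, :, plane])
        assert pair.wta_px.sum() == pair.viable_px.sum() + pair.necrotic_px.sum()
        assert not (pair.viable_px & pair.necrotic_px).any()

    def test_injected_offset_recovered(self, clean_small_phantom):
        """Shifting both the section content frame and its fiducials by a
        known offset yields the same registered pair as the unshifted one."""
        volume, truth = clean_small_phantom
        entry = truth.manifest().entries[0]
        section = truth.section(entry.section_id)
        dx_px, dy_px = 16, 24  # fine pixels (= 2 and 3 mm)
        h = section.pixel_size_mm
        shifted_labels = np.full_like(section.labels, AIR)
        shifted_labels[dx_px:, dy_px:] = section.labels[:-dx_px, :-dy_px]
        shifted = HistologySection(
            labels=shifted_labels, pixel_size_mm=h, cluster_id=section.cluster_id,
            side=section.side, section_id=section.section_id,
        )
        shift_mm = np.array([dx_px * h, dy_px * h])
        entry_shifted = ManifestEntry(
            section_id=entry.section_id,
            pet_slice_index=entry.pet_slice_index,
            cluster_id=entry.cluster_id,
            fiducials_histo_mm=entry.fiducials_histo_mm + shift_mm,
            fiducials_pet_mm=entry.fiducials_pet_mm,
        )
        ref = build_pair(volume, section, entry)
        rec = build_pair(volume, shifted, entry_shifted)
        assert np.array_equal(ref.labels_coarse, rec.labels_coarse)
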