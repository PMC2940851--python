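"""DX, H, SM, PSM computed on disc-aligned images."""

import numpy as np
import pytest

from discsig import (
    DiscAlignedImage,
    IntensityProfile,
    PipelineSettings,
    ZeroMassError,
    compute_all,
    compute_DX,
    compute_H,
    compute_profile,
    compute_SM_PSM,
    generate_disc_phantom,
    geometric_center,
    nucleus_seed_pixel,
    weighted_center,
)

from conftest import SPACING, make_spec


def aligned_from(intensity, mask, spacing=1.0):
    intensity = np.asarray(intensity, dtype=float)
    rows, cols = intensity.shape
    return DiscAlignedImage(
        intensity=intensity, mask=np.asarray(mask, bool),
        pixel_spacing_mm=spacing,
        axis_positions_mm=np.arange(cols) * spacing,
        perp_positions_mm=np.arange(rows) * spacing,
    )


class TestWeightedCenter:
    def test_hand_example_three_pixels(self):
        # pixels at x = 0, 1, 2 mm with Si = 1, 1, 2 -> X = 1.25 mm
        aligned = aligned_from([[1.0, 1.0, 2.0]], [[1, 1, 1]])
        assert weighted_center(aligned)[0] == pytest.approx(1.25)

    def test_uniform_intensity_gives_geometric_center(self):
        mask = np.zeros((7, 9), bool)
        mask[2:5, 3:8] = True
        aligned = aligned_from(np.full((7, 9), 4.2), mask)
        assert np.allclose(weighted_center(aligned), geometric_center(aligned))

    def test_zero_mass_raises(self):
        aligned = aligned_from([[0.0, 0.0]], [[1, 1]])
        with pytest.raises(ZeroMassError):
            weighted_center(aligned)


class TestDX:
    def test_symmetric_intensity_gives_zero(self):
        aligned = aligned_from([[1.0, 5.0, 1.0]], [[1, 1, 1]])
        signed, dx = compute_DX(aligned)
        assert signed == 0.0 and dx == 0.0

    def test_doubling_intensities_leaves_dx_unchanged(self, gradient_phantom):
        spec, slc, truth = gradient_phantom
        m1 = compute_all(slc, nucleus_seed_pixel(spec))
        doubled = type(slc)(slc.intensity * 2, slc.pixel_spacing_mm)
        m2 = compute_all(doubled, nucleus_seed_pixel(spec))
        assert m2.DX_mm == pytest.approx(m1.DX_mm, abs=1e-12)
        assert m2.SM == pytest.approx(2 * m1.SM, rel=1e-12)

    def test_gradient_phantom_matches_oracle_to_numerical_precision(
            self, gradient_phantom):
        from discsig import NucleusMask, to_disc_frame
        from discsig.metrics import metrics_from_aligned
        spec, _, truth = gradient_phantom
        noiseless = type(generate_disc_phantom(spec)[0])(
            truth.noiseless_intensity, spec.pixel_spacing_mm)
        aligned = to_disc_frame(noiseless, NucleusMask(truth.nucleus_mask),
                                truth.frame)
        m = metrics_from_aligned(aligned)
        assert m.signed_DX_mm > 0
        assert m.signed_DX_mm == pytest.approx(truth.true_signed_DX_mm,
                                               abs=1e-9)


class TestProfile:
    def test_two_column_hand_example(self):
        aligned = aligned_from([[1.0, 2.0], [2.0, 3.0]], [[1, 1], [1, 1]],
                               spacing=0.625)
        profile = compute_profile(aligned)
        assert np.allclose(profile.sums, [3.0, 5.0])
        sm, psm = compute_SM_PSM(profile)
        assert sm == 5.0 and psm == pytest.approx(0.625)

    def test_profile_conserves_masked_total(self, gradient_phantom):
        from discsig import NucleusMask, to_disc_frame
        spec, slc, truth = gradient_phantom
        mask = NucleusMask(truth.nucleus_mask)
        aligned = to_disc_frame(slc, mask, truth.frame)
        profile = compute_profile(aligned)
        assert profile.sums.sum() == pytest.approx(
            aligned.intensity[aligned.mask].sum(), rel=1e-12)

    def test_profile_covers_only_masked_columns(self):
        mask = np.zeros((3, 5), bool)
        mask[1, 1:4] = True
        aligned = aligned_from(np.ones((3, 5)), mask)
        profile = compute_profile(aligned)
        assert np.allclose(profile.positions_mm, [1.0, 2.0, 3.0])

    def test_constant_profile_tie_breaks_to_smallest_position(self):
        aligned = aligned_from(np.ones((2, 4)), np.ones((2, 4), bool))
        sm, psm = compute_SM_PSM(compute_profile(aligned))
        assert psm == 0.0

    def test_uniform_rectangle_gives_constant_profile(self):
        aligned = aligned_from(np.full((4, 6), 2.0), np.ones((4, 6), bool))
        assert np.allclose(compute_profile(aligned).sums, 8.0)


class TestHeight:
    def test_single_pixel_line_height_is_one_spacing(self):
        mask = np.zeros((5, 7), bool)
        mask[2, 1:6] = True
        aligned = aligned_from(np.ones((5, 7)), mask, spacing=0.5)
        assert compute_H(aligned) == pytest.approx(0.5)

    def test_rasterized_ellipse_height(self, centered_phantom):
        # 3.5 mm perpendicular semi-axis: oracle-mask height 7.0 +- one px;
        # the segmenting pipeline may add one closing ring on top of that
        spec, slc, truth = centered_phantom
        assert truth.true_H_mm == pytest.approx(7.0, abs=SPACING)
        m = compute_all(slc, nucleus_seed_pixel(spec))
        assert m.H_mm == pytest.approx(truth.true_H_mm, abs=SPACING)

    def test_center_mode_reads_central_column(self):
        mask = np.zeros((6, 5), bool)
        mask[1:5, 0] = True      # tall end column
        mask[2:4, 1:5] = True    # thin body
        aligned = aligned_from(np.ones((6, 5)), mask)
        assert compute_H(aligned, mode="max") == 4.0
        assert compute_H(aligned, mode="center") == 2.0


class TestComputeAll:
    def test_matches_truth_on_noiseless_default_phantom(self, centered_phantom):
        spec, slc, truth = centered_phantom
        m = compute_all(slc, nucleus_seed_pixel(spec))
        assert m.DX_mm == pytest.approx(truth.true_DX_mm, abs=SPACING)
        assert m.H_mm == pytest.approx(truth.true_H_mm, abs=SPACING)
        assert m.PSM_mm == pytest.approx(truth.true_PSM_mm, abs=SPACING)
        assert m.SM == pytest.approx(truth.true_SM, rel=0.01)

    def test_repeated_runs_bit_identical(self, gradient_phantom):
        spec, slc, _ = gradient_phantom
        m1 = compute_all(slc, nucleus_seed_pixel(spec))
        m2 = compute_all(slc, nucleus_seed_pixel(spec))
        assert m1.as_dict() == m2.as_dict()

    def test_offset_pair_recovered_in_fixed_disc_frame(self):
        """Measured in one common (endplate-style) frame, translating the
        nucleus by d moves PSM by d."""
        cx, cy = 50.0, 50.0
        axis = ((cx - 30.0, cy), (cx + 30.0, cy))
        settings = PipelineSettings(axis_points_mm=axis)
        results = {}
        # 2.5 mm = 4 whole pixels: the translated phantom is an exact
        # raster shift, so the recovery is exact in the common frame
        for off in (0.0, 2.5):
            spec = make_spec(nucleus_offset_mm=off, intensity_gradient=0.2)
            slc, _ = generate_disc_phantom(spec)
            results[off] = compute_all(slc, nucleus_seed_pixel(spec), settings)
        delta = results[2.5].PSM_mm - results[0.0].PSM_mm
        assert delta == pytest.approx(2.5, abs=1e-9)

    def test_provenance_carries_settings_and_frame(self, centered_phantom):
        spec, slc, _ = centered_phantom
        m = compute_all(slc, nucleus_seed_pixel(spec))
        assert "settings_hash" in m.provenance
        assert m.provenance["frame"]["angle_deg"] == pytest.approx(0.0)
        assert m.provenance["segmentation"]["threshold_fraction"] == 0.5

    def test_stage_errors_name_the_stage(self, centered_phantom):
        _, slc, _ = centered_phantom
        with pytest.raises(Exception) as excinfo:
            compute_all(slc, (-5, -5))
        assert any("segmentation" in note
                   for note in getattr(excinfo.value, "__notes__", []))


class TestTranslationInvariance:
    def test_padding_changes_no_metric(self, gradient_phantom):
        spec, slc, _ = gradient_phantom
        m1 = compute_all(slc, nucleus_seed_pixel(spec))
        pad = 10
        padded = np.pad(slc.intensity, pad, constant_values=spec.background_intensity)
        slc2 = type(slc)(padded, slc.pixel_spacing_mm)
        r, c = nucleus_seed_pixel(spec)
        m2 = compute_all(slc2, (r + pad, c + pad))
        assert m1.as_dict() == m2.as_dict()
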