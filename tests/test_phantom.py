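"""Phantom generator and its brute-force ground-truth oracle."""

import numpy as np
import pytest

from discsig import (
    EffectModel,
    GeometryError,
    PhantomSpec,
    ValidationError,
    generate_cohort,
    generate_disc_phantom,
    sample_metric_cohort,
)
from discsig.phantom import closed_form_metrics

from conftest import SPACING, make_spec


class TestPhantomSpecValidation:
    def test_default_grid_spans_stated_field_of_view(self):
        spec = PhantomSpec()
        rows, cols = spec.image_shape
        sr, sc = spec.pixel_spacing_mm
        assert (rows * sr, cols * sc) == (320.0, 320.0)

    @pytest.mark.parametrize("bad", [
        dict(pixel_spacing_mm=(0.0, 0.625)),
        dict(nucleus_semi_axes_mm=(-1.0, 3.5)),
        dict(noise_sigma=-1.0),
        dict(nucleus_intensity=10.0),       # below annulus default
        dict(annulus_intensity=2.0),        # below background default
    ])
    def test_invariant_violations_name_the_field(self, bad):
        with pytest.raises(ValidationError):
            make_spec(**bad)

    def test_nucleus_must_fit_inside_disc(self):
        with pytest.raises(GeometryError):
            make_spec(nucleus_semi_axes_mm=(23.0, 3.5))
        with pytest.raises(GeometryError):
            make_spec(nucleus_offset_mm=14.0)


class TestGroundTruth:
    def test_symmetric_phantom_has_exactly_zero_dx(self, centered_phantom):
        _, _, truth = centered_phantom
        assert truth.true_DX_mm == 0.0
        assert np.allclose(truth.true_weighted_center_mm,
                           truth.true_geometric_center_mm)

    def test_symmetric_phantom_psm_matches_independent_column_sums(
            self, centered_phantom):
        """For an axis-aligned phantom the oracle profile must equal plain
        per-column sums of the masked raster; with uniform nucleus
        intensity the discrete profile has a flat plateau around the
        centre and the tie rule puts PSM at its posterior edge."""
        spec, _, truth = centered_phantom
        masked = np.where(truth.nucleus_mask, truth.noiseless_intensity, 0.0)
        sums = masked.sum(axis=0)
        cols = np.flatnonzero(truth.nucleus_mask.any(axis=0))
        expected_psm = (np.argmax(sums[cols[0]:cols[-1] + 1])) * SPACING
        assert truth.true_PSM_mm == pytest.approx(expected_psm, abs=1e-12)
        assert truth.true_SM == pytest.approx(sums.max(), rel=1e-12)
        # the plateau straddles the centre: PSM posterior of (at most) it
        half_length = spec.nucleus_semi_axes_mm[0]
        assert 0.5 * half_length < truth.true_PSM_mm <= half_length + SPACING

    def test_positive_gradient_shifts_weighted_center_forward(
            self, gradient_phantom):
        _, _, truth = gradient_phantom
        assert truth.true_signed_DX_mm > 0
        assert truth.true_DX_mm == truth.true_signed_DX_mm

    def test_truth_height_matches_rasterized_extent(self, centered_phantom):
        spec, _, truth = centered_phantom
        # 3.5 mm perpendicular semi-axis -> 7.0 mm height +- one pixel
        assert truth.true_H_mm == pytest.approx(7.0, abs=SPACING)

    def test_intensity_scaling_scales_sm_only(self):
        base = make_spec(intensity_gradient=0.2, nucleus_offset_mm=1.0)
        scaled = make_spec(intensity_gradient=0.2 * 3, nucleus_offset_mm=1.0,
                           nucleus_intensity=210.0, annulus_intensity=36.0,
                           background_intensity=9.0)
        _, t0 = generate_disc_phantom(base)
        _, t3 = generate_disc_phantom(scaled)
        assert t3.true_SM == pytest.approx(3 * t0.true_SM, rel=1e-12)
        assert t3.true_DX_mm == pytest.approx(t0.true_DX_mm, abs=1e-9)
        assert t3.true_H_mm == t0.true_H_mm
        assert t3.true_PSM_mm == t0.true_PSM_mm

    def test_noise_does_not_change_truth(self):
        quiet = make_spec()
        noisy = make_spec(noise_sigma=5.0, rng_seed=3)
        _, t_quiet = generate_disc_phantom(quiet)
        slc_noisy, t_noisy = generate_disc_phantom(noisy)
        assert t_noisy.true_SM == t_quiet.true_SM
        assert np.array_equal(t_noisy.nucleus_mask, t_quiet.nucleus_mask)
        assert (slc_noisy.intensity >= 0).all()

    def test_offset_translates_mask_but_not_nucleus_anchored_psm(self):
        """PSM is measured from the posterior end of the nucleus itself,
        so translating the nucleus inside the disc leaves it unchanged;
        the mask moves by the offset."""
        a, b = generate_disc_phantom(make_spec(nucleus_offset_mm=0.0))[1], \
            generate_disc_phantom(make_spec(nucleus_offset_mm=2.5))[1]
        assert b.true_PSM_mm == pytest.approx(a.true_PSM_mm, abs=SPACING)
        shift_px = np.flatnonzero(b.nucleus_mask.any(axis=0))[0] - \
            np.flatnonzero(a.nucleus_mask.any(axis=0))[0]
        assert shift_px * SPACING == pytest.approx(2.5, abs=SPACING)


class TestCohort:
    def test_cell_counts(self):
        model = EffectModel(n_per_cell=2, image_shape=(128, 128))
        subjects = generate_cohort(model)
        assert len(subjects) == 12
        cells = {(s.pathology, s.severity) for s in subjects}
        assert len(cells) == 6

    def test_same_seed_reproduces_identical_cohort(self):
        model = EffectModel(n_per_cell=2, image_shape=(128, 128), rng_seed=5)
        a = generate_cohort(model)
        b = generate_cohort(model)
        for x, y in zip(a, b):
            assert np.array_equal(x.slice.intensity, y.slice.intensity)
            assert x.truth.true_SM == y.truth.true_SM

    def test_zero_noise_zero_effects_gives_identical_truths(self):
        model = EffectModel.null(n_per_cell=2, image_shape=(192, 192),
                                 peak_shift_sd_mm=0.0, sd_intensity=0.0,
                                 sd_length_mm=0.0, sd_height_mm=0.0,
                                 sd_offset_mm=0.0, noise_sigma_frac=0.0)
        subjects = generate_cohort(model)
        ref = subjects[0].truth
        for s in subjects[1:]:
            assert s.truth.true_SM == ref.true_SM
            assert s.truth.true_PSM_mm == ref.true_PSM_mm
            assert s.truth.true_H_mm == ref.true_H_mm

    def test_n_per_cell_below_two_rejected(self):
        with pytest.raises(ValidationError):
            generate_cohort(EffectModel(n_per_cell=1))

    def test_default_effect_directions(self):
        cm = EffectModel().cell_means
        spondy = "spondylolisthesis"
        scol = "scoliosis"
        s = SPACING
        sm = {c: cm["nucleus_intensity"][c]
              * 2 * cm["nucleus_height_semi_mm"][c] / s
              for c in cm["nucleus_intensity"]}
        assert np.mean([sm[(scol, k)] for k in (1, 2, 3)]) > \
            np.mean([sm[(spondy, k)] for k in (1, 2, 3)])
        for p in (spondy, scol):
            lengths = [cm["nucleus_length_semi_mm"][(p, k)] for k in (1, 2, 3)]
            assert lengths == sorted(lengths, reverse=True)
        heights = [cm["nucleus_height_semi_mm"][(spondy, k)] for k in (1, 2, 3)]
        assert heights == sorted(heights, reverse=True)

    def test_metric_sample_matches_rendered_truth(self):
        """Closed-form metric draws track the rendered-phantom truths."""
        model = EffectModel(n_per_cell=2, rng_seed=11, image_shape=(192, 192),
                            noise_sigma_frac=0.0)
        rng = np.random.default_rng(11)
        for cell in [("scoliosis", 1), ("spondylolisthesis", 3)]:
            params = model._draw_subject(cell, rng)
            cf = closed_form_metrics(params, SPACING)
            spec = model.subject_spec(params, rng_seed=0)
            _, truth = generate_disc_phantom(spec)
            assert truth.true_H_mm == pytest.approx(cf["H_mm"], abs=2 * SPACING)
            # rasterised profiles of weak-gradient nuclei have a flat-top
            # plateau whose tie-broken edge can sit well off the continuous
            # peak; allow for it (plateau half-width scales with length)
            plateau = 0.4 * params["length_semi"]
            assert truth.true_PSM_mm == pytest.approx(cf["PSM_mm"],
                                                      abs=plateau + SPACING)
            assert truth.true_SM == pytest.approx(cf["SM"], rel=0.1)

    def test_sample_metric_cohort_shape_and_determinism(self):
        model = EffectModel(n_per_cell=3, rng_seed=2)
        df = sample_metric_cohort(model)
        assert len(df) == 18
        assert set(df["pathology"]) == {"scoliosis", "spondylolisthesis"}
        assert df.equals(sample_metric_cohort(model))
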