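"""Angle PDFs, the anisotropy factor, curves and calibration analyses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wtmm_aniso import (
    AnisotropyCurve,
    BinningPolicy,
    FieldSpec,
    NoMaximaError,
    ScalarField,
    anisotropy_factor,
    build_angle_pdf,
    central_crop_curve,
    coefficient_of_variation,
    generate_field,
    multiscale_curve,
    normalize_by_reference,
)
from wtmm_aniso.anisotropy import ISOTROPIC_DENSITY

VARIABLE = BinningPolicy(mode="variable")
FIXED64 = BinningPolicy(mode="fixed", n_bins=64)


def bin_center_angles(n_bins, per_bin):
    """Angles placed at bin centers, exactly per_bin each: a perfectly flat PDF."""
    width = 2 * np.pi / n_bins
    centers = -np.pi + width * (np.arange(n_bins) + 0.5)
    return np.repeat(centers, per_bin)


def brute_force_fa(angles, n_bins):
    """Loop-based histogram + loop-based L1 sum, independent of numpy paths."""
    width = 2 * np.pi / n_bins
    counts = [0] * n_bins
    for a in angles:
        idx = int((a + np.pi) // width)
        counts[min(idx, n_bins - 1)] += 1
    total = 0.0
    for c in counts:
        density = c / (len(angles) * width)
        total += abs(density - 1 / (2 * np.pi)) * width
    return total


class TestAnglePdf:
    def test_variable_binning_100_per_bin(self):
        pdf = build_angle_pdf(np.random.default_rng(0).uniform(-np.pi, np.pi, 6400), VARIABLE)
        assert pdf.n_bins == 64
        assert pdf.n_samples == 6400

    def test_variable_binning_clamps_to_floor(self):
        pdf = build_angle_pdf(np.random.default_rng(0).uniform(-np.pi, np.pi, 250), VARIABLE)
        assert pdf.n_bins == 4  # floor(250/100) = 2, clamped to min_bins = 4

    @pytest.mark.parametrize("policy", [VARIABLE, FIXED64])
    def test_uniform_sampling_near_flat(self, policy):
        angles = np.random.default_rng(3).uniform(-np.pi, np.pi, 6400)
        pdf = build_angle_pdf(angles, policy)
        rel = np.abs(pdf.density - ISOTROPIC_DENSITY) / ISOTROPIC_DENSITY
        assert np.all(rel < 5 * np.sqrt(100) / 100)  # multinomial fluctuation bound

    def test_empty_angle_set_raises(self):
        with pytest.raises(NoMaximaError):
            build_angle_pdf([], VARIABLE)

    def test_out_of_range_angles_rejected(self):
        with pytest.raises(ValueError, match=r"\[-pi, pi\)"):
            build_angle_pdf([0.0, np.pi], FIXED64)

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(5, 3000))
    def test_density_normalization_property(self, seed, n):
        angles = np.random.default_rng(seed).uniform(-np.pi, np.pi, n)
        for policy in (VARIABLE, FIXED64):
            pdf = build_angle_pdf(angles, policy)
            assert abs(np.sum(pdf.density) * pdf.bin_width - 1.0) < 1e-9
            assert np.all(pdf.density >= 0)
            assert pdf.left_edges[0] == -np.pi
            assert pdf.n_bins * pdf.bin_width == pytest.approx(2 * np.pi)


class TestAnisotropyFactor:
    def test_exactly_uniform_pdf_is_zero(self):
        pdf = build_angle_pdf(bin_center_angles(64, 10), FIXED64)
        assert anisotropy_factor(pdf) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_bins", [64, 1024, 65536])
    def test_single_bin_closed_form(self, n_bins):
        policy = BinningPolicy(mode="fixed", n_bins=n_bins)
        pdf = build_angle_pdf(np.full(50, -np.pi), policy)
        assert anisotropy_factor(pdf) == pytest.approx(2 * (1 - 1 / n_bins), abs=1e-12)

    def test_half_circle_value_is_one(self):
        # uniform at 1/pi over half the circle, zero elsewhere
        pdf = build_angle_pdf(bin_center_angles(64, 10)[: 32 * 10], FIXED64)
        assert anisotropy_factor(pdf) == pytest.approx(1.0, abs=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        angles = rng.vonmises(rng.uniform(-3, 3), rng.uniform(0, 4), size=500)
        angles = np.clip(angles, -np.pi, np.pi - 1e-12)
        for policy in (VARIABLE, FIXED64):
            pdf = build_angle_pdf(angles, policy)
            assert abs(anisotropy_factor(pdf) - brute_force_fa(angles, pdf.n_bins)) < 1e-12

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 2000))
    def test_bounds_property(self, seed, n):
        angles = np.random.default_rng(seed).vonmises(0.3, 2.0, size=n)
        angles = np.clip(angles, -np.pi, np.pi - 1e-12)
        for policy in (VARIABLE, FIXED64):
            pdf = build_angle_pdf(angles, policy)
            fa = anisotropy_factor(pdf)
            assert 0.0 <= fa <= 2 * (1 - 1 / pdf.n_bins) < 2


class TestMultiscaleCurve:
    def test_stripes_exceed_white_noise_at_every_scale(
        self, white_noise_256, stripes_256_wide, small_ladder
    ):
        wn = multiscale_curve(white_noise_256, small_ladder, VARIABLE)
        stripes = multiscale_curve(stripes_256_wide, small_ladder, VARIABLE)
        assert np.all(stripes.fa > wn.fa)

    def test_constant_image_flags_all_scales(self, constant_field, small_ladder):
        with pytest.warns(UserWarning, match="no maxima"):
            curve = multiscale_curve(constant_field, small_ladder, VARIABLE)
        assert np.all(np.isnan(curve.fa))
        assert np.all(curve.n_samples == 0)

    def test_deterministic_rerun(self, white_noise_256, small_ladder):
        a = multiscale_curve(white_noise_256, small_ladder, VARIABLE)
        b = multiscale_curve(white_noise_256, small_ladder, VARIABLE)
        assert np.array_equal(a.fa, b.fa)
        assert np.array_equal(a.n_samples, b.n_samples)

    def test_quarter_turn_invariance_of_fa(self, white_noise_256, small_ladder):
        # 64 bins: a pi/2 angle shift permutes bins, leaving Fa unchanged
        rotated = ScalarField(np.rot90(white_noise_256.values))
        a = multiscale_curve(white_noise_256, small_ladder, FIXED64)
        b = multiscale_curve(rotated, small_ladder, FIXED64)
        assert np.allclose(a.fa, b.fa, atol=1e-12)

    def test_chain_mean_unit_runs(self, stripes_256_wide, small_ladder):
        policy = BinningPolicy(mode="variable", unit="chain_mean")
        curve = multiscale_curve(stripes_256_wide, small_ladder, policy)
        assert np.all(curve.n_samples < 3000)  # far fewer chains than points
        assert np.all(curve.fa[np.isfinite(curve.fa)] > 0.5)  # still clearly anisotropic


class TestCentralCrop:
    def test_crop_counts_are_subsets(self, white_noise_256, small_ladder):
        full = multiscale_curve(white_noise_256, small_ladder, VARIABLE)
        cropped = central_crop_curve(white_noise_256, small_ladder, VARIABLE, crop=128)
        assert np.all(cropped.n_samples < full.n_samples)

    def test_crop_must_be_smaller_than_image(self, white_noise_256, small_ladder):
        with pytest.raises(ValueError, match="crop"):
            central_crop_curve(white_noise_256, small_ladder, VARIABLE, crop=256)

    def test_crop_of_uniform_image_flags_no_maxima(self, constant_field, small_ladder):
        with pytest.warns(UserWarning, match="no maxima"):
            curve = central_crop_curve(constant_field, small_ladder, VARIABLE, crop=64)
        assert np.all(np.isnan(curve.fa))


def _curve(fa_values, scales=(4.0, 8.0, 16.0), image_id="x"):
    fa = np.asarray(fa_values, dtype=float)
    return AnisotropyCurve(
        image_id=image_id,
        policy=VARIABLE,
        scales_px=np.asarray(scales, dtype=float),
        fa=fa,
        n_samples=np.full(fa.size, 100),
        n_bins=np.full(fa.size, 4),
    )


class TestCoefficientOfVariation:
    def test_identical_curves_have_zero_cv(self):
        curves = [_curve([0.3, 0.4, 0.5])] * 5
        assert np.allclose(coefficient_of_variation(curves)["cv"], 0.0)

    def test_sample_sd_convention(self):
        # hand arithmetic with {0.5, 1.0, 1.5}: mean 1, sample SD 0.5 -> CV 0.5
        curves = [_curve([v, v, v]) for v in (0.5, 1.0, 1.5)]
        assert np.allclose(coefficient_of_variation(curves)["cv"], 0.5)

    def test_requires_three_curves(self):
        with pytest.raises(ValueError, match="at least 3"):
            coefficient_of_variation([_curve([0.1] * 3)] * 2)

    def test_mismatched_ladders_rejected(self):
        a = _curve([0.1, 0.2, 0.3])
        b = _curve([0.1, 0.2, 0.3], scales=(5.0, 9.0, 17.0))
        with pytest.raises(ValueError, match="common"):
            coefficient_of_variation([a, b, a])


class TestNormalization:
    def test_self_normalization_is_unity(self):
        curve = _curve([0.2, 0.4, 0.8])
        assert np.allclose(normalize_by_reference(curve, curve.fa).fa, 1.0)

    def test_double_reference_is_two(self):
        ref = np.array([0.1, 0.2, 0.4])
        curve = _curve(2 * ref)
        assert np.allclose(normalize_by_reference(curve, ref).fa, 2.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            normalize_by_reference(_curve([0.2, 0.4, 0.8]), np.array([0.1, 0.0, 0.4]))

    def test_difference_mode(self):
        curve = _curve([0.3, 0.5, 0.9])
        out = normalize_by_reference(curve, np.array([0.1, 0.1, 0.1]), mode="difference")
        assert np.allclose(out.fa, [0.2, 0.4, 0.8])
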