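"""Polymer elasticity: FRC/WLC models, transforms and increment arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forcespec as fs
from forcespec.polymer_models import (
    LowForceWarning,
    apparent_contour_length,
    extension_model,
    wlc_force,
)


class TestFrcExtensionRatio:
    def test_high_force_asymptote(self, frc_params):
        assert fs.frc_extension_ratio(1e5, frc_params) >= 0.99

    def test_monotone_in_force(self, frc_params):
        assert fs.frc_extension_ratio(200.0, frc_params) < fs.frc_extension_ratio(
            400.0, frc_params
        )

    def test_value_at_200pN_matches_direct_evaluation(self, frc_params):
        # independent arithmetic: 200 pN is in the discrete-chain regime,
        # x/L = 1 - kBT / (2 F b) with b = 0.11 nm, kBT = 4.114 pN nm
        expected = 1.0 - 4.114 / (2.0 * 200.0 * 0.11)
        assert fs.frc_extension_ratio(200.0, frc_params) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.9065, abs=1e-10)

    def test_wlc_like_regime_matches_direct_evaluation(self, frc_params):
        # 50 pN is below the regime boundary (~124 pN): WLC-like branch
        p = frc_params.frc_persistence
        expected = 1.0 - math.sqrt(4.114 / (4.0 * 50.0 * p))
        assert fs.frc_extension_ratio(50.0, frc_params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_branches_continuous_at_boundary(self, frc_params):
        fb = frc_params.frc_regime_boundary
        lo = fs.frc_extension_ratio(fb * (1 - 1e-9), frc_params)
        hi = fs.frc_extension_ratio(fb * (1 + 1e-9), frc_params)
        assert lo == pytest.approx(hi, abs=1e-7)

    def test_nonpositive_force_rejected(self, frc_params):
        with pytest.raises(ValueError):
            fs.frc_extension_ratio(0.0, frc_params)
        with pytest.raises(ValueError):
            fs.frc_extension_ratio(-5.0, frc_params)

    def test_low_force_flagged_but_computed(self, frc_params):
        with pytest.warns(LowForceWarning):
            val = fs.frc_extension_ratio(5.0, frc_params)
        assert 0.0 < val < 1.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        f1=st.floats(min_value=10.0, max_value=2000.0),
        f2=st.floats(min_value=10.0, max_value=2000.0),
    )
    def test_strictly_increasing_and_bounded(self, f1, f2):
        params = fs.PolymerParams(qm_correction=None)
        r1 = fs.frc_extension_ratio(f1, params)
        r2 = fs.frc_extension_ratio(f2, params)
        assert 0.0 < r1 < 1.0
        if f1 < f2:
            assert r1 < r2
        elif f1 > f2:
            assert r1 > r2


class TestBackboneStretch:
    def test_unity_at_zero_force(self):
        assert fs.backbone_stretch_factor(0.0, fs.PolymerParams()) == 1.0

    def test_monotone(self):
        p = fs.PolymerParams()
        f100 = fs.backbone_stretch_factor(100.0, p)
        f600 = fs.backbone_stretch_factor(600.0, p)
        assert 1.0 <= f100 <= f600

    def test_default_coefficients_at_600pN(self):
        # independent polynomial evaluation of the default coefficient set
        c1, c2 = 3.0e-5, 3.0e-8
        expected = 1.0 + c1 * 600.0 + c2 * 600.0**2
        assert fs.backbone_stretch_factor(600.0, fs.PolymerParams()) == pytest.approx(
            expected, rel=1e-12
        )

    def test_disabled_correction_is_identity(self, frc_params):
        forces = np.linspace(0.0, 2000.0, 50)
        assert np.all(fs.backbone_stretch_factor(forces, frc_params) == 1.0)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            fs.backbone_stretch_factor(-1.0, fs.PolymerParams())


class TestForceAtExtension:
    def test_slack_chain(self, frc_params):
        assert fs.force_at_extension(0.0, 100.0, frc_params) == 0.0

    @pytest.mark.parametrize("force", [50.0, 250.0, 800.0])
    def test_round_trip(self, force, frc_params):
        L0 = 120.0
        x = extension_model(force, L0, frc_params)
        back = fs.force_at_extension(x, L0, frc_params)
        assert back == pytest.approx(force, rel=1e-6)

    def test_round_trip_with_qm_correction(self):
        params = fs.PolymerParams()  # QM correction on
        x = extension_model(400.0, 90.0, params)
        assert fs.force_at_extension(x, 90.0, params) == pytest.approx(400.0, rel=1e-6)

    def test_wlc_interpolation_closed_form(self, wlc_params):
        # x/L = 0.5, p = 0.38 nm: F = kBT/p * (1/(4*(1-s)^2) - 1/4 + s)
        expected = 4.114 / 0.38 * (1.0 / (4.0 * 0.25) - 0.25 + 0.5)
        got = fs.force_at_extension(0.5 * 64.0, 64.0, wlc_params)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(13.5329, abs=1e-4)
        # and the ratio inversion agrees
        assert fs.polymer_models.wlc_extension_ratio(expected, wlc_params) == (
            pytest.approx(0.5, abs=1e-10)
        )

    def test_unattainable_extension(self, frc_params):
        with pytest.raises(ValueError):
            fs.force_at_extension(200.0, 100.0, frc_params)


class TestApparentContourLength:
    def test_inverts_generator(self, frc_params):
        x = extension_model(300.0, 100.0, frc_params)
        L = apparent_contour_length(300.0, x, frc_params)
        assert L == pytest.approx(100.0, abs=1e-6)

    def test_inverts_generator_with_qm(self):
        params = fs.PolymerParams()
        x = extension_model(500.0, 150.0, params)
        assert apparent_contour_length(500.0, x, params) == pytest.approx(
            150.0, abs=1e-6
        )

    def test_below_threshold_rejected_as_nan(self, frc_params):
        assert np.isnan(apparent_contour_length(5.0, 50.0, frc_params))

    def test_mean_recovery_under_force_noise(self, frc_params):
        # Monte Carlo: model points at L0 = 150 nm, Gaussian force noise 5 pN
        rng = np.random.default_rng(11)
        L0 = 150.0
        f_true = rng.uniform(100.0, 600.0, 3000)
        x = extension_model(f_true, L0, frc_params)
        f_noisy = f_true + rng.normal(0.0, 5.0, f_true.shape)
        L = apparent_contour_length(f_noisy, x, frc_params)
        assert np.nanmean(L) == pytest.approx(L0, abs=1.0)

    def test_scale_equivariance(self, frc_params):
        x = extension_model(250.0, 80.0, frc_params)
        L1 = apparent_contour_length(250.0, x, frc_params)
        L2 = apparent_contour_length(250.0, 2.0 * x, frc_params)
        assert L2 == pytest.approx(2.0 * L1, rel=1e-12)


class TestIncrements:
    def test_arithmetic(self):
        assert fs.expected_increment(100, 5.0) == pytest.approx(31.5)

    def test_single_residue_is_residue_length(self):
        assert fs.expected_increment(1, 0.0) == pytest.approx(0.365)

    def test_folded_longer_than_stretched_rejected(self):
        with pytest.raises(ValueError):
            fs.expected_increment(10, 4.0)

    def test_default_table_matches_fingerprints(self):
        incs = fs.IncrementTable().increments()
        assert incs["Xyn"] == pytest.approx(89.0, abs=0.5)
        assert incs["CBM"] == pytest.approx(56.0, abs=0.5)
        assert incs["XMod"] == pytest.approx(34.0, abs=0.5)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            fs.PolymerParams(b=-0.1)
        with pytest.raises(ValueError):
            fs.PolymerParams(gamma=95.0)
        with pytest.raises(ValueError):
            fs.expected_increment(0, 1.0)
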