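"""Hertz fitting: forward-model round trips, noise robustness, folds."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from matriscope.afm import (
    ForceCurve,
    ModulusEstimate,
    fit_hertz,
    fold_change,
    round_fold,
    summarize_moduli,
    summary_from_means,
)
from matriscope.synthetic import generate_force_curve

#: per-sample mean Young's moduli (kPa) of the four breast-tissue sample
#: types measured in the study this package models
STUDY_MEANS_KPA = {
    "normal_tissue": 1.328,
    "tumor_tissue": 3.193,
    "normal_ecm": 1.263,
    "tumor_ecm": 7.203,
}


class TestFitHertz:
    @pytest.mark.parametrize("modulus_pa", [100.0, 1263.0, 10_000.0, 100_000.0])
    def test_noiseless_round_trip(self, modulus_pa):
        curve = generate_force_curve(modulus_pa, 0.5, 18.0, 1e-6, 100, 0.0, 0)
        est = fit_hertz(curve, 0.5, 18.0)
        assert est.youngs_modulus_Pa == pytest.approx(modulus_pa, rel=1e-6)
        assert est.fit_residual_N == pytest.approx(0.0, abs=1e-18)
        assert est.n_points_used == 100

    def test_normal_ecm_modulus_round_trip(self):
        curve = generate_force_curve(1263.0)
        est = fit_hertz(curve)
        assert est.youngs_modulus_Pa == pytest.approx(1263.0, rel=1e-6)

    def test_zero_force_flagged(self):
        curve = ForceCurve(np.linspace(0, 1e-6, 50), np.zeros(50), "s", "p")
        with pytest.warns(UserWarning, match="zero force"):
            est = fit_hertz(curve)
        assert est.youngs_modulus_Pa == 0.0
        assert est.zero_force

    def test_inverted_force_rejected(self):
        curve = generate_force_curve(1000.0)
        bad = ForceCurve(curve.indentation_m, -curve.force_N)
        with pytest.raises(ValueError, match="negative"):
            fit_hertz(bad)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_hertz(ForceCurve(np.linspace(0, 1e-6, 9), np.ones(9)))

    def test_noisy_recovery_median_under_5_percent(self):
        errors = []
        for seed in range(20):
            curve = generate_force_curve(2000.0, max_depth_m=1e-6, seed=seed)
            noise_sd = 0.05 * curve.force_N.max()
            noisy = generate_force_curve(
                2000.0, max_depth_m=1e-6, noise_sd_N=noise_sd, seed=seed
            )
            est = fit_hertz(noisy)
            errors.append(abs(est.youngs_modulus_Pa - 2000.0) / 2000.0)
        assert np.median(errors) < 0.05

    def test_residual_grows_with_noise(self):
        residuals = []
        levels = [1e-12, 5e-12, 2e-11, 1e-10]
        for sd in levels:
            per_seed = [
                fit_hertz(
                    generate_force_curve(1263.0, noise_sd_N=sd, seed=s)
                ).fit_residual_N
                for s in range(20)
            ]
            residuals.append(np.mean(per_seed))
        assert residuals == sorted(residuals)
        pooled = [
            (sd, fit_hertz(generate_force_curve(1263.0, noise_sd_N=sd, seed=s)).fit_residual_N)
            for sd in levels
            for s in range(20)
        ]
        rho = spearmanr([p[0] for p in pooled], [p[1] for p in pooled]).statistic
        assert rho > 0.9

    def test_contact_offset_cofit(self):
        base = generate_force_curve(3000.0, max_depth_m=1e-6, n_points=200)
        shift = 2e-7  # true contact 0.2 um into the sweep
        shifted_force = np.interp(
            base.indentation_m - shift, base.indentation_m, base.force_N, left=0.0
        )
        curve = ForceCurve(base.indentation_m, shifted_force)
        naive = fit_hertz(curve)
        offset = fit_hertz(curve, fit_contact_offset=True)
        err_naive = abs(naive.youngs_modulus_Pa - 3000.0) / 3000.0
        err_offset = abs(offset.youngs_modulus_Pa - 3000.0) / 3000.0
        assert err_offset < 0.01 < err_naive


class TestFoldChange:
    def test_study_fold_changes(self):
        m = STUDY_MEANS_KPA
        assert fold_change(m["tumor_tissue"], m["normal_tissue"]) == 2.4
        assert fold_change(m["tumor_ecm"], m["normal_ecm"]) == 5.7
        assert fold_change(m["tumor_ecm"], m["tumor_tissue"]) == 2.3

    def test_identity(self):
        assert fold_change(3.3, 3.3) == 1.0

    @pytest.mark.parametrize("a,b", [(1.1, 2.7), (5.0, 0.3), (7.203, 1.263)])
    def test_reciprocal_product_exact_before_rounding(self, a, b):
        assert fold_change(a, b, rounded=False) * fold_change(b, a, rounded=False) == 1.0

    def test_rounding_is_half_up(self):
        assert round_fold(2.25) == 2.3
        assert round_fold(2.249) == 2.2
        assert round_fold(5.65) == 5.7

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        a=st.floats(0.01, 1e4, allow_nan=False),
        b=st.floats(0.01, 1e4, allow_nan=False),
    )
    def test_fold_properties_hold_for_any_positive_means(self, a, b):
        raw = fold_change(a, b, rounded=False)
        assert raw * fold_change(b, a, rounded=False) == pytest.approx(1.0)
        assert abs(fold_change(a, b) - raw) <= 0.05 + 1e-12  # half-up to 0.1


class TestSummaries:
    def _estimate(self, pa, sample="s", spot="p"):
        return ModulusEstimate(pa, 0.0, 100, sample, spot)

    def test_summary_from_printed_means(self):
        summary = summary_from_means(STUDY_MEANS_KPA)
        np.testing.assert_allclose(
            summary.mean_kPa, [1.328, 3.193, 1.263, 7.203]
        )
        assert summary.fold("tumor_tissue", "normal_tissue") == 2.4
        assert summary.fold("tumor_ecm", "normal_ecm") == 5.7
        assert summary.fold("tumor_ecm", "tumor_tissue") == 2.3
        np.testing.assert_allclose(np.diag(summary.fold_matrix), 1.0)

    def test_single_estimate_sd_zero(self):
        with pytest.warns(UserWarning, match="spots"):
            summary = summarize_moduli([self._estimate(1500.0)])
        assert summary.sd_kPa[0] == 0.0
        assert summary.mean_kPa[0] == pytest.approx(1.5)

    def test_seven_identical_estimates(self):
        ests = [self._estimate(2000.0, spot=f"p{i}") for i in range(7)]
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no under-sampling warning at 7
            summary = summarize_moduli(ests)
        assert summary.mean_kPa[0] == pytest.approx(2.0)
        assert summary.sd_kPa[0] == 0.0

    def test_grouped_input_and_fold_matrix(self):
        grouped = {
            "soft": [self._estimate(1000.0, "soft", f"p{i}") for i in range(7)],
            "stiff": [self._estimate(2400.0, "stiff", f"p{i}") for i in range(7)],
        }
        summary = summarize_moduli(grouped)
        assert summary.fold("stiff", "soft") == 2.4
        assert summary.fold("stiff", "soft", rounded=False) == pytest.approx(2.4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no estimates"):
            summarize_moduli({"s": []})
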