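"""Scatchard analysis, biphasic curve fitting, and panel summaries."""

import numpy as np
import pandas as pd
import pytest

from ryrcicr import binding_fit as bf
from ryrcicr import synthetic_data as sd
from ryrcicr.binding_fit import (
    STATUS_NOT_DETERMINED,
    STATUS_OK,
    BindingCurve,
    DegenerateDataError,
    InvalidNormalizationError,
    SaturationSeries,
)
from ryrcicr.model_core import BindingModelParams


class TestScatchard:
    def test_noiseless_recovery_is_exact(self):
        series = sd.gen_saturation(Bmax=10.0, Kd_nM=5.0, grid_nM=(3, 5, 10, 20))
        result = bf.scatchard_bmax(series)
        assert result["Bmax"] == pytest.approx(10.0, abs=1e-9)
        assert result["Kd_nM"] == pytest.approx(5.0, abs=1e-9)

    def test_isotherm_identities_pin_the_intercept(self):
        # F = Kd gives B = Bmax/2; F >> Kd approaches Bmax
        kd, bmax = 5.0, 10.0
        series = sd.gen_saturation(bmax, kd, grid_nM=(kd, 100 * kd, 1e6 * kd))
        assert bf.scatchard_bmax(series)["Bmax"] == pytest.approx(bmax, rel=1e-6)

    def test_noisy_recovery_within_5_percent(self):
        rng = np.random.default_rng(2024)
        free = np.linspace(3.0, 20.0, 8)
        bound = 10.0 * free / (free + 5.0) + rng.normal(0, 0.2, 8)  # sigma = 2% Bmax
        result = bf.scatchard_bmax(SaturationSeries(free, bound))
        assert result["Bmax"] == pytest.approx(10.0, rel=0.05)

    def test_nonsaturable_data_rejected(self):
        free = np.array([3.0, 6.0, 12.0, 20.0])
        series = SaturationSeries(free, 0.5 * free)  # linear, no saturation
        with pytest.raises(DegenerateDataError):
            bf.scatchard_bmax(series)


class TestNormalizeToBmax:
    def test_elementwise_division(self):
        out = bf.normalize_to_bmax([1.0, 2.0, 4.0], 8.0)
        assert np.allclose(out, [0.125, 0.25, 0.5])
        assert bf.normalize_to_bmax([8.0], 8.0)[0] == 1.0
        assert bf.normalize_to_bmax([0.0], 8.0)[0] == 0.0

    def test_nonpositive_bmax_rejected(self):
        with pytest.raises(InvalidNormalizationError):
            bf.normalize_to_bmax([1.0], 0.0)


class TestFitCurve:
    def test_noiseless_recovery(self, wt_params):
        curve = sd.gen_binding_curve(wt_params, noise_sd=0.0, replicates=1)
        fit = bf.fit_curve(curve)
        assert fit.ok
        assert fit.params.KA == pytest.approx(wt_params.KA, rel=1e-6)
        assert fit.params.Amax == pytest.approx(wt_params.Amax, rel=1e-6)
        assert fit.params.KI == pytest.approx(wt_params.KI, rel=1e-4)

    def test_noisy_wt_recovery_within_tolerance(self, wt_params):
        curve = sd.gen_binding_curve(wt_params, seed=42)
        fit = bf.fit_curve(curve)
        assert fit.ok
        assert fit.pCa50 == pytest.approx(4.79, abs=0.05)
        assert fit.stderr["pKA"] is not None and fit.stderr["pKA"] < 0.1

    def test_lost_binding_reports_not_determined(self):
        pca = np.linspace(8, 3, 8)
        curve = BindingCurve.from_replicate_matrix(
            "E3847A-like", "control", pca, np.zeros((8, 4))
        )
        fit = bf.fit_curve(curve)
        assert fit.status == STATUS_NOT_DETERMINED
        assert fit.pCa50 is None

    def test_row_order_invariance(self, wt_params):
        curve = sd.gen_binding_curve(wt_params, seed=9)
        shuffled = BindingCurve(
            curve.genotype,
            curve.condition,
            curve.data.sample(frac=1.0, random_state=3).reset_index(drop=True),
        )
        f1, f2 = bf.fit_curve(curve), bf.fit_curve(shuffled)
        assert f1.pCa50 == pytest.approx(f2.pCa50, abs=1e-8)
        assert f1.r_squared == pytest.approx(f2.r_squared, abs=1e-10)

    def test_monophasic_mode_for_high_salt_medium(self):
        truth = BindingModelParams(Amax=0.8, KA=1e-5, KI=np.inf, nA=2.0, nI=1.0)
        curve = sd.gen_binding_curve(truth, seed=5)
        fit = bf.fit_curve(curve, inactivation=False)
        assert fit.ok
        assert fit.pCa50 == pytest.approx(5.0, abs=0.05)

    def test_means_only_mode_matches_replicates_closely(self, wt_params):
        curve = sd.gen_binding_curve(wt_params, seed=13)
        full = bf.fit_curve(curve)
        means = bf.fit_curve(curve, use_means=True)
        # balanced replicates: means-only fit solves the same normal equations
        assert means.pCa50 == pytest.approx(full.pCa50, abs=1e-6)

    def test_parameter_recovery_statistics(self, wt_params):
        """Median |pCa50 error| < 0.03 and |bias| < 0.01 over 200 curves."""
        errors = []
        for seed in range(200):
            curve = sd.gen_binding_curve(wt_params, seed=seed)
            fit = bf.fit_curve(curve)
            assert fit.ok
            errors.append(fit.pCa50 - 4.79)
        errors = np.asarray(errors)
        assert np.median(np.abs(errors)) < 0.03
        assert abs(errors.mean()) < 0.01


class TestHillSelection:
    @staticmethod
    def _panel(na, ni, noise_sd, seed):
        rng = np.random.default_rng(seed)
        curves = []
        for i in range(6):
            truth = BindingModelParams.from_pk(
                Amax=rng.uniform(0.2, 0.6),
                pKA=rng.uniform(4.5, 5.5),
                pKI=-np.log10(rng.uniform(3e-4, 3e-3)),
                nA=na,
                nI=ni,
            )
            curves.append(
                sd.gen_binding_curve(
                    truth, noise_sd=noise_sd,
                    replicates=1 if noise_sd == 0 else 4,
                    seed=1000 + i, genotype=f"g{i}",
                )
            )
        return curves

    def test_single_candidate_grid_is_forced(self, wt_params):
        curve = sd.gen_binding_curve(wt_params, seed=1)
        na, ni, _ = bf.select_hill_coefficients([curve], grid_nA=(2.0,), grid_nI=(1.0,))
        assert (na, ni) == (2.0, 1.0)

    def test_noiseless_panel_selects_the_true_pair(self):
        curves = self._panel(na=2.0, ni=1.0, noise_sd=0.0, seed=5)
        na, ni, table = bf.select_hill_coefficients(
            curves, grid_nA=(1.0, 1.5, 2.0, 2.5), grid_nI=(0.5, 1.0, 1.5)
        )
        assert (na, ni) == (2.0, 1.0)
        assert table["sum_r2"].max() == pytest.approx(6.0, abs=1e-8)

    def test_noiseless_panel_with_na_1p5_prefers_truth_over_2(self):
        curves = self._panel(na=1.5, ni=1.0, noise_sd=0.0, seed=5)
        na, _, _ = bf.select_hill_coefficients(
            curves, grid_nA=(1.0, 1.5, 2.0), grid_nI=(1.0,)
        )
        assert na == 1.5

    def test_selection_reproducible_for_fixed_seed(self):
        curves = self._panel(na=2.0, ni=1.0, noise_sd=0.02, seed=8)
        first = bf.select_hill_coefficients(curves, grid_nA=(1.5, 2.0), grid_nI=(1.0,))
        second = bf.select_hill_coefficients(curves, grid_nA=(1.5, 2.0), grid_nI=(1.0,))
        assert first[:2] == second[:2]
        assert np.allclose(first[2]["sum_r2"], second[2]["sum_r2"])


class TestSensitizationTable:
    @staticmethod
    def _panel_fits(wt_params):
        curves = [
            sd.gen_binding_curve(wt_params, seed=1, genotype="WT", condition="control"),
            sd.gen_binding_curve(
                wt_params.replace(KA=10**-5.8), seed=2, genotype="WT",
                condition="caffeine-10mM",
            ),
            sd.gen_binding_curve(
                wt_params.replace(KA=wt_params.KA / 8), seed=3,
                genotype="C4192W-like", condition="control",
            ),
        ]
        return [bf.fit_curve(c) for c in curves]

    def test_delta_and_fold_columns(self, wt_params):
        rows = bf.sensitization_table(self._panel_fits(wt_params))
        by_genotype = {r.genotype: r for r in rows}
        wt = by_genotype["WT"]
        assert wt.delta_pCa50 == pytest.approx(
            wt.pCa50_caffeine - wt.pCa50_control, abs=1e-12
        )
        assert wt.resting_fold_vs_wt == pytest.approx(1.0, abs=1e-12)
        mut = by_genotype["C4192W-like"]
        assert mut.pCa50_caffeine is None and mut.delta_pCa50 is None
        assert mut.resting_fold_vs_wt == pytest.approx(63.85, rel=0.30)

    def test_identical_conditions_give_zero_delta(self, wt_params):
        import dataclasses

        fit = bf.fit_curve(sd.gen_binding_curve(wt_params, seed=4, genotype="X"))
        fits = [
            bf.fit_curve(sd.gen_binding_curve(wt_params, seed=1, genotype="WT")),
            fit,
            dataclasses.replace(fit, condition="caffeine-10mM"),
        ]
        rows = bf.sensitization_table(fits)
        assert {r.genotype: r for r in rows}["X"].delta_pCa50 == pytest.approx(0.0)

    def test_not_determined_propagates_with_absent_numbers(self, wt_params):
        dead = bf.FitResult("E3847A-like", "control", None, None,
                            status=STATUS_NOT_DETERMINED)
        fits = [
            bf.fit_curve(sd.gen_binding_curve(wt_params, seed=1, genotype="WT")),
            dead,
        ]
        rows = bf.sensitization_table(fits)
        row = {r.genotype: r for r in rows}["E3847A-like"]
        assert row.status != STATUS_OK
        assert row.pCa50_control is None and row.resting_fold_vs_wt is None

    def test_missing_wt_control_raises(self, wt_params):
        curve = sd.gen_binding_curve(wt_params, seed=1, genotype="mut")
        with pytest.raises(DegenerateDataError):
            bf.sensitization_table([bf.fit_curve(curve)])
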