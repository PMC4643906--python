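"""Potency and kinetics estimation: self-consistency, selection, robustness."""

import numpy as np
import pytest

import inhibkin as ik
from inhibkin.curve_fitting import (
    DegenerateDataError,
    DesignError,
    aic_from_rss,
    robust_line,
    select_by_aic,
)


class TestFitPotency:
    def test_noiseless_recovery(self, log_conc_grid):
        truth = ik.PotencyParameters(pIC50=6.0, hill_slope=1.0)
        conc = np.asarray(log_conc_grid)
        resp = ik.four_pl_response(np.log10(conc * 1e-6), truth)
        fit = ik.fit_potency(conc, resp, bottom_mode="fixed_zero")
        assert fit.params.pIC50 == pytest.approx(6.0, abs=1e-6)
        assert fit.params.hill_slope == pytest.approx(1.0, abs=1e-6)
        assert fit.ic50_uM == pytest.approx(1.0, rel=1e-5)

    def test_floating_bottom_recovery(self, log_conc_grid):
        truth = ik.PotencyParameters(pIC50=6.0, hill_slope=1.2, bottom=15.0)
        conc = np.asarray(log_conc_grid)
        resp = ik.four_pl_response(np.log10(conc * 1e-6), truth)
        fit = ik.fit_potency(conc, resp, bottom_mode="floating")
        assert fit.params.pIC50 == pytest.approx(6.0, abs=1e-4)
        assert fit.params.bottom == pytest.approx(15.0, abs=1e-3)

    def test_monte_carlo_pic50_recovery(self, log_conc_grid):
        """Median |pIC50 error| stays within 0.1 at the assay's 5% CV."""
        errs = []
        for seed in range(200):
            cfg = ik.SimulationConfig(
                seed=seed, inhibitor_grid=log_conc_grid, noise_cv=0.05, n_replicates=3
            )
            cr = ik.simulate_conc_response(cfg, ik.PotencyParameters(pIC50=6.13))
            fit = ik.fit_potency(cr["inhibitor_uM"], cr["response_pct"])
            errs.append(abs(fit.params.pIC50 - 6.13))
        assert np.median(errs) <= 0.1

    def test_bottom_zero_data_prefers_fixed_zero_by_aic(self, log_conc_grid):
        wins = 0
        for seed in range(60):
            cfg = ik.SimulationConfig(
                seed=1000 + seed, inhibitor_grid=log_conc_grid, noise_cv=0.05
            )
            cr = ik.simulate_conc_response(cfg, ik.PotencyParameters(pIC50=6.13))
            fits = [
                ik.fit_potency(cr["inhibitor_uM"], cr["response_pct"], m)
                for m in ("fixed_zero", "floating")
            ]
            wins += fits[0].aic < fits[1].aic
        assert wins > 30  # majority of runs

    def test_flat_responses_rejected(self):
        with pytest.raises(DegenerateDataError):
            ik.fit_potency(np.geomspace(0.01, 100, 8), np.full(8, 100.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(DesignError):
            ik.fit_potency([0.1, 1.0, 10.0], [90.0, 50.0, 10.0])


class TestSelectByAIC:
    def test_smallest_aic_wins_and_deltas_anchor_at_zero(self, log_conc_grid):
        conc = np.asarray(log_conc_grid)
        resp = ik.four_pl_response(
            np.log10(conc * 1e-6), ik.PotencyParameters(pIC50=6.0, bottom=20.0)
        )
        fits = [ik.fit_potency(conc, resp, m) for m in ("fixed_zero", "floating")]
        cmp_ = select_by_aic(fits)
        assert cmp_.best.bottom_mode == "floating"
        assert cmp_.delta_aic[cmp_.selected] == 0.0
        assert all(d >= 0 for d in cmp_.delta_aic)

    def test_tie_resolves_to_fewer_parameters(self):
        a = ik.PotencyFit(
            params=ik.PotencyParameters(pIC50=6), se={}, bottom_mode="floating",
            aic=10.0, rss=1.0, n_obs=10, data_id="d",
        )
        b = ik.PotencyFit(
            params=ik.PotencyParameters(pIC50=6), se={}, bottom_mode="fixed_zero",
            aic=10.0, rss=1.0, n_obs=10, data_id="d",
        )
        assert select_by_aic([a, b]).best.bottom_mode == "fixed_zero"

    def test_different_data_rejected(self):
        a = ik.PotencyFit(
            params=ik.PotencyParameters(pIC50=6), se={}, bottom_mode="fixed_zero",
            aic=1.0, rss=1.0, n_obs=10, data_id="aaa",
        )
        b = ik.PotencyFit(
            params=ik.PotencyParameters(pIC50=6), se={}, bottom_mode="fixed_zero",
            aic=2.0, rss=1.0, n_obs=12, data_id="bbb",
        )
        with pytest.raises(ValueError, match="different data"):
            select_by_aic([a, b])

    def test_aic_formula(self):
        # n*ln(RSS/n) + 2(k_free + 1)
        assert aic_from_rss(10.0, 20, 3) == pytest.approx(
            20 * np.log(0.5) + 8
        )


class TestFitInhibitionKinetics:
    def test_noiseless_mixed_recovery_and_selection(self, noiseless_mixed_table):
        cmp_ = ik.fit_inhibition_kinetics(noiseless_mixed_table)
        best = cmp_.best
        assert best.model_label == "mixed"
        assert best.inhib.Ki == pytest.approx(0.8, rel=1e-5)
        assert best.inhib.alpha == pytest.approx(3.2, rel=1e-4)
        assert best.mm.Km == pytest.approx(1.5, rel=1e-5)

    def test_noiseless_competitive_data_selects_competitive(self, mm, competitive_inhib):
        cfg = ik.SimulationConfig(seed=0, mm=mm, inhib=competitive_inhib, noise_cv=0.0)
        cmp_ = ik.fit_inhibition_kinetics(ik.simulate_velocity_table(cfg))
        best = cmp_.best
        assert best.model_label == "competitive"
        assert best.inhib.Ki == pytest.approx(0.8, rel=1e-5)
        # the mixed candidate matches the RSS only by inflating alpha
        mixed = next(c for c in cmp_.candidates if c.model_label == "mixed")
        assert mixed.inhib.alpha > 100.0

    def test_velocity_rescaling_leaves_ki_alpha_km_invariant(self, noisy_mixed_table):
        base = ik.fit_inhibition_kinetics(noisy_mixed_table).best
        scaled = noisy_mixed_table.copy()
        scaled["velocity"] = scaled["velocity"] * 1e3
        res = ik.fit_inhibition_kinetics(scaled).best
        assert res.inhib.Ki == pytest.approx(base.inhib.Ki, rel=1e-5)
        assert res.inhib.alpha == pytest.approx(base.inhib.alpha, rel=1e-4)
        assert res.mm.Km == pytest.approx(base.mm.Km, rel=1e-5)
        assert res.mm.Vmax == pytest.approx(base.mm.Vmax * 1e3, rel=1e-5)

    def test_reports_standard_errors(self, noisy_mixed_table):
        best = ik.fit_inhibition_kinetics(noisy_mixed_table).best
        assert set(best.se) >= {"Km", "Vmax", "Ki"}
        assert all(np.isfinite(v) and v > 0 for v in best.se.values())

    def test_single_substrate_level_rejected(self, mm, mixed_inhib):
        cfg = ik.SimulationConfig(
            seed=0, mm=mm, inhib=mixed_inhib, substrate_grid=(0.5,), noise_cv=0.0
        )
        with pytest.raises(DesignError, match="substrate"):
            ik.fit_inhibition_kinetics(ik.simulate_velocity_table(cfg))

    def test_single_inhibitor_level_rejected(self, mm, mixed_inhib):
        cfg = ik.SimulationConfig(
            seed=0, mm=mm, inhib=mixed_inhib, inhibitor_grid=(1.0,), noise_cv=0.0
        )
        with pytest.raises(DesignError, match="inhibitor"):
            ik.fit_inhibition_kinetics(ik.simulate_velocity_table(cfg))


class TestRobustLine:
    def test_exact_line(self):
        x = np.arange(8.0)
        fit = robust_line(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)

    def test_two_points_interpolated_exactly(self):
        fit = robust_line([0.0, 2.0], [1.0, 5.0])
        assert fit.method == "ols"
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_outlier_resistance_beats_ols(self):
        rng = np.random.default_rng(7)
        x = np.arange(8.0)
        y = 2 * x + 1 + rng.normal(0, 0.05, 8)
        y[3] += 25.0  # gross outlier
        rob = robust_line(x, y)
        ols = robust_line(x, y, method="ols")
        assert abs(rob.slope - 2.0) < 0.05 * 2.0
        assert abs(rob.slope - 2.0) < abs(ols.slope - 2.0)

    def test_vertical_line_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            robust_line([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
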