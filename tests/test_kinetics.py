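"""Decay kinetics: fits, model selection, adsorption, comparisons, trend."""
import numpy as np
import pandas as pd
import pytest

from conftest import oracle_first_order_grid
from quorumflow import synthetic
from quorumflow.kinetics import (
    DecaySeries,
    FirstOrderDecayFitter,
    ZeroOrderDecayFitter,
    adsorption_fraction,
    analyse_decay_table,
    chain_length_trend,
    compare_half_lives,
    correct_for_adsorption,
    fit_first_order,
    fit_zero_order,
    holm_sidak_adjust,
    select_model,
)

LN2 = np.log(2.0)


def _series(times, conc, condition="live", ahl="C6-HSL"):
    return DecaySeries(ahl=ahl, condition=condition, times=np.asarray(times),
                       concentrations=np.asarray(conc))


class TestZeroOrder:
    def test_exact_line_recovered(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = fit_zero_order(_series(t, 10.0 - 2.0 * t))
        assert fit.rate_k == pytest.approx(2.0, abs=1e-12)
        assert fit.c0_hat == pytest.approx(10.0, abs=1e-12)
        assert fit.half_life == pytest.approx(2.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_half_life_identity_holds(self, rng):
        for _ in range(20):
            t = np.sort(np.r_[0.0, rng.uniform(0.2, 6.0, 6)])
            c = np.maximum(rng.uniform(4, 8) - rng.uniform(0.3, 1.0) * t, 0.01)
            c *= rng.lognormal(0, 0.05, len(t))
            fit = fit_zero_order(_series(t, c))
            if fit.ok:
                assert fit.half_life == pytest.approx(fit.c0_hat / (2 * fit.rate_k))

    def test_degenerate_series_fail_gracefully(self):
        assert not fit_zero_order(_series([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])).ok
        rising = fit_zero_order(_series([0.0, 1.0, 2.0], [5.0, 6.0, 7.0]))
        assert not rising.ok and "non-degrading" in rising.reason

    def test_parameter_recovery_under_noise(self):
        """Mean half-life over 100 noisy replicates (CV 10%) within 5% of truth."""
        t = np.linspace(0, 4, 8)
        truth_hl = 5.0 / (2 * 1.0)
        hls = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sigma = np.sqrt(np.log1p(0.1**2))
            noise = rng.lognormal(-sigma**2 / 2, sigma, len(t))
            c = np.maximum(5.0 - 1.0 * t, 0.05) * noise
            fit = fit_zero_order(_series(t, c))
            assert fit.ok
            hls.append(fit.half_life)
        assert np.mean(hls) == pytest.approx(truth_hl, rel=0.05)


class TestFirstOrder:
    def test_closed_form_half_life(self):
        t = np.linspace(0, 5, 8)
        fit = fit_first_order(_series(t, 5.0 * np.exp(-0.6931 * t)))
        assert fit.half_life == pytest.approx(1.0, abs=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_recovers_reported_short_chain_half_lives(self):
        """Noiseless series built from the measured 1.95 h / 2.57 h half-lives."""
        t = np.linspace(0, 6, 8)
        for hl in (1.95, 2.57):
            fit = fit_first_order(_series(t, 5.0 * np.exp(-LN2 / hl * t)))
            assert fit.half_life == pytest.approx(hl, rel=1e-6)

    def test_agrees_with_grid_search_oracle(self, rng):
        for i in range(20):
            t = np.linspace(0, 6, 8)
            c0, k = rng.uniform(3, 8), rng.uniform(0.2, 1.5)
            c = c0 * np.exp(-k * t) * rng.lognormal(0, 0.05, len(t))
            fit = fit_first_order(_series(t, c))
            c0_o, k_o = oracle_first_order_grid(t, c)
            assert fit.rate_k == pytest.approx(k_o, rel=0.01)
            assert fit.c0_hat == pytest.approx(c0_o, rel=0.01)

    def test_zero_floor_applied_before_log(self):
        t = np.linspace(0, 6, 8)
        c = 5.0 * np.exp(-2.0 * t)
        c[-1] = 0.0
        fit = fit_first_order(_series(t, c), zero_floor=0.001)
        assert fit.ok and fit.rate_k > 0

    def test_long_zero_tail_fails(self):
        t = np.linspace(0, 6, 8)
        c = np.array([5.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        fit = fit_first_order(_series(t, c))
        assert not fit.ok and "zero tail" in fit.reason

    def test_model_mismatch_lowers_r_squared(self):
        t = np.linspace(0, 5, 10)
        c = 5.0 * np.exp(-0.8 * t)
        assert fit_zero_order(_series(t, c)).r_squared < fit_first_order(
            _series(t, c)
        ).r_squared

    def test_estimator_interface(self):
        t = np.linspace(0, 5, 8)
        est = FirstOrderDecayFitter(refine=False).fit(t, 5.0 * np.exp(-0.5 * t))
        assert est.get_params() == {"refine": False, "zero_floor": None}
        np.testing.assert_allclose(est.predict(t), 5.0 * np.exp(-0.5 * t), rtol=1e-6)
        assert est.half_life_ == pytest.approx(LN2 / 0.5, rel=1e-6)


class TestSelectModel:
    def test_perfect_exponential_prefers_first_order(self):
        t = np.linspace(0, 5, 10)
        s = _series(t, 5.0 * np.exp(-0.8 * t))
        assert select_model(fit_zero_order(s), fit_first_order(s)).order == 1

    def test_perfect_line_prefers_zero_order(self):
        t = np.linspace(0, 3, 10)
        s = _series(t, 10.0 - 2.0 * t)
        assert select_model(fit_zero_order(s), fit_first_order(s)).order == 0

    def test_tie_goes_to_first_order(self):
        from quorumflow.kinetics import KineticFit
        f0 = KineticFit(order=0, r_squared=0.95)
        f1 = KineticFit(order=1, r_squared=0.95)
        assert select_model(f0, f1).order == 1

    def test_failures_propagate(self):
        from quorumflow.kinetics import KineticFit
        bad = KineticFit(order=0, ok=False, reason="x")
        good = KineticFit(order=1, r_squared=0.5)
        assert select_model(bad, good).order == 1
        assert not select_model(bad, KineticFit(order=1, ok=False, reason="y")).ok


class TestAdsorption:
    def _pair(self, heat_scale):
        t = np.array([0.0, 1.0, 2.0])
        sww = _series(t, [5.0, 5.0, 5.0], condition="sww_control")
        heat = _series(t, heat_scale * np.array([5.0, 5.0, 5.0]),
                       condition="heat_inactivated")
        return sww, heat

    def test_twenty_percent_loss(self):
        frac, per_point = adsorption_fraction(*self._pair(0.8))
        assert frac == pytest.approx(0.20, abs=1e-12)
        assert per_point == pytest.approx((0.2, 0.2))

    def test_no_adsorption(self):
        assert adsorption_fraction(*self._pair(1.0))[0] == 0.0

    def test_heat_above_sww_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            frac, _ = adsorption_fraction(*self._pair(1.1))
        assert frac == 0.0

    def test_missing_one_hour_neighbourhood_fails(self):
        t = np.array([0.0, 3.0, 4.0])
        sww = _series(t, [5.0, 5.0, 5.0], condition="sww_control")
        heat = _series(t, [4.0, 4.0, 4.0], condition="heat_inactivated")
        with pytest.raises(ValueError, match="within"):
            adsorption_fraction(sww, heat)

    def test_correction_rescales_live_series(self):
        t = np.array([0.0, 1.0, 2.0])
        live = _series(t, 0.8 * 5.0 * np.exp(-0.5 * t))
        corrected = correct_for_adsorption(live, 0.2)
        np.testing.assert_allclose(corrected.concentrations,
                                   5.0 * np.exp(-0.5 * t), rtol=1e-12)


class TestCompareHalfLives:
    def test_holm_sidak_hand_example(self):
        adj = holm_sidak_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2, abs=1e-10)  # 0.0199
        assert adj[1] == pytest.approx(0.04, abs=1e-10)

    def test_adjusted_monotone_and_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 12)
        adj = holm_sidak_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_identical_groups_not_significant(self):
        groups = {"C6-HSL": [2.0, 2.1, 1.9]}
        out = compare_half_lives(groups, groups)
        assert out["p_adj"].iloc[0] > 0.9

    def test_separated_groups_all_significant(self, rng):
        live = {a: rng.normal(2.0, 0.1, 5) for a in ("C6-HSL", "C8-HSL", "C12-HSL")}
        heat = {a: rng.normal(20.0, 1.0, 5) for a in live}
        out = compare_half_lives(live, heat)
        assert (out["p_adj"] < 0.05).all()

    def test_underreplicated_ahls_excluded(self):
        out = compare_half_lives({"C6-HSL": [1.0]}, {"C6-HSL": [2.0, 2.0]})
        assert len(out) == 0


class TestChainLengthTrend:
    def test_strictly_decreasing_gives_minus_one(self):
        hl = {"C6-HSL": 1.95, "C8-HSL": 1.2, "C12-HSL": 0.79}
        out = chain_length_trend(hl)
        row = out[out.substitution == "unsubstituted"].iloc[0]
        assert row.spearman_rho == pytest.approx(-1.0)
        assert row.inverse_trend

    def test_reported_panel_flags_inverse_trend(self):
        hl = {"C6-HSL": 1.95, "C8-HSL": 1.4, "C12-HSL": 0.79,
              "3OC6-HSL": 2.57, "3OC8-HSL": 1.8, "3OC12-HSL": 0.66}
        out = chain_length_trend(hl)
        assert out["inverse_trend"].all()

    def test_shuffled_half_lives_average_small_correlation(self):
        hls = [1.95, 1.4, 1.1, 0.9, 0.79]
        chains = ["C4-HSL", "C6-HSL", "C8-HSL", "C10-HSL", "C12-HSL"]
        rhos = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            shuffled = rng.permutation(hls)
            out = chain_length_trend(dict(zip(chains, shuffled)))
            rhos.append(out["spearman_rho"].iloc[0])
        assert abs(np.mean(rhos)) < 0.1

    def test_tied_half_lives_reported_undefined(self):
        out = chain_length_trend({"C6-HSL": 1.0, "C8-HSL": 1.0, "C12-HSL": 1.0})
        assert np.isnan(out["spearman_rho"].iloc[0])
        assert "undefined" in out["note"].iloc[0]


class TestAnalyseDecayTable:
    def test_end_to_end_on_synthetic_panel(self):
        frames = []
        panel = {"C6-HSL": LN2 / 1.95, "C12-HSL": LN2 / 0.79}
        for j, (ahl, k) in enumerate(panel.items()):
            for rep in range(3):
                plan = synthetic.DecaySimPlan(
                    ahl=ahl, order=1, rate_constant=k, adsorption_fraction=0.2,
                    noise_cv=0.05, seed=100 + 10 * j + rep,
                    timepoints=tuple(np.linspace(0, 6, 8)),
                )
                frames.append(synthetic.decay_table(synthetic.gen_decay(plan),
                                                    replicate=rep + 1))
        report = analyse_decay_table(pd.concat(frames, ignore_index=True))
        live = report.fits[(report.fits.condition == "live") & report.fits.ok]
        mean_hl = live.groupby("ahl")["half_life"].mean()
        assert mean_hl["C6-HSL"] == pytest.approx(1.95, rel=0.1)
        assert mean_hl["C12-HSL"] == pytest.approx(0.79, rel=0.1)
        assert mean_hl["C12-HSL"] < mean_hl["C6-HSL"]
        assert report.adsorption["C6-HSL"] == pytest.approx(0.2, abs=0.1)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            analyse_decay_table(pd.DataFrame({"ahl": []}))
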