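"""Likelihoods, marginalization schemes, and maximum-likelihood fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import reachconf as rc
from tests.conftest import FAST_FIT, FAST_INTEGRATION


def make_control(t, e, i):
    t, e, i = (np.atleast_2d(np.asarray(x, float)) for x in (t, e, i))
    return pd.DataFrame({
        "trial": np.arange(1, len(t) + 1),
        "target_x": t[:, 0], "target_y": t[:, 1],
        "endpoint_x": e[:, 0], "endpoint_y": e[:, 1],
        "indicated_x": i[:, 0], "indicated_y": i[:, 1],
    })


class TestControlLoglik:
    def test_density_peaks_closed_form(self):
        """One trial with endpoint on target and the indicated endpoint at
        the MAP prediction: the log-likelihood is the two mode densities."""
        sm, sp = 20.0, 35.0
        df = make_control([0.0, 150.0], [0.0, 150.0], [0.0, 150.0])
        w = sm**2 / (sm**2 + sp**2)
        expected = -np.log(2 * np.pi * sm**2) - np.log(
            2 * np.pi * (w * sp)**2)
        assert rc.control_loglik(df, sm, sp) == pytest.approx(expected)

    def test_against_univariate_density_oracle(self):
        """Matches per-coordinate scipy normal log-densities on simulated
        trials to 1e-9."""
        params = rc.ObserverParams(18.0, 30.0, 5.0)
        df = rc.simulate_control_task(params, 100, seed=11)
        sm, sp = 22.0, 28.0  # evaluate away from the generating values
        w = sm**2 / (sm**2 + sp**2)
        t = df[["target_x", "target_y"]].to_numpy()
        e = df[["endpoint_x", "endpoint_y"]].to_numpy()
        i = df[["indicated_x", "indicated_y"]].to_numpy()
        oracle = (stats.norm.logpdf(e, t, sm).sum()
                  + stats.norm.logpdf(i, w * e + (1 - w) * t, w * sp).sum())
        assert rc.control_loglik(df, sm, sp) == pytest.approx(oracle,
                                                              abs=1e-9)

    def test_ml_consistency_in_sigma_m(self):
        params = rc.ObserverParams(20.0, 35.0, 5.0)
        df = rc.simulate_control_task(params, 10_000, seed=12)
        grid = 20.0 * np.linspace(0.8, 1.2, 81)
        lls = [rc.control_loglik(df, sm, 35.0) for sm in grid]
        best = grid[int(np.argmax(lls))]
        assert abs(best - 20.0) / 20.0 < 0.05

    def test_invalid_sigma_rejected(self):
        df = make_control([0, 150], [0, 150], [0, 150])
        with pytest.raises(ValueError):
            rc.control_loglik(df, -1.0, 20.0)


class TestPolicyTable:
    params = rc.ObserverParams(20.0, 20.0, 5.0)

    def test_prospective_table_is_constant(self):
        table = rc.policy_table(rc.ModelKind.PROSPECTIVE, self.params)
        d = np.array([0.0, 40.0, 250.0])
        assert np.ptp(table(d)) == 0.0

    @pytest.mark.parametrize("model", [rc.ModelKind.IDEAL,
                                       rc.ModelKind.RETROSPECTIVE])
    def test_interpolation_refinement(self, model):
        """Linear interpolation at off-grid distances stays within 0.2 mm of
        the directly optimized circle (default 0.5 mm table step)."""
        table = rc.policy_table(model, self.params)
        rng = np.random.default_rng(13)
        d = rng.uniform(0.0, 120.0, 40)
        direct = rc.optimal_circle(model, self.params, d)
        assert np.max(np.abs(table(d) - direct)) < 0.2

    def test_reproducible(self):
        a = rc.policy_table(rc.ModelKind.IDEAL, self.params)
        b = rc.policy_table(rc.ModelKind.IDEAL, self.params)
        assert np.array_equal(a.values, b.values)


class TestConfidenceLoglik:
    params = rc.ObserverParams(20.0, 20.0, 5.0)

    def _conf_df(self, circles, e=None, t=None):
        n = len(circles)
        t = np.tile([0.0, 183.0], (n, 1)) if t is None else np.asarray(t)
        e = t + 5.0 if e is None else np.asarray(e)
        return pd.DataFrame({
            "target_x": t[:, 0], "target_y": t[:, 1],
            "endpoint_x": e[:, 0], "endpoint_y": e[:, 1],
            "kind": "confidence", "circle_radius": circles,
        })

    def test_prospective_mode_density(self):
        c_opt = rc.optimal_circle(rc.ModelKind.PROSPECTIVE, self.params, 0.0)
        df = self._conf_df([c_opt])
        ll = rc.confidence_loglik(rc.ModelKind.PROSPECTIVE, df, self.params)
        assert ll == pytest.approx(-np.log(np.sqrt(2 * np.pi) * 5.0))

    def test_grid_and_radial_modes_agree(self, params_equal):
        """Two independent discretizations of the sensed-location integral
        agree within 1e-3 nats per trial."""
        main = rc.simulate_main_task(rc.ModelKind.IDEAL, params_equal, 50,
                                     seed=14)
        conf = main[main["kind"] == "confidence"]
        ll_1d = rc.confidence_loglik(
            rc.ModelKind.IDEAL, conf, params_equal,
            rc.IntegrationConfig(mode="1d-radial"))
        ll_2d = rc.confidence_loglik(
            rc.ModelKind.IDEAL, conf, params_equal,
            rc.IntegrationConfig(mode="2d-grid"))
        assert abs(ll_1d - ll_2d) / len(conf) < 1e-3

    def test_halving_resolution_is_converged(self, params_equal):
        main = rc.simulate_main_task(rc.ModelKind.RETROSPECTIVE, params_equal,
                                     50, seed=15)
        conf = main[main["kind"] == "confidence"]
        coarse = rc.confidence_loglik(
            rc.ModelKind.RETROSPECTIVE, conf, params_equal,
            rc.IntegrationConfig(radial_nodes=200, policy_table_step=0.5))
        fine = rc.confidence_loglik(
            rc.ModelKind.RETROSPECTIVE, conf, params_equal,
            rc.IntegrationConfig(radial_nodes=400, policy_table_step=0.25))
        assert abs(coarse - fine) / len(conf) < 1e-3

    def test_per_trial_marginal_against_monte_carlo(self):
        """Quadrature marginal equals a 1e6-draw Monte-Carlo average of the
        setting-noise density over sensed locations."""
        rng = np.random.default_rng(16)
        e = np.array([[12.0, 190.0]])
        t = np.array([[0.0, 183.0]])
        df = self._conf_df([28.0], e=e, t=t)
        logm = rc.confidence_loglik(rc.ModelKind.IDEAL, df, self.params,
                                    return_per_trial=True)[0]
        table = rc.policy_table(rc.ModelKind.IDEAL, self.params,
                                rc.IntegrationConfig(policy_table_step=0.25))
        n = 1_000_000
        p = e + rng.normal(0.0, self.params.sigma_p, (n, 2))
        d = np.linalg.norm(p - t, axis=1)
        dens = stats.norm.pdf(28.0, loc=table(d), scale=self.params.sigma_s)
        mc, se = dens.mean(), dens.std() / np.sqrt(n)
        assert abs(np.exp(logm) - mc) < 3 * se

    def test_prospective_independent_of_sigma_p(self):
        """sigma_p is structurally unidentifiable from prospective confidence
        rows; it enters only through the control task."""
        df = self._conf_df([25.0, 30.0, 35.0])
        lls = [rc.confidence_loglik(
            rc.ModelKind.PROSPECTIVE, df,
            rc.ObserverParams(20.0, sp, 5.0)) for sp in (10.0, 100.0)]
        assert lls[0] == pytest.approx(lls[1])

    def test_missing_circle_rejected(self):
        df = self._conf_df([25.0])
        df.loc[0, "circle_radius"] = np.nan
        with pytest.raises(ValueError):
            rc.confidence_loglik(rc.ModelKind.IDEAL, df, self.params)


class TestTotalLoglik:
    def test_additivity(self, params_equal, control_300, ideal_main_300):
        total = rc.total_loglik(rc.ModelKind.IDEAL, control_300,
                                ideal_main_300, params_equal)
        conf = ideal_main_300[ideal_main_300["kind"] == "confidence"]
        part_control = rc.control_loglik(control_300, 20.0, 20.0)
        e = ideal_main_300[["endpoint_x", "endpoint_y"]].to_numpy()
        t = ideal_main_300[["target_x", "target_y"]].to_numpy()
        part_endpoints = stats.norm.logpdf(e, t, 20.0).sum()
        part_conf = rc.confidence_loglik(rc.ModelKind.IDEAL, conf,
                                         params_equal)
        assert total == pytest.approx(
            part_control + part_endpoints + part_conf, rel=1e-12)

    def test_truth_beats_perturbed_sigma_m(self, params_equal, control_300,
                                           prospective_main_300):
        ll_true = rc.total_loglik(rc.ModelKind.PROSPECTIVE, control_300,
                                  prospective_main_300, params_equal)
        ll_wrong = rc.total_loglik(
            rc.ModelKind.PROSPECTIVE, control_300, prospective_main_300,
            rc.ObserverParams(40.0, 20.0, 5.0))
        assert ll_true > ll_wrong

    def test_empty_data_rejected(self, params_equal, control_300):
        with pytest.raises(ValueError):
            rc.total_loglik(rc.ModelKind.IDEAL, control_300.iloc[:0],
                            control_300, params_equal)


class TestFitModel:
    @pytest.mark.parametrize("model", list(rc.ModelKind))
    def test_self_fit_recovers_and_dominates_truth(self, model, params_equal,
                                                   control_300):
        """Fitting the generating model: the optimized log-likelihood must
        not fall below the likelihood at the generating parameters, and the
        estimates land near the truth."""
        main = rc.simulate_main_task(model, params_equal, 300,
                                     seed=20 + list(rc.ModelKind).index(model))
        fit = rc.fit_model(model, control_300, main, FAST_FIT,
                           FAST_INTEGRATION)
        ll_truth = rc.total_loglik(model, control_300, main, params_equal,
                                   FAST_INTEGRATION)
        assert fit.loglik >= ll_truth - 1e-3
        assert fit.params.sigma_m == pytest.approx(20.0, rel=0.10)
        assert fit.params.sigma_s == pytest.approx(5.0, rel=0.25)
        if model is not rc.ModelKind.PROSPECTIVE:
            assert fit.params.sigma_p == pytest.approx(20.0, rel=0.15)
        assert (fit.n_control, fit.n_main, fit.n_confidence) == (300, 900,
                                                                 300)

    def test_moment_start_is_sane(self, control_300, ideal_main_300):
        start = rc.fitting.moment_start(control_300, ideal_main_300)
        assert start.sigma_m == pytest.approx(20.0, rel=0.15)
        assert start.sigma_p == pytest.approx(20.0, rel=0.5)

    def test_fit_deterministic_under_config(self, params_equal, control_300,
                                            prospective_main_300):
        cfg = rc.FitConfig(n_starts=2, seed=7)
        fits = [rc.fit_model(rc.ModelKind.PROSPECTIVE, control_300,
                             prospective_main_300, cfg, FAST_INTEGRATION)
                for _ in range(2)]
        assert fits[0].params == fits[1].params


def test_integration_config_validation():
    with pytest.raises(ValueError):
        rc.IntegrationConfig(mode="3d")
    with pytest.raises(ValueError):
        rc.IntegrationConfig(grid_half_width=1.0)
    with pytest.raises(ValueError):
        rc.FitConfig(lower=10.0, upper=5.0)
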