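import numpy as np
import pandas as pd
import pytest

from u5trends import spacetime_model as st
from u5trends import synthetic_data as sd


def make_cells(regions, years, y, v):
    return st.ObservedCells(
        regions=tuple(regions), years=np.asarray(years), y=y, v=v
    )


class TestStructureMatrices:
    def test_icar_path3_explicit(self, path3_graph):
        q = st.build_icar_precision(path3_graph)
        assert np.array_equal(q, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_icar_fixture_rank_and_rowsums(self, fixture_graph):
        q = st.build_icar_precision(fixture_graph)
        assert np.allclose(q.sum(axis=1), 0.0)
        assert np.allclose(q, q.T)
        assert np.linalg.matrix_rank(q) == 7

    def test_icar_disconnected_rejected(self):
        g = sd.AdjacencyGraph(
            region_names=("A", "B", "C", "D"),
            edges=frozenset({frozenset(("A", "B")), frozenset(("C", "D"))}),
        )
        with pytest.raises(ValueError, match="connected"):
            st.build_icar_precision(g)

    def test_rw1_explicit(self):
        r = st.build_rw_precision(3, 1)
        assert np.array_equal(r, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_rw2_null_space_and_rank(self):
        T = 33
        r = st.build_rw_precision(T, 2)
        t = np.arange(T, dtype=float)
        assert np.allclose(r @ np.ones(T), 0.0, atol=1e-10)
        assert np.allclose(r @ t, 0.0, atol=1e-9)
        assert np.linalg.matrix_rank(r) == T - 2

    def test_rw2_matches_difference_product(self):
        d2 = np.diff(np.eye(5), n=2, axis=0)
        assert np.allclose(st.build_rw_precision(5, 2), d2.T @ d2)

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            st.build_rw_precision(10, 3)


class TestGibbsReducedModels:
    """Single-block reduced models against closed-form conjugate posteriors."""

    def _grid(self, n=4, T=6, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal((n, T)) - 2.0
        v = rng.uniform(0.05, 0.3, size=(n, T))
        return y, v

    def test_mu_only_matches_precision_weighted_mean(self, path3_graph):
        y, v = self._grid(n=3, T=5, seed=1)
        cells = make_cells(path3_graph.region_names, range(2000, 2005), y, v)
        spec = st.ModelSpec(n_iter=3000, n_burn=500, thin=1, seed=2)
        fit = st.gibbs_fit(cells, path3_graph, spec, include={"mu"})
        w = 1.0 / v
        prec = w.sum() + 1e-6
        mean = (w * y).sum() / prec
        S = fit.n_draws
        se = fit.mu.std(ddof=1) / np.sqrt(S)  # draws are iid here
        assert abs(fit.mu.mean() - mean) < 3 * se
        assert abs(fit.mu.var(ddof=1) - 1 / prec) < 3 * (1 / prec) * np.sqrt(2 / S)

    def test_theta_only_matches_closed_form(self, path3_graph):
        y, v = self._grid(n=3, T=8, seed=3)
        cells = make_cells(path3_graph.region_names, range(2000, 2008), y, v)
        tau0 = 2.0
        spec = st.ModelSpec(n_iter=3000, n_burn=500, thin=1, seed=4)
        fit = st.gibbs_fit(
            cells, path3_graph, spec,
            include={"theta"}, fixed_precisions={"theta": tau0},
        )
        w = 1.0 / v
        prec = tau0 + w.sum(axis=1)
        mean = (w * y).sum(axis=1) / prec
        S = fit.n_draws
        for i in range(3):
            se = fit.theta[:, i].std(ddof=1) / np.sqrt(S)
            assert abs(fit.theta[:, i].mean() - mean[i]) < 3 * se
            assert abs(fit.theta[:, i].var(ddof=1) - 1 / prec[i]) < 3 * (
                1 / prec[i]
            ) * np.sqrt(2 / S)

    def test_alpha_only_matches_closed_form(self, path3_graph):
        y, v = self._grid(n=3, T=4, seed=5)
        cells = make_cells(path3_graph.region_names, range(2000, 2004), y, v)
        tau0 = 1.5
        spec = st.ModelSpec(n_iter=3000, n_burn=500, thin=1, seed=6)
        fit = st.gibbs_fit(
            cells, path3_graph, spec,
            include={"alpha"}, fixed_precisions={"alpha": tau0},
        )
        w = 1.0 / v
        prec = tau0 + w.sum(axis=0)
        mean = (w * y).sum(axis=0) / prec
        S = fit.n_draws
        err = np.abs(fit.alpha.mean(axis=0) - mean)
        se = fit.alpha.std(axis=0, ddof=1) / np.sqrt(S)
        assert np.all(err < 3 * se)

    def test_pinned_variances_reduce_to_mu(self, path3_graph):
        """All effect precisions pinned huge: posterior of mu is the
        precision-weighted mean of all observations."""
        y, v = self._grid(n=3, T=5, seed=7)
        cells = make_cells(path3_graph.region_names, range(2000, 2005), y, v)
        spec = st.ModelSpec(n_iter=4000, n_burn=1000, thin=1, seed=8)
        fit = st.gibbs_fit(
            cells, path3_graph, spec,
            fixed_precisions=dict.fromkeys(
                ("alpha", "gamma", "theta", "phi", "delta"), 1e12
            ),
        )
        w = 1.0 / v
        mean = (w * y).sum() / (w.sum() + 1e-6)
        se = fit.mu.std(ddof=1) / np.sqrt(fit.n_draws)
        assert abs(fit.mu.mean() - mean) < 5 * se + 1e-4


class TestGibbsFullModel:
    def test_same_seed_identical_draws(self, path3_graph):
        y = np.full((3, 5), -2.0)
        v = np.full((3, 5), 0.04)
        cells = make_cells(path3_graph.region_names, range(2000, 2005), y, v)
        spec = st.ModelSpec(n_iter=300, n_burn=100, thin=2, seed=13)
        a = st.gibbs_fit(cells, path3_graph, spec)
        b = st.gibbs_fit(cells, path3_graph, spec)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.delta, b.delta)
        for k in a.tau:
            assert np.array_equal(a.tau[k], b.tau[k])

    def test_constraints_hold_per_draw(self, model2_fit):
        _, _, fit = model2_fit
        T = fit.gamma.shape[1]
        t = np.arange(T) - (T - 1) / 2
        assert np.max(np.abs(fit.alpha.sum(axis=1))) < 1e-8
        assert np.max(np.abs(fit.gamma.sum(axis=1))) < 1e-8
        assert np.max(np.abs(fit.gamma @ t)) < 1e-6  # orthogonal to linear trend
        assert np.max(np.abs(fit.theta.sum(axis=1))) < 1e-8
        assert np.max(np.abs(fit.phi.sum(axis=1))) < 1e-8
        assert np.max(np.abs(fit.delta.sum(axis=1))) < 1e-8
        assert np.max(np.abs(fit.delta.sum(axis=2))) < 1e-8
        for k, draws in fit.tau.items():
            assert np.all(draws > 0)

    def test_recovers_truth_and_shrinks(self, model2_fit):
        surface, cells, fit = model2_fit
        eta_med = np.median(fit.eta_draws(), axis=0)
        r = np.corrcoef(eta_med.ravel(), surface.eta.ravel())[0, 1]
        assert r > 0.95
        mse_post = np.mean((eta_med - surface.eta) ** 2)
        mse_raw = np.mean((cells.y - surface.eta) ** 2)
        assert mse_post < mse_raw

    def test_missing_cells_allowed(self, path3_graph):
        rng = np.random.default_rng(20)
        y = rng.standard_normal((3, 6)) - 2
        v = np.full((3, 6), 0.05)
        y[1, 2] = np.nan
        v[1, 2] = np.nan
        cells = make_cells(path3_graph.region_names, range(2000, 2006), y, v)
        spec = st.ModelSpec(n_iter=400, n_burn=100, thin=1, seed=21)
        fit = st.gibbs_fit(cells, path3_graph, spec)
        assert np.all(np.isfinite(fit.eta_draws()))

    def test_unknown_region_rejected(self, path3_graph):
        est = pd.DataFrame(
            {"region": ["Z"], "year": [2000], "logit_mean": [0.0],
             "logit_variance": [0.1]}
        )
        with pytest.raises(ValueError, match="unknown region"):
            st.cells_from_estimates(est, path3_graph.region_names, range(2000, 2003))


class TestSummaries:
    def _point_mass_samples(self, path3_graph, value=0.5):
        S, n, T = 120, 3, 5
        spec = st.ModelSpec(n_iter=10, n_burn=0, thin=1, seed=0)
        return st.PosteriorSamples(
            regions=path3_graph.region_names,
            years=np.arange(2000, 2005),
            spec=spec,
            mu=np.full(S, -2.0),
            alpha=np.zeros((S, T)),
            gamma=np.tile(np.linspace(-1, 1, T), (S, 1)) * value,
            theta=np.zeros((S, n)),
            phi=np.tile([0.2, -0.1, -0.1], (S, 1)),
            delta=np.zeros((S, n, T)),
            tau={k: np.ones(S) for k in ("alpha", "gamma", "theta", "phi", "delta")},
        )

    def test_point_mass_draws_zero_width(self, path3_graph):
        samples = self._point_mass_samples(path3_graph)
        summ = st.posterior_summaries(samples)
        assert np.allclose(summ["phi"]["median"], [0.2, -0.1, -0.1])
        assert np.allclose(summ["phi"].upper - summ["phi"].lower, 0.0)

    def test_phi_medians_inherit_constraint(self, model2_fit):
        _, _, fit = model2_fit
        summ = st.posterior_summaries(fit)
        assert abs(summ["phi"]["median"].sum()) < 0.01

    def test_u5mr_scale(self, path3_graph):
        samples = self._point_mass_samples(path3_graph, value=0.0)
        summ = st.posterior_summaries(samples)
        from scipy.special import expit

        row = summ["u5mr"].iloc[0]  # region A, first year: eta = mu + phi_A
        assert row["median"] == pytest.approx(1000 * expit(-2.0 + 0.2))


class TestForecast:
    def test_pinned_precision_continues_line(self, path3_graph):
        """With enormous RW2 precision and linear gamma the forecast is the
        exact linear continuation."""
        S, n, T = 200, 3, 10
        slope, mu0 = -0.05, -2.0
        t = np.arange(T, dtype=float)
        gamma_line = slope * (t - t.mean())
        spec = st.ModelSpec(temporal_order=2, n_iter=10, n_burn=0, thin=1, seed=0)
        samples = st.PosteriorSamples(
            regions=path3_graph.region_names,
            years=np.arange(2000, 2010),
            spec=spec,
            mu=np.full(S, mu0),
            alpha=np.zeros((S, T)),
            gamma=np.tile(gamma_line, (S, 1)),
            theta=np.zeros((S, n)),
            phi=np.zeros((S, n)),
            delta=np.zeros((S, n, T)),
            tau={k: np.full(S, 1e24) for k in ("alpha", "gamma", "theta", "phi", "delta")},
        )
        res = st.forecast(samples, H=8, seed=1)
        from scipy.special import logit

        got = res.table[res.table.region == "A"].sort_values("year")
        expected_gamma = slope * (T + np.arange(8) - t.mean())
        got_logit = logit(got["median"].to_numpy() / 1000.0)
        assert np.allclose(got_logit - mu0, expected_gamma, atol=1e-6)

    def test_zero_horizon_empty(self, model2_fit):
        _, _, fit = model2_fit
        res = st.forecast(fit, H=0, seed=0)
        assert len(res.table) == 0

    def test_interval_width_grows_with_horizon(self, model2_fit):
        _, _, fit = model2_fit
        res = st.forecast(fit, H=8, seed=2)
        w = (
            res.table.assign(width=lambda d: d.upper - d.lower)
            .groupby("year")["width"].mean()
            .to_numpy()
        )
        assert np.all(np.diff(w) > 0)

    def test_bounds_ordered(self, model2_fit):
        _, _, fit = model2_fit
        res = st.forecast(fit, H=5, seed=3)
        assert (res.table.lower <= res.table["median"]).all()
        assert (res.table["median"] <= res.table.upper).all()
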