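"""Resampling schemes, p-values, adjustment, quantiles, full pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from wtonet import (CorrelationConfig, ExpressionMatrix, FixtureSpec,
                    NullDistribution, ResamplingConfig, adjust_pvalues,
                    build_null_distribution, correlation_adjacency,
                    empirical_quantiles, make_ar1_series,
                    pvalues_bootstrap, pvalues_permutation,
                    resample_columns_block, resample_columns_bootstrap,
                    reshuffle_matrix, suggest_lag, wto, wto_complete)


def small_expr(seed=0, n=5, s=12, ts=False):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(tuple(f"g{i}" for i in range(n)),
                            tuple(f"s{j}" for j in range(s)),
                            rng.normal(size=(n, s)), is_time_series=ts)


class TestBootstrapResampling:
    def test_deterministic_under_seed_and_columns_are_originals(self):
        expr = small_expr()
        a = resample_columns_bootstrap(expr, np.random.default_rng(3))
        b = resample_columns_bootstrap(expr, np.random.default_rng(3))
        np.testing.assert_array_equal(a.values, b.values)
        assert a.n_samples == expr.n_samples
        orig = {tuple(col) for col in expr.values.T}
        assert all(tuple(col) in orig for col in a.values.T)

    def test_column_frequencies_match_binomial(self):
        expr = small_expr(n=3, s=5)
        rng = np.random.default_rng(0)
        counts = np.zeros(5)
        draws = 10_000
        for _ in range(draws):
            res = resample_columns_bootstrap(expr, rng)
            for col in res.values.T:
                for j in range(5):
                    if np.array_equal(col, expr.values[:, j]):
                        counts[j] += 1
                        break
        freqs = counts / (draws * 5)
        assert np.all(np.abs(freqs - 0.2) < 0.02)


class TestBlockBootstrap:
    def test_requires_time_series_and_valid_lag(self):
        expr = small_expr(ts=False)
        with pytest.raises(ValueError, match="plain bootstrap"):
            resample_columns_block(expr, 2, np.random.default_rng(0))
        ts = small_expr(ts=True)
        with pytest.raises(ValueError, match="lag"):
            resample_columns_block(ts, ts.n_samples, np.random.default_rng(0))

    def test_blocks_preserve_consecutive_runs(self):
        ts = ExpressionMatrix(("a", "b", "c"), tuple(f"t{j}" for j in range(10)),
                              np.tile(np.arange(10.0), (3, 1)) +
                              np.array([[0.0], [100.0], [200.0]]),
                              is_time_series=True)
        res = resample_columns_block(ts, 4, np.random.default_rng(1))
        assert res.n_samples == 10
        first = res.values[0]
        # inside each length-4 block, consecutive entries step by exactly 1
        for start in range(0, 8, 4):
            diffs = np.diff(first[start:start + 4])
            np.testing.assert_array_equal(diffs, np.ones(3))

    def test_lag_one_is_plain_column_bootstrap(self):
        ts = small_expr(ts=True)
        res = resample_columns_block(ts, 1, np.random.default_rng(2))
        orig = {tuple(col) for col in ts.values.T}
        assert all(tuple(col) in orig for col in res.values.T)

    def test_block_resampling_preserves_autocorrelation_better(self):
        spec = FixtureSpec(n_nodes=1, n_samples=200, n_modules=1,
                           within_module_correlation=0.0, ar_phi=0.8, seed=5)
        # single-row spec violates N >= 3; use 3 independent AR rows
        spec = FixtureSpec(n_nodes=3, n_samples=200, n_modules=3,
                           within_module_correlation=0.0, ar_phi=0.8, seed=5)
        ts = make_ar1_series(spec)
        rng = np.random.default_rng(0)

        def lag1(x):
            return np.corrcoef(x[:-1], x[1:])[0, 1]

        block_acf, plain_acf = [], []
        for _ in range(200):
            b = resample_columns_block(ts, 5, rng)
            p = resample_columns_bootstrap(ts, rng)
            block_acf.append(np.mean([lag1(r) for r in b.values]))
            plain_acf.append(np.mean([lag1(r) for r in p.values]))
        true_acf = 0.8
        assert abs(np.mean(block_acf) - true_acf) < abs(np.mean(plain_acf) - true_acf)
        assert np.mean(block_acf) > np.mean(plain_acf) + 0.2


class TestSuggestLag:
    def test_white_noise_suggests_one(self):
        spec = FixtureSpec(n_nodes=10, n_samples=100, n_modules=10,
                           within_module_correlation=0.0, ar_phi=0.0, seed=1)
        assert suggest_lag(make_ar1_series(spec)) == 1

    def test_slow_sinusoid_suggests_larger_lag(self):
        rng = np.random.default_rng(2)
        t = np.arange(100.0)
        rows = np.vstack([np.sin(2 * np.pi * t / 40) + 0.1 * rng.normal(size=100)
                          for _ in range(5)])
        ts = ExpressionMatrix(tuple(f"g{i}" for i in range(5)),
                              tuple(f"t{j}" for j in range(100)), rows,
                              is_time_series=True)
        assert suggest_lag(ts, max_lag=10) > 1


class TestReshuffle:
    def test_columns_are_permutations_and_seeded(self):
        expr = small_expr()
        a = reshuffle_matrix(expr, np.random.default_rng(7))
        b = reshuffle_matrix(expr, np.random.default_rng(7))
        np.testing.assert_array_equal(a.values, b.values)
        for j in range(expr.n_samples):
            assert sorted(a.values[:, j]) == pytest.approx(
                sorted(expr.values[:, j]))

    def test_row_means_converge_to_pooled_mean(self):
        expr = small_expr(n=4, s=6)
        rng = np.random.default_rng(0)
        acc = np.zeros(4)
        n_shuffles = 1000
        for _ in range(n_shuffles):
            acc += reshuffle_matrix(expr, rng).values.mean(axis=1)
        pooled = expr.values.mean()
        assert np.all(np.abs(acc / n_shuffles - pooled) < 0.05)


def _null_from(values_signed, values_abs, edges):
    return NullDistribution(edges, np.asarray(values_signed, float),
                            np.asarray(values_abs, float))


class TestPValues:
    @pytest.fixture
    def tiny_net(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 0.6
        A[0, 2] = A[2, 0] = 0.3
        from wtonet import AdjacencyMatrix
        return wto(AdjacencyMatrix(("a", "b", "c"), A))

    def test_bootstrap_delta_band_counts(self, tiny_net):
        edges = tiny_net.as_edge_list()
        m = len(edges)
        omega = edges["wTO_sign"].to_numpy()
        # distances (0.1, 0.25, 0.3, 0.05) from the observed value, delta 0.2
        dist = np.array([0.1, 0.25, 0.3, 0.05])
        signed = omega[:, None] + dist[None, :]
        null = _null_from(signed, np.abs(signed), edges)
        # use unsigned channel carefully: construct from abs omega too
        null = NullDistribution(edges, signed,
                                edges["wTO_abs"].to_numpy()[:, None] + dist[None, :])
        p = pvalues_bootstrap(tiny_net, null, delta=0.2)
        assert (p["pval_sig"] == 0.5).all()
        # all-within and all-beyond extremes
        close = omega[:, None] + np.full((1, 4), 0.01)
        null_close = NullDistribution(
            edges, close,
            edges["wTO_abs"].to_numpy()[:, None] + np.full((1, 4), 0.01))
        assert (pvalues_bootstrap(tiny_net, null_close, 0.2)["pval_sig"] == 0).all()
        far = omega[:, None] + np.full((1, 4), 0.9)
        null_far = NullDistribution(
            edges, far,
            edges["wTO_abs"].to_numpy()[:, None] + np.full((1, 4), 0.9))
        assert (pvalues_bootstrap(tiny_net, null_far, 0.2)["pval_sig"] == 1).all()

    def test_bootstrap_monotone_in_delta(self, tiny_net):
        edges = tiny_net.as_edge_list()
        rng = np.random.default_rng(0)
        vals = edges["wTO_sign"].to_numpy()[:, None] + rng.normal(0, 0.3, (len(edges), 50))
        null = NullDistribution(edges, vals, np.abs(vals))
        p_small = pvalues_bootstrap(tiny_net, null, 0.1)
        p_big = pvalues_bootstrap(tiny_net, null, 0.3)
        assert (p_big["pval_sig"] <= p_small["pval_sig"]).all()

    def test_permutation_addone_extremes(self, tiny_net):
        edges = tiny_net.as_edge_list()
        m, n = len(edges), 20
        null = NullDistribution(edges, np.zeros((m, n)), np.zeros((m, n)))
        p = pvalues_permutation(tiny_net, null)
        nonzero = edges["wTO_sign"].to_numpy() != 0
        assert np.allclose(p["pval_sig"][nonzero], 1 / (n + 1))
        # an observed weight of exactly 0 can never be extreme
        assert np.allclose(p["pval_sig"][~nonzero], 1.0)

    def test_permutation_pvalues_uniform_under_null(self, independent_expr):
        cfg = ResamplingConfig(method="reshuffle", n_resamples=200, seed=3)
        null = build_null_distribution(independent_expr, None,
                                       CorrelationConfig(), cfg)
        real = wto(correlation_adjacency(independent_expr))
        p = pvalues_permutation(real, null)["pval_sig"].to_numpy()
        frac = (p < 0.05).mean()
        assert 0.02 <= frac <= 0.08
        assert kstest(p, "uniform").statistic < 0.1


class TestAdjustPValues:
    def test_bh_hand_stepup(self):
        # m=4 sorted: min over j>=i of m p_j / j = (.04,.04,.04,.04)
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equal_and_singleton_pass_through(self):
        np.testing.assert_allclose(adjust_pvalues([0.3, 0.3, 0.3]), [0.3] * 3)
        np.testing.assert_allclose(adjust_pvalues([0.2]), [0.2])

    def test_padj_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        padj = adjust_pvalues(p)
        assert (padj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()

    def test_bonferroni_and_holm_and_unknown(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.4], "bonferroni"),
                                   [0.02, 0.8])
        holm = adjust_pvalues([0.01, 0.04], "holm")
        np.testing.assert_allclose(holm, [0.02, 0.04])
        with pytest.raises(ValueError, match="benjamini_hochberg"):
            adjust_pvalues([0.5], "fdr_magic")


class TestQuantiles:
    def test_type7_closed_form_and_constant(self):
        edges = pd.DataFrame({"Node.1": ["a"], "Node.2": ["b"]})
        vals = np.arange(1.0, 1001.0)[None, :]
        null = NullDistribution(edges, vals, np.abs(vals))
        from wtonet import AdjacencyMatrix
        A = np.zeros((3, 3)); A[0, 1] = A[1, 0] = 0.5
        net = wto(AdjacencyMatrix(("a", "b", "c"), A), ["a", "b"])
        q = empirical_quantiles(null, net)
        # type-7: q(0.9) of 1..1000 = 1 + 0.9*999 = 900.1
        assert q.loc["Empirical.Quantile", "90%"] == pytest.approx(900.1)
        assert (np.diff(q.loc["Empirical.Quantile"]) >= 0).all()
        const = NullDistribution(edges, np.full((1, 50), 0.3),
                                 np.full((1, 50), 0.3))
        qc = empirical_quantiles(const, net)
        np.testing.assert_allclose(qc.loc["Empirical.Quantile"].to_numpy(), 0.3)


class TestWTOComplete:
    def test_planted_blocks_get_stronger_and_more_significant_links(self, two_block_expr):
        res_cfg = ResamplingConfig(method="reshuffle", n_resamples=100, seed=1)
        result = wto_complete(two_block_expr, res_cfg=res_cfg)
        t = result.wto
        labels = {nid: int(nid[1:]) // 30 for nid in two_block_expr.node_ids}
        within = t[[labels[a] == labels[b]
                    for a, b in zip(t["Node.1"], t["Node.2"])]]
        between = t[[labels[a] != labels[b]
                     for a, b in zip(t["Node.1"], t["Node.2"])]]
        assert within["wTO_sign"].abs().mean() > 3 * between["wTO_sign"].abs().mean()
        assert within["pval_sig"].mean() < between["pval_sig"].mean()

    def test_no_resamples_returns_plain_wto(self, independent_expr):
        result = wto_complete(independent_expr,
                              res_cfg=ResamplingConfig(n_resamples=0))
        assert "pval_sig" not in result.wto.columns
        assert list(result.quantiles.index) == ["Real.Quantile"]
        m = independent_expr.n_nodes
        assert len(result.wto) == m * (m - 1) // 2

    def test_worker_count_does_not_change_results(self, independent_expr):
        with pytest.warns(UserWarning, match="low"):
            cfg = ResamplingConfig(method="bootstrap", n_resamples=20, seed=9)
        r1 = wto_complete(independent_expr, res_cfg=cfg, threads=1)
        r4 = wto_complete(independent_expr, res_cfg=cfg, threads=4)
        pd.testing.assert_frame_equal(r1.wto, r4.wto)
        pd.testing.assert_frame_equal(r1.quantiles, r4.quantiles)

    def test_bootstrap_pvalues_floored_for_fisher(self, independent_expr):
        cfg = ResamplingConfig(method="bootstrap", n_resamples=100, seed=2)
        result = wto_complete(independent_expr, res_cfg=cfg)
        assert (result.wto["pval_sig"] > 0).all()
        assert (result.wto["padj_sig"] >= result.wto["pval_sig"] - 1e-12).all()

    def test_correlation_output_off_by_default(self, independent_expr):
        cfg = ResamplingConfig(n_resamples=0)
        assert wto_complete(independent_expr, res_cfg=cfg).correlation is None
        out = wto_complete(independent_expr, res_cfg=cfg, return_correlation=True)
        m = independent_expr.n_nodes
        assert len(out.correlation) == m * (m - 1) // 2


class TestResamplingConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="lag"):
            ResamplingConfig(method="block_bootstrap", lag=None)
        with pytest.raises(ValueError, match="delta"):
            ResamplingConfig(delta=0.0)
        with pytest.raises(ValueError, match="unknown resampling"):
            ResamplingConfig(method="jackknife")
        with pytest.raises(ValueError, match=">= 10"):
            ResamplingConfig(n_resamples=5)
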