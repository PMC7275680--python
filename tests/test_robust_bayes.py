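import numpy as np
import pytest

from fenclone.robust_bayes import (Priors, RegressionModel, Schedule,
                                   classify, ess, ess_multichain,
                                   gelman_rubin, hdi, mpv, pdist,
                                   run_all_regressions, sample_posterior,
                                   standardize, summarize_posterior)


class TestStandardize:
    def test_simple_case(self):
        assert standardize(np.array([1.0, 2.0, 3.0])) == \
            pytest.approx([-1.0, 0.0, 1.0])

    def test_moments_and_idempotence(self):
        v = np.random.default_rng(0).uniform(5, 50, 40)
        z = standardize(v)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12
        assert np.allclose(standardize(z), z, atol=1e-12)

    def test_constant_rejected_by_name(self):
        with pytest.raises(ValueError, match="potassium"):
            standardize(np.full(5, 3.0), name="potassium")


class TestHDI:
    def test_standard_normal(self):
        z = np.random.default_rng(1).standard_normal(10 ** 6)
        lo, hi = hdi(z, 0.90)
        assert lo == pytest.approx(-1.645, abs=0.01)
        assert hi == pytest.approx(1.645, abs=0.01)

    def test_constant_draws(self):
        assert hdi(np.full(500, 2.5), 0.90) == (2.5, 2.5)

    def test_skewed_interval_is_mode_anchored(self):
        e = np.random.default_rng(2).exponential(size=10 ** 5)
        lo, hi = hdi(e, 0.90)
        assert lo < np.quantile(e, 0.02)      # starts near the minimum
        assert hi < np.quantile(e, 0.97)      # and excludes the long tail

    def test_never_wider_than_equal_tailed(self):
        rng = np.random.default_rng(3)
        for draws in (rng.standard_normal(5000), rng.exponential(size=5000),
                      rng.beta(0.5, 2.0, 5000)):
            lo, hi = hdi(draws, 0.90)
            eq = np.quantile(draws, [0.05, 0.95])
            assert hi - lo <= eq[1] - eq[0] + 1e-12

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50.0), 0.9)


class TestPDist:
    def test_extremes_and_symmetry(self):
        assert pdist(np.ones(10)) == 100.0
        assert pdist(-np.ones(10)) == 0.0
        sym = np.concatenate([np.arange(1, 501), -np.arange(1, 501)])
        assert pdist(sym) == 50.0

    def test_normal_quantile(self):
        z = np.random.default_rng(4).standard_normal(10 ** 6) + 1.28
        assert pdist(z) == pytest.approx(90.0, abs=0.3)


class TestMPV:
    def test_known_mode(self):
        draws = 0.65 + 0.3 * np.random.default_rng(5).standard_normal(10 ** 5)
        assert mpv(draws) == pytest.approx(0.65, abs=0.03)

    def test_constant(self):
        assert mpv(np.full(200, 1.25)) == 1.25

    def test_bimodal_tie_breaks_low(self):
        rng = np.random.default_rng(6)
        draws = np.concatenate([rng.normal(-2, 0.1, 5000),
                                rng.normal(2, 0.1, 5000)])
        m = mpv(draws)
        assert m == pytest.approx(-2.0, abs=0.1) or \
            m == pytest.approx(2.0, abs=0.1)
        # deterministic given the draws
        assert mpv(draws) == m


class TestESSAndRhat:
    def test_iid_draws(self):
        # the truncated-autocorrelation estimator is noisy on any single
        # chain; its average over replicates is the accuracy that matters
        rng = np.random.default_rng(7)
        vals = [ess(rng.standard_normal(10000)) for _ in range(10)]
        assert np.mean(vals) == pytest.approx(10000, rel=0.10)

    def test_ar1_closed_form(self):
        rho, m = 0.9, 40000
        rng = np.random.default_rng(8)
        x = np.empty(m)
        x[0] = 0.0
        eps = rng.standard_normal(m)
        for i in range(1, m):
            x[i] = rho * x[i - 1] + eps[i]
        assert ess(x) == pytest.approx(m * (1 - rho) / (1 + rho), rel=0.20)

    def test_identical_chains_rhat_one(self):
        x = np.random.default_rng(9).standard_normal(2000)
        assert gelman_rubin(np.vstack([x, x])) == pytest.approx(1.0, abs=0.01)

    def test_single_chain_rhat_undefined(self):
        assert gelman_rubin(np.arange(100.0)[None, :]) is None

    def test_ess_cross_checked_against_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(10)
        x = rng.standard_normal(4000)
        for i in range(1, 4000):
            x[i] = 0.6 * x[i - 1] + x[i]
        ours = ess(x)
        theirs = float(arviz.ess(x[None, :]))
        assert ours == pytest.approx(theirs, rel=0.25)


class TestClassify:
    def test_truth_table_exhaustive(self):
        for lo in (-1.0, -0.1, 0.1):
            for hi in (0.2, 1.0):
                if hi <= lo:
                    continue
                for pd in (5.0, 50.0, 95.0):
                    got = classify(lo, hi, pd)
                    if lo > 0 or hi < 0:
                        assert got == "credible"
                    elif pd > 90 or pd < 10:
                        assert got == "trend"
                    else:
                        assert got == "none"

    def test_published_style_rows(self):
        assert classify(0.20, 1.14, 98.59) == "credible"
        assert classify(-0.02, 1.27, 93.59) == "trend"
        assert classify(-1.0, 1.0, 50.0) == "none"


class TestSampler:
    def test_parameter_recovery_large_n(self, fast_schedule):
        """With n=500 generated from the model, the posterior mode of the
        planted slope is recovered and agrees with least squares."""
        rng = np.random.default_rng(11)
        n = 500
        X = np.column_stack([standardize(rng.standard_normal(n))
                             for _ in range(3)])
        y = 0.8 * X[:, 0] + 0.3 * rng.standard_t(30, size=n)
        model = RegressionModel(standardize(y), X)
        chains = sample_posterior(model, fast_schedule, seed=12)
        scale = y.std(ddof=1)
        post_mode = mpv(chains.pooled("elevation"))
        assert post_mode == pytest.approx(0.8 / scale, abs=0.1)
        ols = np.linalg.lstsq(
            np.column_stack([np.ones(n), X]), standardize(y), rcond=None)[0]
        assert post_mode == pytest.approx(ols[1], abs=0.05)

    def test_null_slopes_covered(self, fast_schedule):
        """With no true effect, slope HDIs contain zero in nearly all
        replicates."""
        rng = np.random.default_rng(13)
        n, hits, reps = 200, 0, 20
        for _ in range(reps):
            X = np.column_stack([standardize(rng.standard_normal(n))
                                 for _ in range(3)])
            y = standardize(rng.standard_normal(n))
            chains = sample_posterior(RegressionModel(y, X), fast_schedule,
                                      seed=int(rng.integers(2 ** 31)))
            if all(hdi(chains.pooled(p))[0] <= 0 <= hdi(chains.pooled(p))[1]
                   for p in ("elevation", "P", "K")):
                hits += 1
        assert hits >= int(0.85 * reps)

    def test_prior_predictive_matches_normal_prior(self):
        """Without a data term the coefficient draws reproduce the
        Normal(0, sd 0.5) prior."""
        sched = Schedule(adapt=500, burnin=500, saved_total=20000,
                         ess_target=0.0)
        chains = sample_posterior(RegressionModel(None, None), sched, seed=42)
        for p in ("Intercept", "elevation", "P", "K"):
            draws = chains.pooled(p)
            assert abs(draws.std(ddof=1) - 0.5) < 0.02
            assert abs(draws.mean()) < 0.02

    def test_determinism(self, fast_schedule):
        rng = np.random.default_rng(14)
        X = np.column_stack([standardize(rng.standard_normal(16))
                             for _ in range(3)])
        y = standardize(rng.standard_normal(16))
        c1 = sample_posterior(RegressionModel(y, X), fast_schedule, seed=99)
        c2 = sample_posterior(RegressionModel(y, X), fast_schedule, seed=99)
        for p in c1.draws:
            assert np.array_equal(c1.draws[p], c2.draws[p])

    def test_ess_shortfall_warns_at_thin_cap(self):
        rng = np.random.default_rng(15)
        X = np.column_stack([standardize(rng.standard_normal(16))
                             for _ in range(3)])
        y = standardize(rng.standard_normal(16))
        sched = Schedule(adapt=100, burnin=100, saved_total=400,
                         ess_target=1e6, thin_cap=2)
        chains = sample_posterior(RegressionModel(y, X), sched, seed=0)
        assert chains.thin == 2
        assert any("ESS" in w for w in chains.warnings)


class TestRunAllRegressions:
    def test_one_summary_per_response(self, fast_schedule):
        from fenclone.datasets import carex_fen_diversity
        summaries = run_all_regressions(
            carex_fen_diversity(), None, seed=5, schedule=fast_schedule,
            responses=("G", "R", "He"))
        assert [s.response for s in summaries] == ["G", "R", "He"]
        for s in summaries:
            assert [r.parameter for r in s.rows] == \
                ["Intercept", "elevation", "P", "K", "scale", "normality"]
            for r in s.rows:
                assert r.hdi_low < r.hdi_high
                if r.pdist is not None:
                    assert 0 <= r.pdist <= 100
            for slope in ("elevation", "P", "K"):
                assert s.row(slope).credibility in ("credible", "trend", "none")
            assert s.row("scale").credibility is None

    def test_constant_response_skipped(self, fast_schedule):
        from fenclone.datasets import carex_fen_diversity
        div = carex_fen_diversity()
        for d in div:
            d.Ho = 0.5
        summaries = run_all_regressions(div, None, seed=5,
                                        schedule=fast_schedule,
                                        responses=("Ho", "He"))
        assert [s.response for s in summaries] == ["He"]

    def test_too_few_plots_rejected(self):
        from fenclone.datasets import carex_fen_diversity
        with pytest.raises(ValueError):
            run_all_regressions(carex_fen_diversity()[:4], None, seed=0)
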