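"""KDE, Bayes-rule initial scores, pretraining, density-only baseline."""

import numpy as np
import pytest
from scipy import stats

import cellscore as cs
from cellscore.density import DensityModel, ProductKDE, _fit_kde

# jitter-free configs: the closed-form oracles below assume every sample's
# healthy cells follow the pooled healthy density exactly
def _flat_cfg(**kw):
    base = dict(seed=5, n_pos=4, n_neg=4, cells_per_sample=(2000, 3000), jitter_sd=0.0)
    base.update(kw)
    return cs.standard_fixture_config(**base)


def _gauss_cohort(n=1000, seed=0):
    """1D cohort: one negative N(0,1) sample and one positive mixture sample."""
    rng = np.random.default_rng(seed)
    panel = cs.MarkerPanel.identity(["x"])
    neg = cs.SampleRecord(cs.EventMatrix("neg", rng.normal(size=(n, 1))), label=0, burden=0.0)
    n_p = int(0.3 * n)
    pos_vals = np.concatenate([rng.normal(size=n - n_p), rng.normal(5.0, 1.0, size=n_p)])
    pos = cs.SampleRecord(cs.EventMatrix("pos", pos_vals[:, None]), label=1, burden=0.3)
    return cs.Cohort(panel=panel, samples=[neg, pos])


class TestProductKDE:
    def test_gaussian_log_density_at_mode(self):
        # KDE on 1000 N(0,1) draws, Scott bandwidth: log f(0) ~ -0.5 ln(2 pi)
        cohort = _gauss_cohort(n=1000, seed=1)
        dm = cs.fit_density_model(cohort, seed=1)
        logf0 = dm.healthy_kde.logpdf(np.array([[0.0]]))[0]
        assert abs(logf0 - (-0.5 * np.log(2 * np.pi))) < 0.1

    def test_matches_scipy_kde_in_1d(self):
        # same kernel and Scott factor as scipy.stats.gaussian_kde in 1D
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        ours = ProductKDE(points=x[:, None],
                          bandwidths=np.array([x.std(ddof=1) * 500 ** (-1 / 5)]))
        ref = stats.gaussian_kde(x, bw_method="scott")
        grid = np.linspace(-3, 3, 41)
        np.testing.assert_allclose(ours.logpdf(grid[:, None]), ref.logpdf(grid),
                                   rtol=0, atol=5e-4)

    def test_leave_one_out_removes_self_mass(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        kde = _fit_kde(X, "scott", None, None, rng)
        plain = kde.logpdf(X)
        loo = kde.logpdf_loo()
        assert np.all(loo < plain)  # self kernel always adds mass

    def test_max_fit_cells_subsamples(self):
        rng = np.random.default_rng(4)
        kde = _fit_kde(rng.normal(size=(1000, 2)), "scott", None, 100, rng)
        assert kde.n_fit == 100

    def test_degenerate_channel_is_named(self):
        panel = cs.MarkerPanel.identity(["good", "flat"])
        rng = np.random.default_rng(5)
        vals = np.column_stack([rng.normal(size=50), np.ones(50)])
        neg = cs.SampleRecord(cs.EventMatrix("n", vals), label=0, burden=0.0)
        pos = cs.SampleRecord(cs.EventMatrix("p", vals + 0.0), label=1, burden=0.5)
        cohort = cs.Cohort(panel=panel, samples=[neg, pos])
        with pytest.raises(ValueError, match="flat"):
            cs.fit_density_model(cohort)

    def test_no_negatives_errors(self):
        cohort, _ = cs.generate_cohort(_flat_cfg(n_pos=2, n_neg=0))
        with pytest.raises(ValueError, match="negative"):
            cs.fit_density_model(cohort)


class TestBayesInitScores:
    def test_negative_samples_get_zero(self):
        cohort, _ = cs.generate_cohort(_flat_cfg())
        dm = cs.fit_density_model(cohort, seed=0)
        init = cs.bayes_init_scores(dm, cohort)
        for s in cohort.negatives():
            assert np.all(init.scores[s.sample_id] == 0.0)

    def test_density_ratio_one_gives_burden(self):
        # healthy and per-sample densities supplied as the same estimator,
        # evaluated at points that are not fit points: ratio exactly 1, so
        # s' = 1 - (1 - y) = y
        rng = np.random.default_rng(6)
        kde = ProductKDE(points=rng.normal(size=(500, 2)),
                         bandwidths=np.array([0.3, 0.3]), fit_indices=None)
        y = 0.3
        panel = cs.MarkerPanel.identity(["a", "b"])
        sample = cs.SampleRecord(cs.EventMatrix("p", rng.normal(size=(40, 2))), label=1, burden=y)
        neg = cs.SampleRecord(cs.EventMatrix("n", rng.normal(size=(40, 2))), label=0, burden=0.0)
        cohort = cs.Cohort(panel=panel, samples=[neg, sample])
        dm = DensityModel(healthy_kde=kde, per_sample_kde={"p": kde})
        init = cs.bayes_init_scores(dm, cohort, prior_mode="burden")
        np.testing.assert_allclose(init.scores["p"], y, atol=1e-6)

    def test_scores_always_in_unit_interval(self):
        cohort, _ = cs.generate_cohort(_flat_cfg())
        dm = cs.fit_density_model(cohort, seed=0)
        for mode, prior in (("burden", 0.9), ("fixed_prior", 0.5)):
            init = cs.bayes_init_scores(dm, cohort, prior_mode=mode, fixed_prior=prior)
            for v in init.scores.values():
                assert v.min() >= 0.0 and v.max() <= 1.0

    def test_monotone_in_prior(self):
        # holding densities fixed, s' is non-decreasing in the burden y
        cohort, _ = cs.generate_cohort(_flat_cfg(n_pos=1, n_neg=2))
        dm = cs.fit_density_model(cohort, seed=0)
        sid = cohort.positives()[0].sample_id
        ratio = dm.log_ratio(cohort.positives()[0])
        prev = None
        for y in (0.1, 0.3, 0.5, 0.8):
            s = np.clip(1.0 - np.exp(ratio + np.log1p(-y)), 0.0, 1.0)
            if prev is not None:
                assert np.all(s >= prev - 1e-12)
            prev = s

    def test_missing_burden_rejected(self):
        cohort, _ = cs.generate_cohort(_flat_cfg(n_pos=1, n_neg=1))
        pos = cohort.positives()[0]
        stripped = cs.SampleRecord(pos.events, label=1, burden=None)
        c2 = cs.Cohort(panel=cohort.panel, samples=[cohort.negatives()[0], stripped])
        dm = cs.fit_density_model(cohort, seed=0)
        with pytest.raises(ValueError, match="burden"):
            cs.bayes_init_scores(dm, c2, prior_mode="burden")

    def test_1d_mixture_matches_closed_form_posterior(self):
        # KDE-based s' vs the analytic posterior of the
        # 0.7 N(0,1) + 0.3 N(5,1) mixture, at a smaller fit size
        cohort = _gauss_cohort(n=20000, seed=7)
        dm = cs.fit_density_model(cohort, seed=7)
        grid = np.arange(-3.0, 8.0 + 1e-9, 0.05)[:, None]
        eval_sample = cs.SampleRecord(cs.EventMatrix("pos", grid), label=1, burden=0.3)
        eval_cohort = cs.Cohort(panel=cohort.panel, samples=[eval_sample])
        s_kde = cs.bayes_init_scores(dm, eval_cohort).scores["pos"]
        phi = stats.norm.pdf
        s_true = 1 - 0.7 * phi(grid[:, 0]) / (0.7 * phi(grid[:, 0]) + 0.3 * phi(grid[:, 0] - 5))
        assert np.mean(np.abs(s_kde - s_true)) < 0.05


class TestPretraining:
    def test_constant_zero_targets(self, small_cohort):
        cohort, _ = small_cohort
        init = cs.InitScores(scores={s.sample_id: np.zeros(s.events.n_cells) for s in cohort.samples})
        net, loss = cs.pretrain_scoring_net(init, cohort, cs.ScoringNetSpec(8),
                                            epochs=200, seed=0)
        for s in cohort.samples:
            assert net.score(s.events.values).max() < 0.05

    def test_fits_step_targets(self):
        rng = np.random.default_rng(8)
        panel = cs.MarkerPanel.identity(["x"])
        x = rng.uniform(-3, 5, size=(2000, 1))
        t = np.where(x[:, 0] < 0, 0.0, np.where(x[:, 0] > 2, 1.0, (x[:, 0]) / 2))
        sample = cs.SampleRecord(cs.EventMatrix("s", x), label=1, burden=0.5)
        cohort = cs.Cohort(panel=panel, samples=[sample])
        init = cs.InitScores(scores={"s": t})
        net, _ = cs.pretrain_scoring_net(init, cohort, cs.ScoringNetSpec(1),
                                         epochs=400, seed=0)
        assert np.mean(np.abs(net.score(x) - t)) < 0.1

    def test_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        dm = cs.fit_density_model(cohort, max_fit_cells=1000, seed=0)
        init = cs.bayes_init_scores(dm, cohort)
        nets = [cs.pretrain_scoring_net(init, cohort, cs.ScoringNetSpec(8),
                                        epochs=20, seed=3)[0] for _ in range(2)]
        for (W1, b1), (W2, b2) in zip(nets[0].params, nets[1].params):
            assert np.array_equal(W1, W2) and np.array_equal(b1, b2)


class TestDensityOnlyBaseline:
    def test_pure_healthy_sample_scores_low(self):
        cohort, _ = cs.generate_cohort(_flat_cfg())
        dm = cs.fit_density_model(cohort, seed=0)
        healthy_cfg = _flat_cfg(n_pos=0, n_neg=1, seed=99)
        healthy, _ = cs.generate_cohort(healthy_cfg)
        pred = cs.density_only_predict(dm, healthy.samples[0])
        assert pred < 0.1

    def test_recovers_burden_of_separated_sample(self):
        cohort, truth = cs.generate_cohort(_flat_cfg(seed=12))
        dm = cs.fit_density_model(cohort, seed=0)
        for s in cohort.positives()[:2]:
            pred = cs.density_only_predict(dm, s)
            assert abs(pred - truth.true_burden[s.sample_id]) < 0.1

    def test_deterministic(self):
        cohort, _ = cs.generate_cohort(_flat_cfg())
        dm = cs.fit_density_model(cohort, seed=0)
        s = cohort.positives()[0]
        assert cs.density_only_predict(dm, s) == cs.density_only_predict(dm, s)
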