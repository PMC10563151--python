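"""Scoring network, losses, training protocol and prediction."""

import numpy as np
import pytest

import cellscore as cs
from cellscore import _nn
from cellscore.model import sample_auroc


def _zero_output_net(input_dim=4, hidden=(8,)):
    """Network whose final layer is identically zero: every score = 0.5."""
    spec = cs.ScoringNetSpec(input_dim, hidden)
    rng = np.random.default_rng(0)
    params = _nn.init_params(spec.layer_sizes, rng)
    W, b = params[-1]
    params[-1] = (np.zeros_like(W), np.zeros_like(b))
    return cs.model.ScoringNet(spec, params)


class TestScoreCells:
    def test_zero_final_layer_scores_half(self):
        net = _zero_output_net()
        em = cs.EventMatrix("s", np.random.default_rng(1).normal(size=(20, 4)))
        np.testing.assert_array_equal(cs.score_cells(net, em), 0.5)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(2)
        spec = cs.ScoringNetSpec(4, (8,))
        net = cs.model.ScoringNet(spec, _nn.init_params(spec.layer_sizes, rng))
        X = rng.normal(size=(50, 4))
        perm = rng.permutation(50)
        np.testing.assert_allclose(net.score(X[perm]), net.score(X)[perm], rtol=1e-12)

    def test_matches_row_at_a_time_evaluation(self):
        rng = np.random.default_rng(3)
        spec = cs.ScoringNetSpec(3, (5, 4))
        net = cs.model.ScoringNet(spec, _nn.init_params(spec.layer_sizes, rng))
        X = rng.normal(size=(17, 3))
        batch = net.score(X)
        rowwise = np.array([net.score(x[None, :])[0] for x in X])
        np.testing.assert_allclose(batch, rowwise, rtol=1e-12)

    def test_dimension_mismatch(self):
        net = _zero_output_net(input_dim=4)
        with pytest.raises(ValueError, match="expected"):
            net.score(np.zeros((5, 3)))


class TestAggregate:
    def test_mean_semantics(self):
        assert cs.aggregate(np.array([0.0, 0.0, 1.0, 1.0])) == 0.5
        assert cs.aggregate(np.full(7, 0.31)) == pytest.approx(0.31)

    def test_matches_pairwise_summation_oracle(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(size=1000)

        def pairwise_sum(a):
            if len(a) == 1:
                return a[0]
            mid = len(a) // 2
            return pairwise_sum(a[:mid]) + pairwise_sum(a[mid:])

        assert cs.aggregate(v) == pytest.approx(pairwise_sum(v) / 1000, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.aggregate(np.array([]))


class TestLogisticProb:
    def test_flat_head_gives_half(self):
        head = cs.LogisticHead(0.0, 0.0)
        for sbar in (0.0, 0.3, 1.0):
            assert cs.logistic_prob(sbar, head) == 0.5

    def test_closed_forms(self):
        assert cs.logistic_prob(0.0, cs.LogisticHead(1.5, -3.0)) == pytest.approx(1 / (1 + np.exp(1.5)))
        assert cs.logistic_prob(0.5, cs.LogisticHead(0.0, -4.0)) == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-9)

    def test_overflow_safe(self):
        assert cs.logistic_prob(1.0, cs.LogisticHead(0.0, -5000.0)) == 1.0
        assert cs.logistic_prob(1.0, cs.LogisticHead(0.0, 5000.0)) == 0.0

    def test_orientation_follows_beta_sign(self):
        assert cs.LogisticHead(0.0, -2.0).orientation == 1
        assert cs.LogisticHead(0.0, 2.0).orientation == -1


class TestLosses:
    def test_reg_hand_arithmetic(self):
        # one positive (sbar 0.5, y 0.3), one negative (sbar 0.1), lambda 2:
        # (0.5-0.3)^2 + 2 * 0.1^2 = 0.06
        loss = cs.loss_reg(np.array([0.5, 0.1]), np.array([0.3, 0.0]), lam=2.0)
        assert loss == pytest.approx(0.06, abs=1e-12)

    def test_reg_zero_at_exact_predictions(self):
        loss = cs.loss_reg(np.array([0.3, 0.0, 0.0]), np.array([0.3, 0.0, 0.0]), lam=4.0)
        assert loss == 0.0

    def test_reg_lambda_scales_only_negative_term(self):
        s = np.array([0.5, 0.1])
        y = np.array([0.3, 0.0])
        l2, l4 = cs.loss_reg(s, y, 2.0), cs.loss_reg(s, y, 4.0)
        assert l4 - l2 == pytest.approx(2 * 0.1 ** 2, abs=1e-12)

    def test_reg_rejects_lambda_at_most_one(self):
        with pytest.raises(ValueError):
            cs.loss_reg(np.array([0.5]), np.array([0.3]), lam=1.0)
        with pytest.raises(ValueError):
            cs.TrainConfig(mode="reg", lam=0.5)

    def test_class_hand_arithmetic(self):
        # P = 0.5 for one positive and one negative at w=1: loss = 2 ln 2
        head = cs.LogisticHead(0.0, 0.0)
        loss = cs.loss_class(np.array([0.2, 0.8]), np.array([1, 0]), head, class_weight=1.0)
        assert loss == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_class_weight_scales_only_positive_term(self):
        head = cs.LogisticHead(0.3, -2.0)
        s = np.array([0.7, 0.2])
        y = np.array([1, 0])
        l1 = cs.loss_class(s, y, head, class_weight=1.0)
        l2 = cs.loss_class(s, y, head, class_weight=2.0)
        pos_term = -np.log(cs.logistic_prob(0.7, head))
        assert l2 - l1 == pytest.approx(pos_term, rel=1e-9)

    def test_class_clamps_confident_predictions(self):
        head = cs.LogisticHead(0.0, -10000.0)
        loss = cs.loss_class(np.array([1.0, 1.0]), np.array([1, 1]), head)
        assert np.isfinite(loss) and loss >= 0


@pytest.fixture(scope="module")
def tiny():
    cfg = cs.standard_fixture_config(seed=21, n_pos=4, n_neg=4,
                                     cells_per_sample=(300, 500))
    return cs.generate_cohort(cfg)[0]


@pytest.fixture(scope="module")
def search_cohort():
    cfg = cs.standard_fixture_config(seed=31, n_pos=6, n_neg=6,
                                     cells_per_sample=(200, 300))
    return cs.generate_cohort(cfg)[0]


class TestFit:
    def test_loss_decreases_early(self, tiny):
        cfg = cs.TrainConfig(mode="reg", epochs=30, n_restarts=1, seed=0,
                             use_density_init=False, cells_per_sample_cap=None)
        res = cs.fit(tiny, None, cs.ScoringNetSpec(8), cfg)
        hist = res.train_loss_history
        assert hist[10] < hist[0]

    def test_deterministic(self, tiny):
        cfg = cs.TrainConfig(mode="reg", epochs=15, n_restarts=1, seed=5,
                             use_density_init=False)
        a = cs.fit(tiny, None, cs.ScoringNetSpec(8), cfg)
        b = cs.fit(tiny, None, cs.ScoringNetSpec(8), cfg)
        assert a.train_loss_history == b.train_loss_history
        for (W1, _), (W2, _) in zip(a.net.params, b.net.params):
            assert np.array_equal(W1, W2)

    def test_selected_restart_attains_minimum(self, tiny):
        cfg = cs.TrainConfig(mode="reg", epochs=15, n_restarts=3, seed=1,
                             use_density_init=False)
        res = cs.fit(tiny, None, cs.ScoringNetSpec(8), cfg)
        assert res.restart_losses[res.selected_restart] == min(res.restart_losses)

    def test_reg_requires_burdens(self, tiny):
        stripped = cs.Cohort(
            panel=tiny.panel,
            samples=[cs.SampleRecord(s.events, label=s.label, burden=None) for s in tiny.samples],
        )
        cfg = cs.TrainConfig(mode="reg", epochs=5, n_restarts=1, use_density_init=False)
        with pytest.raises(ValueError, match="burden"):
            cs.fit(stripped, None, cs.ScoringNetSpec(8), cfg)


class TestPredictions:
    def test_flat_net_flat_head_probability_half(self, small_cohort):
        cohort, _ = small_cohort
        net = _zero_output_net(input_dim=8)
        fr = cs.FitResult(net=net, head=cs.LogisticHead(0.0, 0.0),
                          config=cs.TrainConfig(mode="class"),
                          train_loss_history=[], restart_losses=[0.0], selected_restart=0)
        preds = cs.predict(fr, cohort)
        assert all(p == 0.5 for p in preds.probability.values())

    def test_sbar_invariant_to_cell_order(self, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(9)
        spec = cs.ScoringNetSpec(8, (8,))
        net = cs.model.ScoringNet(spec, _nn.init_params(spec.layer_sizes, rng))
        fr = cs.FitResult(net=net, head=None, config=cs.TrainConfig(mode="reg"),
                          train_loss_history=[], restart_losses=[0.0], selected_restart=0)
        s = cohort.samples[0]
        shuffled = cs.Cohort(
            panel=cohort.panel,
            samples=[cs.SampleRecord(
                cs.EventMatrix(s.sample_id, s.events.values[rng.permutation(s.events.n_cells)]),
                label=s.label, burden=s.burden)],
        )
        a = cs.predict(fr, cohort.subset([s.sample_id])).sbar[s.sample_id]
        b = cs.predict(fr, shuffled).sbar[s.sample_id]
        assert a == pytest.approx(b, rel=1e-12)

    def test_auroc_matches_pairwise_concordance(self, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(10)
        spec = cs.ScoringNetSpec(8, (8,))
        net = cs.model.ScoringNet(spec, _nn.init_params(spec.layer_sizes, rng))
        fr = cs.FitResult(net=net, head=None, config=cs.TrainConfig(mode="reg"),
                          train_loss_history=[], restart_losses=[0.0], selected_restart=0)
        preds = cs.predict(fr, cohort)
        labels = cohort.labels
        stat = np.array([preds.sbar[i] for i in cohort.sample_ids])
        pos, neg = stat[labels == 1], stat[labels == 0]
        conc = np.mean([(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg])
        assert sample_auroc(preds, cohort) == pytest.approx(conc, abs=1e-12)

    def test_subsampling_stability_of_mean_score(self):
        # mean over a 50% subsample of 20000 cells concentrates within 0.02
        rng = np.random.default_rng(11)
        spec = cs.ScoringNetSpec(4, (8,))
        net = cs.model.ScoringNet(spec, _nn.init_params(spec.layer_sizes, rng))
        X = rng.normal(size=(20000, 4))
        full = cs.aggregate(net.score(X))
        devs = []
        for _ in range(40):
            idx = rng.choice(20000, size=10000, replace=False)
            devs.append(abs(cs.aggregate(net.score(X[idx])) - full))
        assert np.mean(np.array(devs) <= 0.02) >= 0.99


class TestHyperparameterSearch:
    def test_single_point_grid_returned(self, search_cohort):
        only = cs.TrainConfig(mode="reg", lam=3.0, epochs=10, n_restarts=1,
                              use_density_init=False)
        best, final, table = cs.hyperparameter_search(search_cohort, [only], n_folds=2, seed=0)
        assert best is only
        assert len(table) == 1

    def test_dominating_config_selected(self, search_cohort):
        sane = cs.TrainConfig(mode="reg", lam=3.0, lr=5e-3, epochs=25, n_restarts=1,
                              use_density_init=False)
        insane = cs.TrainConfig(mode="reg", lam=3.0, lr=1e3, epochs=25, n_restarts=1,
                                use_density_init=False)
        best, _, table = cs.hyperparameter_search(search_cohort, [insane, sane], n_folds=2, seed=0)
        assert best is sane

    def test_deterministic(self, search_cohort):
        grid = [cs.TrainConfig(mode="reg", lam=lam, epochs=8, n_restarts=1,
                               use_density_init=False) for lam in (2.0, 4.0)]
        out1 = cs.hyperparameter_search(search_cohort, grid, n_folds=2, seed=3)
        out2 = cs.hyperparameter_search(search_cohort, grid, n_folds=2, seed=3)
        assert [r["mean_val_auroc"] for r in out1[2]] == [r["mean_val_auroc"] for r in out2[2]]
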