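import numpy as np
import pandas as pd
import pytest

from traitlens.aggregator import AggregatorConfig
from traitlens.encoder import TinyEncoder
from traitlens.nn import Tensor
from traitlens.training import (
    FoldPlan,
    TargetScaler,
    TrainConfig,
    cf_train,
    evaluate,
    make_folds,
    summarize_report,
    train_aggregator,
    two_step_train,
)

from conftest import MICRO_WINDOW


class TestTargetScaler:
    def test_two_point_case(self):
        sc = TargetScaler.fit([90, 110], trait="O")
        assert (sc.mu, sc.sigma) == (100.0, 10.0)
        assert np.allclose(sc.transform([90, 110]), [-1.0, 1.0])

    def test_identity_scaler(self):
        sc = TargetScaler(trait="O", mu=0.0, sigma=1.0)
        y = np.linspace(-3, 3, 7)
        assert np.array_equal(sc.transform(y), y)

    def test_roundtrip_exact(self):
        rng = np.random.default_rng(0)
        sc = TargetScaler.fit(rng.uniform(0, 192, size=50))
        y = rng.uniform(0, 192, size=20)
        assert np.abs(sc.inverse(sc.transform(y)) - y).max() < 1e-12

    def test_degenerate_targets_rejected(self):
        with pytest.raises(ValueError):
            TargetScaler.fit([100.0, 100.0, 100.0])

    def test_population_standard_deviation(self):
        # ddof=0: sd of {0, 2} is 1, not sqrt(2)
        assert TargetScaler.fit([0.0, 2.0]).sigma == 1.0


class TestMakeFolds:
    def test_equal_disjoint_exhaustive_split(self):
        ids = [f"t{i}" for i in range(10)]
        plan = make_folds(ids, n_folds=5, val_fraction=0.0, seed=1)
        tests = [set(f["test"]) for f in plan.folds]
        assert all(len(t) == 2 for t in tests)
        assert set().union(*tests) == set(ids)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]

    def test_same_seed_reproduces_plan(self):
        ids = [f"t{i}" for i in range(23)]
        assert make_folds(ids, seed=7) == make_folds(ids, seed=7)

    def test_validation_drawn_from_training_portion_only(self):
        ids = [f"t{i}" for i in range(40)]
        plan = make_folds(ids, n_folds=4, val_fraction=0.1, seed=2)
        for fold in plan.folds:
            assert not set(fold["val"]) & set(fold["test"])
            assert not set(fold["train"]) & set(fold["test"])
            assert not set(fold["train"]) & set(fold["val"])
            assert len(fold["val"]) == 3  # 10% of the 30-transcript pool
        assert all(
            len(f["train"]) + len(f["val"]) + len(f["test"]) == 40 for f in plan.folds
        )

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], n_folds=5)


class TestEvaluate:
    def test_perfect_predictions(self):
        assert evaluate([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_constant_mean_predictor_scores_zero(self):
        y = np.array([0.0, 1.0, 2.0, 5.0])
        mse, r2 = evaluate(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_closed_form_negative_r2(self):
        mse, r2 = evaluate([0, 1, 2], [0, 0, 0])
        assert mse == pytest.approx(5 / 3)
        assert r2 == pytest.approx(-1.5)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1.0], [1.0])


class _WorseningModel:
    """Training pushes theta toward +1; the val target is -1, so validation
    MSE strictly worsens every epoch — exercising the patience semantics."""

    training = True

    def __init__(self):
        self.theta = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self):
        return [self.theta]

    def state_dict(self):
        return {"theta": self.theta.data.copy()}

    def load_state_dict(self, state):
        self.theta.data = state["theta"].copy()

    def train(self):
        self.training = True

    def eval(self):
        self.training = False

    def forward(self, x, mask):
        return (Tensor(np.zeros(len(x))) + self.theta[0]), Tensor(mask / mask.sum())


def _fake_set(targets):
    from traitlens.encoder import EmbeddingSequence

    seqs = []
    for i, y in enumerate(targets):
        seqs.append((EmbeddingSequence(f"t{i}", np.ones((2, 3)), np.ones(2, bool)), y))
    return seqs


class TestPatienceSemantics:
    def test_strictly_worsening_validation_stops_after_patience(self):
        model = _WorseningModel()
        cfg = TrainConfig(lr=0.05, max_epochs=50, patience=5, seed=0)
        hist = train_aggregator(model, _fake_set([1.0] * 8), _fake_set([-1.0] * 4), cfg)
        assert hist["epochs_run"] == 6  # best epoch 0, then patience 5
        assert hist["best_epoch"] == 0

    def test_best_checkpoint_restored(self):
        model = _WorseningModel()
        cfg = TrainConfig(lr=0.05, max_epochs=50, patience=3, seed=0)
        train_aggregator(model, _fake_set([1.0] * 8), _fake_set([-1.0] * 4), cfg)
        # restored to the best-validation state: the one after the first epoch
        assert 0 < model.theta.data[0] < 0.06


def _micro_train_setup(micro_corpus, seed=0):
    corpus, targets, _ = micro_corpus
    plan = make_folds([t.transcript_id for t in corpus], n_folds=2,
                      val_fraction=0.1, seed=seed)
    enc = TinyEncoder(vocab_size=61, embed_dim=8, n_heads=2, seed=seed)
    acfg = AggregatorConfig(variant="rnn", input_dim=8, hidden=6, layers=2, seed=seed)
    tcfg = TrainConfig(lr=5e-3, stage1_lr=5e-3, batch=8, max_epochs=3,
                       patience=5, seed=seed)
    return corpus, targets, plan, enc, acfg, tcfg


class TestTwoStepTrain:
    def test_run_is_reproducible_and_isolated(self, micro_corpus):
        rows = []
        for _ in range(2):
            corpus, targets, plan, enc, acfg, tcfg = _micro_train_setup(micro_corpus)
            res = two_step_train(corpus, targets, "O", enc, MICRO_WINDOW,
                                 acfg, tcfg, plan.folds[0])
            # frozen encoder untouched by stage 2
            assert res.model.encoder.checksum() == res.report_row["encoder_checksum_post_stage1"]
            assert res.report_row["variant"] == "2step-rnn"
            rows.append(res.report_row)
        assert rows[0]["mse"] == rows[1]["mse"]
        assert rows[0]["r2"] == rows[1]["r2"]

    def test_traits_are_independent_models(self, micro_corpus):
        corpus, targets, plan, enc, acfg, tcfg = _micro_train_setup(micro_corpus)
        res_a = two_step_train(corpus, targets, "O", enc, MICRO_WINDOW,
                               acfg, tcfg, plan.folds[0])
        corrupted = targets.copy()
        corrupted["N"] = 0.0  # destroying another trait's targets
        _, _, _, enc2, acfg2, tcfg2 = _micro_train_setup(micro_corpus)
        res_b = two_step_train(corpus, corrupted, "O", enc2, MICRO_WINDOW,
                               acfg2, tcfg2, plan.folds[0])
        assert res_a.report_row["mse"] == res_b.report_row["mse"]

    def test_missing_target_is_reported_by_id(self, micro_corpus):
        corpus, targets, plan, enc, acfg, tcfg = _micro_train_setup(micro_corpus)
        truncated = targets[targets["transcript_id"] != corpus[0].transcript_id]
        with pytest.raises(ValueError, match=corpus[0].transcript_id):
            two_step_train(corpus, truncated, "O", enc, MICRO_WINDOW,
                           acfg, tcfg, plan.folds[0])

    def test_leakage_guard_scaler_refit(self, micro_corpus):
        corpus, targets, plan, enc, acfg, tcfg = _micro_train_setup(micro_corpus)
        res = two_step_train(corpus, targets, "O", enc, MICRO_WINDOW,
                             acfg, tcfg, plan.folds[0])
        y = dict(zip(targets["transcript_id"], targets["O"].astype(float)))
        refit = TargetScaler.fit([y[tid] for tid in res.report_row["train_ids"]], "O")
        assert (refit.mu, refit.sigma) == (res.report_row["scaler_mu"],
                                           res.report_row["scaler_sigma"])


class TestCfTrain:
    def test_rejects_frozen_encoder(self, micro_corpus):
        corpus, targets, plan, enc, acfg, tcfg = _micro_train_setup(micro_corpus)
        with pytest.raises(ValueError):
            cf_train(corpus, targets, "O", enc.freeze(), MICRO_WINDOW,
                     acfg, tcfg, plan.folds[0])

    def test_gradients_reach_encoder_and_variant_label(self, micro_corpus):
        corpus, targets, plan, enc, acfg, tcfg = _micro_train_setup(micro_corpus)
        tcfg = TrainConfig(lr=5e-3, stage1_lr=5e-3, batch=8, max_epochs=1,
                           patience=5, seed=0)
        before = enc.checksum()
        res = cf_train(corpus, targets, "O", enc, MICRO_WINDOW, acfg, tcfg,
                       plan.folds[0])
        assert res.model.encoder.checksum() != before
        assert res.report_row["variant"] == "cf-rnn"


def test_summarize_report_shapes():
    rows = [
        {"trait": "O", "variant": "2step-rnn", "mse": m, "r2": r,
         "baseline_mse": m + 0.1, "baseline_r2": r - 0.1}
        for m, r in [(0.5, 0.5), (0.7, 0.3)]
    ]
    out = summarize_report(rows)
    assert out.loc[0, "mse_mean"] == pytest.approx(0.6)
    assert out.loc[0, "r2_std"] == pytest.approx(np.std([0.5, 0.3], ddof=1))
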