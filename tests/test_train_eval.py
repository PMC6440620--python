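import numpy as np
import pytest

from bhcnet.architectures import bhcnet_spec, build_network
from bhcnet.data import ChannelStats, SyntheticSpec, generate_synthetic_breakhis, load_arrays, split
from bhcnet.schedulers import ErfSchedule, ErfScheduleParams, StepSchedule, StepScheduleSpec, tabulate_schedule
from bhcnet.train_eval import (
    EvalReport,
    TrainConfig,
    confusion_matrix,
    cross_entropy,
    evaluate,
    format_mean_std,
    macro_precision_recall_f,
    make_manifest,
    mcc,
    nesterov_step,
    report_from_probs,
    train,
    train_repeats,
)


class TestNesterovStep:
    def test_zero_gradient_fixed_point(self):
        theta = [np.array([1.0, -2.0])]
        vel = [np.zeros(2)]
        nesterov_step(theta, vel, lambda t: (0.0, [np.zeros(2)]), lr=0.1, momentum=0.9)
        np.testing.assert_array_equal(theta[0], [1.0, -2.0])
        np.testing.assert_array_equal(vel[0], 0.0)

    def test_hand_computed_single_step(self):
        # quadratic loss L = theta^2 / 2; theta0=1, v0=0, m=0.9, lr=0.1
        theta = [np.array([1.0])]
        vel = [np.zeros(1)]

        def grad_fn(t):
            return float(t[0][0] ** 2 / 2), [t[0].copy()]

        loss = nesterov_step(theta, vel, grad_fn, lr=0.1, momentum=0.9)
        assert loss == pytest.approx(0.5)         # evaluated at interim point 1.0
        assert vel[0][0] == pytest.approx(-0.1)   # 0.9*0 - 0.1*1.0
        assert theta[0][0] == pytest.approx(0.9)  # 1.0 + (-0.1)

    def test_ten_step_formula_oracle(self):
        # 3-parameter quadratic; compare against an explicit recurrence
        A = np.array([1.0, 2.0, 0.5])
        theta = [np.array([1.0, -1.0, 2.0])]
        vel = [np.zeros(3)]
        m, lr, wd = 0.85, 0.05, 0.01

        def grad_fn(t):
            return float(0.5 * (A * t[0] ** 2).sum()), [A * t[0]]

        ref_theta = np.array([1.0, -1.0, 2.0])
        ref_v = np.zeros(3)
        for _ in range(10):
            interim = ref_theta + m * ref_v
            g = A * interim + wd * interim
            ref_v = m * ref_v - lr * g
            ref_theta = ref_theta + ref_v
            nesterov_step(theta, vel, grad_fn, lr=lr, momentum=m, weight_decay=wd)
        np.testing.assert_allclose(theta[0], ref_theta, atol=1e-10)
        np.testing.assert_allclose(vel[0], ref_v, atol=1e-10)

    def test_zero_momentum_is_plain_sgd(self):
        theta = [np.array([2.0])]
        vel = [np.zeros(1)]

        def grad_fn(t):
            return 1.0, [np.array([3.0])]

        nesterov_step(theta, vel, grad_fn, lr=0.1, momentum=0.0)
        assert theta[0][0] == pytest.approx(2.0 - 0.1 * 3.0)

    def test_nonfinite_loss_aborts(self):
        theta = [np.array([1.0])]
        vel = [np.zeros(1)]
        with pytest.raises(FloatingPointError):
            nesterov_step(theta, vel, lambda t: (float("nan"), [np.zeros(1)]),
                          lr=0.1, momentum=0.9)


class TestCrossEntropy:
    def test_uniform_logits(self):
        logits = np.zeros((4, 3))
        y = np.array([0, 1, 2, 0])
        loss, grad = cross_entropy(logits, y)
        assert loss == pytest.approx(np.log(3))
        np.testing.assert_allclose(grad.sum(axis=1), 0.0, atol=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(3, 4))
        y = np.array([1, 3, 0])
        _loss, grad = cross_entropy(logits, y)
        eps = 1e-6
        for i in range(3):
            for j in range(4):
                lp = logits.copy(); lp[i, j] += eps
                lm = logits.copy(); lm[i, j] -= eps
                num = (cross_entropy(lp, y)[0] - cross_entropy(lm, y)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestMetrics:
    def test_perfect_and_antiperfect_mcc(self):
        assert mcc(np.array([[10, 0], [0, 10]])) == pytest.approx(1.0)
        assert mcc(np.array([[0, 10], [10, 0]])) == pytest.approx(-1.0)

    def test_binary_mcc_frozen_value(self):
        # direct substitution into the TP/TN/FP/FN formula
        assert mcc(np.array([[6, 2], [1, 11]])) == pytest.approx(0.6847367880174606)

    def test_all_one_class_predictor_gives_zero(self):
        assert mcc(np.array([[50, 0], [50, 0]])) == 0.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            mcc(np.ones((2, 3)))

    def _definition_metrics(self, conf):
        """Independent from-definition computation."""
        k = conf.shape[0]
        precs, recs, fs = [], [], []
        for i in range(k):
            tp = conf[i, i]
            p = tp / conf[:, i].sum() if conf[:, i].sum() else 0.0
            r = tp / conf[i, :].sum() if conf[i, :].sum() else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
            precs.append(p); recs.append(r); fs.append(f)
        s = conf.sum(); c = np.trace(conf)
        t = conf.sum(axis=1).astype(float); p_ = conf.sum(axis=0).astype(float)
        num = c * s - t @ p_
        den = np.sqrt(s * s - p_ @ p_) * np.sqrt(s * s - t @ t)
        m = num / den if den else 0.0
        return np.mean(precs), np.mean(recs), np.mean(fs), m

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6, 7, 8])
    def test_macro_metrics_match_definition_oracle(self, k):
        rng = np.random.default_rng(k)
        for _ in range(30):
            conf = rng.integers(0, 40, size=(k, k))
            macro_p, macro_r, macro_f, _per = macro_precision_recall_f(conf)
            ep, er, ef, em = self._definition_metrics(conf)
            assert macro_p == pytest.approx(ep, abs=1e-12)
            assert macro_r == pytest.approx(er, abs=1e-12)
            assert macro_f == pytest.approx(ef, abs=1e-12)
            assert mcc(conf) == pytest.approx(em, abs=1e-12)

    def test_binary_mcc_agrees_with_generalized_form(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            conf = rng.integers(0, 30, size=(2, 2))
            _, _, _, em = self._definition_metrics(conf)
            assert mcc(conf) == pytest.approx(em, abs=1e-12)

    def test_confusion_matrix(self):
        conf = confusion_matrix([0, 1, 1, 0], [0, 1, 0, 0], 2)
        np.testing.assert_array_equal(conf, [[2, 0], [1, 1]])


class TestEvalReport:
    def test_perfect_predictions(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8], [0.95, 0.05], [0.1, 0.9]])
        y = np.array([0, 1, 0, 1])
        rep = report_from_probs(probs, y, class_names=["benign", "malignant"])
        assert rep.accuracy == 1.0
        assert rep.mcc == pytest.approx(1.0)
        assert rep.macro_f_measure == pytest.approx(1.0)
        assert rep.auc == pytest.approx(1.0)
        assert rep.confusion.sum() == 4

    def test_single_class_test_set_auc_unavailable(self):
        probs = np.array([[0.6, 0.4], [0.7, 0.3]])
        rep = report_from_probs(probs, np.array([0, 0]))
        assert rep.auc is None

    def test_multiclass_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        logits = rng.normal(size=(60, 4))
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        y = rng.integers(0, 4, size=60)
        rep = report_from_probs(probs, y)
        expect = roc_auc_score(y, probs, multi_class="ovr", average="macro",
                               labels=[0, 1, 2, 3])
        assert rep.auc == pytest.approx(expect)

    def test_json_roundtrip(self, tmp_path):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        rep = report_from_probs(probs, np.array([0, 1]))
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["accuracy"] == 1.0
        assert loaded["confusion"] == [[1, 0], [0, 1]]


class TestTrainLoop:
    def _toy_problem(self, n=40, size=8, seed=0):
        rng = np.random.default_rng(seed)
        # linearly separable two-class textures: bright vs dark images
        X0 = rng.normal(0.5, 0.1, size=(n // 2, 3, size, size))
        X1 = rng.normal(-0.5, 0.1, size=(n // 2, 3, size, size))
        X = np.concatenate([X0, X1])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_logged_lr_equals_schedule_table(self):
        X, y = self._toy_problem()
        model = build_network(bhcnet_spec(1, num_classes=2), seed=0)
        sched = ErfSchedule(ErfScheduleParams(0.05, 0.001, -3, 3, 5))
        cfg = TrainConfig(batch_size=10, epochs=5, seed=0)
        log = train(model, X, y, cfg, sched)
        table = dict(tabulate_schedule(sched, 5))
        assert [rec.lr for rec in log] == [table[e] for e in range(1, 6)]

    def test_step_schedule_contract(self):
        X, y = self._toy_problem(n=20)
        model = build_network(bhcnet_spec(1, num_classes=2), seed=0)
        sched = StepSchedule(StepScheduleSpec(0.05, ((2, 0.01),)), total_epochs=4)
        cfg = TrainConfig(batch_size=10, epochs=4, seed=0)
        log = train(model, X, y, cfg, sched)
        assert [rec.lr for rec in log] == [0.05, 0.05, 0.01, 0.01]

    def test_loss_decreases_on_separable_toy(self):
        X, y = self._toy_problem()
        model = build_network(bhcnet_spec(1, num_classes=2), seed=1)
        sched = ErfSchedule(ErfScheduleParams(0.05, 0.001, -3, 3, 5))
        cfg = TrainConfig(batch_size=10, epochs=5, seed=1)
        log = train(model, X, y, cfg, sched)
        assert log[-1].loss < log[0].loss

    def test_empty_training_set_rejected(self):
        model = build_network(bhcnet_spec(1, num_classes=2), seed=0)
        sched = ErfSchedule(ErfScheduleParams(0.05, 0.001, -3, 3, 5))
        with pytest.raises(ValueError):
            train(model, np.zeros((0, 3, 8, 8)), np.zeros(0, dtype=int),
                  TrainConfig(epochs=1), sched)

    def test_repeats_protocol(self):
        X, y = self._toy_problem(n=20)
        sched = ErfSchedule(ErfScheduleParams(0.05, 0.001, -3, 3, 2))
        cfg = TrainConfig(batch_size=10, epochs=2, seed=5, repeats=3)
        runs = train_repeats(
            lambda seed: build_network(bhcnet_spec(1, num_classes=2), seed=seed),
            X, y, cfg, sched,
        )
        assert len(runs) == 3
        # distinct seeds -> distinct final weights
        finals = [runs[i][0].params()[0].value.copy() for i in range(3)]
        assert not np.array_equal(finals[0], finals[1])
        summary = format_mean_std([run[1][-1].accuracy * 100 for run in runs])
        assert "±" in summary


def test_format_mean_std():
    assert format_mean_std([98.77, 98.87, 98.97]) == "98.87 ± 0.10"
    assert format_mean_std([50.0]) == "50.00 ± 0.00"


def test_make_manifest_contains_seeds_and_hash():
    cfg = TrainConfig(epochs=2)
    manifest = make_manifest(cfg, [1, 2, 3], extra={"arch": "bhcnet-1"})
    assert manifest["seeds"] == [1, 2, 3]
    assert len(manifest["config_hash"]) == 16
    assert manifest["arch"] == "bhcnet-1"
    assert manifest["version"]
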