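"""Nonlinear Hebbian weight updates, termination criteria, and training."""

import numpy as np
import pytest

from fcmgc import Concept, FCMModel, TransferFunction
from fcmgc.fcm_core import ConfigurationError, InputError
from fcmgc.nhl_training import (
    OutputTargetSpec,
    TrainingConfig,
    f1_criterion,
    f2_criterion,
    grid_search,
    nhl_update,
    target_midpoint,
    train,
)


def relaxed(eta, gamma, **kw):
    return TrainingConfig(eta=eta, gamma=gamma, strict=False, **kw)


class TestTargetMidpoint:
    @pytest.mark.parametrize(
        "t_min,t_max,mid", [(0, 1, 0.5), (0.66, 1, 0.83), (0.5, 0.5, 0.5)]
    )
    def test_midpoint(self, t_min, t_max, mid):
        assert target_midpoint(t_min, t_max) == pytest.approx(mid)

    def test_inverted_range_rejected(self):
        with pytest.raises(InputError):
            target_midpoint(0.8, 0.2)

    def test_spec_midpoint_property(self):
        spec = OutputTargetSpec("C28", 0.2, 0.6)
        assert spec.t_mid == pytest.approx(0.4)


class TestNhlUpdate:
    def test_hand_substitution_positive_weight(self):
        cfg = TrainingConfig(eta=0.045, gamma=0.98)
        # 0.98*0.5 + 0.045*0.6*(0.7 - 0.5*0.6)
        assert nhl_update(0.5, 0.6, 0.7, cfg) == pytest.approx(0.5008, abs=1e-12)

    def test_hand_substitution_negative_weight(self):
        cfg = TrainingConfig(eta=0.045, gamma=0.98)
        # sgn(w) = -1: 0.98*(-0.5) + 0.045*0.6*(0.7 - (-1)*(-0.5)*0.6)
        assert nhl_update(-0.5, 0.6, 0.7, cfg) == pytest.approx(-0.4792, abs=1e-12)

    def test_identity_limit(self):
        cfg = relaxed(eta=0.0, gamma=1.0)
        for w in (-0.8, -0.1, 0.3, 1.0):
            assert nhl_update(w, 0.4, 0.9, cfg) == w

    def test_result_clipped_to_unit_interval(self):
        cfg = relaxed(eta=0.09, gamma=1.0)
        assert nhl_update(1.0, 1.0, 1.0, cfg) <= 1.0

    def test_zero_weight_is_contract_violation(self):
        with pytest.raises(InputError):
            nhl_update(0.0, 0.5, 0.5, TrainingConfig())


class TestTerminationCriteria:
    def test_f1_zero_at_target(self):
        targets = [OutputTargetSpec("A", 0.4, 0.6)]
        assert f1_criterion([0.5], targets) == 0.0

    def test_f1_single_squared_difference(self):
        assert f1_criterion([0.6], [OutputTargetSpec("A", 0.0, 1.0)]) == pytest.approx(0.01)

    def test_f1_sums_over_outputs(self):
        targets = [OutputTargetSpec("A", 0.4, 0.6), OutputTargetSpec("B", 0.0, 0.6)]
        # diffs 0.1 and 0.2
        assert f1_criterion([0.6, 0.5], targets) == pytest.approx(0.05)

    def test_f2_true_for_identical_vectors(self):
        assert f2_criterion([0.3, 0.7], [0.3, 0.7], e=0.002)

    def test_f2_strict_at_threshold(self):
        # a change of exactly e does NOT terminate (strict <)
        assert not f2_criterion([0.502], [0.5], e=0.002)
        assert f2_criterion([0.5019], [0.5], e=0.002)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            f1_criterion([0.5], [])
        with pytest.raises(InputError):
            f2_criterion([0.5], [0.5, 0.6], e=0.002)


class TestTrainingConfigBounds:
    def test_best_pair_accepted(self):
        cfg = TrainingConfig(eta=0.045, gamma=0.98)
        assert (cfg.eta, cfg.gamma) == (0.045, 0.98)

    @pytest.mark.parametrize("eta", [0.0, 0.1, 0.5, -0.01])
    def test_eta_outside_open_interval_rejected(self, eta):
        with pytest.raises(ConfigurationError, match="eta"):
            TrainingConfig(eta=eta)

    @pytest.mark.parametrize("gamma", [0.9, 1.0, 0.5, 1.2])
    def test_gamma_outside_open_interval_rejected(self, gamma):
        with pytest.raises(ConfigurationError, match="gamma"):
            TrainingConfig(gamma=gamma)

    def test_relaxed_mode_admits_no_learning_limit(self):
        cfg = relaxed(eta=0.0, gamma=1.0)
        assert cfg.eta == 0.0 and cfg.gamma == 1.0


@pytest.fixture()
def toy_setup():
    """Two concepts A -> B, B output; one record; explicit targets."""
    model = FCMModel(
        concepts=(Concept("A", "a"), Concept("B", "b", role="output")),
        weights=np.array([[0.0, 0.5], [0.0, 0.0]]),
        transfer=TransferFunction(steepness=1.0),
        output_ids=("B",),
    )
    X = np.array([[1.0, 0.0]])
    targets = {"high": OutputTargetSpec("B", 0.6, 1.0)}
    return model, X, ["high"], targets


class TestTrain:
    def test_no_learning_limit_returns_expert_matrix(self, toy_setup):
        model, X, labels, targets = toy_setup
        cfg = relaxed(eta=0.0, gamma=1.0, max_epochs=5)
        result = train(model, X, labels, cfg, targets)
        assert np.array_equal(result.weights, model.weights)

    def test_two_iterations_match_hand_stepped_oracle(self, toy_setup):
        """Alternating state step and weight sweep, replayed for two
        iterations by independent scalar hand arithmetic."""
        model, X, labels, _ = toy_setup
        eta, gamma = 0.05, 0.95
        t_mid = 0.7  # target range [0.6, 0.8]
        targets = {"high": OutputTargetSpec("B", 0.6, 0.8)}

        def f(x):
            return 1 / (1 + np.exp(-x))

        # baseline pass (no learning), record (A, B) = (1, 0), w = 0.5:
        a1, b1 = f(1.0), f(0.5 * 1.0)
        a2, b2 = f(a1), f(b1 + 0.5 * a1)
        f1_baseline = (b2 - t_mid) ** 2
        # learning pass: sweep uses the pre-step activations of each iteration
        w1 = gamma * 0.5 + eta * 0.0 * (1.0 - 0.5 * 0.0)          # A=1, B=0
        w2 = gamma * w1 + eta * b1 * (a1 - w1 * b1)               # A=a1, B=b1
        # epoch F1 is evaluated under the snapshot w2 in an inference-only pass
        b1e = f(w2 * 1.0)
        b2e = f(b1e + w2 * f(1.0))
        f1_epoch1 = (b2e - t_mid) ** 2

        cfg = TrainingConfig(
            eta=eta, gamma=gamma, max_epochs=1, record_iter_cap=2,
            plateau_patience=10,
        )
        result = train(model, X, labels, cfg, targets)
        assert result.f1_trajectory == pytest.approx(
            (f1_baseline, f1_epoch1), abs=1e-12
        )
        # learning improves F1 here, so the returned matrix is epoch 1's
        assert f1_epoch1 < f1_baseline
        assert result.weights[0, 1] == pytest.approx(w2, abs=1e-12)
        assert result.epochs_run == 1
        assert result.terminated_by == "max_epochs"

    def test_zero_pattern_and_sign_preserved_over_50_epochs(self):
        rng = np.random.default_rng(11)
        n = 8
        concepts = tuple(
            Concept(f"N{i}", f"n{i}", role="output" if i == n - 1 else "input")
            for i in range(n)
        )
        w = rng.uniform(-1, 1, (n, n)) * (rng.random((n, n)) < 0.3)
        np.fill_diagonal(w, 0)
        model = FCMModel(concepts=concepts, weights=w, output_ids=(f"N{n-1}",))
        X = rng.random((12, n))
        labels = list(rng.choice(["low", "high"], size=12))
        targets = {
            "low": OutputTargetSpec(f"N{n-1}", 0.0, 0.5),
            "high": OutputTargetSpec(f"N{n-1}", 0.5, 1.0),
        }
        cfg = TrainingConfig(eta=0.045, gamma=0.98, max_epochs=50,
                             plateau_patience=10**6)
        result = train(model, X, labels, cfg, targets)
        assert np.array_equal(result.weights != 0, w != 0)
        assert np.array_equal(np.sign(result.weights), np.sign(w))
        assert np.all(np.abs(result.weights) <= 1)

    def test_empty_dataset_rejected(self, toy_setup):
        model, _, _, targets = toy_setup
        with pytest.raises(InputError):
            train(model, np.empty((0, 2)), [], TrainingConfig(), targets)

    def test_unknown_label_rejected(self, toy_setup):
        model, X, _, targets = toy_setup
        with pytest.raises(InputError, match="unknown|no output target"):
            train(model, X, ["mystery"], TrainingConfig(), targets)


class TestGridSearch:
    def test_single_cell_grid(self, toy_setup):
        model, X, labels, targets = toy_setup
        table = grid_search(
            model, X, labels, X, labels,
            etas=[0.045], gammas=[0.98],
            cfg=TrainingConfig(max_epochs=2),
            targets=targets,
        )
        assert len(table) == 1
        assert {"eta", "gamma", "confusion", "accuracy"} <= set(table.columns)
        assert 0 <= table["accuracy"].iloc[0] <= 100

    def test_out_of_bounds_values_rejected(self, toy_setup):
        model, X, labels, targets = toy_setup
        with pytest.raises(ConfigurationError, match="eta"):
            grid_search(
                model, X, labels, X, labels,
                etas=[0.5], gammas=[0.98],
                cfg=TrainingConfig(max_epochs=1),
                targets=targets,
            )

    def test_empty_grid_rejected(self, toy_setup):
        model, X, labels, targets = toy_setup
        with pytest.raises(InputError):
            grid_search(model, X, labels, X, labels, [], [0.98],
                        TrainingConfig(), targets)
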