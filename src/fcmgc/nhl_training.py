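"""Nonlinear Hebbian Learning (NHL) of FCM edge weights.

NHL refines the expert weight matrix from data without supervision of the
weights themselves: only edges the experts declared (nonzero entries) are
updated, and each update strengthens co-activation while a decay term pulls
the weight back. The per-edge recurrence for an edge ``j -> i`` is

.. math::

    \\omega_{ji}^{(k)} = \\gamma\\,\\omega_{ji}^{(k-1)}
        + \\eta\\,A_i^{(k-1)}\\big(A_j^{(k-1)}
        - \\mathrm{sgn}(\\omega_{ji})\\,\\omega_{ji}^{(k-1)} A_i^{(k-1)}\\big)

with learning rate ``eta`` (small, < 0.1) and weight decay ``gamma`` (close
to 1). Two termination functions monitor training: F1, the squared distance
of the output concepts from the midpoints of their class target ranges, and
F2, the max change of the output concepts between consecutive iterations,
which must fall below a threshold ``e`` (default 0.002, strict inequality).

Training iterates over labeled records: each record initializes the
activations, and state updates alternate with weight sweeps until F2 holds
or an iteration cap is reached. The returned matrix is the epoch snapshot
with the lowest F1 (including the initial expert matrix as the baseline
candidate), which operationalizes "stop once F1 is minimized".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fcm_core import ConfigurationError, FCMModel, InputError

#: weight magnitudes never shrink below this during training, so expert sign
#: judgments (and the nonzero pattern) are hard constraints
SIGN_FLOOR = 1e-6

__all__ = [
    "TrainingConfig",
    "OutputTargetSpec",
    "TrainingResult",
    "target_midpoint",
    "nhl_update",
    "f1_criterion",
    "f2_criterion",
    "train",
    "grid_search",
]


@dataclass(frozen=True)
class TrainingConfig:
    """NHL hyper-parameters.

    ``strict`` enforces the operating bounds 0 < eta < 0.1 and
    0.9 < gamma < 1 used for real runs; relaxing it admits the degenerate
    no-learning limit (eta=0, gamma=1), useful for contract checks.
    """

    eta: float = 0.045
    gamma: float = 0.98
    e: float = 0.002
    max_epochs: int = 50
    seed: int = 0
    record_iter_cap: int = 100
    plateau_patience: int = 3
    plateau_delta: float = 1e-6
    strict: bool = True

    def __post_init__(self) -> None:
        eta_ok = (0 < self.eta < 0.1) if self.strict else (0 <= self.eta < 0.1)
        if not eta_ok:
            raise ConfigurationError(
                f"learning rate eta={self.eta} outside accepted range (0, 0.1)"
            )
        gamma_ok = (0.9 < self.gamma < 1) if self.strict else (0 < self.gamma <= 1)
        if not gamma_ok:
            raise ConfigurationError(
                f"weight decay gamma={self.gamma} outside accepted range (0.9, 1)"
            )
        if not self.e > 0:
            raise ConfigurationError("termination threshold e must be positive")
        if self.max_epochs < 1 or self.record_iter_cap < 1:
            raise ConfigurationError("max_epochs and record_iter_cap must be >= 1")


def target_midpoint(t_min: float, t_max: float) -> float:
    """Midpoint T of an output-concept target range [t_min, t_max]."""
    if t_min > t_max:
        raise InputError(f"target range is inverted: [{t_min}, {t_max}]")
    return (t_min + t_max) / 2.0


@dataclass(frozen=True)
class OutputTargetSpec:
    """Desired steady-state range for one output concept (one risk class)."""

    oc_id: str
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_min <= self.t_max <= 1):
            raise InputError(
                f"target range [{self.t_min}, {self.t_max}] must satisfy "
                "0 <= t_min <= t_max <= 1"
            )

    @property
    def t_mid(self) -> float:
        return target_midpoint(self.t_min, self.t_max)


@dataclass(frozen=True)
class TrainingResult:
    weights: np.ndarray
    epochs_run: int
    f1_trajectory: tuple[float, ...]
    terminated_by: str  # "F1" | "F2" | "max_epochs"


def nhl_update(w: float, a_i: float, a_j: float, cfg: TrainingConfig) -> float:
    """One NHL update of a single nonzero weight (edge j -> i), clipped to [-1, 1].

    ``a_i`` is the target-concept activation, ``a_j`` the source-concept
    activation. Zero weights are outside the contract: only expert-declared
    edges are ever updated.
    """
    if w == 0:
        raise InputError("nhl_update applies only to nonzero (declared) edges")
    new = cfg.gamma * w + cfg.eta * a_i * (a_j - np.sign(w) * w * a_i)
    return float(np.clip(new, -1.0, 1.0))


def f1_criterion(
    oc_values: Sequence[float], targets: Sequence[OutputTargetSpec]
) -> float:
    """Sum of squared distances of output concepts from their target midpoints."""
    if len(oc_values) != len(targets):
        raise InputError("oc_values and targets must have the same length")
    return float(
        sum((oc - t.t_mid) ** 2 for oc, t in zip(oc_values, targets))
    )


def f2_criterion(
    oc_next: Sequence[float], oc_prev: Sequence[float], e: float
) -> bool:
    """True iff every output concept moved by strictly less than ``e``."""
    if len(oc_next) != len(oc_prev):
        raise InputError("consecutive OC vectors must have the same length")
    if not e > 0:
        raise InputError("e must be positive")
    diff = np.max(np.abs(np.asarray(oc_next, float) - np.asarray(oc_prev, float)))
    return bool(diff < e)


def _sweep(
    w: np.ndarray,
    a: np.ndarray,
    eta: float,
    gamma: float,
    mask: np.ndarray,
    sign0: np.ndarray,
) -> np.ndarray:
    """Vectorized NHL sweep over all declared edges.

    Applies the per-edge recurrence to every nonzero entry using the current
    activations ``a``, clips to [-1, 1], and floors magnitudes at
    ``SIGN_FLOOR`` on the expert side of zero so signs never flip and no
    entry ever becomes zero.
    """
    hebb = np.outer(a, a) - np.abs(w) * (a * a)[np.newaxis, :]
    new = gamma * w + eta * hebb
    new = np.where(
        sign0 > 0,
        np.clip(new, SIGN_FLOOR, 1.0),
        np.clip(new, -1.0, -SIGN_FLOOR),
    )
    return np.where(mask, new, 0.0)


def train(
    model: FCMModel,
    initial_states: np.ndarray,
    labels: Sequence[str],
    cfg: TrainingConfig,
    targets: Mapping[str, OutputTargetSpec],
) -> TrainingResult:
    """Train the weight matrix on a labeled cohort.

    ``initial_states`` has one encoded activation vector per record (shape
    (records, concepts)); ``labels[r]`` selects the record's class target
    spec. Per epoch, records are visited in a seed-shuffled order; for each
    record, one synchronous state step alternates with one weight sweep
    until F2 holds on the output concepts or the per-record cap is reached.
    An epoch's F1 is the mean squared OC-to-midpoint distance over records,
    evaluated under the epoch's final weight snapshot in a separate
    inference-only pass — so every F1 value (including the epoch-0 baseline,
    the untouched expert matrix) measures a single well-defined matrix.
    Training stops when F1 has not improved by more than ``plateau_delta``
    for ``plateau_patience`` consecutive epochs, when every record reaches
    F2 and the matrix itself has stabilized, or at ``max_epochs``; the
    snapshot with the lowest F1 is returned.
    """
    X = np.asarray(initial_states, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n:
        raise InputError("initial_states must have shape (records, n_concepts)")
    if X.shape[0] == 0:
        raise InputError("training dataset is empty")
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise InputError("labels and initial_states must have the same length")
    unknown = sorted(set(labels) - set(targets))
    if unknown:
        raise InputError(f"no output target spec for class labels {unknown}")
    oc_idx = model.output_indices
    for spec in targets.values():
        if spec.oc_id not in model.output_ids:
            raise InputError(
                f"target spec references non-output concept {spec.oc_id!r}"
            )

    w = model.weights.copy()
    mask = w != 0
    sign0 = np.sign(w)
    clamp = model.clamped_mask
    rng = np.random.default_rng(cfg.seed)
    t_mid = {lbl: spec.t_mid for lbl, spec in targets.items()}

    def record_pass(w_cur: np.ndarray, learn: bool):
        """One pass over all records; returns (w, mean F1, all reached F2)."""
        order = rng.permutation(X.shape[0]) if learn else np.arange(X.shape[0])
        f1_sum = 0.0
        all_f2 = True
        for r in order:
            a = X[r].copy()
            reached = False
            for _ in range(cfg.record_iter_cap):
                raw = model.transfer(a + a @ w_cur)
                a_next = np.where(clamp, a, raw)
                if learn:
                    w_cur = _sweep(w_cur, a, cfg.eta, cfg.gamma, mask, sign0)
                if f2_criterion(a_next[oc_idx], a[oc_idx], cfg.e):
                    a = a_next
                    reached = True
                    break
                a = a_next
            all_f2 &= reached
            f1_sum += float(np.sum((a[oc_idx] - t_mid[labels[r]]) ** 2))
        return w_cur, f1_sum / X.shape[0], all_f2

    # baseline: F1 of the untouched expert matrix
    _, f1_0, _ = record_pass(w, learn=False)
    f1_traj = [f1_0]
    best_f1, best_w = f1_0, w.copy()
    stall = 0
    terminated_by = "max_epochs"
    epochs_run = 0
    for _ in range(cfg.max_epochs):
        w_before = w.copy()
        w, _, all_f2 = record_pass(w, learn=True)
        _, f1, _ = record_pass(w, learn=False)
        epochs_run += 1
        f1_traj.append(f1)
        if f1 < best_f1 - cfg.plateau_delta:
            best_f1, best_w = f1, w.copy()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.plateau_patience:
                terminated_by = "F1"
                break
        if all_f2 and float(np.max(np.abs(w - w_before))) < cfg.e:
            terminated_by = "F2"
            break
    return TrainingResult(
        weights=best_w,
        epochs_run=epochs_run,
        f1_trajectory=tuple(f1_traj),
        terminated_by=terminated_by,
    )


def grid_search(
    model: FCMModel,
    train_states: np.ndarray,
    train_labels: Sequence[str],
    test_states: np.ndarray,
    test_labels: Sequence[str],
    etas: Sequence[float],
    gammas: Sequence[float],
    cfg: TrainingConfig,
    targets: Mapping[str, OutputTargetSpec],
    thresholds: tuple[float, float] = (1 / 3, 2 / 3),
    max_iter: int = 100,
) -> pd.DataFrame:
    """Train once per (eta, gamma) pair and score the held-out split.

    Returns one row per pair with the 3x3 confusion matrix (rows predicted,
    columns actual; order high, medium, low) and overall accuracy in percent.
    Every pair uses the same seed, so rows differ only in (eta, gamma).
    """
    from dataclasses import replace

    from .evaluation import accuracy, confusion
    from .fcm_core import run_batch
    from .gc_model import classify

    if len(etas) == 0 or len(gammas) == 0:
        raise InputError("eta and gamma grids must be non-empty")
    oc = model.output_indices[0]
    rows = []
    for eta in etas:
        for gamma in gammas:
            pair_cfg = replace(cfg, eta=eta, gamma=gamma)  # re-validates bounds
            result = train(model, train_states, train_labels, pair_cfg, targets)
            trained = model.with_weights(result.weights)
            final, _ = run_batch(trained, test_states, max_iter=max_iter, eps=cfg.e)
            predicted = [classify(v, thresholds) for v in final[:, oc]]
            m = confusion(predicted, list(test_labels))
            rows.append(
                {
                    "eta": eta,
                    "gamma": gamma,
                    "confusion": m.counts.tolist(),
                    "accuracy": accuracy(m),
                }
            )
    return pd.DataFrame(rows)
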