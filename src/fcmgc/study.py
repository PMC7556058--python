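"""End-to-end study protocol on synthetic cohorts.

The full pipeline the original study ran on its private 560-patient data,
reproduced here on synthetic cohorts: draw a cohort from the published
marginals, label it with the ground-truth map, split 70/30, perturb the
true weights (the "expert matrix" an elicitation would have produced),
retrain with NHL, and score the held-out records with the full metric
suite. All randomness derives from a single seed via independent child
streams (cohort, perturbation, shuffling, split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, confusion, metrics_report
from .fcm_core import run_batch
from .gc_model import GCModelBundle, default_bundle, encode_cohort
from .nhl_training import TrainingConfig, TrainingResult, train
from .synthetic_cohort import CohortConfig, MarginalTable, label_with_fcm, sample_cohort, split

__all__ = ["StudyOutcome", "perturb_weights", "run_study"]


@dataclass(frozen=True)
class StudyOutcome:
    """Everything the protocol produced, from cohort to held-out metrics."""

    cohort: pd.DataFrame
    train_set: pd.DataFrame
    test_set: pd.DataFrame
    initial_weights: np.ndarray
    training: TrainingResult
    report: MetricsReport


def perturb_weights(
    weights: np.ndarray, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Add uniform(-amplitude, +amplitude) noise to every nonzero weight.

    The zero pattern is preserved exactly; results are clipped to [-1, 1].
    Emulates the disagreement between an elicited expert matrix and the
    underlying truth.
    """
    w = weights.copy()
    mask = w != 0
    w[mask] = np.clip(w[mask] + rng.uniform(-amplitude, amplitude, mask.sum()), -1, 1)
    return w


def run_study(
    seed: int = 1,
    n: int = 560,
    bundle: GCModelBundle | None = None,
    perturbation: float = 0.2,
    eta: float = 0.045,
    gamma: float = 0.98,
    max_epochs: int = 20,
    split_fraction: float = 0.7,
    eps: float = 0.002,
) -> StudyOutcome:
    """Run the complete synthetic study once.

    ``bundle`` is the ground truth; training starts from its weights
    perturbed by ``perturbation`` (0 disables perturbation, i.e. training
    starts from the truth itself). Returns the held-out metric report along
    with every intermediate artifact.
    """
    if bundle is None:
        bundle = default_bundle()
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    cohort = sample_cohort(
        MarginalTable(bundle.features), CohortConfig(n=n, seed=int(seeds[0]))
    )
    labeled = label_with_fcm(cohort, bundle, eps=eps)
    train_set, test_set = split(
        labeled, fraction=split_fraction, seed=int(seeds[1]), stratified=False
    )

    rng = np.random.default_rng(int(seeds[2]))
    w0 = (
        perturb_weights(bundle.model.weights, perturbation, rng)
        if perturbation > 0
        else bundle.model.weights.copy()
    )
    start = bundle.model.with_weights(w0)

    cfg = TrainingConfig(
        eta=eta, gamma=gamma, e=eps, max_epochs=max_epochs, seed=int(seeds[3])
    )
    X_train = encode_cohort(train_set, bundle.features)
    result = train(start, X_train, train_set["risk_label"], cfg, bundle.targets())

    trained = bundle.with_weights(result.weights)
    X_test = encode_cohort(test_set, bundle.features)
    final, _ = run_batch(trained.model, X_test, eps=eps)
    oc = final[:, trained.model.output_indices[0]]
    from .gc_model import classify

    predicted = [classify(v, bundle.thresholds) for v in oc]
    actual = list(test_set["risk_label"])
    truth_final, _ = run_batch(bundle.model, X_test, eps=eps)
    truth_oc = truth_final[:, bundle.model.output_indices[0]]
    report = metrics_report(
        confusion(predicted, actual),
        real_ocs=truth_oc[:, None],
        predicted_ocs=oc[:, None],
    )
    return StudyOutcome(
        cohort=labeled,
        train_set=train_set,
        test_set=test_set,
        initial_weights=w0,
        training=result,
        report=report,
    )
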