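"""Synthetic patient cohorts matching the published marginal frequencies.

The study's 560-patient dataset is private, so every data-driven part of
this package is exercised on synthetic cohorts instead. Each feature is
drawn independently from its published per-level frequency (count / 560);
no between-factor correlation is modeled, because only marginals were ever
published. Risk labels are produced by running the ground-truth map on each
record, which gives a cohort whose labels are exactly consistent with a
known weight matrix — the setting needed for parameter-recovery studies.

Reported percentages are truncated, not rounded, which is the arithmetic
convention of the published tables (e.g. 85/560 -> 15.17).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .evaluation import truncate
from .fcm_core import ConfigurationError, InputError
from .gc_model import FeatureSpec, GCModelBundle, assess_cohort

__all__ = [
    "MarginalTable",
    "CohortConfig",
    "sample_cohort",
    "label_with_fcm",
    "split",
    "summarize",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class MarginalTable:
    """Per-feature level lists and probabilities."""

    features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        for f in self.features:
            if not f.counts:
                raise ConfigurationError(
                    f"feature {f.id} has no counts; cannot derive marginals"
                )
            if sum(f.counts) == 0:
                raise ConfigurationError(
                    f"feature {f.id} has only zero-probability levels"
                )

    def probabilities(self, feature: FeatureSpec) -> np.ndarray:
        p = np.asarray(feature.counts, dtype=float)
        return p / p.sum()


@dataclass(frozen=True)
class CohortConfig:
    n: int = 560
    seed: int = 0
    label_mode: str = "none"  # "none" | "ground_truth_fcm"
    split_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("cohort size n must be >= 1")
        if not (0 < self.split_fraction < 1):
            raise ConfigurationError("split_fraction must lie in (0, 1)")
        if self.label_mode not in ("none", "ground_truth_fcm"):
            raise ConfigurationError(f"unknown label_mode {self.label_mode!r}")


def sample_cohort(marginals: MarginalTable, cfg: CohortConfig) -> pd.DataFrame:
    """Draw ``cfg.n`` records, each feature independently from its marginal.

    Reproducible: the same config yields the identical cohort.
    """
    rng = np.random.default_rng(cfg.seed)
    data = {}
    for f in marginals.features:
        p = marginals.probabilities(f)
        data[f.id] = rng.choice(np.asarray(f.levels, dtype=object), size=cfg.n, p=p)
    return pd.DataFrame(data)


def label_with_fcm(
    cohort: pd.DataFrame,
    bundle: GCModelBundle,
    max_iter: int = 100,
    eps: float = 0.002,
) -> pd.DataFrame:
    """Attach deterministic ground-truth risk labels from the given bundle."""
    report = assess_cohort(cohort, bundle, max_iter=max_iter, eps=eps)
    labeled = cohort.copy()
    labeled["risk_label"] = report["risk_level"].to_numpy()
    return labeled


def split(
    dataset: pd.DataFrame,
    fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a cohort into train/test (disjoint, exhaustive).

    ``fraction`` is the train share: 560 records at 0.7 give exactly
    392 / 168. Stratified mode preserves the risk_label proportions to
    within one record per class (classes with a single member fall back to
    an unstratified split, with a warning).
    """
    if not (0 < fraction < 1):
        raise InputError("split fraction must lie in (0, 1)")
    stratify = None
    if stratified:
        if "risk_label" not in dataset.columns:
            raise InputError("stratified split requires a risk_label column")
        counts = dataset["risk_label"].value_counts()
        if (counts < 2).any():
            import warnings

            warnings.warn(
                "some classes have < 2 members; falling back to unstratified split",
                stacklevel=2,
            )
        else:
            stratify = dataset["risk_label"]
    train_df, test_df = train_test_split(
        dataset,
        train_size=fraction,
        random_state=seed,
        shuffle=True,
        stratify=stratify,
    )
    return train_df, test_df


def summarize(
    dataset: pd.DataFrame,
    features: Sequence[FeatureSpec] | None = None,
    dp: int = 2,
) -> pd.DataFrame:
    """Per-level counts and truncated percentages, one row per level.

    With a feature dictionary, every declared level appears (zero counts
    included) in dictionary order; otherwise observed levels are listed.
    """
    if len(dataset) == 0:
        raise InputError("cannot summarize an empty dataset")
    n = len(dataset)
    rows = []
    if features is not None:
        for f in features:
            col = f.id if f.id in dataset.columns else f.name
            vc = dataset[col].astype(str).value_counts()
            for lvl in f.levels:
                c = int(vc.get(lvl, 0))
                rows.append(
                    {
                        "feature": f.id,
                        "level": lvl,
                        "count": c,
                        "percent": truncate(100.0 * c / n, dp),
                    }
                )
    else:
        for col in dataset.columns:
            vc = dataset[col].astype(str).value_counts()
            for lvl, c in vc.items():
                rows.append(
                    {
                        "feature": col,
                        "level": lvl,
                        "count": int(c),
                        "percent": truncate(100.0 * int(c) / n, dp),
                    }
                )
    return pd.DataFrame(rows)


def write_cohort(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)
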