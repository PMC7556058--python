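"""The concrete 28-concept gastric-cancer risk map.

Bundles the 27-feature data dictionary, the default signed weight fixture
(38 edges), patient-record encoding, steady-state inference, and the
three-level risk classification. A patient record is one categorical level
per feature; :func:`encode` turns it into a 28-long activation vector
(features at their encoded level, the GC outcome concept at 0), the map is
run to a steady state with the feature concepts clamped as observed
boundary conditions, and the converged GC activation is cut into
low / medium / high by two thresholds.

The default thresholds were calibrated once so that, on a large synthetic
cohort drawn from the published marginal frequencies, the three classes
occur in the published risk-score proportions (low 13.2%, medium 33.2%,
high 53.6% of 560); they are configuration, not clinical cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fcm_core import (
    ActivationState,
    Concept,
    ConfigurationError,
    FCMModel,
    InputError,
    TransferFunction,
    run,
    run_batch,
)
from .nhl_training import OutputTargetSpec

RISK_LEVELS = ("low", "medium", "high")

GC_CONCEPT_ID = "C28"

#: bundle risk cutoffs on the converged GC activation, calibrated once on a
#: 10,000-record synthetic cohort (seed 12345) so the three classes occur in
#: the published risk-score proportions; they sit high because the mostly
#: positive edge mass saturates the sigmoid (see module docstring)
DEFAULT_THRESHOLDS = (0.9914, 0.9980)

#: lower edge of the low-risk training target range: the 0.5th percentile of
#: the outcome activation on the same calibration cohort. The raw low band
#: [0, t1] would put the class target midpoint far below any reachable
#: outcome value, which turns the F1 training monitor into a reward for
#: indiscriminate weight decay; clipping the band to the reachable span
#: keeps every class midpoint attainable.
DEFAULT_TARGET_FLOOR = 0.9351

__all__ = [
    "RISK_LEVELS",
    "GC_CONCEPT_ID",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_TARGET_FLOOR",
    "FeatureSpec",
    "GCModelBundle",
    "load_feature_dictionary",
    "default_bundle",
    "encode",
    "encode_cohort",
    "classify",
    "assess",
    "assess_cohort",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One risk factor: its levels in ascending-activation order."""

    id: str
    name: str
    category: str
    levels: tuple[str, ...]
    counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.levels) < 2:
            raise ConfigurationError(f"feature {self.id} needs >= 2 levels")
        if self.counts and len(self.counts) != len(self.levels):
            raise ConfigurationError(
                f"feature {self.id}: counts and levels differ in length"
            )

    @property
    def encoding(self) -> dict[str, float]:
        """Equally spaced activations {0, 1/(k-1), ..., 1} over the levels."""
        k = len(self.levels)
        return {lvl: i / (k - 1) for i, lvl in enumerate(self.levels)}

    def decode(self, activation: float) -> str:
        """Inverse of the encoding (nearest level)."""
        k = len(self.levels)
        return self.levels[int(round(activation * (k - 1)))]


def load_feature_dictionary(path=None) -> tuple[FeatureSpec, ...]:
    """Load the 27-feature dictionary (the packaged default, or a file)."""
    if path is None:
        text = (
            resources.files("fcmgc.data").joinpath("feature_dictionary.yaml")
        ).read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return tuple(
        FeatureSpec(
            id=f["id"],
            name=f["name"],
            category=f["category"],
            levels=tuple(f["levels"]),
            counts=tuple(f.get("counts", ())),
        )
        for f in raw["features"]
    )


def _load_default_edges() -> list[dict]:
    text = (resources.files("fcmgc.data").joinpath("default_edges.yaml")).read_text()
    return yaml.safe_load(text)["edges"]


@dataclass(frozen=True)
class GCModelBundle:
    """Everything needed to assess one patient: map, dictionary, cutoffs."""

    model: FCMModel
    features: tuple[FeatureSpec, ...]
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    target_floor: float = DEFAULT_TARGET_FLOOR

    def __post_init__(self) -> None:
        t1, t2 = self.thresholds
        if not (0 < t1 < t2 < 1):
            raise ConfigurationError(
                f"thresholds must satisfy 0 < t1 < t2 < 1, got {self.thresholds}"
            )
        if len(self.features) + 1 != self.model.n:
            raise ConfigurationError(
                "bundle model must have one concept per feature plus the outcome"
            )

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.features)

    def targets(self) -> dict[str, OutputTargetSpec]:
        """Per-class steady-state target ranges for NHL training.

        The classification bands double as the output-concept target
        ranges, with the low band clipped at ``target_floor`` so every
        class midpoint is attainable: low -> [floor, t1],
        medium -> [t1, t2], high -> [t2, 1].
        """
        t1, t2 = self.thresholds
        oc = self.model.output_ids[0]
        return {
            "low": OutputTargetSpec(oc, self.target_floor, t1),
            "medium": OutputTargetSpec(oc, t1, t2),
            "high": OutputTargetSpec(oc, t2, 1.0),
        }

    def with_weights(self, weights: np.ndarray) -> "GCModelBundle":
        return GCModelBundle(
            model=self.model.with_weights(weights),
            features=self.features,
            thresholds=self.thresholds,
            target_floor=self.target_floor,
        )


def default_bundle(
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    steepness: float = 1.0,
) -> GCModelBundle:
    """The shipped 28-concept / 38-edge gastric-cancer bundle.

    Feature concepts are clamped during inference: a patient's measured
    factors are boundary conditions, only the outcome (and nothing else)
    is being predicted.
    """
    features = load_feature_dictionary()
    concepts = tuple(
        Concept(id=f.id, name=f.name, category=f.category, role="input")
        for f in features
    ) + (
        Concept(
            id=GC_CONCEPT_ID, name="gastric_cancer", category="output", role="output"
        ),
    )
    ids = {c.id: k for k, c in enumerate(concepts)}
    w = np.zeros((len(concepts), len(concepts)))
    for e in _load_default_edges():
        w[ids[e["source"]], ids[e["target"]]] = float(e["weight"])
    model = FCMModel(
        concepts=concepts,
        weights=w,
        transfer=TransferFunction(steepness=steepness),
        output_ids=(GC_CONCEPT_ID,),
        clamped_ids=frozenset(f.id for f in features),
    )
    return GCModelBundle(model=model, features=features, thresholds=thresholds)


def encode(
    record: Mapping[str, str], features: Sequence[FeatureSpec]
) -> ActivationState:
    """Encode one patient record into a 28-long initial activation vector.

    Feature concepts take their encoded level; the outcome concept starts
    at 0. Unknown levels or missing features raise with the feature named.
    """
    values = np.zeros(len(features) + 1)
    for k, f in enumerate(features):
        if f.id in record:
            raw = record[f.id]
        elif f.name in record:
            raw = record[f.name]
        else:
            raise InputError(f"record is missing feature {f.id} ({f.name})")
        raw = str(raw)
        enc = f.encoding
        if raw not in enc:
            raise InputError(
                f"feature {f.id} ({f.name}): unknown level {raw!r}; "
                f"expected one of {list(f.levels)}"
            )
        values[k] = enc[raw]
    return ActivationState(values)


def encode_cohort(
    cohort: pd.DataFrame, features: Sequence[FeatureSpec]
) -> np.ndarray:
    """Encode a cohort table into an (records, concepts) activation array."""
    out = np.zeros((len(cohort), len(features) + 1))
    for k, f in enumerate(features):
        col = f.id if f.id in cohort.columns else f.name
        if col not in cohort.columns:
            raise InputError(f"cohort lacks a column for feature {f.id} ({f.name})")
        series = cohort[col].astype(str)
        mapped = series.map(f.encoding)
        if mapped.isna().any():
            bad = sorted(series[mapped.isna()].unique())
            raise InputError(
                f"feature {f.id} ({f.name}): unknown level(s) {bad}"
            )
        out[:, k] = mapped.to_numpy(dtype=float)
    return out


def classify(oc_value: float, thresholds: tuple[float, float] = (1 / 3, 2 / 3)) -> str:
    """Cut a converged outcome activation into low / medium / high.

    Bands are half-open, left-closed: low on [0, t1), medium on [t1, t2),
    high on [t2, 1].
    """
    t1, t2 = thresholds
    if not (0 < t1 < t2 < 1):
        raise InputError(f"thresholds must satisfy 0 < t1 < t2 < 1, got {thresholds}")
    if not (0 <= oc_value <= 1):
        raise InputError(f"output activation {oc_value} outside [0, 1]")
    if oc_value < t1:
        return "low"
    if oc_value < t2:
        return "medium"
    return "high"


def assess(
    record: Mapping[str, str],
    bundle: GCModelBundle,
    max_iter: int = 100,
    eps: float = 0.002,
) -> tuple[str, float, bool]:
    """Assess one patient: returns (risk level, GC activation, converged).

    Non-convergence within ``max_iter`` is reported through the flag; the
    last state is still classified.
    """
    state = encode(record, bundle.features)
    traj, converged = run(bundle.model, state, max_iter=max_iter, eps=eps)
    oc = float(traj[-1].values[bundle.model.output_indices[0]])
    return classify(oc, bundle.thresholds), oc, converged


def assess_cohort(
    cohort: pd.DataFrame,
    bundle: GCModelBundle,
    max_iter: int = 100,
    eps: float = 0.002,
) -> pd.DataFrame:
    """Vectorized :func:`assess` over a cohort table.

    Returns a frame with columns risk_level, oc_value, converged aligned
    with the input index.
    """
    states = encode_cohort(cohort, bundle.features)
    final, converged = run_batch(bundle.model, states, max_iter=max_iter, eps=eps)
    oc = final[:, bundle.model.output_indices[0]]
    return pd.DataFrame(
        {
            "risk_level": [classify(v, bundle.thresholds) for v in oc],
            "oc_value": oc,
            "converged": converged,
        },
        index=cohort.index,
    )
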