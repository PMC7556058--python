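"""Aggregation and defuzzification of expert linguistic causal weights.

Experts judge each causal link twice: first its direction (sign), then its
strength on a five-level linguistic scale (very low ... very high). Each
level is a triangular fuzzy membership function on the magnitude axis [0, 1].
Multiple experts' terms for the same edge are combined by the SUM technique —
unclipped pointwise addition of their membership curves — and the combined
curve is collapsed to a single magnitude by centroid defuzzification
(center of mass of the curve). The signed weight is the majority-vote sign
times that magnitude.

The default bank places the five triangle peaks at 0.1, 0.3, 0.5, 0.7, 0.9
with half-width 0.25; curves are evaluated on a fixed grid over [0, 1], so
the two extreme triangles are truncated at the domain boundary and their
centroids sit slightly inside their peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fcm_core import Concept, InputError

LEVELS = ("very_low", "low", "medium", "high", "very_high")

#: integration grid on the magnitude axis, step 1e-4
GRID = np.linspace(0.0, 1.0, 10001)

__all__ = [
    "LEVELS",
    "GRID",
    "MembershipFunction",
    "ExpertOpinion",
    "ConsensusError",
    "default_bank",
    "aggregate_sum",
    "defuzzify_centroid",
    "build_weight_matrix",
    "read_opinions",
]


class ConsensusError(InputError):
    """Experts are tied on the sign of an edge; no majority exists."""


@dataclass(frozen=True)
class MembershipFunction:
    """Triangular membership function with support [left, right], peak 1."""

    left: float
    peak: float
    right: float

    def __post_init__(self) -> None:
        if not self.left <= self.peak <= self.right:
            raise InputError("membership function requires left <= peak <= right")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            up = np.where(
                self.peak > self.left, (x - self.left) / (self.peak - self.left), 1.0
            )
            dn = np.where(
                self.right > self.peak, (self.right - x) / (self.right - self.peak), 1.0
            )
        return np.clip(np.minimum(up, dn), 0.0, None)


def default_bank(half_width: float = 0.25) -> dict[str, MembershipFunction]:
    """Five evenly spaced overlapping triangles peaked at 0.1 .. 0.9."""
    peaks = (0.1, 0.3, 0.5, 0.7, 0.9)
    return {
        lvl: MembershipFunction(p - half_width, p, p + half_width)
        for lvl, p in zip(LEVELS, peaks)
    }


@dataclass(frozen=True)
class ExpertOpinion:
    """One expert's judgment on one directed edge."""

    source: str
    target: str
    sign: int
    term: str
    expert: str

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise InputError(f"self-edge opinion on {self.source!r}")
        if self.sign not in (1, -1):
            raise InputError(f"sign must be +1 or -1, got {self.sign!r}")
        if self.term not in LEVELS:
            raise InputError(f"unknown linguistic term {self.term!r}")


def aggregate_sum(
    terms: Sequence[str],
    mfs: Mapping[str, MembershipFunction] | None = None,
    grid: np.ndarray = GRID,
    clip: bool = False,
) -> np.ndarray:
    """SUM-aggregate linguistic terms: pointwise sum of their curves.

    The sum is not renormalized — the centroid is scale-invariant, and
    clipping would discard information about how many experts agree. Pass
    ``clip=True`` for the bounded-sum (clip at 1) variant.
    """
    if len(terms) == 0:
        raise InputError("cannot aggregate an empty term list")
    bank = default_bank() if mfs is None else mfs
    curve = np.zeros_like(grid)
    for t in terms:
        if t not in bank:
            raise InputError(f"no membership function for term {t!r}")
        curve += bank[t](grid)
    return np.clip(curve, 0.0, 1.0) if clip else curve


def defuzzify_centroid(curve: np.ndarray, grid: np.ndarray = GRID) -> float:
    """Center of mass of a membership curve, by trapezoidal integration."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape != grid.shape:
        raise InputError("curve and grid must have the same shape")
    if np.any(curve < 0):
        raise InputError("membership curve must be non-negative")
    area = np.trapezoid(curve, grid)
    if area == 0:
        raise InputError("cannot defuzzify an identically-zero curve")
    return float(np.trapezoid(grid * curve, grid) / area)


def build_weight_matrix(
    opinions: Iterable[ExpertOpinion],
    concepts: Sequence[Concept],
    mfs: Mapping[str, MembershipFunction] | None = None,
    clip: bool = False,
) -> np.ndarray:
    """Turn a pool of expert opinions into a signed weight matrix.

    For every (source, target) pair with at least one opinion the magnitude
    is the centroid of the SUM of *all* experts' terms (magnitudes aggregate
    sign-free) and the sign is a strict majority vote; a tied vote raises
    :class:`ConsensusError` rather than guessing. Pairs nobody judged are 0.
    """
    index = {c.id: k for k, c in enumerate(concepts)}
    groups: dict[tuple[str, str], list[ExpertOpinion]] = {}
    seen: set[tuple[str, str, str]] = set()
    for op in opinions:
        for cid in (op.source, op.target):
            if cid not in index:
                raise InputError(f"opinion references unknown concept {cid!r}")
        key = (op.source, op.target, op.expert)
        if key in seen:
            raise InputError(
                f"duplicate opinion by expert {op.expert!r} on edge "
                f"{op.source}->{op.target}"
            )
        seen.add(key)
        groups.setdefault((op.source, op.target), []).append(op)

    w = np.zeros((len(index), len(index)))
    for (src, dst), ops in groups.items():
        vote = sum(op.sign for op in ops)
        if vote == 0:
            raise ConsensusError(
                f"tied sign vote on edge {src}->{dst}: "
                f"{[op.sign for op in ops]}"
            )
        magnitude = defuzzify_centroid(
            aggregate_sum([op.term for op in ops], mfs=mfs, clip=clip)
        )
        w[index[src], index[dst]] = float(np.sign(vote)) * magnitude
    return w


def read_opinions(path) -> list[ExpertOpinion]:
    """Read an expert-opinion table (CSV: source,target,sign,term,expert)."""
    df = pd.read_csv(path, dtype=str)
    required = {"source", "target", "sign", "term", "expert"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"opinion table lacks columns: {sorted(missing)}")
    return [
        ExpertOpinion(
            source=row.source,
            target=row.target,
            sign=int(row.sign),
            term=row.term,
            expert=row.expert,
        )
        for row in df.itertuples(index=False)
    ]
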