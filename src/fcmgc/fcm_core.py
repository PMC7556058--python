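"""Core fuzzy-cognitive-map (FCM) data model and synchronous inference.

An FCM is a signed directed graph of *concepts*. Each concept ``i`` carries an
activation :math:`A_i \\in [0, 1]`; each directed edge ``j -> i`` carries a
causal weight :math:`\\omega_{ji} \\in [-1, 1]`. The map evolves synchronously:

.. math::

    A_i^{(k+1)} = f\\Big(A_i^{(k)} + \\sum_{j \\ne i} \\omega_{ji} A_j^{(k)}\\Big)

where ``f`` is a strictly increasing transfer (squashing) function mapping the
reals into ``(0, 1)``; here the logistic sigmoid ``1 / (1 + exp(-lambda*x))``.
Concepts listed in ``clamped_ids`` are held at their initial value and act as
boundary conditions (observed inputs), while all other concepts — in
particular the designated output concepts — evolve freely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import yaml
from scipy.special import expit

CATEGORIES = (
    "personal",
    "diet_food",
    "systemic_condition",
    "stomach_condition",
    "output",
)

__all__ = [
    "Concept",
    "TransferFunction",
    "ActivationState",
    "FCMModel",
    "FCMError",
    "ConfigurationError",
    "InputError",
    "transfer",
    "step",
    "run",
]


class FCMError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(FCMError):
    """Invalid model or training configuration."""


class InputError(FCMError, ValueError):
    """Invalid data passed to an operation."""


@dataclass(frozen=True)
class Concept:
    """A node of the map: a risk factor or the assessed outcome."""

    id: str
    name: str
    category: str = "personal"
    role: str = "input"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigurationError(
                f"unknown category {self.category!r} for concept {self.id}"
            )
        if self.role not in ("input", "output"):
            raise ConfigurationError(f"role must be input|output, got {self.role!r}")


@dataclass(frozen=True)
class TransferFunction:
    """Logistic squashing function ``f(x) = 1 / (1 + exp(-steepness * x))``.

    ``steepness`` (often written lambda) controls how sharply net input is
    mapped into ``(0, 1)``; the value at 0 is always 0.5.
    """

    kind: str = "sigmoid"
    steepness: float = 1.0

    def __post_init__(self) -> None:
        if self.kind != "sigmoid":
            raise ConfigurationError(f"unsupported transfer kind {self.kind!r}")
        if not self.steepness > 0:
            raise ConfigurationError("transfer steepness must be positive")

    def __call__(self, x):
        return expit(self.steepness * np.asarray(x, dtype=float))


def transfer(x: float, fn: TransferFunction) -> float:
    """Evaluate the transfer function at ``x``; result lies in (0, 1)."""
    return float(fn(x))


@dataclass(frozen=True)
class ActivationState:
    """Concept activation vector at a given iteration."""

    values: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise InputError("activation state must be a 1-D vector")
        if np.any(v < 0) or np.any(v > 1):
            raise InputError("activations must lie in [0, 1]")


def _validate_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n, n):
        raise ConfigurationError(f"weight matrix must be {n}x{n}, got {w.shape}")
    if np.any(np.abs(w) > 1):
        raise ConfigurationError("edge weights must lie in [-1, 1]")
    if np.any(np.diag(w) != 0):
        raise ConfigurationError("self-influence weights (diagonal) must be zero")
    return w


@dataclass(frozen=True)
class FCMModel:
    """An FCM: ordered concepts, weight matrix, transfer, output concepts.

    ``weights[j, i]`` is the causal weight of the edge from concept ``j`` to
    concept ``i``. Diagonal entries are zero: a concept never feeds its own
    weighted term back (the bare ``A_i`` carry-over term in the update is not
    an edge).
    """

    concepts: tuple[Concept, ...]
    weights: np.ndarray
    transfer: TransferFunction = TransferFunction()
    output_ids: tuple[str, ...] = ()
    clamped_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        concepts = tuple(self.concepts)
        object.__setattr__(self, "concepts", concepts)
        ids = [c.id for c in concepts]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("concept ids must be unique")
        object.__setattr__(self, "weights", _validate_weights(self.weights, len(ids)))
        object.__setattr__(self, "output_ids", tuple(self.output_ids))
        object.__setattr__(self, "clamped_ids", frozenset(self.clamped_ids))
        if not self.output_ids:
            raise ConfigurationError("at least one output concept is required")
        known = set(ids)
        for oid in (*self.output_ids, *self.clamped_ids):
            if oid not in known:
                raise ConfigurationError(f"unknown concept id {oid!r}")

    # -- indexing helpers -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.concepts)

    def index(self, concept_id: str) -> int:
        for i, c in enumerate(self.concepts):
            if c.id == concept_id:
                return i
        raise InputError(f"unknown concept id {concept_id!r}")

    @property
    def output_indices(self) -> np.ndarray:
        return np.array([self.index(i) for i in self.output_ids], dtype=int)

    @property
    def clamped_mask(self) -> np.ndarray:
        mask = np.zeros(self.n, dtype=bool)
        for cid in self.clamped_ids:
            mask[self.index(cid)] = True
        return mask

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield (source id, target id, weight) for every nonzero entry."""
        ids = [c.id for c in self.concepts]
        src, dst = np.nonzero(self.weights)
        for j, i in zip(src, dst):
            yield ids[j], ids[i], float(self.weights[j, i])

    def with_weights(self, weights: np.ndarray) -> "FCMModel":
        return replace(self, weights=weights)

    # -- serialization ----------------------------------------------------

    def to_config(self) -> dict:
        return {
            "concepts": [
                {"id": c.id, "name": c.name, "category": c.category, "role": c.role}
                for c in self.concepts
            ],
            "edges": [
                {"source": s, "target": t, "weight": w} for s, t, w in self.edges()
            ],
            "transfer": {"kind": self.transfer.kind, "steepness": self.transfer.steepness},
            "output_ids": list(self.output_ids),
            "clamped_ids": sorted(self.clamped_ids),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "FCMModel":
        concepts = tuple(Concept(**c) for c in cfg["concepts"])
        ids = {c.id: k for k, c in enumerate(concepts)}
        w = np.zeros((len(concepts), len(concepts)))
        for e in cfg.get("edges", ()):
            j, i = ids[e["source"]], ids[e["target"]]
            if j == i:
                raise ConfigurationError(f"self-edge on {e['source']} is not allowed")
            w[j, i] = float(e["weight"])
        tr = cfg.get("transfer", {})
        return cls(
            concepts=concepts,
            weights=w,
            transfer=TransferFunction(
                kind=tr.get("kind", "sigmoid"), steepness=tr.get("steepness", 1.0)
            ),
            output_ids=tuple(cfg["output_ids"]),
            clamped_ids=frozenset(cfg.get("clamped_ids", ())),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "FCMModel":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


# -- inference -----------------------------------------------------------


def step(model: FCMModel, state: ActivationState) -> ActivationState:
    """One synchronous update of every (unclamped) concept.

    All concepts are computed from the previous state; clamped concepts keep
    their value.
    """
    a = state.values
    if a.shape != (model.n,):
        raise InputError(
            f"state has {a.shape[0]} values but model has {model.n} concepts"
        )
    new = np.asarray(model.transfer(a + a @ model.weights), dtype=float)
    mask = model.clamped_mask
    if mask.any():
        new = np.where(mask, a, new)
    return ActivationState(new, state.iteration + 1)


def run(
    model: FCMModel,
    initial: ActivationState,
    max_iter: int = 100,
    eps: float = 0.002,
) -> tuple[list[ActivationState], bool]:
    """Iterate :func:`step` to a steady state.

    Stops when the max-norm change of the full state falls below ``eps``
    (converged) or after ``max_iter`` steps. The returned trajectory includes
    the initial state.
    """
    if max_iter < 1:
        raise InputError("max_iter must be >= 1")
    if not eps > 0:
        raise InputError("eps must be positive")
    traj = [initial]
    state = initial
    for _ in range(max_iter):
        nxt = step(model, state)
        traj.append(nxt)
        if float(np.max(np.abs(nxt.values - state.values))) < eps:
            return traj, True
        state = nxt
    return traj, False


def run_batch(
    model: FCMModel,
    initial: np.ndarray,
    max_iter: int = 100,
    eps: float = 0.002,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized steady-state inference for many initial states at once.

    ``initial`` has shape (records, concepts). Returns the final states and a
    boolean convergence flag per record. Rows that converge early are frozen
    so results match per-record :func:`run` output.
    """
    a = np.array(initial, dtype=float)  # copy: rows are updated in place
    if a.ndim != 2 or a.shape[1] != model.n:
        raise InputError("initial must have shape (records, n_concepts)")
    mask = model.clamped_mask
    active = np.ones(a.shape[0], dtype=bool)
    converged = np.zeros(a.shape[0], dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        cur = a[active]
        new = np.asarray(model.transfer(cur + cur @ model.weights), dtype=float)
        if mask.any():
            new[:, mask] = cur[:, mask]
        done = np.max(np.abs(new - cur), axis=1) < eps
        a[active] = new
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False
    return a, converged
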