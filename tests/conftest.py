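import numpy as np
import pytest

from fcmgc import Concept, FCMModel, TransferFunction, default_bundle


@pytest.fixture(scope="session")
def bundle():
    """The shipped 28-concept gastric-cancer bundle."""
    return default_bundle()


@pytest.fixture()
def two_concept_model():
    """Minimal map: A -> B with weight 0.5, B designated as output."""
    concepts = (
        Concept("A", "a"),
        Concept("B", "b", role="output"),
    )
    w = np.array([[0.0, 0.5], [0.0, 0.0]])
    return FCMModel(
        concepts=concepts,
        weights=w,
        transfer=TransferFunction(steepness=1.0),
        output_ids=("B",),
    )


def random_model(rng: np.random.Generator, n: int = 6, density: float = 0.4):
    """A random small FCM with weights in [-1, 1] and zero diagonal."""
    concepts = tuple(Concept(f"N{i}", f"n{i}") for i in range(n))
    w = rng.uniform(-1, 1, (n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(w, 0.0)
    return FCMModel(
        concepts=concepts,
        weights=w,
        transfer=TransferFunction(steepness=float(rng.uniform(0.5, 3.0))),
        output_ids=("N0",),
    )
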