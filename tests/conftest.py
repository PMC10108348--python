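import numpy as np
import pytest

from fibrilight.records import manifold_from_pairs


def random_manifold(rng, n_states=2, hermitian=True, scale=2.0):
    """Random 2- or 3-state manifold with optional left/right asymmetry."""
    labels = ["S1", "S2"][: n_states - 1]
    energies = {"0": 0.0}
    for label, e in zip(labels, np.sort(rng.uniform(0.05, 0.4, n_states - 1))):
        energies[label] = float(e)
    states = ["0"] + labels
    pairs = [(a, b) for i, a in enumerate(states) for b in states[i + 1 :]]
    right = {p: rng.normal(0, scale, 3) for p in pairs}
    if hermitian:
        left = None
    else:
        left = {
            p: v * (1 + 0.2 * rng.standard_normal()) + 0.1 * rng.normal(0, scale, 3)
            for p, v in right.items()
        }
    state_dipoles = {s: rng.normal(0, scale, 3) for s in states}
    return manifold_from_pairs(energies, state_dipoles, right, left)


@pytest.fixture
def rng():
    return np.random.default_rng(20230404)
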