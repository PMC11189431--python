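"""Shared fixtures: small seeded dictionaries and patch pools."""

import numpy as np
import pytest

from v1sparse.dictionary_init import Atom, Dictionary, random_dictionary


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture(scope="session")
def orthonormal_basis_12():
    """A complete orthonormal 144-atom basis of the 12x12 patch space."""
    q, _ = np.linalg.qr(np.random.default_rng(7).standard_normal((144, 144)))
    atoms = [Atom(kernel=col.reshape(12, 12), label="random") for col in q.T]
    return Dictionary(atoms=atoms, frame_size=12)


@pytest.fixture(scope="session")
def small_random_dictionary():
    """An under-complete 30-atom dictionary on 6x6 frames."""
    return random_dictionary(30, 6, rng_seed=42)
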