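"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from abeta_ims import chem


@pytest.fixture(scope="session")
def abeta_composition():
    return chem.composition_from_sequence(chem.ABETA42_SEQUENCE)


@pytest.fixture(scope="session")
def drift_grid():
    return np.arange(4.0, 16.0, 0.05)


def enumerate_isotopologues(composition) -> dict[int, float]:
    """Exhaustive multinomial oracle: probability per nominal mass shift,
    by enumerating every per-atom isotope choice.  Only feasible for tiny
    compositions (<= ~10 atoms); deliberately independent of the
    convolution implementation."""
    from abeta_ims.elements import ISOTOPES

    atoms: list[list[tuple[int, float]]] = []
    for el, count in composition.items():
        isos = ISOTOPES[el]
        m0 = isos[0][0]
        choices = [(round(m - m0), a) for m, a in isos]
        atoms.extend([choices] * count)
    dist: dict[int, float] = {}
    for combo in itertools.product(*atoms):
        offset = sum(c[0] for c in combo)
        prob = 1.0
        for c in combo:
            prob *= c[1]
        dist[offset] = dist.get(offset, 0.0) + prob
    return dist
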