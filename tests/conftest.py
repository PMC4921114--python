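"""Shared fixtures: one noiseless helix study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from noefold.synth import (FixtureSpec, make_shift_table, make_structure,
                           make_talos_predictions, simulate_peaks)

HELIX_SEQUENCE = "AEKLLAKSIEQA"


@pytest.fixture(scope="session")
def helix_spec() -> FixtureSpec:
    return FixtureSpec(sequence=HELIX_SEQUENCE, topology="helix", seed=1,
                       noise_h=0.0, noise_heavy=0.0, intensity_noise=0.0)


@pytest.fixture(scope="session")
def helix_structure(helix_spec):
    return make_structure(helix_spec)


@pytest.fixture(scope="session")
def helix_shifts(helix_spec):
    return make_shift_table(helix_spec)


@pytest.fixture(scope="session")
def helix_peaks(helix_spec, helix_structure, helix_shifts):
    return [simulate_peaks(helix_structure, helix_shifts, helix_spec, kind)
            for kind in ("N15-NOESY", "C13-NOESY")]


@pytest.fixture(scope="session")
def helix_talos(helix_spec):
    return make_talos_predictions(helix_spec)


def backbone_coords(structure, n_residues: int) -> np.ndarray:
    return np.array([structure.position(i, a)
                     for i in range(1, n_residues + 1)
                     for a in ("N", "CA", "C")])
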