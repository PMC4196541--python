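"""Shared fixtures: grids, generator specs and cached synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest

from adaptbci.montage import ElectrodeGrid, default_montage, parse_derivation
from adaptbci.preprocessing import RejectionConfig, TrialTiming
from adaptbci.synthetic import GeneratorSpec, default_spec, generate_session


@pytest.fixture(scope="session")
def grid30() -> ElectrodeGrid:
    return default_montage()


@pytest.fixture()
def row4() -> ElectrodeGrid:
    """One coronal row of four adjacent electrodes."""
    return ElectrodeGrid.from_pairs([("A", 0, 0), ("B", 0, 1), ("C", 0, 2), ("D", 0, 3)])


@pytest.fixture(scope="session")
def small_grid() -> ElectrodeGrid:
    """Four electrodes forming the two derivations FCz-CPz and P1-P2."""
    return ElectrodeGrid.from_pairs(
        [("FCz", 2, 4), ("CPz", 4, 4), ("P1", 5, 3), ("P2", 5, 5)]
    )


def small_spec(seed: int = 0, **overrides) -> GeneratorSpec:
    """A fast two-class generator on the 4-electrode grid: ERD for Hand at
    FCz (10-13 Hz) and for Word at P1 (16-24 Hz)."""
    grid = ElectrodeGrid.from_pairs(
        [("FCz", 2, 4), ("CPz", 4, 4), ("P1", 5, 3), ("P2", 5, 5)]
    )
    defaults = dict(
        grid=grid,
        classes=("Hand", "Word"),
        runs=2,
        trials_per_class_per_run=7,
        effect_matrix={("Hand", "FCz", 1): -0.8, ("Word", "P1", 3): -0.7},
        rhythm_amplitudes={("FCz", 1): 8.0, ("P1", 3): 7.0},
        seed=seed,
    )
    defaults.update(overrides)
    return GeneratorSpec(**defaults)


@pytest.fixture(scope="session")
def strong_session():
    """The default strong-effect 200-trial session (seed 0) + ground truth."""
    return generate_session(default_spec(seed=0))


@pytest.fixture(scope="session")
def two_class_session():
    """A fast 28-trial two-class session on the small grid."""
    return generate_session(small_spec(seed=3))


@pytest.fixture()
def lenient_rejection() -> RejectionConfig:
    """Rejection that never fires: isolates scheduling logic from screening."""
    return RejectionConfig(amplitude_limit=1e9, z_limit=1e9)


@pytest.fixture(scope="session")
def small_derivs(small_grid):
    return (
        parse_derivation(small_grid, "FCz-CPz"),
        parse_derivation(small_grid, "P1-P2"),
    )


def reorder(session, order):
    """Session with trials rearranged into the given arrival order."""
    return session.subset(np.asarray(order, dtype=int))
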