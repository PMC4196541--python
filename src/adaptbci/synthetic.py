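"""Seeded generator of cue-paradigm EEG sessions with class-conditional ERD.

Each trial of each electrode is the sum of 1/f background noise, white
sensor noise, and narrowband oscillations (band-pass-filtered Gaussian
noise, so band-power estimates have realistic variance rather than the
zero-variance power of a pure sinusoid).  During the imagery period
[cue, trial end) a class-conditional effect scales each oscillation's
amplitude by ``sqrt(1 + effect)`` — band power changes by the ``effect``
fraction, negative values being event-related desynchronization (ERD) —
with a 250 ms raised-cosine ramp at cue onset to avoid spectral splatter.
Artifact trials additionally receive high-amplitude spikes at independent
times on every channel, which violate the ±100 μV amplitude rule by
construction.

Sessions follow the five-task cue paradigm: eight runs of 25 trials, five
per class per run, cue order random within each run; everything is
reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .features import DEFAULT_BANDS, bandpass_sos
from .montage import ElectrodeGrid, default_montage
from .preprocessing import EpochedSession, TrialTiming

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "default_spec",
    "generate_session",
    "generate_continuous",
    "make_cohort",
    "shuffle_labels",
    "DEFAULT_CLASSES",
]

DEFAULT_CLASSES: tuple[str, ...] = ("Feet", "Hand", "Word", "Math", "Nav")

#: Default class-conditional band-power effects: (class, electrode,
#: band index into ``bands``) -> fractional power change during imagery.
#: Band indices: 0: 8-10, 1: 10-13, 2: 13-16, 3: 16-24, 4: 24-30 Hz.
#: The template concentrates motor ERD near the vertex and left motor
#: cortex in the mu/low-beta bands and gives the non-motor tasks parietal
#: effects, so (Hand, Word) is the designed most-separable pair.  These are
#: free generator parameters chosen to mimic plausible session structure.
DEFAULT_EFFECTS: dict[tuple[str, str, int], float] = {
    ("Hand", "FCz", 1): -0.85,
    ("Hand", "C3", 1): -0.35,
    ("Feet", "FCz", 1): -0.50,
    ("Feet", "P1", 3): -0.35,
    ("Feet", "CPz", 2): -0.30,
    ("Word", "P1", 3): -0.78,
    ("Math", "FCz", 1): -0.50,
    ("Math", "P1", 3): -0.35,
    ("Math", "PO4", 3): -0.25,
    ("Math", "P2", 2): -0.25,
}

#: Baseline oscillation RMS amplitudes in μV per (electrode, band index).
DEFAULT_RHYTHMS: dict[tuple[str, int], float] = {
    ("FCz", 1): 8.0,
    ("C3", 1): 7.0,
    ("CPz", 2): 6.0,
    ("P1", 3): 7.0,
    ("PO4", 3): 5.0,
    ("P2", 2): 5.0,
    ("Cz", 1): 2.5,
    ("Pz", 1): 2.5,
}

#: Raised-cosine amplitude ramp length at cue onset, seconds.
RAMP_SECONDS = 0.25

# 1/f-shaping IIR (white -> pink), a standard 3-pole/3-zero approximation.
_PINK_B = (0.049922035, -0.095993537, 0.050612699, -0.004408786)
_PINK_A = (1.0, -2.494956002, 2.017265875, -0.522189400)


@dataclass
class GeneratorSpec:
    """Full parameterization of one synthetic session."""

    grid: ElectrodeGrid = field(default_factory=default_montage)
    timing: TrialTiming = TrialTiming()
    classes: tuple[str, ...] = DEFAULT_CLASSES
    runs: int = 8
    trials_per_class_per_run: int = 5
    bands: tuple = DEFAULT_BANDS
    effect_matrix: Mapping[tuple[str, str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    rhythm_amplitudes: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_RHYTHMS)
    )
    noise_sd: float = 2.0  # white sensor noise, μV
    pink_noise_scale: float = 5.0  # 1/f background RMS, μV
    artifact_rate: float = 0.0  # fraction of trials receiving spikes
    artifact_amplitude: float = 150.0  # μV
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")
        labels = set(self.grid.labels)
        nb = len(self.bands)
        for cls, elec, bi in self.effect_matrix:
            if cls not in self.classes:
                raise ValueError(f"effect for unknown class {cls!r}")
            if elec not in labels:
                raise ValueError(f"effect for unknown electrode {elec!r}")
            if not 0 <= bi < nb:
                raise ValueError(f"effect band index {bi} out of range")
        if any(v < -1 for v in self.effect_matrix.values()):
            raise ValueError("effects must be >= -1 (cannot remove more than all power)")
        for elec, bi in self.rhythm_amplitudes:
            if elec not in labels:
                raise ValueError(f"rhythm at unknown electrode {elec!r}")
            if not 0 <= bi < nb:
                raise ValueError(f"rhythm band index {bi} out of range")

    @property
    def trials_per_run(self) -> int:
        return len(self.classes) * self.trials_per_class_per_run

    @property
    def n_trials(self) -> int:
        return self.runs * self.trials_per_run


@dataclass
class GroundTruth:
    """Per-trial truth and the design targets tests verify against."""

    labels: np.ndarray
    artifact_flags: np.ndarray
    effect_matrix: dict
    designed_best_pair: tuple[str, str]


def pair_contrast(
    effect_matrix: Mapping[tuple[str, str, int], float],
    a: str,
    b: str,
) -> float:
    """Total log-power contrast between two classes over all effect cells."""
    cells = {(e, bi) for (cls, e, bi) in effect_matrix if cls in (a, b)}
    total = 0.0
    for e, bi in cells:
        ea = effect_matrix.get((a, e, bi), 0.0)
        eb = effect_matrix.get((b, e, bi), 0.0)
        total += abs(np.log1p(ea) - np.log1p(eb))
    return total


def designed_best_pair(spec: GeneratorSpec) -> tuple[str, str]:
    """argmax over class pairs of the effect-matrix contrast (ties:
    lexicographic pair order)."""
    best_pair, best = None, -1.0
    for p in combinations(sorted(spec.classes), 2):
        contrast = pair_contrast(spec.effect_matrix, *p)
        if contrast > best:  # strict: ties keep the lexicographically first
            best_pair, best = p, contrast
    return best_pair


def default_spec(seed: int = 0, **overrides) -> GeneratorSpec:
    """The packaged default session spec, optionally with field overrides."""
    return GeneratorSpec(seed=seed, **overrides)


def _cue_sequence(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    per_run = np.repeat(np.asarray(spec.classes, dtype=object), spec.trials_per_class_per_run)
    out = []
    for _ in range(spec.runs):
        out.append(rng.permutation(per_run))
    return np.concatenate(out)


def _envelope_gains(spec: GeneratorSpec, labels: np.ndarray, elec: str, bi: int) -> np.ndarray:
    """Per-trial imagery amplitude gain sqrt(1 + effect) for one cell."""
    gains = np.ones(len(labels))
    for t, lab in enumerate(labels):
        eff = spec.effect_matrix.get((str(lab), elec, bi), 0.0)
        gains[t] = np.sqrt(1.0 + eff)
    return gains


def _ramped_envelope(spec: GeneratorSpec, gains: np.ndarray) -> np.ndarray:
    """(trials, samples) amplitude envelope: 1 before cue, raised-cosine
    ramp to the trial's gain over RAMP_SECONDS, gain until trial end."""
    timing = spec.timing
    ns = timing.n_samples
    cue = timing.sample(timing.cue_onset)
    n_ramp = int(round(RAMP_SECONDS * timing.fs))
    shape = np.zeros(ns)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(1, n_ramp + 1) / n_ramp))
    shape[cue : cue + n_ramp] = ramp[: max(0, min(n_ramp, ns - cue))]
    shape[cue + n_ramp :] = 1.0
    return 1.0 + np.outer(gains - 1.0, shape)


def generate_session(spec: GeneratorSpec) -> tuple[EpochedSession, GroundTruth]:
    """Generate one epoched session plus its ground truth.

    Byte-identical output for identical specs (including the seed).
    """
    rng = np.random.default_rng(spec.seed)
    timing = spec.timing
    n, ne, ns = spec.n_trials, len(spec.grid), timing.n_samples
    labels = _cue_sequence(spec, rng)
    artifact_flags = rng.random(n) < spec.artifact_rate

    # 1/f background: shape white noise with the pink filter, then set RMS.
    pink = sps.lfilter(_PINK_B, _PINK_A, rng.standard_normal((n, ne, ns)), axis=-1)
    pink *= spec.pink_noise_scale / max(pink.std(), 1e-30)
    epochs = pink
    epochs += rng.standard_normal((n, ne, ns)) * spec.noise_sd

    # narrowband rhythms with class-conditional imagery gains
    pad = int(round(timing.fs))  # 1 s pre-roll swallows the filter transient
    elec_index = {lab: i for i, lab in enumerate(spec.grid.labels)}
    for (elec, bi), amp in sorted(spec.rhythm_amplitudes.items()):
        if amp <= 0:
            continue
        sos = bandpass_sos(spec.bands[bi], timing.fs)
        carrier = sps.sosfilt(sos, rng.standard_normal((n, ns + pad)), axis=-1)[:, pad:]
        carrier *= amp / max(carrier.std(), 1e-30)
        gains = _envelope_gains(spec, labels, elec, bi)
        if np.any(gains != 1.0):
            carrier *= _ramped_envelope(spec, gains)
        epochs[:, elec_index[elec], :] += carrier

    # artifact spikes: independent times per channel so no bipolar
    # derivation can cancel them
    for t in np.flatnonzero(artifact_flags):
        pos = rng.integers(0, ns, size=(ne, 4))
        signs = np.where((np.arange(4) % 2) == 0, 1.0, -1.0)
        for c in range(ne):
            epochs[t, c, pos[c]] += signs * spec.artifact_amplitude

    session = EpochedSession(
        epochs=epochs,
        labels=labels,
        timing=timing,
        channel_labels=list(spec.grid.labels),
    )
    truth = GroundTruth(
        labels=labels.copy(),
        artifact_flags=artifact_flags,
        effect_matrix=dict(spec.effect_matrix),
        designed_best_pair=designed_best_pair(spec),
    )
    return session, truth


def generate_continuous(
    spec: GeneratorSpec, inter_trial_seconds: float = 1.0
) -> tuple[np.ndarray, list[tuple[float, str]], GroundTruth]:
    """A continuous recording with an event list, for the epoching pipeline.

    Trials are laid back-to-back separated by ``inter_trial_seconds`` of
    white noise; events mark each cue onset.
    """
    session, truth = generate_session(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xC0)))
    timing = spec.timing
    gap = int(round(inter_trial_seconds * timing.fs))
    n, ne, ns = session.epochs.shape
    total = n * (ns + gap) + gap
    continuous = rng.standard_normal((ne, total)) * spec.noise_sd
    events = []
    for t in range(n):
        start = gap + t * (ns + gap)
        continuous[:, start : start + ns] = session.epochs[t]
        events.append((start / timing.fs + timing.cue_onset, str(session.labels[t])))
    return continuous, events, truth


def make_cohort(
    base_spec: GeneratorSpec,
    n_subjects: int,
    inter_subject_sd: float,
    seed: int,
) -> list[GeneratorSpec]:
    """Jitter the effect matrix to emulate between-subject variability.

    Each subject's effect magnitudes are multiplied by independent
    lognormal factors with unit mean (``exp(N(-sd²/2, sd))``), clipped so
    no effect falls below -0.95; subjects get fresh session seeds derived
    from ``seed``.  Deterministic.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects >= 1 required")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_subjects):
        effects = {}
        for key, eff in sorted(base_spec.effect_matrix.items()):
            j = (
                np.exp(rng.normal(-(inter_subject_sd**2) / 2, inter_subject_sd))
                if inter_subject_sd > 0
                else 1.0
            )
            effects[key] = float(np.clip(eff * j, -0.95, None))
        specs.append(
            dataclasses.replace(
                base_spec,
                effect_matrix=effects,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def shuffle_labels(session: EpochedSession, seed: int) -> EpochedSession:
    """A copy of the session with randomly permuted class labels (null
    control: any decodable class structure is destroyed)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(session.n_trials)
    return EpochedSession(
        epochs=session.epochs,
        labels=np.asarray(session.labels)[perm],
        timing=session.timing,
        channel_labels=list(session.channel_labels),
    )
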