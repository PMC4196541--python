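"""Epoch extraction and trial-based outlier rejection.

Rejection runs in three phases, in order:

1. **amplitude** — any sample beyond ±``amplitude_limit`` μV rejects the trial;
2. **statistical** — per-channel trial kurtosis and mean log empirical
   probability (histogram density over the pooled samples of that channel),
   z-scored across trials; a trial beyond ``z_limit`` SD on any channel and
   either measure is rejected;
3. **band power** — per-trial mean log band power in every feature band,
   iteratively trimmed at ``z_limit`` SD until a pass rejects nothing.

Phases 2-3 run separately on the relax segment (pooled over classes) and
the analysed imagery segment (one group per class).  Rejection only sets
flags; signal values are never modified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .features import DEFAULT_BANDS, POWER_FLOOR, as_bands, bandpass_sos

logger = logging.getLogger(__name__)

__all__ = [
    "TrialTiming",
    "EpochedSession",
    "RejectionConfig",
    "extract_epochs",
    "reject_amplitude",
    "reject_statistical",
    "reject_bandpower_iterative",
    "run_outlier_pipeline",
]


@dataclass(frozen=True)
class TrialTiming:
    """Cue-paradigm trial timing in seconds (epoch time 0 = relax start).

    Defaults follow the Graz-style paradigm: 3 s relax, visual cue at 3 s,
    sustained mental task until 10 s; the analysed imagery window ends at
    8 s.
    """

    relax_start: float = 0.0
    relax_end: float = 3.0
    cue_onset: float = 3.0
    imagery_end_analysis: float = 8.0
    trial_end: float = 10.0
    fs: float = 256.0

    def __post_init__(self) -> None:
        ok = (
            self.relax_start
            < self.relax_end
            <= self.cue_onset
            < self.imagery_end_analysis
            <= self.trial_end
        )
        if not ok:
            raise ValueError(f"inconsistent trial timing {self}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_end * self.fs))

    def sample(self, t: float) -> int:
        return int(round(t * self.fs))

    def segment(self, name: str) -> slice:
        """Sample slice of the 'relax' or 'imagery' rejection segment."""
        if name == "relax":
            return slice(self.sample(self.relax_start), self.sample(self.relax_end))
        if name == "imagery":
            return slice(self.sample(self.cue_onset), self.sample(self.imagery_end_analysis))
        raise ValueError(f"unknown segment {name!r}")


@dataclass
class EpochedSession:
    """Per-trial EEG segments with labels, timing and artifact bookkeeping."""

    epochs: np.ndarray  # (trials, channels, samples), μV
    labels: np.ndarray  # (trials,) class names
    timing: TrialTiming
    channel_labels: list[str]
    artifact_flags: np.ndarray = None  # (trials,) bool
    rejection_log: list = None  # per trial: list of (phase, reason)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (trials, channels, samples)")
        if self.labels.shape[0] != self.epochs.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels length must equal channel count")
        if self.epochs.shape[2] != self.timing.n_samples:
            raise ValueError(
                f"expected {self.timing.n_samples} samples per trial, "
                f"got {self.epochs.shape[2]}"
            )
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.n_trials, dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.rejection_log is None:
            self.rejection_log = [[] for _ in range(self.n_trials)]

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def classes(self) -> list[str]:
        return sorted(np.unique(self.labels).tolist())

    def subset(self, mask: np.ndarray) -> "EpochedSession":
        mask = np.asarray(mask)
        return EpochedSession(
            epochs=self.epochs[mask],
            labels=self.labels[mask],
            timing=self.timing,
            channel_labels=list(self.channel_labels),
            artifact_flags=self.artifact_flags[mask],
            rejection_log=[list(self.rejection_log[i]) for i in np.flatnonzero(mask)]
            if mask.dtype == bool
            else [list(self.rejection_log[i]) for i in mask],
        )

    def clean(self) -> "EpochedSession":
        """Artifact-free trials only."""
        return self.subset(~self.artifact_flags)


@dataclass(frozen=True)
class RejectionConfig:
    """Thresholds of the three-phase outlier rejection."""

    amplitude_limit: float = 100.0  # μV
    z_limit: float = 3.5  # SD multiples for kurtosis/probability/band power
    bands: tuple = DEFAULT_BANDS
    max_iterations: int = 20
    n_bins: int = 100  # histogram bins of the probability measure
    excluded_channels: tuple[str, ...] = ()  # e.g. artifact-congested lateral channels

    def __post_init__(self) -> None:
        if self.amplitude_limit <= 0 or self.z_limit <= 0:
            raise ValueError("amplitude_limit and z_limit must be positive")


def extract_epochs(
    continuous: np.ndarray,
    channel_labels: Sequence[str],
    events: Sequence[tuple[float, str]],
    timing: TrialTiming,
) -> EpochedSession:
    """Cut trials out of a continuous recording.

    ``events`` are ``(cue_time_seconds, label)`` pairs; each epoch starts at
    ``cue_time - timing.cue_onset`` so epoch time 0 is the relax-period
    start, and spans ``timing.trial_end`` seconds (half-open window).
    Trials that would run past either end of the recording are dropped with
    a warning.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim != 2:
        raise ValueError("continuous must be (channels, samples)")
    n_samples = timing.n_samples
    epochs, labels = [], []
    for t, label in events:
        start = int(round((t - timing.cue_onset) * timing.fs))
        stop = start + n_samples
        if start < 0 or stop > continuous.shape[1]:
            warnings.warn(
                f"event at t={t:.3f}s ({label}): trial truncated, dropped",
                stacklevel=2,
            )
            continue
        epochs.append(continuous[:, start:stop])
        labels.append(label)
    if epochs:
        arr = np.stack(epochs)
    else:
        arr = np.empty((0, continuous.shape[0], n_samples))
    return EpochedSession(
        epochs=arr,
        labels=np.asarray(labels, dtype=object) if labels else np.empty(0, dtype=object),
        timing=timing,
        channel_labels=list(channel_labels),
    )


def reject_amplitude(segment: np.ndarray, limit: float) -> bool:
    """True iff any sample of a single-trial segment exceeds ±limit (strict)."""
    segment = np.asarray(segment)
    if segment.size == 0:
        raise ValueError("empty segment")
    return bool(np.abs(segment).max() > limit)


def _trial_log_probability(segments: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-trial, per-channel mean log empirical probability.

    The density is a per-channel histogram over the pooled samples of all
    trials; each trial's samples are scored by the log bin probability and
    averaged.  Shape in: (trials, channels, samples); out: (trials, channels).
    """
    n_tr, n_ch, _ = segments.shape
    out = np.empty((n_tr, n_ch))
    for c in range(n_ch):
        pooled = segments[:, c, :].ravel()
        lo, hi = pooled.min(), pooled.max()
        if hi <= lo:
            out[:, c] = 0.0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, segments[:, c, :], side="right") - 1, 0, n_bins - 1)
        counts = np.bincount(idx.ravel(), minlength=n_bins).astype(float)
        p = counts / counts.sum()
        logp = np.log(np.where(p > 0, p, 1.0))  # empty bins hold no samples
        out[:, c] = logp[idx].mean(axis=-1)
    return out


def _zscore_outliers(values: np.ndarray, z_limit: float) -> np.ndarray:
    """Boolean mask of rows deviating > z_limit SD from the column mean on
    any column; zero-SD columns reject nothing."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(values - mean) / sd
    z[:, sd == 0] = 0.0
    return (z > z_limit).any(axis=tuple(range(1, values.ndim)))


def reject_statistical(
    segments: np.ndarray,
    z_limit: float = 3.5,
    n_bins: int = 100,
) -> set[int]:
    """Kurtosis / probability outlier trials of a (trials, channels, samples)
    segment collection.  Fewer than 3 trials: returns the empty set."""
    segments = np.asarray(segments, dtype=np.float64)
    if segments.shape[0] < 3:
        return set()
    kurt = stats.kurtosis(segments, axis=-1, fisher=True, bias=True)
    logp = _trial_log_probability(segments, n_bins)
    bad = _zscore_outliers(kurt, z_limit) | _zscore_outliers(logp, z_limit)
    return set(np.flatnonzero(bad).tolist())


def segment_log_bandpower(
    segments: np.ndarray, bands: Sequence, fs: float
) -> np.ndarray:
    """Mean log band power per trial/channel/band of a segment collection.

    Band-pass filters causally, squares, averages over the segment, logs.
    Shape in (trials, channels, samples); out (trials, channels, bands).
    """
    segments = np.asarray(segments, dtype=np.float64)
    bands = as_bands(bands)
    out = np.empty(segments.shape[:2] + (len(bands),))
    for bi, band in enumerate(bands):
        sos = bandpass_sos(band, fs)
        filt = sps.sosfilt(sos, segments, axis=-1)
        out[..., bi] = np.log(np.maximum((filt * filt).mean(axis=-1), POWER_FLOOR))
    return out


def iterative_trim(values: np.ndarray, z_limit: float, max_iterations: int = 20) -> set[int]:
    """Iteratively reject rows of a (trials, cells) value matrix beyond
    ``z_limit`` SD of the surviving rows' mean in any cell, until a pass
    rejects nothing, fewer than 3 rows survive, or ``max_iterations``."""
    values = np.asarray(values, dtype=np.float64)
    n_tr = values.shape[0]
    values = values.reshape(n_tr, -1)
    rejected: set[int] = set()
    for _ in range(max_iterations):
        alive = np.asarray([i for i in range(n_tr) if i not in rejected])
        if alive.size < 3:
            break
        bad = _zscore_outliers(values[alive], z_limit)
        new = set(alive[bad].tolist())
        if not new:
            break
        rejected |= new
    return rejected


def reject_bandpower_iterative(
    segments: np.ndarray,
    bands: Sequence,
    fs: float,
    z_limit: float = 3.5,
    max_iterations: int = 20,
) -> set[int]:
    """Iterative log band-power trimming.

    Each pass computes mean/SD of the per-trial mean log band power over the
    surviving trials for every (channel, band) cell and rejects trials
    beyond ``z_limit`` SD in any cell; repeats until a pass rejects nothing
    or ``max_iterations``.  Returns the union of rejected trial indices.
    """
    segments = np.asarray(segments, dtype=np.float64)
    if segments.shape[0] < 3:
        return set()
    values = segment_log_bandpower(segments, bands, fs)
    return iterative_trim(values, z_limit, max_iterations)


def _used_channel_mask(session: EpochedSession, cfg: RejectionConfig) -> np.ndarray:
    mask = np.asarray(
        [lab not in cfg.excluded_channels for lab in session.channel_labels]
    )
    if not mask.any():
        raise ValueError("all channels excluded")
    return mask


def run_outlier_pipeline(session: EpochedSession, cfg: RejectionConfig) -> EpochedSession:
    """Three-phase rejection over a labelled session; returns a copy with
    ``artifact_flags`` and ``rejection_log`` filled.

    Relax segments are pooled over classes; imagery segments are processed
    per class.  A class group with fewer than 3 surviving trials skips the
    statistical and iterative phases (logged).
    """
    session = EpochedSession(
        epochs=session.epochs,
        labels=session.labels,
        timing=session.timing,
        channel_labels=list(session.channel_labels),
    )
    ch = _used_channel_mask(session, cfg)
    timing = session.timing
    flags = session.artifact_flags
    log = session.rejection_log
    segs = {
        name: session.epochs[:, ch, :][:, :, timing.segment(name)]
        for name in ("relax", "imagery")
    }

    # phase 1: amplitude, per trial and segment
    for name, seg in segs.items():
        for i in range(session.n_trials):
            if reject_amplitude(seg[i], cfg.amplitude_limit):
                flags[i] = True
                log[i].append(("amplitude", name))

    # groups for phases 2-3: relax pooled, imagery per class
    def groups():
        alive = ~flags
        yield "relax", "pooled", np.flatnonzero(alive)
        for cls in session.classes:
            yield "imagery", str(cls), np.flatnonzero(alive & (session.labels == cls))

    # phase 2: kurtosis / probability
    stat_hits: list[tuple[int, str, str]] = []
    for seg_name, group_name, idx in list(groups()):
        if idx.size < 3:
            logger.info(
                "statistical phase skipped for %s/%s (%d trials)",
                seg_name, group_name, idx.size,
            )
            continue
        for j in reject_statistical(segs[seg_name][idx], cfg.z_limit, cfg.n_bins):
            stat_hits.append((int(idx[j]), seg_name, group_name))
    for i, seg_name, group_name in stat_hits:
        flags[i] = True
        log[i].append(("statistical", f"{seg_name}/{group_name}"))

    # phase 3: iterative band power on the survivors
    bp_hits: list[tuple[int, str, str]] = []
    for seg_name, group_name, idx in list(groups()):
        if idx.size < 3:
            logger.info(
                "band-power phase skipped for %s/%s (%d trials)",
                seg_name, group_name, idx.size,
            )
            continue
        rej = reject_bandpower_iterative(
            segs[seg_name][idx], cfg.bands, timing.fs, cfg.z_limit, cfg.max_iterations
        )
        for j in rej:
            bp_hits.append((int(idx[j]), seg_name, group_name))
    for i, seg_name, group_name in bp_hits:
        flags[i] = True
        log[i].append(("bandpower", f"{seg_name}/{group_name}"))

    session.artifact_flags = flags
    session.rejection_log = log
    return session
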