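"""Causal log band-power features and Fisher-criterion separability.

The decoder's feature layer: each bipolar derivation is band-pass filtered
in a set of narrow bands (defaults 8-10, 10-13, 13-16, 16-24, 24-30 Hz),
squared, smoothed with a trailing 1-s moving average and log-transformed.
Everything is strictly causal so that a simulated online run never sees the
future; the first ``avg_window`` seconds of every time course are a warm-up
region and flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "FeatureTimecourse",
    "bandpass_sos",
    "bandpower_timecourse",
    "log_bandpower_features",
    "fisher_score",
    "select_best_band",
]

#: Feature bands (Hz) showing power modulation under motor imagery and the
#: non-motor mental tasks (word association, arithmetic, navigation).
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (8.0, 10.0),
    (10.0, 13.0),
    (13.0, 16.0),
    (16.0, 24.0),
    (24.0, 30.0),
)

#: Floor (μV²) applied to averaged power before the log, so silent input
#: maps to a finite value instead of -inf.
POWER_FLOOR = 1e-10

FISHER_EPS = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band in Hz, 0 < low < high < Nyquist."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"bad band ({self.low}, {self.high})")

    def validate(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band edge {self.high} Hz at or above Nyquist ({fs / 2} Hz)"
            )


def as_bands(bands: Sequence) -> list[BandDefinition]:
    return [b if isinstance(b, BandDefinition) else BandDefinition(*b) for b in bands]


@dataclass
class FeatureTimecourse:
    """Per-trial log band-power time courses.

    Attributes
    ----------
    values : ndarray, shape (trials, features, samples)
        Natural-log band power in log μV² units.
    feature_index : list of (derivation_name, band_index)
        One entry per feature row.
    valid_from : float
        Seconds of warm-up at the start of each trial during which values
        are not meaningful (filter and moving-average transients).
    fs : float
    """

    values: np.ndarray
    feature_index: list[tuple[str, int]]
    valid_from: float
    fs: float

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def first_valid_sample(self) -> int:
        return int(np.ceil(self.valid_from * self.fs)) - 1

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice of a half-open [start, end) window in seconds."""
        lo = int(round(window[0] * self.fs))
        hi = int(round(window[1] * self.fs))
        return slice(lo, hi)

    def window_mean(self, window: tuple[float, float]) -> np.ndarray:
        """Trial x feature matrix of values averaged over a time window."""
        return self.values[:, :, self.window_slice(window)].mean(axis=-1)


def bandpass_sos(band, fs: float, order: int = 4) -> np.ndarray:
    """Causal Butterworth band-pass in second-order sections."""
    band = band if isinstance(band, BandDefinition) else BandDefinition(*band)
    band.validate(fs)
    return sps.butter(order, (band.low, band.high), btype="bandpass", fs=fs, output="sos")


def _trailing_mean(x: np.ndarray, n: int) -> np.ndarray:
    """Trailing moving average over the last axis; first n-1 values are
    partial-window averages (they lie inside the warm-up region)."""
    cs = np.cumsum(x, axis=-1, dtype=np.float64)
    out = np.empty_like(cs)
    out[..., :n] = cs[..., :n] / np.arange(1, n + 1)
    out[..., n:] = (cs[..., n:] - cs[..., :-n]) / n
    return out


def bandpower_timecourse(
    x: np.ndarray,
    band,
    fs: float,
    avg_window: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Causal log band-power of a signal (last axis = time).

    Band-pass filter -> square -> trailing ``avg_window``-s moving average
    -> natural log (power floored at ``POWER_FLOOR`` μV²).  Returns the time
    course and ``valid_from`` = ``avg_window`` seconds.
    """
    x = np.asarray(x, dtype=np.float64)
    n_avg = int(round(avg_window * fs))
    if x.shape[-1] < n_avg:
        raise ValueError("signal shorter than the averaging window")
    sos = bandpass_sos(band, fs)
    filtered = sps.sosfilt(sos, x, axis=-1)
    power = _trailing_mean(filtered * filtered, n_avg)
    return np.log(np.maximum(power, POWER_FLOOR)), avg_window


def log_bandpower_features(
    derived: np.ndarray,
    derivation_names: Sequence[str],
    bands: Sequence,
    fs: float,
    avg_window: float = 1.0,
) -> FeatureTimecourse:
    """Feature time courses for ``(trials, derivations, samples)`` signals.

    The feature axis enumerates derivations (outer) x bands (inner).
    """
    derived = np.asarray(derived, dtype=np.float64)
    if derived.ndim != 3 or derived.shape[1] != len(derivation_names):
        raise ValueError("derived must be (trials, derivations, samples)")
    bands = as_bands(bands)
    n_tr, n_d, n_s = derived.shape
    nb = len(bands)
    values = np.empty((n_tr, n_d * nb, n_s), dtype=np.float64)
    valid_from = avg_window
    for bi, band in enumerate(bands):
        # feature f = derivation_index * nb + band_index (derivation-major)
        tc, valid_from = bandpower_timecourse(derived, band, fs, avg_window)
        values[:, bi::nb, :] = tc
    index = [(str(name), bi) for name in derivation_names for bi in range(nb)]
    return FeatureTimecourse(values, index, valid_from, fs)


def fisher_score(x1, x2, eps: float = FISHER_EPS) -> float:
    """Fisher criterion between two scalar samples.

    ``(mean(x1) - mean(x2))**2 / (var(x1) + var(x2) + eps)`` with unbiased
    variances; nonnegative, symmetric, invariant to a common offset.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("fisher_score needs at least 2 samples per class")
    d = x1.mean() - x2.mean()
    return float(d * d / (x1.var(ddof=1) + x2.var(ddof=1) + eps))


def select_best_band(
    values: np.ndarray,
    labels: np.ndarray,
    window: tuple[float, float],
    fs: float,
) -> tuple[int, float]:
    """Pick the most separable band for one derivation.

    ``values`` is ``(trials, bands, samples)`` log band power; each trial is
    averaged over the half-open ``window`` (seconds), then the Fisher score
    between the two classes is computed per band.  Returns ``(band_index,
    score)``; ties resolve to the lowest band index.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    m0 = labels == classes[0]
    m1 = labels == classes[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("a class has no trials")
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    pooled = values[:, :, lo:hi].mean(axis=-1)  # trials x bands
    best_idx, best_score = 0, -1.0
    for bi in range(pooled.shape[1]):
        score = fisher_score(pooled[m0, bi], pooled[m1, bi])
        if score > best_score:  # strict: ties keep the lower index
            best_idx, best_score = bi, score
    return best_idx, best_score
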