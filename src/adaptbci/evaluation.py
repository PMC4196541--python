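"""Performance measures, channel/class ranking sweep and separability maps.

Simulated-online performance is summarized by the accuracy time course over
evaluated trials; the median of that curve inside the 4-8 s analysis window
drives model and channel ranking, while the peak inside the same window is
the headline per-session figure.  Better-than-chance bounds come from the
exact one-sided binomial tail at the requested significance level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import analysis_window
from .engine import AdaptiveConfig, AdaptiveSessionResult, run_session
from .features import as_bands, fisher_score, log_bandpower_features
from .montage import BipolarDerivation, derivations_overlap, derive_epochs
from .preprocessing import EpochedSession, RejectionConfig, run_outlier_pipeline

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyTimecourse",
    "SweepResult",
    "accuracy_timecourse",
    "median_accuracy",
    "peak_accuracy",
    "chance_level",
    "run_channel_sweep",
    "select_channels",
    "select_classes",
    "separability_map",
]

#: Motor-imagery classes of the five-task paradigm; the rest are non-motor.
MOTOR_CLASSES = frozenset({"Feet", "Hand"})


@dataclass
class AccuracyTimecourse:
    """Fraction of evaluated trials correct at each timepoint."""

    times: np.ndarray  # seconds
    accuracy: np.ndarray  # in [0, 1]
    n_trials: int


def accuracy_timecourse(result: AdaptiveSessionResult) -> AccuracyTimecourse:
    """Prequential accuracy curve over a run's evaluated trials.

    Evaluated trials are the artifact-free trials classified after initial
    calibration; the curve covers the timepoints valid in all of them.
    """
    recs = result.evaluated_records()
    if not recs:
        raise ValueError("no evaluated trials in this result")
    correct = np.stack([r.correct for r in recs])
    fs = result.timing.fs
    times = (result.first_valid_sample + np.arange(correct.shape[1])) / fs
    return AccuracyTimecourse(times, correct.mean(axis=0), len(recs))


def _window_values(tc: AccuracyTimecourse, window: tuple[float, float]) -> np.ndarray:
    mask = (tc.times >= window[0]) & (tc.times < window[1])
    vals = tc.accuracy[mask]
    if vals.size == 0:
        raise ValueError(f"window {window} does not overlap the time course")
    return vals


def median_accuracy(tc: AccuracyTimecourse, window: tuple[float, float] = (4.0, 8.0)) -> float:
    """Median of the accuracy curve inside a half-open window (seconds)."""
    return float(np.median(_window_values(tc, window)))


def peak_accuracy(tc: AccuracyTimecourse, window: tuple[float, float] = (4.0, 8.0)) -> float:
    """Maximum of the accuracy curve inside a half-open window (seconds)."""
    return float(np.max(_window_values(tc, window)))


def chance_level(n_trials: int, n_classes: int = 2, alpha: float = 0.01) -> float:
    """Exact binomial better-than-chance accuracy bound.

    The smallest ``k / n_trials`` such that ``P(X >= k)`` under
    ``Binomial(n_trials, 1/n_classes)`` is at most ``alpha``; e.g. 40/60 ≈
    66.7% for 60 trials, two classes, alpha 0.01.  No normal approximation.
    """
    if n_trials < 1 or n_classes < 2 or not 0 < alpha < 1:
        raise ValueError("need n_trials >= 1, n_classes >= 2, 0 < alpha < 1")
    p = 1.0 / n_classes
    # P(X >= k) = sf(k - 1); find the smallest k in 0..n with tail <= alpha
    ks = np.arange(n_trials + 1)
    tails = stats.binom.sf(ks - 1, n_trials, p)
    ok = np.flatnonzero(tails <= alpha)
    if ok.size == 0:  # alpha below (1/c)^n: no attainable accuracy is significant
        return (n_trials + 1) / n_trials
    return int(ok[0]) / n_trials


@dataclass
class SweepResult:
    """One Mini-run per (derivation, class pair) with its median accuracy."""

    cells: pd.DataFrame  # columns: derivation, pair, median_accuracy (NaN = missing)
    derivations: dict[str, BipolarDerivation]
    selection_trace: list = field(default_factory=list)

    def cell(self, derivation: str, pair: tuple[str, str]) -> float:
        pname = "|".join(sorted(pair))
        row = self.cells[
            (self.cells.derivation == derivation) & (self.cells.pair == pname)
        ]
        return float(row.median_accuracy.iloc[0])

    def derivation_scores(self, statistic: str = "median") -> pd.Series:
        """Per-derivation ranking statistic over class-pair cells."""
        agg = {"median": "median", "mean": "mean"}[statistic]
        return self.cells.groupby("derivation").median_accuracy.agg(agg)


def run_channel_sweep(
    session: EpochedSession,
    derivations: Sequence[BipolarDerivation],
    class_pairs: Iterable[tuple[str, str]] | None = None,
    cfg_template: AdaptiveConfig | None = None,
    **cfg_kwargs,
) -> SweepResult:
    """Simulate the Mini configuration on every (derivation, pair) cell.

    ``class_pairs`` defaults to all binary combinations of the session's
    classes.  Cells whose run never calibrates (or evaluates no trial) are
    recorded as missing and excluded from ranking medians.
    """
    if class_pairs is None:
        class_pairs = list(combinations(session.classes, 2))
    class_pairs = [tuple(sorted(p)) for p in class_pairs]
    window = None
    rows = []
    for d in derivations:
        for pair in class_pairs:
            if cfg_template is not None:
                cfg = AdaptiveConfig(
                    mode="mini",
                    derivations=(d,),
                    classes=pair,
                    n_init_tpc=cfg_template.n_init_tpc,
                    n_update_tpc=cfg_template.n_update_tpc,
                    bands=cfg_template.bands,
                    timing=cfg_template.timing,
                    rejection=cfg_template.rejection,
                    feature_selection=cfg_template.feature_selection,
                    update_counting=cfg_template.update_counting,
                )
            else:
                cfg = AdaptiveConfig(mode="mini", derivations=(d,), classes=pair, **cfg_kwargs)
            if window is None:
                window = analysis_window(cfg.timing)
            result = run_session(session, cfg)
            if result.calibrated and result.n_evaluated > 0:
                acc = median_accuracy(accuracy_timecourse(result), window)
            else:
                acc = np.nan
                logger.warning("sweep cell (%s, %s): never calibrated", d.name, pair)
            rows.append({"derivation": d.name, "pair": "|".join(pair), "median_accuracy": acc})
    return SweepResult(
        cells=pd.DataFrame(rows), derivations={d.name: d for d in derivations}
    )


def select_channels(
    sweep: SweepResult, k: int = 3, statistic: str = "median"
) -> list[BipolarDerivation]:
    """Greedy non-overlapping top-k derivations from a sweep ranking.

    Derivations are ranked by the ``statistic`` of their class-pair cells
    (ties broken by name); traversing best-first, a derivation is kept iff
    its covered scalp positions overlap none already kept.
    """
    scores = sweep.derivation_scores(statistic)
    order = sorted(scores.index, key=lambda n: (-scores[n], n))
    kept: list[BipolarDerivation] = []
    trace = []
    for name in order:
        d = sweep.derivations[name]
        if any(derivations_overlap(d, other) for other in kept):
            trace.append({"derivation": name, "score": float(scores[name]), "kept": False})
            continue
        trace.append({"derivation": name, "score": float(scores[name]), "kept": True})
        kept.append(d)
        if len(kept) == k:
            break
    if len(kept) < k:
        logger.warning("only %d non-overlapping derivations available (k=%d)", len(kept), k)
    sweep.selection_trace = trace
    return kept


def select_classes(
    sweep: SweepResult,
    selected_derivations: Sequence[BipolarDerivation],
    m: int = 4,
) -> list[str]:
    """Top-m classes by mean cell value over all pairs containing the class,
    restricted to the selected derivations.  Ties break lexicographically."""
    names = {d.name for d in selected_derivations}
    cells = sweep.cells[sweep.cells.derivation.isin(names)]
    scores: dict[str, list[float]] = {}
    for _, row in cells.iterrows():
        if np.isnan(row.median_accuracy):
            continue
        for cls in row.pair.split("|"):
            scores.setdefault(cls, []).append(row.median_accuracy)
    ranked = sorted(scores, key=lambda c: (-float(np.mean(scores[c])), c))
    return ranked[:m]


def _pair_filter(pair: tuple[str, str], kind: str, motor: frozenset) -> bool:
    a_mt, b_mt = pair[0] in motor, pair[1] in motor
    if kind == "mt_vs_mt":
        return a_mt and b_mt
    if kind == "nm_vs_nm":
        return not a_mt and not b_mt
    if kind == "mt_vs_nm":
        return a_mt != b_mt
    if kind == "all":
        return True
    raise ValueError(f"unknown class-combination filter {kind!r}")


def separability_map(
    session: EpochedSession,
    derivations: Sequence[BipolarDerivation],
    bands: Sequence,
    class_filter: str = "all",
    rejection: RejectionConfig | None = None,
    motor_classes: frozenset = MOTOR_CLASSES,
) -> pd.DataFrame:
    """Average Fisher separability per (derivation, band).

    After outlier rejection, window-averaged imagery log band-power features
    are scored with the Fisher criterion for every class pair passing the
    ``class_filter`` (``mt_vs_mt``, ``mt_vs_nm``, ``nm_vs_nm`` or ``all``)
    and averaged over pairs.  Returns a derivation x band DataFrame; a
    topographic rendering can be layered on top but the numbers are the map.
    """
    if rejection is not None:
        session = run_outlier_pipeline(session, rejection)
    clean = session.clean()
    pairs = [
        p
        for p in combinations(clean.classes, 2)
        if _pair_filter(tuple(p), class_filter, motor_classes)
    ]
    if not pairs:
        raise ValueError(f"no class pair passes filter {class_filter!r}")
    bands = as_bands(bands)
    derived = derive_epochs(clean.epochs, clean.channel_labels, derivations)
    feat = log_bandpower_features(
        derived, [d.name for d in derivations], bands, clean.timing.fs
    )
    pooled = feat.window_mean(analysis_window(clean.timing))  # trials x features
    nb = len(bands)
    table = np.zeros((len(derivations), nb))
    for a, b in pairs:
        ma, mb = clean.labels == a, clean.labels == b
        for f, (dname, bi) in enumerate(feat.feature_index):
            di = f // nb
            table[di, bi] += fisher_score(pooled[ma, f], pooled[mb, f])
    table /= len(pairs)
    return pd.DataFrame(
        table,
        index=[d.name for d in derivations],
        columns=[f"{b.low:g}-{b.high:g}Hz" for b in bands],
    )
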