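"""Classifier calibration: feature selection, LooCV window search, LDA.

Calibration picks, per bipolar derivation, the most class-separable
frequency band (Fisher criterion over the 4-8 s analysis window), then
scores eight adjacent 0.5-s training windows by leave-one-out
cross-validation: for each window, an LDA is trained on window-averaged
features of the held-in trials and applied to the held-out trial's full
feature time course; per-timepoint correctness is pooled over folds and its
median over the analysis window is the window's score.  The best window
(ties: earliest) trains the final classifier on all trials.

The Auto configuration additionally chooses which two of four mental-task
classes to discriminate: regular calibration runs for all six pairs and the
pair with the highest LooCV median accuracy wins (ties: higher Fisher score
of the best selected feature, then lexicographic pair order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .features import (
    FeatureTimecourse,
    fisher_score,
    log_bandpower_features,
    select_best_band,
)
from .montage import derive_epochs
from .preprocessing import EpochedSession, TrialTiming

__all__ = [
    "CalibratedClassifier",
    "CalibrationReport",
    "CalibrationDeferred",
    "train_lda",
    "calibrate",
    "calibrate_features",
    "auto_select_classes",
    "auto_select_classes_features",
    "analysis_window",
]

#: Width of each candidate training window, seconds.
TRAIN_WINDOW_WIDTH = 0.5

#: Ridge added to the pooled covariance diagonal, relative to trace/dim.
LDA_RIDGE = 1e-6


class CalibrationDeferred(Exception):
    """Not enough artifact-free trials yet; the adaptive engine keeps
    collecting instead of treating this as a failure."""


def analysis_window(timing: TrialTiming) -> tuple[float, float]:
    """The [cue+1, imagery-end) window (seconds) used for feature selection,
    window search and accuracy summaries; [4, 8) under default timing."""
    return (timing.cue_onset + 1.0, timing.imagery_end_analysis)


@dataclass
class CalibratedClassifier:
    """A trained pairwise linear discriminant.

    ``weights`` and ``bias`` act on the selected features; the decision
    value ``w @ x + b`` is positive for ``class_pair[1]``.
    """

    class_pair: tuple[str, str]
    selected_features: list[tuple[str, int]]  # (derivation name, band index)
    selected_idx: list[int]  # positions in the full feature axis
    train_window: tuple[float, float]
    weights: np.ndarray
    bias: float
    loocv_median_accuracy: float
    best_feature_fisher: float

    def decision_values(self, values: np.ndarray) -> np.ndarray:
        """``w @ x + b`` over a (..., features, samples) selected-feature
        array (features axis must match ``selected_idx`` order)."""
        return np.tensordot(self.weights, values, axes=([0], [-2])) + self.bias

    def predict_timecourse(self, feat_values: np.ndarray) -> np.ndarray:
        """Predicted class label per timepoint from full feature values
        ``(..., all_features, samples)``."""
        vals = feat_values[..., self.selected_idx, :]
        dv = self.decision_values(vals)
        return np.where(dv > 0, self.class_pair[1], self.class_pair[0])


@dataclass
class CalibrationReport:
    """Per-window LooCV results and, in Auto mode, per-pair outcomes."""

    window_starts: list[float]
    window_accuracies: list[float]
    chosen_window: int
    chosen_pair: tuple[str, str] | None = None
    per_pair: dict = field(default_factory=dict)  # pair name -> summary dict

    def to_dict(self) -> dict:
        return {
            "window_starts": list(self.window_starts),
            "window_accuracies": [float(a) for a in self.window_accuracies],
            "chosen_window": int(self.chosen_window),
            "chosen_pair": list(self.chosen_pair) if self.chosen_pair else None,
            "per_pair": self.per_pair,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def train_lda(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Two-class LDA with pooled covariance and midpoint bias.

    ``y`` holds 0/1 class indices, each class with at least 2 trials.  The
    pooled covariance is ridge-stabilized (``LDA_RIDGE * trace/dim`` on the
    diagonal) so near-singular small-sample fits never crash.
    Returns ``(weights, bias)`` with the boundary at the class-mean midpoint
    (decision value positive for class 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be (trials, features)")
    X0, X1 = X[y == 0], X[y == 1]
    if len(X0) < 2 or len(X1) < 2:
        raise CalibrationDeferred("need at least 2 trials per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    S0 = (X0 - mu0).T @ (X0 - mu0)
    S1 = (X1 - mu1).T @ (X1 - mu1)
    cov = (S0 + S1) / (n0 + n1 - 2)
    dim = cov.shape[0]
    cov = cov + np.eye(dim) * (LDA_RIDGE * np.trace(cov) / dim + 1e-300)
    w = np.linalg.solve(cov, mu1 - mu0)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return w, b


def _select_features(
    feat: FeatureTimecourse,
    mask: np.ndarray,
    labels: np.ndarray,
    window: tuple[float, float],
    selection: str,
) -> tuple[list[int], list[tuple[str, int]], float]:
    """Chosen feature rows (per-derivation best band, or the single best
    overall), with the highest Fisher score among them."""
    deriv_names = []
    for name, _ in feat.feature_index:
        if name not in deriv_names:
            deriv_names.append(name)
    nb = len(feat.feature_index) // len(deriv_names)
    picked_idx: list[int] = []
    picked_desc: list[tuple[str, int]] = []
    scores: list[float] = []
    for di, name in enumerate(deriv_names):
        block = feat.values[mask][:, di * nb : (di + 1) * nb, :]
        bi, score = select_best_band(block, labels, window, feat.fs)
        picked_idx.append(di * nb + bi)
        picked_desc.append((name, bi))
        scores.append(score)
    if selection == "global_single":
        best = int(np.argmax(scores))  # argmax keeps the first on ties
        picked_idx, picked_desc, scores = (
            [picked_idx[best]],
            [picked_desc[best]],
            [scores[best]],
        )
    elif selection != "per_derivation":
        raise ValueError(f"unknown feature selection mode {selection!r}")
    return picked_idx, picked_desc, float(max(scores))


def calibrate_features(
    feat: FeatureTimecourse,
    labels: np.ndarray,
    pair: tuple[str, str],
    timing: TrialTiming,
    selection: str = "per_derivation",
) -> tuple[CalibratedClassifier, CalibrationReport]:
    """Calibrate a pairwise classifier from precomputed feature time courses.

    Only trials whose label is in ``pair`` are used; both classes need at
    least 2 trials or :class:`CalibrationDeferred` is raised.
    """
    labels = np.asarray(labels)
    pair = tuple(sorted(pair))
    mask = np.isin(labels, pair)
    y_lab = labels[mask]
    n0, n1 = int((y_lab == pair[0]).sum()), int((y_lab == pair[1]).sum())
    if n0 < 2 or n1 < 2:
        raise CalibrationDeferred(
            f"pair {pair}: {n0} vs {n1} artifact-free trials; need >= 2 each"
        )
    window = analysis_window(timing)
    y = (y_lab == pair[1]).astype(int)

    sel_idx, sel_desc, best_fisher = _select_features(
        feat, mask, y_lab, window, selection
    )
    values = feat.values[mask][:, sel_idx, :]  # trials x nsel x samples
    eval_sl = feat.window_slice(window)
    eval_vals = values[:, :, eval_sl]
    n_trials = values.shape[0]

    n_windows = int(round((window[1] - window[0]) / TRAIN_WINDOW_WIDTH))
    starts = [window[0] + k * TRAIN_WINDOW_WIDTH for k in range(n_windows)]
    medians = np.empty(n_windows)
    for k, start in enumerate(starts):
        wsl = feat.window_slice((start, start + TRAIN_WINDOW_WIDTH))
        Xw = values[:, :, wsl].mean(axis=-1)  # trials x nsel
        correct = np.empty((n_trials, eval_vals.shape[-1]), dtype=bool)
        for i in range(n_trials):
            keep = np.arange(n_trials) != i
            w, b = train_lda(Xw[keep], y[keep])
            dv = w @ eval_vals[i] + b
            correct[i] = (dv > 0) == (y[i] == 1)
        medians[k] = np.median(correct.mean(axis=0))
    chosen = int(np.argmax(medians))  # argmax -> earliest window on ties
    wsl = feat.window_slice((starts[chosen], starts[chosen] + TRAIN_WINDOW_WIDTH))
    w, b = train_lda(values[:, :, wsl].mean(axis=-1), y)

    clf = CalibratedClassifier(
        class_pair=pair,
        selected_features=sel_desc,
        selected_idx=sel_idx,
        train_window=(starts[chosen], starts[chosen] + TRAIN_WINDOW_WIDTH),
        weights=w,
        bias=b,
        loocv_median_accuracy=float(medians[chosen]),
        best_feature_fisher=best_fisher,
    )
    report = CalibrationReport(
        window_starts=starts,
        window_accuracies=medians.tolist(),
        chosen_window=chosen,
    )
    return clf, report


def auto_select_classes_features(
    feat: FeatureTimecourse,
    labels: np.ndarray,
    classes: Sequence[str],
    timing: TrialTiming,
    selection: str = "per_derivation",
) -> tuple[tuple[str, str], CalibratedClassifier, CalibrationReport]:
    """Run regular calibration for every binary combination of ``classes``
    and keep the best pair (LooCV median, then Fisher, then pair order)."""
    pairs = [tuple(sorted(p)) for p in combinations(sorted(classes), 2)]
    best: tuple[tuple[str, str], CalibratedClassifier, CalibrationReport] | None = None
    per_pair: dict[str, dict] = {}
    for pair in pairs:
        clf, rep = calibrate_features(feat, labels, pair, timing, selection)
        per_pair["|".join(pair)] = {
            "loocv_median_accuracy": clf.loocv_median_accuracy,
            "best_feature_fisher": clf.best_feature_fisher,
            "chosen_window": rep.chosen_window,
        }
        if best is None:
            best = (pair, clf, rep)
            continue
        _, bclf, _ = best
        if clf.loocv_median_accuracy > bclf.loocv_median_accuracy or (
            clf.loocv_median_accuracy == bclf.loocv_median_accuracy
            and clf.best_feature_fisher > bclf.best_feature_fisher
        ):
            best = (pair, clf, rep)
    assert best is not None
    pair, clf, rep = best
    rep.chosen_pair = pair
    rep.per_pair = per_pair
    return pair, clf, rep


def _session_features(
    session: EpochedSession, derivations, bands
) -> FeatureTimecourse:
    derived = derive_epochs(session.epochs, session.channel_labels, derivations)
    return log_bandpower_features(
        derived, [d.name for d in derivations], bands, session.timing.fs
    )


def calibrate(
    session: EpochedSession,
    derivations,
    bands,
    timing: TrialTiming | None = None,
    selection: str = "per_derivation",
) -> tuple[CalibratedClassifier, CalibrationReport]:
    """Calibrate on the artifact-free trials of a two-class session."""
    timing = timing or session.timing
    clean = session.clean()
    classes = clean.classes
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, found {classes}")
    feat = _session_features(clean, derivations, bands)
    return calibrate_features(feat, clean.labels, tuple(classes), timing, selection)


def auto_select_classes(
    session: EpochedSession,
    derivations,
    bands,
    timing: TrialTiming | None = None,
    selection: str = "per_derivation",
) -> tuple[tuple[str, str], CalibratedClassifier, CalibrationReport]:
    """Class-pair auto-selection on the artifact-free trials of a
    four-class session."""
    timing = timing or session.timing
    clean = session.clean()
    feat = _session_features(clean, derivations, bands)
    return auto_select_classes_features(
        feat, clean.labels, clean.classes, timing, selection
    )
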