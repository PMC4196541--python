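"""Simulated-online adaptive BCI loop.

Trials are processed one by one in arrival order.  Each arriving trial is
screened by a prequential version of the outlier pipeline (statistics over
the artifact-free trials collected so far, plus the new trial).  Once every
in-scope class has ``n_init_tpc`` artifact-free trials, the initial
calibration runs — in Auto mode this includes the one-off class-pair
selection, after which only the selected pair's trials are counted,
classified and evaluated.  Every artifact-free trial thereafter is
classified with the most recent model at every valid timepoint, and the
system recalibrates on all collected trials whenever every in-scope class
has accumulated ``n_update_tpc`` new artifact-free trials.

Three configurations:

- ``mini``: 1 bipolar derivation, 2 classes (the screening workhorse);
- ``smr``: 3 derivations, 2 motor-imagery classes;
- ``auto``: 3 derivations, 4 classes with auto-selected pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .calibration import (
    CalibratedClassifier,
    CalibrationDeferred,
    CalibrationReport,
    auto_select_classes_features,
    calibrate_features,
)
from .features import DEFAULT_BANDS, FeatureTimecourse, log_bandpower_features
from .montage import BipolarDerivation, derive_epochs
from .preprocessing import (
    EpochedSession,
    RejectionConfig,
    TrialTiming,
    iterative_trim,
    segment_log_bandpower,
)

__all__ = ["AdaptiveConfig", "AdaptiveSessionResult", "TrialRecord", "ModelEvent", "run_session"]

_MODE_SHAPES = {"mini": (1, 2), "smr": (3, 2), "auto": (3, 4)}


@dataclass(frozen=True)
class AdaptiveConfig:
    """Configuration of one adaptive run."""

    mode: str
    derivations: tuple[BipolarDerivation, ...]
    classes: tuple[str, ...]
    n_init_tpc: int = 7
    n_update_tpc: int = 7
    bands: tuple = DEFAULT_BANDS
    timing: TrialTiming = TrialTiming()
    rejection: RejectionConfig = RejectionConfig()
    feature_selection: str = "per_derivation"
    update_counting: str = "per_class"  # or "total"

    def __post_init__(self) -> None:
        if self.mode not in _MODE_SHAPES:
            raise ValueError(f"unknown mode {self.mode!r}")
        n_deriv, n_cls = _MODE_SHAPES[self.mode]
        if len(self.derivations) != n_deriv:
            raise ValueError(
                f"mode {self.mode!r} needs {n_deriv} derivation(s), "
                f"got {len(self.derivations)}"
            )
        if len(self.classes) != n_cls:
            raise ValueError(
                f"mode {self.mode!r} needs {n_cls} classes, got {len(self.classes)}"
            )
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("classes must be unique")
        if self.n_init_tpc < 2 or self.n_update_tpc < 1:
            raise ValueError("n_init_tpc >= 2 and n_update_tpc >= 1 required")
        if self.update_counting not in ("per_class", "total"):
            raise ValueError(f"bad update_counting {self.update_counting!r}")


@dataclass
class TrialRecord:
    """Outcome of one arriving trial."""

    arrival_index: int
    label: str
    in_scope: bool
    artifact: bool = False
    rejection_reasons: list = field(default_factory=list)
    model_version: int | None = None
    pair: tuple[str, str] | None = None
    pred01: np.ndarray | None = None  # per-timepoint 0/1 vs. pair order

    @property
    def predicted_labels(self) -> np.ndarray | None:
        if self.pred01 is None:
            return None
        return np.where(self.pred01 == 1, self.pair[1], self.pair[0])

    @property
    def correct(self) -> np.ndarray | None:
        """Per-timepoint correctness of the prediction."""
        if self.pred01 is None:
            return None
        true01 = 1 if self.label == self.pair[1] else 0
        return self.pred01 == true01


@dataclass
class ModelEvent:
    arrival_index: int  # trial whose arrival triggered this (re)calibration
    version: int
    classifier: CalibratedClassifier
    report: CalibrationReport


@dataclass
class AdaptiveSessionResult:
    """Prequential predictions, model lineage and rejection log of one run."""

    records: list[TrialRecord]
    models: list[ModelEvent]
    selected_pair: tuple[str, str] | None
    timing: TrialTiming
    first_valid_sample: int

    @property
    def calibrated(self) -> bool:
        return len(self.models) > 0

    def evaluated_records(self) -> list[TrialRecord]:
        return [r for r in self.records if r.pred01 is not None]

    @property
    def n_evaluated(self) -> int:
        return len(self.evaluated_records())

    @property
    def rejected_fraction(self) -> float:
        in_scope = [r for r in self.records if r.in_scope]
        if not in_scope:
            return 0.0
        return sum(r.artifact for r in in_scope) / len(in_scope)


class _PrequentialRejector:
    """Per-trial cached statistics for online outlier screening.

    All cached quantities are computed from a single trial's signal, so
    precomputing them for the whole session leaks no information; group
    statistics are always formed over the collected artifact-free trials
    plus the trial under scrutiny.  Histogram bins for the probability
    measure are fixed at ``n_bins`` over ±amplitude_limit so per-trial
    counts can be pooled incrementally.
    """

    SEGMENTS = ("relax", "imagery")

    def __init__(self, derived: np.ndarray, timing: TrialTiming, cfg: RejectionConfig):
        self.cfg = cfg
        self.kurt: dict[str, np.ndarray] = {}
        self.counts: dict[str, np.ndarray] = {}
        self.n_samp: dict[str, int] = {}
        self.bp: dict[str, np.ndarray] = {}
        self.amp: dict[str, np.ndarray] = {}
        lim = cfg.amplitude_limit
        edges = np.linspace(-lim, lim, cfg.n_bins + 1)
        n_tr, n_ch, _ = derived.shape
        for seg_name in self.SEGMENTS:
            seg = derived[:, :, timing.segment(seg_name)]
            self.amp[seg_name] = np.abs(seg).max(axis=(1, 2)) > lim
            self.kurt[seg_name] = sstats.kurtosis(seg, axis=-1, fisher=True, bias=True)
            idx = np.clip(
                np.searchsorted(edges, np.clip(seg, -lim, lim), side="right") - 1,
                0,
                cfg.n_bins - 1,
            )
            counts = np.zeros((n_tr, n_ch, cfg.n_bins))
            for t in range(n_tr):
                for c in range(n_ch):
                    counts[t, c] = np.bincount(idx[t, c], minlength=cfg.n_bins)
            self.counts[seg_name] = counts
            self.n_samp[seg_name] = seg.shape[-1]
            self.bp[seg_name] = segment_log_bandpower(seg, cfg.bands, timing.fs)

    def amplitude_exceeded(self, i: int) -> list[str]:
        return [s for s in self.SEGMENTS if self.amp[s][i]]

    def _stat_outlier(self, seg: str, group: np.ndarray, i: int) -> bool:
        """Is trial ``i`` a kurtosis/probability outlier within ``group``
        (which includes ``i``)?"""
        z = self.cfg.z_limit
        pos = int(np.flatnonzero(group == i)[0])
        kurt = self.kurt[seg][group]
        if _row_is_outlier(kurt, pos, z):
            return True
        pooled = self.counts[seg][group].sum(axis=0)  # channels x bins
        p = pooled / pooled.sum(axis=-1, keepdims=True)
        logp = np.log(np.where(p > 0, p, 1.0))
        scores = (
            np.einsum("tcb,cb->tc", self.counts[seg][group], logp)
            / self.n_samp[seg]
        )
        return _row_is_outlier(scores, pos, z)

    def _bandpower_outlier(self, seg: str, group: np.ndarray, i: int) -> bool:
        pos = int(np.flatnonzero(group == i)[0])
        rejected = iterative_trim(
            self.bp[seg][group], self.cfg.z_limit, self.cfg.max_iterations
        )
        return pos in rejected

    def screen(
        self, i: int, relax_group: np.ndarray, imagery_group: np.ndarray
    ) -> list[tuple[str, str]]:
        """Screen arriving trial ``i``; groups already include ``i``.
        Returns (phase, segment) reasons; empty list = accepted."""
        reasons = [("amplitude", s) for s in self.amplitude_exceeded(i)]
        if reasons:
            return reasons
        for seg, group in (("relax", relax_group), ("imagery", imagery_group)):
            if len(group) >= 3 and self._stat_outlier(seg, group, i):
                reasons.append(("statistical", seg))
        if reasons:
            return reasons
        for seg, group in (("relax", relax_group), ("imagery", imagery_group)):
            if len(group) >= 3 and self._bandpower_outlier(seg, group, i):
                reasons.append(("bandpower", seg))
        return reasons


def _row_is_outlier(values: np.ndarray, pos: int, z_limit: float) -> bool:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(values[pos] - mean) / sd
    z[sd == 0] = 0.0
    return bool((z > z_limit).any())


def _subset_features(feat: FeatureTimecourse, idx: Sequence[int]) -> FeatureTimecourse:
    return FeatureTimecourse(
        values=feat.values[np.asarray(idx)],
        feature_index=feat.feature_index,
        valid_from=feat.valid_from,
        fs=feat.fs,
    )


def run_session(session: EpochedSession, cfg: AdaptiveConfig) -> AdaptiveSessionResult:
    """Simulate one adaptive run over a session's trials in arrival order.

    The model applied to a trial was trained only on earlier trials; the
    result is bit-for-bit deterministic given identical inputs.  If the
    stream ends before initial calibration the result simply reports
    ``calibrated == False``.
    """
    present = set(np.unique(session.labels).tolist())
    missing = set(cfg.classes) - present
    if missing:
        raise ValueError(f"session lacks configured classes {sorted(missing)}")
    timing = cfg.timing
    derived = derive_epochs(session.epochs, session.channel_labels, cfg.derivations)
    feat = log_bandpower_features(
        derived, [d.name for d in cfg.derivations], cfg.bands, timing.fs
    )
    rejector = _PrequentialRejector(derived, timing, cfg.rejection)

    labels = np.asarray(session.labels)
    scope: tuple[str, ...] = tuple(cfg.classes)
    selected_pair: tuple[str, str] | None = None
    collected: list[int] = []  # artifact-free in-scope trial indices
    counts = {c: 0 for c in scope}
    new_counts = {c: 0 for c in scope}
    new_total = 0
    model: CalibratedClassifier | None = None
    models: list[ModelEvent] = []
    records: list[TrialRecord] = []
    fv = feat.first_valid_sample

    def ready(cnt: dict, need: int, total: int) -> bool:
        if model is not None and cfg.update_counting == "total":
            return total >= need * len(scope)
        return all(cnt[c] >= need for c in scope)

    for i in range(session.n_trials):
        lab = str(labels[i])
        if lab not in scope:
            records.append(TrialRecord(i, lab, in_scope=False))
            continue
        rec = TrialRecord(i, lab, in_scope=True)
        records.append(rec)

        coll = np.asarray(collected, dtype=int)
        relax_group = np.append(coll, i)
        same_class = coll[labels[coll] == lab] if coll.size else coll
        imagery_group = np.append(same_class, i)
        reasons = rejector.screen(i, relax_group, imagery_group)
        if reasons:
            rec.artifact = True
            rec.rejection_reasons = reasons
            continue

        if model is not None:
            rec.model_version = models[-1].version
            rec.pair = model.class_pair
            pred = model.decision_values(feat.values[i][model.selected_idx, :]) > 0
            rec.pred01 = pred[fv:].astype(np.int8)

        collected.append(i)
        counts[lab] += 1
        new_counts[lab] += 1
        new_total += 1

        if model is None:
            if ready(counts, cfg.n_init_tpc, new_total):
                sub = _subset_features(feat, collected)
                sub_labels = labels[collected]
                if cfg.mode == "auto":
                    pair, clf, rep = auto_select_classes_features(
                        sub, sub_labels, scope, timing, cfg.feature_selection
                    )
                    selected_pair = pair
                    scope = pair
                    collected = [j for j in collected if labels[j] in pair]
                else:
                    pair = tuple(sorted(scope))
                    clf, rep = calibrate_features(
                        sub, sub_labels, pair, timing, cfg.feature_selection
                    )
                    selected_pair = pair
                models.append(ModelEvent(i, len(models) + 1, clf, rep))
                model = clf
                new_counts = {c: 0 for c in scope}
                new_total = 0
        elif ready(new_counts, cfg.n_update_tpc, new_total):
            try:
                clf, rep = calibrate_features(
                    _subset_features(feat, collected),
                    labels[collected],
                    model.class_pair,
                    timing,
                    cfg.feature_selection,
                )
            except CalibrationDeferred:  # pragma: no cover - defensive
                continue
            models.append(ModelEvent(i, len(models) + 1, clf, rep))
            model = clf
            new_counts = {c: 0 for c in scope}
            new_total = 0

    return AdaptiveSessionResult(
        records=records,
        models=models,
        selected_pair=selected_pair,
        timing=timing,
        first_valid_sample=fv,
    )
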