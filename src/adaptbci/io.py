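"""Reading and writing sessions, events and results.

Epoched sessions travel as NPZ containers with named fields mirroring
:class:`~adaptbci.preprocessing.EpochedSession`; continuous EEG can come
from EDF files (via :mod:`mne`, an optional dependency) with cue events in
a two-column TSV ``(onset_seconds, label)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import EpochedSession, TrialTiming

__all__ = [
    "save_session",
    "load_session",
    "read_events_tsv",
    "write_events_tsv",
    "read_edf",
    "save_result_json",
]

_TIMING_FIELDS = (
    "relax_start",
    "relax_end",
    "cue_onset",
    "imagery_end_analysis",
    "trial_end",
    "fs",
)


def save_session(path, session: EpochedSession) -> None:
    """Write a session to an NPZ container."""
    np.savez_compressed(
        path,
        epochs=session.epochs,
        labels=np.asarray(session.labels, dtype=str),
        channel_labels=np.asarray(session.channel_labels, dtype=str),
        artifact_flags=session.artifact_flags,
        timing=np.asarray([getattr(session.timing, f) for f in _TIMING_FIELDS]),
        rejection_log=np.asarray(
            json.dumps([[list(entry) for entry in trial] for trial in session.rejection_log])
        ),
    )


def load_session(path) -> EpochedSession:
    with np.load(path, allow_pickle=False) as data:
        timing = TrialTiming(**dict(zip(_TIMING_FIELDS, data["timing"].tolist())))
        log = json.loads(str(data["rejection_log"]))
        return EpochedSession(
            epochs=data["epochs"],
            labels=data["labels"].astype(object),
            timing=timing,
            channel_labels=[str(c) for c in data["channel_labels"]],
            artifact_flags=data["artifact_flags"],
            rejection_log=[[tuple(e) for e in trial] for trial in log],
        )


def read_events_tsv(path) -> list[tuple[float, str]]:
    """Cue events from a TSV with columns ``onset_seconds`` and ``label``."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset_seconds", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"events file needs columns {sorted(required)}, has {list(df.columns)}")
    return [(float(t), str(lab)) for t, lab in zip(df.onset_seconds, df.label)]


def write_events_tsv(path, events) -> None:
    pd.DataFrame(events, columns=["onset_seconds", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_edf(path) -> tuple[np.ndarray, list[str], float]:
    """Continuous EEG from an EDF file: (data μV, channel labels, fs).

    Requires :mod:`mne` (``pip install adaptbci[edf]``); MNE returns volts,
    converted here to μV.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input needs the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, list(raw.ch_names), float(raw.info["sfreq"])


def save_result_json(path, result) -> None:
    """Persist an adaptive run: per-trial outcomes, model lineage, pair."""
    out = {
        "selected_pair": list(result.selected_pair) if result.selected_pair else None,
        "calibrated": result.calibrated,
        "n_evaluated": result.n_evaluated,
        "rejected_fraction": result.rejected_fraction,
        "models": [
            {
                "arrival_index": m.arrival_index,
                "version": m.version,
                "class_pair": list(m.classifier.class_pair),
                "selected_features": [list(f) for f in m.classifier.selected_features],
                "train_window": list(m.classifier.train_window),
                "loocv_median_accuracy": m.classifier.loocv_median_accuracy,
                "report": m.report.to_dict(),
            }
            for m in result.models
        ],
        "trials": [
            {
                "arrival_index": r.arrival_index,
                "label": r.label,
                "in_scope": r.in_scope,
                "artifact": r.artifact,
                "rejection_reasons": [list(x) for x in r.rejection_reasons],
                "model_version": r.model_version,
            }
            for r in result.records
        ],
    }
    Path(path).write_text(json.dumps(out, indent=2))
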