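"""Scoring of session logs and cross-algorithm comparison.

A session is scored on a fixed middle window: the first 60 s (the
training warm-up, during which the subject also settles into the task) and
the last 10 s (anticipation of the session's end) are discarded, and the
centred 400 rows of the remainder — 40 s at the 10 Hz logging rate — are
compared marker-against-prediction.  Accuracy is the fraction of matching
rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .protocol import SessionLog


class ShortLogError(ValueError):
    pass


@dataclass(frozen=True)
class EvaluationWindow:
    skip_head_s: float = 60.0
    skip_tail_s: float = 10.0
    n_rows: int = 400

    def __post_init__(self):
        if self.n_rows <= 0:
            raise ValueError("n_rows must be positive")


def select_scoring_rows(
    log: SessionLog, window: EvaluationWindow = EvaluationWindow()
) -> SessionLog:
    """Return the centred ``n_rows`` scoring rows of a log.

    Rows before ``skip_head_s`` and at or after ``duration - skip_tail_s``
    are dropped first.  When more than ``n_rows`` remain, the selection is
    centred; an odd surplus drops the extra row at the head.
    """
    if len(log) == 0:
        raise ShortLogError("empty log")
    if "duration_s" in log.meta:
        duration = float(log.meta["duration_s"])
    else:
        dt = np.median(np.diff(log.times)) if len(log) > 1 else 0.0
        duration = float(log.times[-1]) + float(dt)
    keep = (log.times >= window.skip_head_s) & (
        log.times < duration - window.skip_tail_s
    )
    idx = np.flatnonzero(keep)
    if idx.size < window.n_rows:
        rate = 1.0 / np.median(np.diff(log.times)) if len(log) > 1 else 10.0
        min_duration = window.skip_head_s + window.skip_tail_s + window.n_rows / rate
        raise ShortLogError(
            f"only {idx.size} rows remain after discarding the first "
            f"{window.skip_head_s:g} s and last {window.skip_tail_s:g} s; "
            f"{window.n_rows} are required (log must span at least "
            f"{min_duration:g} s)"
        )
    surplus = idx.size - window.n_rows
    head_drop = (surplus + 1) // 2  # odd surplus: extra row dropped at the head
    idx = idx[head_drop : head_drop + window.n_rows]
    return SessionLog(
        log.times[idx], log.markers[idx], log.predictions[idx], dict(log.meta)
    )


def accuracy(log: SessionLog) -> float:
    """Fraction of rows whose prediction matches the marker."""
    if len(log) == 0:
        raise ValueError("cannot score an empty set of rows")
    return float(np.mean(log.markers == log.predictions))


def score_log(log: SessionLog, window: EvaluationWindow = EvaluationWindow()) -> float:
    return accuracy(select_scoring_rows(log, window))


@dataclass
class AlgorithmSummary:
    """Per-run accuracies plus per-algorithm and per-subject means."""

    per_run: pd.DataFrame  # columns: subject, algorithm, accuracy
    per_algorithm: pd.Series  # mean accuracy indexed by algorithm
    per_subject_algorithm: pd.Series  # mean indexed by (subject, algorithm)

    def to_csv(self, path) -> None:
        self.per_run.to_csv(path, index=False)


def summarize(results) -> AlgorithmSummary:
    """Aggregate (subject, algorithm, accuracy) records.

    ``results`` is any iterable of 3-tuples or a DataFrame with those
    columns.  The per-algorithm mean is the plain arithmetic mean over all
    of that algorithm's runs; ordering of the input does not matter.
    """
    if isinstance(results, pd.DataFrame):
        frame = results.loc[:, ["subject", "algorithm", "accuracy"]].copy()
    else:
        frame = pd.DataFrame(results, columns=["subject", "algorithm", "accuracy"])
    if frame.empty:
        raise ValueError("no results to summarize")
    bad = frame[(frame["accuracy"] < 0) | (frame["accuracy"] > 1)]
    if not bad.empty:
        raise ValueError("accuracies must lie in [0, 1]")
    per_algorithm = (
        frame.groupby("algorithm", sort=True)["accuracy"].mean().rename("mean_accuracy")
    )
    per_subject_algorithm = (
        frame.groupby(["subject", "algorithm"], sort=True)["accuracy"]
        .mean()
        .rename("mean_accuracy")
    )
    return AlgorithmSummary(
        frame.reset_index(drop=True), per_algorithm, per_subject_algorithm
    )


_ALGORITHM_ALIASES = {
    "backpropagation": "backprop",
    "resilient backpropagation": "rprop",
    "levenberg-marquardt": "levenberg_marquardt",
    "error correction": "error_correction",
}


def load_reference_results() -> pd.DataFrame:
    """Load the bundled live-EEG reference accuracy table.

    The table reproduces, verbatim, the accuracies reported for the
    original hardware sessions this pipeline re-implements (decimal commas
    in the source are converted to points; algorithm names are normalized
    to this package's identifiers).  The ``beep_interval_s`` column flags
    the early 5-second-interval runs, which used a different protocol
    setting from the 10-second standard.
    """
    with resources.files("rhythmnet.data").joinpath(
        "reference_sessions.csv"
    ).open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    frame["accuracy"] = (
        frame["accuracy"].astype(str).str.replace(",", ".", regex=False).astype(float)
    )
    key = frame["algorithm"].str.strip().str.lower().str.replace("–", "-")
    frame["algorithm"] = key.map(_ALGORITHM_ALIASES).fillna(frame["algorithm"])
    frame = frame.rename(columns={"beep": "beep_interval_s"})
    return frame
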