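"""Timed session protocol: markers, warm-up training, prediction logging.

A session follows the auditory-marker protocol: a tone alternates the
requested brain state every ``interval_s`` seconds (state 0 announced by a
1500 Hz high tone, state 1 by a 1000 Hz low tone; the tones are carried as
log metadata only).  During the first ``warmup_s`` seconds the pipeline
accumulates (feature vector, marker state) pairs — starting once the
10-second sample buffer has first filled — then fits the feature
normalization and trains the network on them.  From ``warmup_s`` to the end
of the session it logs one ``(time, marker, prediction)`` row per logging
tick (10 Hz by default, so a 110 s session yields 500 prediction rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import DEFAULT_BUFFER_CAPACITY, SampleStream
from .neural import Network, TrainerConfig, init_network, train
from .rhythms import (
    DEFAULT_AMPLITUDE_SAMPLES,
    FEATURE_BANDS,
    FilterSpec,
    decompose,
    feature_bank,
)

TONE_STATE0_HZ = 1500.0  # high tone: rest / eyes open
TONE_STATE1_HZ = 1000.0  # low tone: task / eyes closed


class TruncatedSessionError(RuntimeError):
    def __init__(self, time_reached_s: float, duration_s: float):
        super().__init__(
            f"sample source exhausted at t={time_reached_s:.2f} s of a "
            f"{duration_s:.2f} s session"
        )
        self.time_reached_s = time_reached_s


class LogParseError(ValueError):
    def __init__(self, message: str, row_number: int):
        super().__init__(f"{message} (row {row_number})")
        self.row_number = row_number


@dataclass(frozen=True)
class MarkerTrack:
    """Alternating 0/1 marker schedule: state(t) = floor(t/interval) mod 2."""

    interval_s: float
    duration_s: float
    tone_state0_hz: float = TONE_STATE0_HZ
    tone_state1_hz: float = TONE_STATE1_HZ

    def __post_init__(self):
        if self.interval_s <= 0 or self.duration_s <= 0:
            raise ValueError("interval_s and duration_s must be positive")

    def state(self, t):
        """Marker state at time(s) ``t`` (scalar or array), starting at 0."""
        t = np.asarray(t, dtype=float)
        # tiny epsilon so ticks computed as k/rate land on the correct side
        # of an interval boundary despite float rounding
        s = (np.floor((t + 1e-9) / self.interval_s).astype(np.int64)) % 2
        return s if s.ndim else int(s)


def marker_schedule(duration_s: float, interval_s: float = 10.0) -> MarkerTrack:
    return MarkerTrack(interval_s=interval_s, duration_s=duration_s)


@dataclass
class SessionConfig:
    """Everything needed to replay a session deterministically."""

    trainer: TrainerConfig = field(default_factory=TrainerConfig)
    warmup_s: float = 60.0
    log_rate_hz: float = 10.0
    interval_s: float = 10.0
    duration_s: float = 110.0
    seed: int = 0
    buffer_capacity: int = DEFAULT_BUFFER_CAPACITY
    normalize: bool = True
    continue_training: bool = False
    bank: list[FilterSpec] | None = None
    #: Latency (s) between a brain-state change and its appearance in the
    #: feature vector: the filter group delay plus half the amplitude
    #: averaging span.  Warm-up training labels are taken at
    #: ``marker(t - latency)`` so the network learns from labels aligned
    #: with what the features actually reflect.  ``None`` computes it from
    #: the filter bank; set 0.0 to disable compensation.
    label_latency_s: float | None = None

    def __post_init__(self):
        if self.duration_s <= self.warmup_s + 10.0:
            raise ValueError(
                "duration_s must exceed warmup_s by more than the 10 s "
                "tail discarded at evaluation"
            )
        if self.log_rate_hz <= 0:
            raise ValueError("log_rate_hz must be positive")


@dataclass
class SessionLog:
    """Time-aligned marker and prediction rows at the logging rate."""

    times: np.ndarray
    markers: np.ndarray
    predictions: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.markers = np.asarray(self.markers, dtype=np.int64)
        self.predictions = np.asarray(self.predictions, dtype=np.int64)
        if not (len(self.times) == len(self.markers) == len(self.predictions)):
            raise ValueError("log columns must have equal length")
        for name, col in (("marker", self.markers), ("prediction", self.predictions)):
            if col.size and not np.isin(col, (0, 1)).all():
                raise ValueError(f"{name} column contains non-binary values")

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionLog):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.markers, other.markers)
            and np.array_equal(self.predictions, other.predictions)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "marker": self.markers,
                "prediction": self.predictions,
            }
        )


@dataclass
class SessionResult:
    """Output of :func:`run_session`: the log plus the trained network."""

    log: SessionLog
    network: Network
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    warmup_mse: float


def _normalization(features: np.ndarray):
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)  # flat feature: leave it centred only
    return mean, sd


def run_session(source: SampleStream, config: SessionConfig) -> SessionResult:
    """Run the full pipeline over a sample stream.

    Phase 1 (buffer-fill to ``warmup_s``): collect feature/marker pairs at
    the logging cadence, labelling each feature vector with the marker
    state at ``t - label_latency_s`` — the state the features actually
    reflect, given the filter group delay and amplitude averaging.  At
    ``warmup_s``: freeze the z-score normalization and train the network.
    Phase 2: one logged prediction row per tick until ``duration_s``.
    Bit-identical for identical (source, config).
    """
    fs = source.sampling_rate_hz
    x = source.samples.astype(float)
    needed = int(round(config.duration_s * fs))
    if len(x) < needed:
        raise TruncatedSessionError(len(x) / fs, config.duration_s)

    bank = config.bank if config.bank is not None else feature_bank(fs)
    markers = marker_schedule(config.duration_s, config.interval_s)
    capacity = config.buffer_capacity
    dt_ticks = 1.0 / config.log_rate_hz
    fill_s = capacity / fs
    if config.label_latency_s is None:
        latency = max(
            spec.group_delay_s + DEFAULT_AMPLITUDE_SAMPLES / (2.0 * fs)
            for spec in bank
        )
    else:
        latency = config.label_latency_s

    def features_at(t: float) -> np.ndarray:
        n = int(round(t * fs))
        frame = decompose(x[n - capacity : n], bank)
        return frame.features(FEATURE_BANDS)

    # Phase 1: warm-up accumulation
    warm_X, warm_T = [], []
    k = 0
    while True:
        t = k * dt_ticks
        if t >= config.warmup_s:
            break
        if t >= fill_s:
            warm_X.append(features_at(t))
            warm_T.append(markers.state(max(t - latency, 0.0)))
        k += 1
    warm_X = np.asarray(warm_X)
    warm_T = np.asarray(warm_T, dtype=float)

    if config.normalize:
        mean, sd = _normalization(warm_X)
    else:
        mean = np.zeros(warm_X.shape[1])
        sd = np.ones(warm_X.shape[1])
    Z = (warm_X - mean) / sd

    net = init_network(config.trainer.network_sizes(), config.seed)
    net = train(net, Z, warm_T, config.trainer)
    from .neural import mse as _mse  # local import avoids a public re-export

    warmup_mse = _mse(net, Z, warm_T)

    # Phase 2: prediction logging (optionally with periodic retraining)
    times, marks, preds = [], [], []
    retrain_ticks = int(round(config.interval_s * config.log_rate_hz))
    while True:
        t = k * dt_ticks
        if t >= config.duration_s:
            break
        feats = features_at(t)
        z = (feats - mean) / sd
        state = markers.state(t)
        times.append(t)
        marks.append(state)
        preds.append(int(net.forward(z) > 0.5))
        if config.continue_training:
            warm_X = np.vstack([warm_X, feats])
            warm_T = np.append(warm_T, float(markers.state(max(t - latency, 0.0))))
            if retrain_ticks and (len(times) % retrain_ticks == 0):
                Z_all = (warm_X - mean) / sd
                net = train(net, Z_all, warm_T, config.trainer)
        k += 1

    log = SessionLog(
        np.asarray(times),
        np.asarray(marks),
        np.asarray(preds),
        meta={
            "seed": config.seed,
            "trainer": config.trainer.algorithm,
            "interval_s": config.interval_s,
            "log_rate_hz": config.log_rate_hz,
            "warmup_s": config.warmup_s,
            "duration_s": config.duration_s,
            "tone_state0_hz": TONE_STATE0_HZ,
            "tone_state1_hz": TONE_STATE1_HZ,
        },
    )
    return SessionResult(log, net, mean, sd, warmup_mse)


# ---------------------------------------------------------------------------
# Log files

_HEADER_KEYS = (
    "seed",
    "trainer",
    "interval_s",
    "log_rate_hz",
    "warmup_s",
    "duration_s",
    "tone_state0_hz",
    "tone_state1_hz",
)


def write_log(log: SessionLog, path) -> None:
    """Write ``# key=value`` header lines then ``time_s,marker,prediction``."""
    with open(path, "w", newline="\n") as fh:
        for key in _HEADER_KEYS:
            if key in log.meta:
                fh.write(f"# {key}={log.meta[key]}\n")
        fh.write("time_s,marker,prediction\n")
        for t, m, p in zip(log.times, log.markers, log.predictions):
            # shortest float repr round-trips exactly through the reader
            fh.write(f"{float(t)!r},{int(m)},{int(p)}\n")


def _parse_binary(token: str, row: int, column: str) -> int:
    token = token.strip()
    if token not in ("0", "1"):
        raise LogParseError(f"non-binary {column} value {token!r}", row)
    return int(token)


def read_log(path, log_rate_hz: float = 10.0, t0: float = 0.0) -> SessionLog:
    """Read a session log.

    Accepts the native format (``# key=value`` header plus
    ``time_s,marker,prediction`` CSV rows) and, for interoperability, the
    legacy two-row layout — first row the markers, second row the
    predictions — in which case times are synthesized at ``log_rate_hz``
    starting from ``t0``.
    """
    meta: dict = {}
    data_lines: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = _coerce(value.strip())
                continue
            if text.lower().replace(" ", "") == "time_s,marker,prediction":
                continue
            data_lines.append((lineno, text))

    if not data_lines:
        return SessionLog(np.empty(0), np.empty(0, int), np.empty(0, int), meta)

    first_fields = data_lines[0][1].replace(",", " ").split()
    two_row = len(data_lines) == 2 and len(first_fields) > 3
    if two_row:
        rows = []
        for row_number, (_, text) in enumerate(data_lines, start=1):
            rows.append(
                [
                    _parse_binary(tok, row_number, "state")
                    for tok in text.replace(",", " ").split()
                ]
            )
        if len(rows[0]) != len(rows[1]):
            raise LogParseError("marker and prediction rows differ in length", 2)
        rate = float(meta.get("log_rate_hz", log_rate_hz))
        times = t0 + np.arange(len(rows[0])) / rate
        return SessionLog(times, rows[0], rows[1], meta)

    times, marks, preds = [], [], []
    for row_number, (_, text) in enumerate(data_lines, start=1):
        parts = text.split(",")
        if len(parts) != 3:
            raise LogParseError(f"expected 3 comma-separated fields, got {len(parts)}", row_number)
        try:
            times.append(float(parts[0]))
        except ValueError:
            raise LogParseError(f"bad time value {parts[0]!r}", row_number) from None
        marks.append(_parse_binary(parts[1], row_number, "marker"))
        preds.append(_parse_binary(parts[2], row_number, "prediction"))
    return SessionLog(np.asarray(times), marks, preds, meta)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value
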