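"""Sample sources and the rolling buffer that feeds the filter bank.

The raw signal is a stream of 10-bit ADC counts (0--1023) sampled at a
nominal 100 Hz, as produced by a single-channel EEG amplifier read through a
microcontroller's analogue input.  Three interchangeable sources share the
:class:`SampleStream` contract:

* an in-memory stream (e.g. from the synthetic generator),
* a plain-text replay file (one decimal integer per line),
* a self-synchronizing 2-byte serial frame format.

The serial frame dialect packs each 10-bit sample into two bytes::

    high byte = 0x80 | (value >> 7)     # sync bit set, top 3 bits
    low  byte = value & 0x7F            # sync bit clear, bottom 7 bits

Because the sync bit (MSB) is set only on the first byte of a frame, a
reader can always re-align after byte loss by scanning for the next byte
with the MSB set.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ADC_MAX = 1023
DEFAULT_SAMPLING_RATE_HZ = 100.0
DEFAULT_BUFFER_CAPACITY = 1000

_SYNC = 0x80


class RangeError(ValueError):
    """A sample value falls outside the 10-bit ADC range [0, 1023]."""


class FrameCorruptionError(ValueError):
    """A serial frame decoded to an impossible sample value."""

    def __init__(self, message: str, byte_offset: int):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset


class ReplayParseError(ValueError):
    """A replay file line could not be parsed as an in-range integer."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"{message} (line {line_number})")
        self.line_number = line_number


def _as_sample_array(samples) -> np.ndarray:
    arr = np.asarray(samples)
    if arr.size == 0:
        return arr.astype(np.int64).reshape(0)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.array_equal(rounded, arr):
            raise RangeError("samples must be integers (10-bit ADC counts)")
        arr = rounded
    arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > ADC_MAX:
        raise RangeError(
            f"sample values must lie in [0, {ADC_MAX}]; "
            f"got range [{arr.min()}, {arr.max()}]"
        )
    return arr


@dataclass
class SampleStream:
    """An ordered sequence of ADC counts with an implicit uniform time base.

    Sample ``i`` is located at time ``t0 + i / sampling_rate_hz`` seconds.
    """

    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.samples = _as_sample_array(self.samples)

    def __len__(self) -> int:
        return int(self.samples.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleStream):
            return NotImplemented
        return (
            self.sampling_rate_hz == other.sampling_rate_hz
            and self.t0 == other.t0
            and np.array_equal(self.samples, other.samples)
        )

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.sampling_rate_hz


class RingBuffer:
    """Keeps the most recent ``capacity`` samples in arrival order.

    With the default capacity of 1000 samples at 100 Hz the buffer spans a
    10-second analysis window.
    """

    def __init__(self, capacity: int = DEFAULT_BUFFER_CAPACITY):
        if capacity <= 0:
            raise ValueError("capacity must be a positive integer")
        self.capacity = int(capacity)
        self._items: deque = deque(maxlen=self.capacity)

    def push(self, sample: int) -> "RingBuffer":
        value = int(sample)
        if value != sample or not (0 <= value <= ADC_MAX):
            raise RangeError(f"sample {sample!r} outside [0, {ADC_MAX}]")
        self._items.append(value)
        return self

    def extend(self, samples) -> "RingBuffer":
        for s in samples:
            self.push(s)
        return self

    def __len__(self) -> int:
        return len(self._items)

    @property
    def full(self) -> bool:
        return len(self._items) == self.capacity

    def snapshot(self) -> np.ndarray:
        """Current contents, oldest first."""
        return np.fromiter(self._items, dtype=np.int64, count=len(self._items))


# ---------------------------------------------------------------------------
# Serial frame format


def encode_frame_stream(samples) -> bytes:
    """Encode samples into the 2-byte self-synchronizing frame dialect."""
    arr = _as_sample_array(samples)
    out = bytearray()
    for v in arr:
        out.append(_SYNC | (int(v) >> 7))
        out.append(int(v) & 0x7F)
    return bytes(out)


def parse_frame_stream(
    data: bytes, sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
) -> SampleStream:
    """Decode a byte stream of 2-byte frames into a :class:`SampleStream`.

    Stray bytes before a sync byte are skipped (resynchronization); a
    truncated trailing frame is discarded.  Both counts are recorded in the
    returned stream's ``meta`` under ``"skipped_bytes"`` and
    ``"discarded_trailing_bytes"``.

    Raises
    ------
    FrameCorruptionError
        If a complete frame decodes to a value above 1023 (cannot happen
        for streams produced by :func:`encode_frame_stream`).
    """
    values: list[int] = []
    skipped = 0
    discarded_trailing = 0
    i = 0
    n = len(data)
    while i < n:
        b = data[i]
        if not b & _SYNC:
            skipped += 1  # low byte without a preceding high byte
            i += 1
            continue
        if i + 1 >= n:
            discarded_trailing = 1  # lone high byte at end of stream
            break
        lo = data[i + 1]
        if lo & _SYNC:
            skipped += 1  # high byte followed by another high byte: lost low
            i += 1
            continue
        value = ((b & 0x7F) << 7) | lo
        if value > ADC_MAX:
            raise FrameCorruptionError(
                f"decoded sample {value} exceeds {ADC_MAX}", byte_offset=i
            )
        values.append(value)
        i += 2
    stream = SampleStream(np.asarray(values, dtype=np.int64), sampling_rate_hz)
    stream.meta["skipped_bytes"] = skipped
    stream.meta["discarded_trailing_bytes"] = discarded_trailing
    return stream


# ---------------------------------------------------------------------------
# Replay files


def write_replay(stream: SampleStream, path) -> None:
    """Write a stream as plain text, one decimal integer per line (LF)."""
    with open(path, "w", newline="\n") as fh:
        for v in stream.samples:
            fh.write(f"{int(v)}\n")


def replay_source(
    path, sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
) -> SampleStream:
    """Load a replay file (one decimal integer per line) as a stream."""
    values: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                value = int(text)
            except ValueError:
                raise ReplayParseError(
                    f"not a decimal integer: {text!r}", line_number=lineno
                ) from None
            if not (0 <= value <= ADC_MAX):
                raise ReplayParseError(
                    f"value {value} outside [0, {ADC_MAX}]", line_number=lineno
                )
            values.append(value)
    stream = SampleStream(np.asarray(values, dtype=np.int64), sampling_rate_hz)
    stream.meta["path"] = str(Path(path))
    return stream
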