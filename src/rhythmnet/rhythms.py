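"""Band-pass filter bank for the clinical EEG rhythm bands.

The pipeline separates the raw signal into the classical rhythm bands —
delta (0.5–3 Hz), alpha (8–13 Hz), the beta range (16–31 Hz, here split
into three sub-bands with a 13–16 Hz low-beta gap filler) and gamma — and
summarizes each band by its mean absolute amplitude over the analysis
window.  Five of those amplitudes (alpha, beta0, beta1, beta2, delta) form
the feature vector fed to the classifier network.

Two filter realizations satisfy the same frequency-response contract
(passband gain within ±1 dB at the band centre, at least 20 dB of
attenuation at DC and at the Nyquist frequency):

``fir_linear_phase``
    A windowed-sinc (Hamming) linear-phase FIR design, 401 taps at a
    100 Hz sampling rate.  Linear phase keeps the band traces time-aligned
    with each other, and the exactly known group delay lets the amplitude
    estimator discard the startup transient.
``iir_butterworth``
    A 4th-order Butterworth band-pass in second-order sections, offered
    because the maximally flat magnitude characteristic is the classical
    reference response the FIR design approximates.

Note that gamma as usually quoted (32–100 Hz) exceeds the Nyquist
frequency of a 100 Hz stream; the default band table clips it to
32–45 Hz and the feature vector excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .acquisition import RingBuffer

DEFAULT_SAMPLING_RATE_HZ = 100.0
DEFAULT_FIR_TAPS = 401
DEFAULT_IIR_ORDER = 4

#: Order of the five amplitude features fed to the network.
FEATURE_BANDS = ("alpha", "beta0", "beta1", "beta2", "delta")

FIR_LINEAR_PHASE = "fir_linear_phase"
IIR_BUTTERWORTH = "iir_butterworth"


class FilterDesignError(ValueError):
    pass


class NotReadyError(RuntimeError):
    """The buffer is not yet full; the caller should keep acquiring."""


class InsufficientDataError(ValueError):
    """The window is shorter than the filter's impulse response."""


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid band edges {self.low_hz}-{self.high_hz} Hz")


def default_bands(sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ):
    """The default rhythm band table (gamma clipped below Nyquist)."""
    gamma_high = min(100.0, 0.9 * sampling_rate_hz / 2)
    return (
        BandDefinition("delta", 0.5, 3.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta0", 13.0, 16.0),
        BandDefinition("beta1", 16.0, 23.0),
        BandDefinition("beta2", 23.0, 31.0),
        BandDefinition("gamma", 32.0, gamma_high),
    )


@dataclass
class FilterSpec:
    """A designed band-pass filter plus the metadata needed to apply it."""

    band: BandDefinition
    mode: str
    taps_or_order: int
    sampling_rate_hz: float
    coefficients: np.ndarray  # FIR taps, or SOS array for the IIR mode

    @property
    def settle_samples(self) -> int:
        """Startup-transient length the amplitude estimator discards."""
        if self.mode == FIR_LINEAR_PHASE:
            return len(self.coefficients) - 1
        # IIR transients decay exponentially; 2 s covers the default bands.
        return int(round(2.0 * self.sampling_rate_hz))

    @property
    def group_delay_s(self) -> float:
        """Signal delay through the filter, in seconds.

        Exact for the linear-phase FIR ((taps-1)/2 samples); taken as zero
        for the IIR mode, whose passband group delay is small and
        frequency-dependent.
        """
        if self.mode == FIR_LINEAR_PHASE:
            return (len(self.coefficients) - 1) / (2.0 * self.sampling_rate_hz)
        return 0.0

    def frequency_response(self, freqs_hz) -> np.ndarray:
        """Complex gain at the given frequencies (direct evaluation)."""
        freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
        if self.mode == FIR_LINEAR_PHASE:
            n = np.arange(len(self.coefficients))
            expo = np.exp(
                -2j * np.pi * freqs_hz[:, None] * n[None, :] / self.sampling_rate_hz
            )
            return expo @ self.coefficients
        _, h = sps.sosfreqz(
            self.coefficients, worN=2 * np.pi * freqs_hz / self.sampling_rate_hz
        )
        return h


def design_bandpass(
    band: BandDefinition,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    mode: str = FIR_LINEAR_PHASE,
    taps_or_order: int | None = None,
) -> FilterSpec:
    """Design one band-pass filter and verify it is realizable.

    Raises :class:`FilterDesignError` when the upper band edge reaches the
    Nyquist frequency; the caller should clip the band below Nyquist (as
    :func:`default_bands` does for gamma).
    """
    nyquist = sampling_rate_hz / 2
    if band.high_hz >= nyquist:
        raise FilterDesignError(
            f"band {band.name} ({band.low_hz}-{band.high_hz} Hz) reaches the "
            f"Nyquist frequency {nyquist} Hz; clip the band below Nyquist"
        )
    if mode == FIR_LINEAR_PHASE:
        numtaps = DEFAULT_FIR_TAPS if taps_or_order is None else int(taps_or_order)
        if numtaps % 2 == 0:
            raise FilterDesignError("FIR band-pass needs an odd tap count")
        coeffs = sps.firwin(
            numtaps,
            [band.low_hz, band.high_hz],
            pass_zero=False,
            window="hamming",
            fs=sampling_rate_hz,
        )
        return FilterSpec(band, mode, numtaps, sampling_rate_hz, coeffs)
    if mode == IIR_BUTTERWORTH:
        order = DEFAULT_IIR_ORDER if taps_or_order is None else int(taps_or_order)
        sos = sps.butter(
            order,
            [band.low_hz, band.high_hz],
            btype="bandpass",
            fs=sampling_rate_hz,
            output="sos",
        )
        spec = FilterSpec(band, mode, order, sampling_rate_hz, sos)
        if not _iir_stable(sos):
            raise FilterDesignError(
                f"IIR design for band {band.name} is numerically unstable"
            )
        return spec
    raise FilterDesignError(f"unknown filter mode {mode!r}")


def _iir_stable(sos: np.ndarray) -> bool:
    for section in sos:
        poles = np.roots(section[3:])
        if np.any(np.abs(poles) >= 1.0):
            return False
    return True


def design_bank(
    bands=None,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    mode: str = FIR_LINEAR_PHASE,
    taps_or_order: int | None = None,
) -> list[FilterSpec]:
    if bands is None:
        bands = default_bands(sampling_rate_hz)
    return [design_bandpass(b, sampling_rate_hz, mode, taps_or_order) for b in bands]


def feature_bank(
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    mode: str = FIR_LINEAR_PHASE,
    taps_or_order: int | None = None,
) -> list[FilterSpec]:
    """The five-band bank behind the network's feature vector."""
    by_name = {b.name: b for b in default_bands(sampling_rate_hz)}
    bands = [by_name[name] for name in FEATURE_BANDS]
    return design_bank(bands, sampling_rate_hz, mode, taps_or_order)


def apply_filter(spec: FilterSpec, window) -> np.ndarray:
    """Filter a window; output has the input length (zero-state startup).

    FIR filtering is evaluated by FFT convolution, which is numerically
    identical (to ~1e-10 absolute) to direct-form convolution.
    """
    x = np.asarray(window, dtype=float)
    if spec.mode == FIR_LINEAR_PHASE:
        if len(x) < len(spec.coefficients):
            raise InsufficientDataError(
                f"window of {len(x)} samples is shorter than the "
                f"{len(spec.coefficients)}-tap filter"
            )
        return sps.fftconvolve(x, spec.coefficients)[: len(x)]
    return sps.sosfilt(spec.coefficients, x)


def mean_amplitude(x) -> float:
    """Mean absolute value of a signal — the pipeline's amplitude measure."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mean_amplitude of an empty signal is undefined")
    return float(np.mean(np.abs(x)))


@dataclass
class RhythmFrame:
    """One buffer snapshot decomposed into rhythm bands.

    ``band_amplitudes`` are mean absolute amplitudes (in ADC counts) of the
    steady-state portion of each filtered trace; ``raw_amplitude`` is the
    mean absolute deviation of the unfiltered window from its mean.
    """

    band_signals: dict[str, np.ndarray]
    band_amplitudes: dict[str, float]
    raw_amplitude: float
    sampling_rate_hz: float

    def features(self, order=FEATURE_BANDS) -> np.ndarray:
        missing = [b for b in order if b not in self.band_amplitudes]
        if missing:
            raise KeyError(f"frame lacks bands {missing}")
        return np.asarray([self.band_amplitudes[b] for b in order], dtype=float)


#: Trailing steady-state span (samples) over which band amplitudes are
#: averaged.  The pipeline is an online detector: the causal linear-phase
#: filter already delays its output by (taps-1)/2 samples (2 s at the
#: defaults), so averaging only the most recent 2 s of valid output keeps
#: the feature responsive to state changes instead of smearing it across
#: half a marker interval.
DEFAULT_AMPLITUDE_SAMPLES = 200


def decompose(
    buffer,
    bank: list[FilterSpec],
    amplitude_samples: int = DEFAULT_AMPLITUDE_SAMPLES,
) -> RhythmFrame:
    """Split a full buffer window into band traces and mean amplitudes.

    The window mean (DC offset, nominally the ADC midpoint) is subtracted
    before filtering.  Each band amplitude is the mean absolute value of
    the trailing ``amplitude_samples`` of the filtered trace, restricted
    to the post-transient (``settle_samples``) region so that the estimate
    reflects steady-state gain.
    """
    if isinstance(buffer, RingBuffer):
        if not buffer.full:
            raise NotReadyError(
                f"buffer holds {len(buffer)}/{buffer.capacity} samples"
            )
        window = buffer.snapshot().astype(float)
    else:
        window = np.asarray(buffer, dtype=float)
    if window.size == 0:
        raise NotReadyError("empty window")
    centred = window - window.mean()
    fs = bank[0].sampling_rate_hz
    band_signals: dict[str, np.ndarray] = {}
    band_amplitudes: dict[str, float] = {}
    for spec in bank:
        trace = apply_filter(spec, centred)
        settle = min(spec.settle_samples, len(trace) - 1)
        start = max(settle, len(trace) - amplitude_samples)
        band_signals[spec.band.name] = trace
        band_amplitudes[spec.band.name] = mean_amplitude(trace[start:])
    return RhythmFrame(band_signals, band_amplitudes, mean_amplitude(centred), fs)


def alpha_ratio(frame: RhythmFrame) -> float:
    """Alpha-to-raw amplitude ratio scaled by 1000.

    This is the quantity plotted during the eyes-open/eyes-closed
    reactivity check: the ratio rises when the eyes close and the alpha
    rhythm strengthens.  Returns NaN when the raw amplitude is zero (a
    flat window), rather than raising.
    """
    if frame.raw_amplitude == 0:
        return float("nan")
    return 1000.0 * frame.band_amplitudes["alpha"] / frame.raw_amplitude


def coefficients_table(spec: FilterSpec):
    """Filter coefficients as a DataFrame, for CSV export and inspection."""
    import pandas as pd

    if spec.mode == FIR_LINEAR_PHASE:
        return pd.DataFrame(
            {"tap": np.arange(len(spec.coefficients)), "coefficient": spec.coefficients}
        )
    cols = ["b0", "b1", "b2", "a0", "a1", "a2"]
    return pd.DataFrame(spec.coefficients, columns=cols)
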