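"""Seeded synthetic EEG source with state-dependent rhythm amplitudes.

Stands in for the amplifier-plus-subject hardware chain: each rhythm band
contributes a sinusoid whose frequency is drawn uniformly inside the band
(re-drawn at every marker interval, phase-continuous across the re-draw)
and whose amplitude depends on the current marker state.  Pink (1/f)
broadband noise and a constant ADC baseline are added before 10-bit
quantization.

The amplitude modulation emulates the two physiological effects the
pipeline is meant to detect: alpha power rising when the eyes close, and
beta power rising (with alpha suppression) during a mental-arithmetic
task.  It deliberately omits blinks, EMG bursts, spindles and slow
nonstationarity — the generator exists to give the pipeline a controlled,
reproducible effect size, not to imitate a particular subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import ADC_MAX, SampleStream
from .rhythms import BandDefinition, default_bands

DEFAULT_NOISE_SD = 10.0
DEFAULT_BASELINE = 512.0

#: Baseline per-band oscillation amplitudes in ADC counts (state 0).
_BASE_AMPLITUDES = {
    "delta": 20.0,
    "alpha": 30.0,
    "beta0": 10.0,
    "beta1": 10.0,
    "beta2": 8.0,
    "gamma": 5.0,
}

PRESET_NAMES = ("eo_ec_alpha", "task_beta", "null")


class PresetError(ValueError):
    pass


class ClippingError(ValueError):
    """The configured amplitudes drive the signal out of the ADC range."""


@dataclass
class StateAmplitudeModel:
    """Per-band, per-state oscillation amplitudes plus the noise model.

    ``band_amplitudes`` maps a band name to ``(state0, state1)`` amplitudes
    in ADC counts.  ``jitter`` widens the per-interval frequency draw by a
    multiplicative ``1 + jitter*U(-1, 1)`` wobble.
    """

    band_amplitudes: dict[str, tuple[float, float]]
    noise_sd: float = DEFAULT_NOISE_SD
    baseline: float = DEFAULT_BASELINE
    jitter: float = 0.0
    bands: tuple[BandDefinition, ...] = field(default_factory=default_bands)

    def __post_init__(self):
        for name, (a0, a1) in self.band_amplitudes.items():
            if a0 < 0 or a1 < 0:
                raise ValueError(f"negative amplitude for band {name}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def preset(name: str) -> StateAmplitudeModel:
    """Return one of the built-in amplitude models.

    ``eo_ec_alpha``
        Eyes-open/eyes-closed reactivity: alpha amplitude doubles in
        state 1, all other bands unchanged.
    ``task_beta``
        Mental-arithmetic task: the three beta sub-bands rise by 50% and
        alpha drops by 30% in state 1.
    ``null``
        No state dependence at all — the negative control that should
        drive the whole pipeline to chance-level accuracy.
    """
    base = dict(_BASE_AMPLITUDES)
    if name == "eo_ec_alpha":
        table = {b: (a, a) for b, a in base.items()}
        table["alpha"] = (base["alpha"], 2.0 * base["alpha"])
        return StateAmplitudeModel(table)
    if name == "task_beta":
        base["alpha"] = 40.0
        base["beta0"] = 12.0
        base["beta1"] = 12.0
        base["beta2"] = 10.0
        table = {b: (a, a) for b, a in base.items()}
        for b in ("beta0", "beta1", "beta2"):
            table[b] = (base[b], 1.5 * base[b])
        table["alpha"] = (base["alpha"], 0.7 * base["alpha"])
        return StateAmplitudeModel(table)
    if name == "null":
        return StateAmplitudeModel({b: (a, a) for b, a in base.items()})
    raise PresetError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


def _pink_noise(rng: np.random.Generator, n: int, sd: float, fs: float) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(np.maximum(freqs[1:], freqs[1]))
    pink = np.fft.irfft(spectrum * shaping, n)
    pink *= sd / pink.std()
    return pink


def generate_session(
    model: StateAmplitudeModel,
    markers,
    sampling_rate_hz: float = 100.0,
    seed: int = 0,
) -> SampleStream:
    """Synthesize one session's raw ADC stream for a marker schedule.

    ``markers`` is a :class:`~rhythmnet.protocol.MarkerTrack`; its duration
    and interval define the stream length and the amplitude switching.
    The same seed always yields a bit-identical stream.

    Raises :class:`ClippingError` if more than 0.1% of samples would be
    clipped at the ADC rails.
    """
    fs = float(sampling_rate_hz)
    n = int(round(markers.duration_s * fs))
    t = np.arange(n) / fs
    state = markers.state(t)
    rng = np.random.default_rng(seed)

    total = np.full(n, model.baseline, dtype=float)
    total += _pink_noise(rng, n, model.noise_sd, fs)

    n_intervals = int(np.ceil(markers.duration_s / markers.interval_s))
    samples_per_interval = int(round(markers.interval_s * fs))
    band_by_name = {b.name: b for b in model.bands}
    for name, (a0, a1) in model.band_amplitudes.items():
        band = band_by_name[name]
        freqs = rng.uniform(band.low_hz, band.high_hz, size=n_intervals)
        if model.jitter > 0:
            freqs = freqs * (1.0 + model.jitter * rng.uniform(-1, 1, size=n_intervals))
        inst_freq = np.repeat(freqs, samples_per_interval)[:n]
        phase = 2 * np.pi * np.cumsum(inst_freq) / fs  # phase-continuous FM
        amp = np.where(state == 1, a1, a0)
        total += amp * np.sin(phase)

    clipped = np.count_nonzero((total < 0) | (total > ADC_MAX))
    if clipped > 0.001 * n:
        raise ClippingError(
            f"{clipped}/{n} samples ({100*clipped/n:.2f}%) exceed the ADC "
            "range; reduce amplitudes, noise_sd or the baseline offset"
        )
    samples = np.clip(np.rint(total), 0, ADC_MAX).astype(np.int64)
    stream = SampleStream(samples, fs)
    stream.meta["seed"] = int(seed)
    return stream
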