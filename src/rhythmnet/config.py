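"""YAML configuration: band table, filter mode, trainer and session knobs.

All values have sensible defaults (the classical band edges, a 401-tap
linear-phase FIR bank, a 60 s warm-up / 110 s session at 10 Hz logging),
so a config file only needs to state what it overrides, e.g.::

    bands:
      alpha: [8, 13]
    filter:
      mode: fir_linear_phase
      taps_or_order: 401
    trainer:
      algorithm: levenberg_marquardt
      epochs: 50
    session:
      warmup_s: 60
      duration_s: 110
    synth:
      noise_sd: 10
"""

from __future__ import annotations

import copy

import yaml

from .neural import TrainerConfig
from .protocol import SessionConfig
from .rhythms import BandDefinition, FIR_LINEAR_PHASE, design_bank, default_bands

DEFAULTS: dict = {
    "sampling_rate_hz": 100.0,
    "bands": None,  # None -> default_bands()
    "filter": {"mode": FIR_LINEAR_PHASE, "taps_or_order": None},
    "trainer": {},
    "session": {},
    "synth": {},
}


def load_config(path=None) -> dict:
    """Merge a YAML file (if given) over the defaults."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def bands_from_config(cfg: dict):
    fs = float(cfg.get("sampling_rate_hz", 100.0))
    raw = cfg.get("bands")
    if raw is None:
        return default_bands(fs)
    return tuple(BandDefinition(name, *edges) for name, edges in raw.items())


def bank_from_config(cfg: dict):
    fs = float(cfg.get("sampling_rate_hz", 100.0))
    filt = cfg.get("filter", {})
    return design_bank(
        bands_from_config(cfg),
        fs,
        filt.get("mode", FIR_LINEAR_PHASE),
        filt.get("taps_or_order"),
    )


def trainer_from_config(cfg: dict, **overrides) -> TrainerConfig:
    params = dict(cfg.get("trainer", {}))
    params.update(overrides)
    return TrainerConfig(**params)


def session_from_config(cfg: dict, trainer: TrainerConfig, **overrides) -> SessionConfig:
    params = dict(cfg.get("session", {}))
    params.update(overrides)
    return SessionConfig(trainer=trainer, **params)
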