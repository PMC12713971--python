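"""Scoring configuration: every tunable of the pipeline in one dataclass.

Values are grouped by pipeline layer.  All frequencies are Hz, durations
seconds, powers relative dB (whole-night baseline removed).  ``from_yaml``
accepts a flat mapping with any subset of the keys; unknown keys are an
error so typos in config files surface immediately.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ScoringConfig:
    # --- wavelet spectrogram ---
    f_min: float = 0.1
    f_max: float = 100.0
    n_freqs: int = 100
    c_min: float = 3.0          # cycles at f_min
    c_max: float = 30.0         # cycles at f_max
    hop_s: float = 0.5
    db_floor: float = 1e-12     # power floor before log, keeps silence finite
    db_mode: str = "power"      # "power": 10*log10(|w|^2); "amplitude": 10*log10(|w|)

    # --- baseline / noise / bands ---
    z_thresh: float = 4.0       # robust-z threshold for noise bins
    rms_window_s: float = 2.0   # window for the raw-signal RMS noise feature
    detrend_window_s: float = 600.0  # local-background window for the noise features
    line_band: tuple[float, float] = (50.0, 70.0)
    smooth_window_s: float = 40.0   # display smoothing only, never scoring
    epoch_len_s: float = 30.0       # >= 10 s supported
    spindle_search: tuple[float, float] = (9.0, 16.0)   # LIGHT peak refinement window
    rem_search: tuple[float, float] = (15.0, 30.0)      # REM peak refinement window

    # --- HMM ---
    max_iter: int = 50
    tol: float = 1e-6           # relative log-likelihood improvement
    var_floor: float = 0.25     # dB^2
    sticky: float = 5.0         # diagonal transition pseudo-count at init
    pi_wake: float = 0.8        # initial-state mass on WAKE (nights start awake)
    noise_epoch_frac: float = 0.5  # epoch flagged noisy if >= this fraction of bins masked

    # --- post-HMM corrections (relative dB thresholds) ---
    theta_ratio: float = 2.0        # beta minus spindle for rule 1
    theta_spindle: float = 0.0      # "relatively low" spindle power (below night baseline)
    theta_total: float = 3.0        # above-median total power for rule 2
    theta_delta: float = 2.0        # "sufficiently high" delta for rule 4
    theta_spindle_high: float = 2.0  # "sufficiently high" spindle for rule 4
    onset_run_len: int = 10         # consecutive non-Wake epochs defining sleep onset

    def __post_init__(self) -> None:
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")
        if self.c_min > self.c_max:
            raise ValueError("need c_min <= c_max")
        if self.hop_s <= 0 or self.epoch_len_s <= 0:
            raise ValueError("hop_s and epoch_len_s must be positive")
        if self.db_mode not in ("power", "amplitude"):
            raise ValueError("db_mode must be 'power' or 'amplitude'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("line_band", "spindle_search", "rem_search"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("line_band", "spindle_search", "rem_search"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def config_hash(self) -> str:
        import hashlib
        import json

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
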