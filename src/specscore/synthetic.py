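"""Synthetic sleep EEG with a known hypnogram.

A night is a 1/f (pink-noise) background with stage-specific oscillatory
content added segment by segment:

* WAKE   — broadband gamma (40-95 Hz) noise;
* REM    — narrowband low-beta around 20 Hz;
* LIGHT  — 13 Hz sleep spindles as 1-s Hann-windowed bursts recurring
  every 4-6 s (jittered), as in physiology, which stresses the epoch
  averaging more than a continuous rhythm would;
* HIDEEP — narrowband delta centred in 1-3 Hz;
* LODEEP — slow oscillations below 1 Hz, plus mild spindle content
  (slow oscillations co-occur with K-complex/spindle activity).

Default amplitudes (gamma 3, beta 5, spindle 8, delta 40, slow
oscillation 60 uV over a 10 uV-RMS pink background) follow the usual
amplitude ordering of human sleep EEG: slow rhythms large, fast rhythms
small.  The same seed reproduces the night bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypnogram import Hypnogram
from .stages import HIDEEP, LIGHT, LODEEP, REM, SPECTRAL_STAGES, WAKE
from .wavelets import EEGRecording

__all__ = ["StageScript", "generate_night", "inject_artifacts", "cycle_script"]

DEFAULT_AMPLITUDES = {WAKE: 3.0, REM: 5.0, LIGHT: 8.0, HIDEEP: 40.0, LODEEP: 60.0}


@dataclass
class StageScript:
    """Recipe for one synthetic night."""

    segments: list[tuple[str, float]]        # (stage, duration s)
    fs: float = 500.0
    amplitudes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    background_exponent: float = 1.0         # 1/f^exponent power slope
    background_rms: float = 10.0             # uV
    epoch_len: float = 30.0
    seed: int = 0
    spindle_freq: float = 13.0               # Hz
    rem_freq: float = 20.0                   # Hz

    def __post_init__(self) -> None:
        for stage, dur in self.segments:
            if stage not in SPECTRAL_STAGES:
                raise ValueError(f"unknown stage {stage!r} in script")
            if abs(dur / self.epoch_len - round(dur / self.epoch_len)) > 1e-9:
                raise ValueError(
                    f"segment duration {dur} s is not a multiple of the "
                    f"{self.epoch_len}-s epoch"
                )
        if self.total_duration < self.epoch_len:
            raise ValueError("script must cover at least one epoch")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))


def cycle_script(
    n_cycles: int = 5,
    fs: float = 500.0,
    seed: int = 0,
    wake_min: float = 10.0,
    light_min: float = 20.0,
    hideep_min: float = 15.0,
    lodeep_min: float = 15.0,
    rem_min: float = 20.0,
    **kwargs,
) -> StageScript:
    """Realistic full-night cycle structure.

    Each ~90-min cycle runs Wake -> Light -> Hi Deep -> Lo Deep -> Light ->
    REM; with the default per-stage minutes, five cycles give an 8-h night.
    """
    segments: list[tuple[str, float]] = []
    for _ in range(n_cycles):
        segments += [
            (WAKE, wake_min * 60),
            (LIGHT, light_min * 60),
            (HIDEEP, hideep_min * 60),
            (LODEEP, lodeep_min * 60),
            (LIGHT, light_min / 2 * 60),
            (REM, rem_min * 60),
        ]
    return StageScript(segments=segments, fs=fs, seed=seed, **kwargs)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, rms: float
) -> np.ndarray:
    """Gaussian noise confined to [lo, hi] Hz, scaled to the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def _spindle_train(
    rng: np.random.Generator, n: int, fs: float, freq: float, amplitude: float
) -> np.ndarray:
    """1-s Hann-windowed spindle bursts starting every 4-6 s (jittered)."""
    x = np.zeros(n)
    burst = int(round(1.0 * fs))
    window = np.hanning(burst)
    pos = 0.0
    while True:
        start = int(round(pos * fs))
        if start + burst > n:
            break
        tt = np.arange(burst) / fs
        phase = rng.uniform(0, 2 * np.pi)
        x[start:start + burst] += amplitude * window * np.sin(
            2 * np.pi * freq * tt + phase
        )
        pos += rng.uniform(4.0, 6.0)
    return x


def generate_night(script: StageScript) -> tuple[EEGRecording, Hypnogram]:
    """Render a script into an EEG recording plus its ground-truth hypnogram."""
    fs = script.fs
    n_total = int(round(script.total_duration * fs))
    rng = np.random.default_rng(script.seed)
    x = _pink_noise(rng, n_total, script.background_exponent, script.background_rms)

    amp = script.amplitudes
    pos = 0
    truth: list[str] = []
    for stage, dur in script.segments:
        n = int(round(dur * fs))
        sl = slice(pos, pos + n)
        if stage == WAKE:
            x[sl] += _bandlimited_noise(rng, n, fs, 40.0, 95.0, amp[WAKE])
        elif stage == REM:
            x[sl] += _bandlimited_noise(
                rng, n, fs, script.rem_freq - 2.0, script.rem_freq + 2.0, amp[REM]
            )
        elif stage == LIGHT:
            x[sl] += _spindle_train(rng, n, fs, script.spindle_freq, amp[LIGHT])
        elif stage == HIDEEP:
            x[sl] += _bandlimited_noise(rng, n, fs, 1.0, 3.0, amp[HIDEEP])
        elif stage == LODEEP:
            x[sl] += _bandlimited_noise(rng, n, fs, 0.3, 0.9, amp[LODEEP])
            # mild spindle content rides on slow oscillations (K-complex milieu)
            x[sl] += _spindle_train(rng, n, fs, script.spindle_freq, amp[LIGHT] * 0.3)
        truth += [stage] * int(round(dur / script.epoch_len))
        pos += n

    rec = EEGRecording(
        samples=x[None, :], fs=fs, channel_labels=["SYN1"], start_time=None
    )
    return rec, Hypnogram(stages=truth, epoch_len=script.epoch_len)


def inject_artifacts(
    rec: EEGRecording, spans: list[tuple[float, float, float]]
) -> EEGRecording:
    """Scale (start_s, duration_s, gain) spans of every channel; elsewhere untouched."""
    out = rec.samples.copy()
    for start, dur, gain in spans:
        i0 = int(round(start * rec.fs))
        i1 = int(round((start + dur) * rec.fs))
        out[:, i0:i1] *= gain
    return EEGRecording(
        samples=out,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        start_time=rec.start_time,
    )
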