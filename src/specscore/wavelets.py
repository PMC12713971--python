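"""Morlet wavelet spectrogram of whole-night EEG.

The raw signal is decomposed into complex amplitude on a log-spaced
frequency grid spanning 0.1-100 Hz, one value per 0.5-s time point.  The
number of cycles per wavelet grows from 3 at the lowest frequency to 30 at
the highest, linearly in log10(frequency) in between, trading frequency
resolution for time resolution as frequency rises.  Power is the complex
coefficient times its conjugate (squared magnitude), floored at a small
positive constant and converted to dB as 10*log10.

Implementation: each Morlet wavelet is an analytic complex exponential
with a Gaussian envelope of width sigma_t = cycles / (2*pi*f), so its
frequency response is a Gaussian of width sigma_f = f / cycles centred on
f.  The transform is computed as a product in the frequency domain; since
only hop-spaced output samples are needed, the product spectrum is folded
modulo the decimated length before a short inverse FFT.  The result equals
the full convolution sampled at the centre of each hop window, at a small
fraction of the cost.  Edges are zero-padded; bins whose wavelet extends
past the record are flagged in ``edge_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from scipy.fft import next_fast_len

__all__ = [
    "EEGRecording",
    "WaveletBank",
    "Spectrogram",
    "design_wavelets",
    "compute_spectrogram",
]

#: Gaussian envelope is treated as zero beyond this many sigma_t.
_SUPPORT_SIGMAS = 5.0
#: Frequency-domain response is evaluated out to this many sigma_f.
_FREQ_SIGMAS = 8.0


@dataclass
class EEGRecording:
    """Raw multi-channel EEG: samples in microvolts, one row per channel."""

    samples: np.ndarray              # (n_channels, n_samples) float
    fs: float                        # Hz
    channel_labels: list[str]
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.isfinite(self.samples).all():
            bad = [
                self.channel_labels[i]
                for i in np.unique(np.nonzero(~np.isfinite(self.samples))[0])
            ]
            raise ValueError(f"non-finite samples in channel(s) {bad}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; have {self.channel_labels}"
            ) from None
        return self.samples[idx]


@dataclass
class WaveletBank:
    """Log-spaced frequency grid with a smooth gradient of cycles."""

    freqs: np.ndarray    # Hz, ascending
    cycles: np.ndarray   # cycles per wavelet, non-decreasing

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.cycles = np.asarray(self.cycles, dtype=np.float64)
        if self.freqs.shape != self.cycles.shape:
            raise ValueError("freqs and cycles must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        if np.any(np.diff(self.cycles) < 0):
            raise ValueError("cycles must be non-decreasing with frequency")

    @property
    def sigma_t(self) -> np.ndarray:
        """Gaussian envelope width (s) of each wavelet."""
        return self.cycles / (2.0 * np.pi * self.freqs)

    @property
    def max_support_s(self) -> float:
        """Time support (s) of the longest wavelet (+-5 sigma)."""
        return float(2.0 * _SUPPORT_SIGMAS * self.sigma_t.max())


def design_wavelets(
    f_min: float = 0.1,
    f_max: float = 100.0,
    n_freqs: int = 100,
    c_min: float = 3.0,
    c_max: float = 30.0,
) -> WaveletBank:
    """Build the wavelet bank: log-spaced frequencies, log-linear cycle gradient.

    Cycles interpolate linearly in log10(f) between (f_min, c_min) and
    (f_max, c_max), giving the smooth time/frequency-resolution trade-off
    across the grid.
    """
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if c_min > c_max:
        raise ValueError("need c_min <= c_max")
    if n_freqs < 2:
        raise ValueError("need at least 2 frequencies")
    freqs = np.logspace(np.log10(f_min), np.log10(f_max), n_freqs)
    t = (np.log10(freqs) - np.log10(f_min)) / (np.log10(f_max) - np.log10(f_min))
    cycles = c_min + (c_max - c_min) * t
    return WaveletBank(freqs=freqs, cycles=np.maximum.accumulate(cycles))


@dataclass
class Spectrogram:
    """Time x frequency power matrix in dB at a fixed hop."""

    power: np.ndarray                # (n_times, n_freqs) dB
    hop: float                       # s
    freqs: np.ndarray                # Hz
    baselined: bool = False
    noise_mask: np.ndarray | None = None     # (n_times,) bool, True = noisy bin
    line_mask_band: tuple[float, float] | None = None
    edge_mask: np.ndarray | None = None      # (n_times, n_freqs) bool

    @property
    def n_times(self) -> int:
        return self.power.shape[0]

    @property
    def n_freqs(self) -> int:
        return self.power.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Centre time (s) of each bin."""
        return (np.arange(self.n_times) + 0.5) * self.hop

    def copy(self) -> "Spectrogram":
        return Spectrogram(
            power=self.power.copy(),
            hop=self.hop,
            freqs=self.freqs.copy(),
            baselined=self.baselined,
            noise_mask=None if self.noise_mask is None else self.noise_mask.copy(),
            line_mask_band=self.line_mask_band,
            edge_mask=None if self.edge_mask is None else self.edge_mask.copy(),
        )


def compute_spectrogram(
    rec: EEGRecording,
    channel: str,
    bank: WaveletBank | None = None,
    hop: float = 0.5,
    db_floor: float = 1e-12,
    db_mode: str = "power",
) -> Spectrogram:
    """Morlet wavelet spectrogram of one channel, not yet baselined.

    Parameters
    ----------
    rec, channel
        Recording and the label of the channel to decompose.
    bank
        Wavelet bank; defaults to ``design_wavelets()``.
    hop
        Output time step in seconds (0.5 by default); ``hop * fs`` must be
        an integer number of samples.
    db_floor
        Power floor applied before the log so silence stays finite.
    db_mode
        ``"power"``: dB of squared magnitude (default); ``"amplitude"``:
        dB of the magnitude itself.
    """
    if bank is None:
        bank = design_wavelets()
    if hop <= 0:
        raise ValueError("hop must be positive")
    if db_mode not in ("power", "amplitude"):
        raise ValueError("db_mode must be 'power' or 'amplitude'")
    x = rec.channel(channel)
    fs = rec.fs
    decim = hop * fs
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError(f"hop * fs must be an integer sample count, got {decim}")
    decim = int(round(decim))
    n0 = x.size
    if rec.duration_s < bank.max_support_s:
        raise ValueError(
            f"record ({rec.duration_s:.1f} s) shorter than the longest wavelet "
            f"support ({bank.max_support_s:.1f} s)"
        )

    sigma_t = bank.sigma_t
    pad = int(np.ceil(_SUPPORT_SIGMAS * sigma_t.max() * fs))
    n_fft = decim * next_fast_len(int(np.ceil((n0 + 2 * pad) / decim)))
    m = n_fft // decim                      # decimated length
    xp = np.zeros(n_fft)
    xp[pad:pad + n0] = x
    spectrum = np.fft.rfft(xp)
    df = fs / n_fft
    n_pos = spectrum.size

    n_times = n0 // decim
    offset = pad + decim // 2               # centre of the first hop window
    phase_rate = 2.0 * np.pi * offset / n_fft

    out = np.empty((n_times, bank.freqs.size))
    fold = np.zeros(m, dtype=np.complex128)
    for fi, (f0, st) in enumerate(zip(bank.freqs, sigma_t)):
        sigma_f = 1.0 / (2.0 * np.pi * st)
        # signed-frequency support of the zero-mean Morlet response: the main
        # Gaussian around f0 plus the kappa correction Gaussian around 0.  Not
        # truncating at DC keeps the wavelet Gaussian-compact in time.
        m_lo = int(np.floor(min(-_FREQ_SIGMAS, (f0 / sigma_f) - _FREQ_SIGMAS) * sigma_f / df))
        m_hi = min(n_pos - 1, int(np.ceil((f0 + _FREQ_SIGMAS * sigma_f) / df)))
        m_idx = np.arange(m_lo, m_hi + 1)
        fj = m_idx * df
        # gain 2 at f0 so a unit real sinusoid yields |w| = 1; kappa term
        # makes the wavelet exactly zero-mean
        kappa = np.exp(-(f0**2) / (2.0 * sigma_f**2))
        gauss = 2.0 * (
            np.exp(-((fj - f0) ** 2) / (2.0 * sigma_f**2))
            - kappa * np.exp(-(fj**2) / (2.0 * sigma_f**2))
        )
        xval = np.where(
            m_idx >= 0,
            spectrum[np.abs(m_idx)],
            np.conj(spectrum[np.abs(m_idx)]),
        )
        vals = xval * gauss * np.exp(1j * phase_rate * m_idx)
        # fold the band onto the decimated spectrum (index mod m), vectorised
        start = m_lo % m
        length = vals.size
        rows = int(np.ceil((start + length) / m))
        buf = np.zeros(rows * m, dtype=np.complex128)
        buf[start:start + length] = vals
        fold[:] = buf.reshape(rows, m).sum(axis=0)
        w = np.fft.ifft(fold)[:n_times] / decim
        out[:, fi] = w.real ** 2 + w.imag ** 2      # coefficient times conjugate

    if db_mode == "amplitude":
        out = np.sqrt(out)
    np.maximum(out, db_floor, out=out)
    power_db = 10.0 * np.log10(out)

    times = (np.arange(n_times) + 0.5) * hop
    half_support = _SUPPORT_SIGMAS * sigma_t          # (n_freqs,)
    edge = (times[:, None] < half_support[None, :]) | (
        times[:, None] > rec.duration_s - half_support[None, :]
    )
    return Spectrogram(
        power=power_db,
        hop=hop,
        freqs=bank.freqs.copy(),
        baselined=False,
        edge_mask=edge,
    )
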