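"""Noise epochs, whole-night baseline, line-noise masking and band features.

The scoring features are five band averages of the *baselined* spectrogram:
the whole-night per-frequency mean (computed over non-noise time bins) is
subtracted from every time point, so each feature reads as dB above or
below that night's own background at those frequencies.  Defaults:

    WAKE    40-95 Hz   (gamma; line-noise band excluded from the average)
    REM     17-26 Hz   (low beta)
    LIGHT   11-15.5 Hz (sleep spindles)
    HIDEEP  1-3 Hz     (delta)
    LODEEP  0.1-1 Hz   (slow oscillations)

The REM and LIGHT bands are re-centred on each night's own spectral peaks
after a first-pass scoring: LIGHT to [peak - 1, peak + 1.5] Hz around the
spindle peak, REM to [peak - 2, peak + 2] Hz around the low-beta peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .stages import LIGHT, REM, SPECTRAL_STAGES
from .wavelets import EEGRecording, Spectrogram

__all__ = [
    "BandDefinition",
    "BandSeries",
    "DominantFrequencySeries",
    "default_bands",
    "detect_noise_epochs",
    "baseline_spectrogram",
    "mask_line_noise",
    "band_features",
    "refine_band_peaks",
    "dominant_frequency",
]


@dataclass(frozen=True)
class BandDefinition:
    """One scoring band: [lo, hi] Hz minus any excluded sub-bands."""

    name: str
    lo: float
    hi: float
    exclusions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.name not in SPECTRAL_STAGES:
            raise ValueError(f"band name must be a spectral stage, got {self.name!r}")
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: need lo < hi, got [{self.lo}, {self.hi}]")

    def row_indices(self, freqs: np.ndarray) -> np.ndarray:
        """Grid rows inside [lo, hi] and outside every exclusion."""
        sel = (freqs >= self.lo) & (freqs <= self.hi)
        for elo, ehi in self.exclusions:
            sel &= ~((freqs >= elo) & (freqs <= ehi))
        return np.nonzero(sel)[0]


def default_bands(line_band: tuple[float, float] = (50.0, 70.0)) -> list[BandDefinition]:
    """The five default scoring bands, in fixed stage order."""
    return [
        BandDefinition("WAKE", 40.0, 95.0, exclusions=(tuple(line_band),)),
        BandDefinition("REM", 17.0, 26.0),
        BandDefinition("LIGHT", 11.0, 15.5),
        BandDefinition("HIDEEP", 1.0, 3.0),
        BandDefinition("LODEEP", 0.1, 1.0),
    ]


@dataclass
class BandSeries:
    """Per-epoch mean relative dB in each of the five bands."""

    values: np.ndarray           # (n_epochs, 5)
    epoch_len: float             # s
    band_defs: list[BandDefinition]
    noisy_epochs: np.ndarray | None = None   # (n_epochs,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.band_defs):
            raise ValueError("values must be (n_epochs, n_bands)")
        if not np.isfinite(self.values).all():
            raise ValueError("band features must be finite")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


@dataclass
class DominantFrequencySeries:
    """Grid frequency of maximal (smoothed) relative power per time bin."""

    freq_at_max: np.ndarray      # Hz, one per spectrogram bin
    smoothing_window: float      # s


def _robust_z(x: np.ndarray) -> np.ndarray | None:
    """Median/MAD z-score; None when MAD is zero (feature uninformative)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    return (x - med) / (1.4826 * mad)


def _detrend_local(x: np.ndarray, window_bins: int) -> np.ndarray:
    """Deviation from a centred rolling median (the local background level)."""
    if window_bins <= 1 or window_bins >= x.size:
        return x - np.median(x)
    import pandas as pd

    trend = (
        pd.Series(x).rolling(window_bins, center=True, min_periods=1).median().to_numpy()
    )
    return x - trend


def detect_noise_epochs(
    spec: Spectrogram,
    rec: EEGRecording | None = None,
    channel: str | None = None,
    z_thresh: float = 4.0,
    rms_window_s: float = 2.0,
    detrend_window_s: float = 600.0,
) -> np.ndarray:
    """Flag time bins with extreme windowed RMS or extreme total power.

    A bin is noisy when the robust z-score (median/MAD) of either feature
    exceeds ``z_thresh`` in absolute value:

    * total power: dB of the summed linear power across the spectrum at
      that bin;
    * windowed RMS: dB of the raw-signal RMS in a ``rms_window_s`` window
      centred on the bin (only when ``rec``/``channel`` are given).

    "Extreme" is judged against the *local* background: each feature is
    detrended by a centred rolling median over ``detrend_window_s`` before
    the z-score, so transient artifacts stand out while sustained
    stage-related power shifts (slow-wave sleep runs far above the
    whole-night level for many minutes) are not mistaken for noise.

    Both features live on a log scale, so the mask is invariant to
    rescaling the whole record.  A constant feature (MAD = 0) flags
    nothing and emits a warning.
    """
    if spec.baselined:
        raise ValueError("noise detection must run on the un-baselined spectrogram")
    detrend_bins = int(round(detrend_window_s / spec.hop))
    total_db = 10.0 * np.log10(np.sum(10.0 ** (spec.power / 10.0), axis=1))
    mask = np.zeros(spec.n_times, dtype=bool)
    any_informative = False
    z = _robust_z(_detrend_local(total_db, detrend_bins))
    if z is None:
        warnings.warn("total-power feature is constant (MAD = 0); not used for masking")
    else:
        any_informative = True
        mask |= np.abs(z) > z_thresh

    if rec is not None:
        x = rec.channel(channel) if channel is not None else rec.samples[0]
        half = int(round(rms_window_s * rec.fs / 2))
        csum = np.concatenate([[0.0], np.cumsum(x.astype(np.float64) ** 2)])
        centers = np.minimum(
            (np.round((np.arange(spec.n_times) + 0.5) * spec.hop * rec.fs)).astype(int),
            x.size - 1,
        )
        lo = np.maximum(centers - half, 0)
        hi = np.minimum(centers + half, x.size)
        ms = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
        rms_db = 10.0 * np.log10(np.maximum(ms, 1e-30))
        z = _robust_z(_detrend_local(rms_db, detrend_bins))
        if z is None:
            warnings.warn("RMS feature is constant (MAD = 0); not used for masking")
        else:
            any_informative = True
            mask |= np.abs(z) > z_thresh
    if not any_informative:
        warnings.warn("all noise features constant; empty mask returned")
    return mask


def baseline_spectrogram(spec: Spectrogram, mask: np.ndarray | None = None) -> Spectrogram:
    """Subtract the whole-night per-frequency mean, excluding noisy bins.

    The mean is taken over unmasked bins only, but subtracted everywhere,
    so masked bins stay on the same relative-dB scale.
    """
    if spec.baselined:
        raise ValueError("spectrogram is already baselined")
    if mask is None:
        mask = np.zeros(spec.n_times, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (spec.n_times,):
        raise ValueError("mask length must equal the number of time bins")
    if mask.all():
        raise ValueError("all time bins are masked; no baseline can be formed")
    baseline = spec.power[~mask].mean(axis=0)
    out = spec.copy()
    out.power = spec.power - baseline[None, :]
    out.baselined = True
    out.noise_mask = mask.copy()
    return out


def mask_line_noise(
    spec: Spectrogram, band: tuple[float, float] = (50.0, 70.0)
) -> Spectrogram:
    """Replace line-noise rows by interpolation of the surrounding frequencies.

    Display-only: scoring bands never read the interpolated rows (the WAKE
    band excludes this range instead).  Power inside ``band`` is replaced,
    per time bin, by linear interpolation in log-frequency between the
    nearest rows below and above the band.
    """
    lo, hi = band
    out = spec.copy()
    inside = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not inside.any():
        out.line_mask_band = (lo, hi)
        return out
    below = np.nonzero(spec.freqs < lo)[0]
    above = np.nonzero(spec.freqs > hi)[0]
    logf = np.log10(spec.freqs)
    if below.size and above.size:
        i0, i1 = below[-1], above[0]
        w = (logf[inside] - logf[i0]) / (logf[i1] - logf[i0])
        out.power[:, inside] = (
            spec.power[:, [i0]] * (1.0 - w)[None, :] + spec.power[:, [i1]] * w[None, :]
        )
    elif below.size:
        out.power[:, inside] = spec.power[:, [below[-1]]]
    elif above.size:
        out.power[:, inside] = spec.power[:, [above[0]]]
    out.line_mask_band = (lo, hi)
    return out


def band_features(
    spec: Spectrogram,
    defs: list[BandDefinition] | None = None,
    epoch_len: float = 30.0,
    noise_epoch_frac: float = 0.5,
) -> BandSeries:
    """Average the baselined spectrogram into per-epoch band features.

    Each cell is the mean relative dB over the band's grid rows (minus
    exclusions) and the epoch's time bins.  A trailing partial epoch is
    dropped.  Epochs whose fraction of noise-masked bins reaches
    ``noise_epoch_frac`` are flagged in ``noisy_epochs``.
    """
    if not spec.baselined:
        raise ValueError("band features require a baselined spectrogram")
    if defs is None:
        defs = default_bands()
    bins_per_epoch = int(round(epoch_len / spec.hop))
    if bins_per_epoch < 1:
        raise ValueError("epoch shorter than one spectrogram bin")
    n_epochs = spec.n_times // bins_per_epoch
    if n_epochs == 0:
        raise ValueError("record shorter than one epoch")
    rows = []
    for bd in defs:
        idx = bd.row_indices(spec.freqs)
        if idx.size == 0:
            raise ValueError(f"band {bd.name} [{bd.lo}, {bd.hi}] contains no grid frequencies")
        rows.append(idx)
    trimmed = spec.power[: n_epochs * bins_per_epoch]
    cube = trimmed.reshape(n_epochs, bins_per_epoch, spec.n_freqs)
    values = np.stack([cube[:, :, idx].mean(axis=(1, 2)) for idx in rows], axis=1)
    noisy = None
    if spec.noise_mask is not None:
        frac = (
            spec.noise_mask[: n_epochs * bins_per_epoch]
            .reshape(n_epochs, bins_per_epoch)
            .mean(axis=1)
        )
        noisy = frac >= noise_epoch_frac
    return BandSeries(values=values, epoch_len=epoch_len, band_defs=list(defs), noisy_epochs=noisy)


def refine_band_peaks(
    spec: Spectrogram,
    first_pass,
    defs: list[BandDefinition] | None = None,
    spindle_search: tuple[float, float] = (9.0, 16.0),
    rem_search: tuple[float, float] = (15.0, 30.0),
) -> list[BandDefinition]:
    """Re-centre the LIGHT and REM bands on the night's own spectral peaks.

    Using the first-pass hypnogram, the mean spectrum over epochs scored
    LIGHT is searched for its peak within ``spindle_search``; the LIGHT
    band becomes [peak - 1, peak + 1.5] Hz.  Likewise the REM band becomes
    [peak - 2, peak + 2] Hz around the peak within ``rem_search``.  A
    stage with no first-pass epochs leaves its band unchanged.
    """
    if not spec.baselined:
        raise ValueError("peak refinement requires a baselined spectrogram")
    if defs is None:
        defs = default_bands()
    epoch_len = first_pass.epoch_len
    bins_per_epoch = int(round(epoch_len / spec.hop))
    stages = np.asarray(first_pass.stages)

    def _peak(stage: str, window: tuple[float, float]) -> float | None:
        epochs = np.nonzero(stages == stage)[0]
        if epochs.size == 0:
            return None
        sel = np.zeros(spec.n_times, dtype=bool)
        for e in epochs:
            sel[e * bins_per_epoch : (e + 1) * bins_per_epoch] = True
        if spec.noise_mask is not None:
            keep = sel & ~spec.noise_mask
            if keep.any():
                sel = keep
        mean_spec = spec.power[sel].mean(axis=0)
        in_win = (spec.freqs >= window[0]) & (spec.freqs <= window[1])
        if not in_win.any():
            return None
        idx = np.nonzero(in_win)[0]
        i = idx[np.argmax(mean_spec[idx])]
        # parabolic interpolation in log-frequency for sub-bin peak location
        if 0 < i < spec.n_freqs - 1:
            y0, y1, y2 = mean_spec[i - 1 : i + 2]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)
                logf = np.log10(spec.freqs)
                step = 0.5 * (logf[i + 1] - logf[i - 1])
                return float(10 ** (logf[i] + delta * step))
        return float(spec.freqs[i])

    out = []
    for bd in defs:
        if bd.name == LIGHT:
            p = _peak(LIGHT, spindle_search)
            if p is not None:
                bd = replace(bd, lo=p - 1.0, hi=p + 1.5)
        elif bd.name == REM:
            p = _peak(REM, rem_search)
            if p is not None:
                bd = replace(bd, lo=p - 2.0, hi=p + 2.0)
        out.append(bd)
    return out


def smooth_display(spec: Spectrogram, window_s: float = 40.0) -> Spectrogram:
    """Centred moving-average over time, for display and dominant frequency only."""
    win = max(1, int(round(window_s / spec.hop)))
    if win == 1:
        return spec.copy()
    out = spec.copy()
    padded = np.pad(spec.power, ((win // 2, win - 1 - win // 2), (0, 0)), mode="edge")
    csum = np.vstack([np.zeros((1, spec.n_freqs)), np.cumsum(padded, axis=0)])
    out.power = (csum[win:] - csum[:-win]) / win
    return out


def dominant_frequency(spec: Spectrogram, smooth_window: float = 40.0) -> DominantFrequencySeries:
    """Frequency of maximal smoothed relative power at each 0.5-s bin.

    The spectrogram is smoothed with a centred moving average over time
    (display smoothing) before the per-bin argmax; ties break toward the
    lower frequency.
    """
    if not spec.baselined:
        raise ValueError("dominant frequency is defined on the baselined spectrogram")
    sm = smooth_display(spec, smooth_window)
    idx = np.argmax(sm.power, axis=1)        # first max = lowest frequency on ties
    return DominantFrequencySeries(
        freq_at_max=spec.freqs[idx], smoothing_window=smooth_window
    )
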