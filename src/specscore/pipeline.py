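"""End-to-end spectral scoring of one channel.

Order of operations: Morlet spectrogram -> noise-bin detection ->
whole-night baseline removal -> default five-band features -> HMM fit and
first-pass posterior decoding -> REM/LIGHT peak refinement -> second-pass
features, fit and decoding with the refined bands -> post-HMM correction
rules.  Every step is deterministic, so scoring the same recording with
the same configuration is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import (
    BandDefinition,
    BandSeries,
    DominantFrequencySeries,
    band_features,
    baseline_spectrogram,
    default_bands,
    detect_noise_epochs,
    dominant_frequency,
    mask_line_noise,
    refine_band_peaks,
)
from .config import ScoringConfig
from .corrections import apply_corrections
from .hmm import HMMModel, PosteriorMatrix, em_fit, init_hmm, posterior_decode
from .hypnogram import Hypnogram
from .wavelets import EEGRecording, Spectrogram, compute_spectrogram, design_wavelets

__all__ = ["ScoringResult", "score_recording"]


@dataclass
class ScoringResult:
    hypnogram: Hypnogram                 # final, corrections applied
    first_pass: Hypnogram                # before band refinement
    posterior: PosteriorMatrix
    bands: BandSeries                    # refined-band features used for the final pass
    band_defs: list[BandDefinition]      # refined definitions
    model: HMMModel
    spectrogram: Spectrogram             # baselined, scoring version
    display_spectrogram: Spectrogram     # line-noise masked, for rendering
    dominant: DominantFrequencySeries
    noise_mask: np.ndarray               # per 0.5-s bin
    channel: str
    config: ScoringConfig


def _fit_and_decode(bands: BandSeries, cfg: ScoringConfig):
    model = init_hmm(
        bands, sticky=cfg.sticky, var_floor=cfg.var_floor, pi_wake=cfg.pi_wake
    )
    model, _ = em_fit(
        model, bands, max_iter=cfg.max_iter, tol=cfg.tol, var_floor=cfg.var_floor
    )
    hyp, post = posterior_decode(model, bands)
    return model, hyp, post


def score_recording(
    rec: EEGRecording,
    channel: str,
    config: ScoringConfig | None = None,
) -> ScoringResult:
    """Score one channel of a recording into a corrected spectral hypnogram."""
    cfg = config or ScoringConfig()
    bank = design_wavelets(cfg.f_min, cfg.f_max, cfg.n_freqs, cfg.c_min, cfg.c_max)
    spec_raw = compute_spectrogram(
        rec, channel, bank, hop=cfg.hop_s, db_floor=cfg.db_floor, db_mode=cfg.db_mode
    )
    noise = detect_noise_epochs(
        spec_raw, rec, channel, z_thresh=cfg.z_thresh,
        rms_window_s=cfg.rms_window_s, detrend_window_s=cfg.detrend_window_s,
    )
    spec = baseline_spectrogram(spec_raw, noise)

    defs0 = default_bands(cfg.line_band)
    bands0 = band_features(
        spec, defs0, epoch_len=cfg.epoch_len_s, noise_epoch_frac=cfg.noise_epoch_frac
    )
    _, first_pass, _ = _fit_and_decode(bands0, cfg)

    defs1 = refine_band_peaks(
        spec, first_pass, defs0,
        spindle_search=cfg.spindle_search, rem_search=cfg.rem_search,
    )
    bands1 = band_features(
        spec, defs1, epoch_len=cfg.epoch_len_s, noise_epoch_frac=cfg.noise_epoch_frac
    )
    model, decoded, post = _fit_and_decode(bands1, cfg)

    thresholds = {
        "theta_ratio": cfg.theta_ratio,
        "theta_spindle": cfg.theta_spindle,
        "theta_total": cfg.theta_total,
        "theta_delta": cfg.theta_delta,
        "theta_spindle_high": cfg.theta_spindle_high,
    }
    final = apply_corrections(decoded, bands1, thresholds, run_len=cfg.onset_run_len)

    display = mask_line_noise(spec, cfg.line_band)
    dom = dominant_frequency(spec, smooth_window=cfg.smooth_window_s)
    return ScoringResult(
        hypnogram=final,
        first_pass=first_pass,
        posterior=post,
        bands=bands1,
        band_defs=defs1,
        model=model,
        spectrogram=spec,
        display_spectrogram=display,
        dominant=dom,
        noise_mask=noise,
        channel=channel,
        config=cfg,
    )
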