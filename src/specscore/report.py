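"""Whole-night sleep report rendering.

Stacked panels on a shared time axis: an optional reference (visual)
hypnogram on top, the spectral hypnogram with colour-coded change-marker
dots beneath it (green = was Wake, red = was REM, cyan = was Light,
blue = was Hi or Lo Deep), the whole-night relative-dB spectrogram with
the line-noise band masked, and the dominant-frequency trace.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.colors import Normalize

from .bands import DominantFrequencySeries, smooth_display
from .hypnogram import Hypnogram
from .stages import HIDEEP, LIGHT, LODEEP, REM, WAKE
from .wavelets import Spectrogram

__all__ = ["render_report", "CHANGE_DOT_COLORS"]

CHANGE_DOT_COLORS = {
    WAKE: "green",
    REM: "red",
    LIGHT: "cyan",
    HIDEEP: "blue",
    LODEEP: "blue",
}

#: plotting height per stage label (deep at bottom, wake on top)
_SPECTRAL_Y = {LODEEP: 0, HIDEEP: 1, LIGHT: 2, REM: 3, WAKE: 4}
_VISUAL_Y = {"N3": 0, "N2": 1, "N1": 2, "REM": 3, "wake": 4}


def _stage_ymap(hyp: Hypnogram) -> dict[str, int]:
    """Visual axis when AASM labels are present, spectral axis otherwise."""
    if any(s in _VISUAL_Y and s not in _SPECTRAL_Y for s in hyp.stages):
        return _VISUAL_Y
    return _SPECTRAL_Y


def _plot_hypnogram(ax, hyp: Hypnogram, ymap: dict[str, int], title: str) -> None:
    t = (hyp.start_seconds() + hyp.epoch_len / 2) / 3600.0
    y = np.array([ymap[s] for s in hyp.stages], dtype=float)
    ax.step(t, y, where="mid", lw=0.8, color="k")
    ax.set_yticks(sorted(ymap.values()))
    ax.set_yticklabels([s for s, _ in sorted(ymap.items(), key=lambda kv: kv[1])])
    ax.set_ylim(-1.2, max(ymap.values()) + 0.5)
    ax.set_title(title, fontsize=9, loc="left")


def render_report(
    spec: Spectrogram,
    hyp: Hypnogram,
    dominant: DominantFrequencySeries,
    path,
    ref_hyp: Hypnogram | None = None,
    smooth_window_s: float = 40.0,
    title: str | None = None,
) -> None:
    """Render the sleep report to an image file.

    ``spec`` should be the baselined (and ideally line-masked) display
    spectrogram; it is additionally smoothed over ``smooth_window_s`` for
    readability.  Omitting ``ref_hyp`` yields a three-panel report.
    """
    n_panels = 4 if ref_hyp is not None else 3
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(12, 2.1 * n_panels), sharex=True,
        constrained_layout=True,
    )
    k = 0
    if ref_hyp is not None:
        _plot_hypnogram(axes[k], ref_hyp, _stage_ymap(ref_hyp), "Reference hypnogram")
        k += 1

    ax = axes[k]
    _plot_hypnogram(ax, hyp, _SPECTRAL_Y, "Spectral hypnogram")
    dot_t, dot_c = [], []
    for e, src in enumerate(hyp.changed_from):
        if src is not None:
            dot_t.append((e + 0.5) * hyp.epoch_len / 3600.0)
            dot_c.append(CHANGE_DOT_COLORS[src])
    if dot_t:
        ax.scatter(dot_t, [-0.8] * len(dot_t), s=8, c=dot_c, marker="o")
    k += 1

    ax = axes[k]
    sm = smooth_display(spec, smooth_window_s)
    t_h = sm.times / 3600.0
    lo, hi = np.percentile(sm.power, [2, 98])
    mesh = ax.pcolormesh(
        t_h, sm.freqs, sm.power.T, shading="nearest",
        norm=Normalize(vmin=lo, vmax=hi), cmap="turbo", rasterized=True,
    )
    ax.set_yscale("log")
    ax.set_ylabel("Hz")
    ax.set_title("Spectrogram (relative dB)", fontsize=9, loc="left")
    fig.colorbar(mesh, ax=ax, pad=0.01, label="dB")
    k += 1

    ax = axes[k]
    ax.plot(spec.times / 3600.0, dominant.freq_at_max, ".", ms=1, color="tab:blue")
    ax.set_yscale("log")
    ax.set_ylabel("Hz")
    ax.set_xlabel("Time (h)")
    ax.set_title("Dominant frequency", fontsize=9, loc="left")

    if title:
        fig.suptitle(title, fontsize=10)
    fig.savefig(path, dpi=110)
    plt.close(fig)
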