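"""Post-HMM correction rules for irregular sleep expressions.

The HMM occasionally mis-scores epochs whose band profile is ambiguous:
noisy "Deep" epochs that are really wake, deep-scored epochs whose spindle
power says Light, wake-scored epochs whose low-frequency rhythms say NREM.
Four rules repair these, evaluated per epoch in a fixed order; the first
rule that fires wins and the pre-correction stage is recorded in
``changed_from``.  On clean sleep none of them fire.

Rules (features are per-epoch relative-dB band powers w, r, l, hd, ld for
WAKE/REM/LIGHT/HIDEEP/LODEEP):

1. Deep -> REM or Wake: the beta-to-spindle ratio is high
   (r - l >= theta_ratio) while total spindle power is relatively low
   (l < theta_spindle).  Wake is chosen over REM when the gamma band
   exceeds the beta band.
2. Deep -> Wake: total power is high (total >= night median of total +
   theta_total) and spindles relatively low — very noisy data, not sleep.
   An epoch's total-power statistic is the *median* of its five band
   features: broadband noise lifts every band, whereas genuine deep sleep
   lifts only the low-frequency bands and must not trip this rule.
3. Deep -> Light: spindle power exceeds the low-frequency power
   (l > max(hd, ld)).
4. Wake -> Hi Deep or Light: delta (hd >= theta_delta) or spindles
   (l >= theta_spindle_high) are sufficiently high, indicating NREM, and
   the epoch lies at or after initial sleep onset.  This also covers the
   wake-with-clear-NREM-rhythms repair: such epochs return to NREM based
   on the lower-frequency sleep rhythms.

A single pass is applied (no cascading) and epochs already carrying a
change marker are left alone, making the operation idempotent.
"""

from __future__ import annotations

import numpy as np

from .bands import BandSeries
from .hypnogram import Hypnogram
from .stages import HIDEEP, LIGHT, LODEEP, REM, WAKE, stage_index

__all__ = ["find_sleep_onset", "apply_corrections", "REQUIRED_THRESHOLDS"]

REQUIRED_THRESHOLDS = (
    "theta_ratio",
    "theta_spindle",
    "theta_total",
    "theta_delta",
    "theta_spindle_high",
)


def find_sleep_onset(hyp: Hypnogram, run_len: int = 10) -> int | None:
    """First epoch of the first run of >= run_len consecutive non-Wake epochs.

    Returns None when the night contains no such run (e.g. all wake).
    """
    if run_len < 1:
        raise ValueError("run_len must be >= 1")
    run_start = None
    run = 0
    for i, s in enumerate(hyp.stages):
        if s != WAKE:
            if run == 0:
                run_start = i
            run += 1
            if run >= run_len:
                return run_start
        else:
            run = 0
    return None


def apply_corrections(
    hyp: Hypnogram, bands: BandSeries, thresholds: dict, run_len: int = 10
) -> Hypnogram:
    """Apply the four correction rules in order; first hit wins per epoch.

    ``thresholds`` must provide every key in :data:`REQUIRED_THRESHOLDS`
    (relative-dB scale).  Sleep onset is computed from the input hypnogram
    (or reused from ``sleep_onset_epoch`` if already set) and gates rule 4:
    pre-onset Wake is never converted.
    """
    missing = [k for k in REQUIRED_THRESHOLDS if k not in thresholds]
    if missing:
        raise ValueError(f"missing correction thresholds: {missing}")
    if hyp.n_epochs != bands.n_epochs:
        raise ValueError(
            f"hypnogram has {hyp.n_epochs} epochs but bands has {bands.n_epochs}"
        )
    th = thresholds
    x = bands.values
    iw, ir, il, ihd, ild = (stage_index(s) for s in (WAKE, REM, LIGHT, HIDEEP, LODEEP))
    total = np.median(x, axis=1)          # broadband level, robust to one band
    total_med = float(np.median(total))

    out = hyp.copy()
    onset = hyp.sleep_onset_epoch
    if onset is None:
        onset = find_sleep_onset(hyp, run_len=run_len)
    out.sleep_onset_epoch = onset

    for e in range(out.n_epochs):
        if out.changed_from[e] is not None:
            continue  # already corrected on a previous pass; single-shot rules
        stage = out.stages[e]
        w, r, l, hd, ld = x[e, iw], x[e, ir], x[e, il], x[e, ihd], x[e, ild]
        new = None
        if stage in (HIDEEP, LODEEP):
            if (r - l >= th["theta_ratio"]) and (l < th["theta_spindle"]):
                new = WAKE if w > r else REM                       # rule 1
            elif (total[e] >= total_med + th["theta_total"]) and (
                l < th["theta_spindle"]
            ):
                new = WAKE                                         # rule 2
            elif l > max(hd, ld):
                new = LIGHT                                        # rule 3
        elif stage == WAKE and onset is not None and e >= onset:
            if hd >= th["theta_delta"] or l >= th["theta_spindle_high"]:
                new = HIDEEP if hd >= l else LIGHT                 # rule 4
        if new is not None and new != stage:
            out.changed_from[e] = stage
            out.stages[e] = new
    return out
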