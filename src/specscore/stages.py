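"""Stage vocabularies.

Spectral stages are named for the frequency band that defines them: WAKE
(gamma, 40-95 Hz), REM (low beta, ~17-26 Hz), LIGHT (spindle band,
~11-15.5 Hz), HIDEEP (delta, 1-3 Hz) and LODEEP (slow oscillations,
0.1-1 Hz).  The ordering below is fixed and doubles as the deterministic
tie-break order for posterior decoding (earlier wins).

Visual (AASM) stages use the lowercase vocabulary ``wake/N1/N2/N3/REM``
and appear only in hypnogram-comparison inputs.
"""

from __future__ import annotations

WAKE = "WAKE"
REM = "REM"
LIGHT = "LIGHT"
HIDEEP = "HIDEEP"
LODEEP = "LODEEP"

#: Fixed stage order: index in this tuple == feature-band index == HMM state index.
SPECTRAL_STAGES: tuple[str, ...] = (WAKE, REM, LIGHT, HIDEEP, LODEEP)

#: AASM visual-scoring vocabulary accepted on the reference side of comparisons.
VISUAL_STAGES: tuple[str, ...] = ("wake", "N1", "N2", "N3", "REM")

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(SPECTRAL_STAGES)}


def stage_index(stage: str) -> int:
    """Index of a spectral stage in the fixed order (raises on unknown labels)."""
    try:
        return STAGE_INDEX[stage]
    except KeyError:
        raise ValueError(
            f"unknown spectral stage {stage!r}; expected one of {SPECTRAL_STAGES}"
        ) from None
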