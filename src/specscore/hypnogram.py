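"""Per-epoch stage sequence with change markers.

``changed_from`` records, for every epoch the correction rules touched,
the stage it held before the correction (the colour-coded dots under the
hypnogram panel in sleep reports).  ``sleep_onset_epoch`` caches the
first sustained-sleep epoch once a correction pass has computed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stages import SPECTRAL_STAGES, VISUAL_STAGES


@dataclass
class Hypnogram:
    stages: list[str]
    epoch_len: float = 30.0
    changed_from: list[str | None] = field(default_factory=list)
    sleep_onset_epoch: int | None = None

    def __post_init__(self) -> None:
        self.stages = list(self.stages)
        vocab = set(SPECTRAL_STAGES) | set(VISUAL_STAGES)
        bad = [s for s in self.stages if s not in vocab]
        if bad:
            raise ValueError(f"unknown stage label(s) {sorted(set(bad))!r}")
        if not self.changed_from:
            self.changed_from = [None] * len(self.stages)
        if len(self.changed_from) != len(self.stages):
            raise ValueError("changed_from must align with stages")
        for s, c in zip(self.stages, self.changed_from):
            if c is not None and c == s:
                raise ValueError("changed_from must differ from the final stage")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def n_changed(self) -> int:
        return sum(c is not None for c in self.changed_from)

    def start_seconds(self) -> np.ndarray:
        """Epoch start times (s); epoch e covers [e*len, (e+1)*len)."""
        return np.arange(self.n_epochs) * self.epoch_len

    def as_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)

    def copy(self) -> "Hypnogram":
        return Hypnogram(
            stages=list(self.stages),
            epoch_len=self.epoch_len,
            changed_from=list(self.changed_from),
            sleep_onset_epoch=self.sleep_onset_epoch,
        )
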