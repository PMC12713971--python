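"""Hypnogram agreement statistics on toy visual/spectral scorings.

Cross-tabulates a visually scored reference (wake/N1/N2/N3/REM) against
a spectral hypnogram, converts the counts to percentages in both
directions, and pools percentage matrices across 'subjects' with
cell-wise medians.
"""

import numpy as np

from specscore import Hypnogram, confusion, percentize, pool_medians

rng = np.random.default_rng(0)

ref = Hypnogram(
    ["wake"] * 4 + ["N1"] * 2 + ["N2"] * 10 + ["N3"] * 6 + ["REM"] * 8
)
test = Hypnogram(
    ["WAKE"] * 3 + ["LIGHT"] + ["LIGHT"] * 2 + ["LIGHT"] * 8 + ["LODEEP"] * 2
    + ["HIDEEP"] * 5 + ["LODEEP"] + ["REM"] * 8
)

cm = confusion(ref, test)
print(f"{int(cm.total)} aligned epochs\n")
print("confusion counts (rows = visual, columns = spectral):")
print(cm.to_frame().astype(int), "\n")

rows = percentize(cm, "rows")
print("row percentages (how each visual stage was scored spectrally):")
print(rows.round(1), "\n")
# e.g. the N2 row shows what fraction of visually scored N2 epochs the
# spectral algorithm called Light versus the two Deep stages.

per_subject = [rows, rows * 0.9 + 5, rows * 1.1 - 5]
print("cell-wise medians across three subjects:")
print(pool_medians(per_subject).round(1))
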