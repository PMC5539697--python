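"""Walk through the three post-processing rules on constructed hypnograms.

Each rule is shown on a minimal fixture: the WRMEnAD sandwich/absence fix,
the 110-170-epoch zero-CI wake-run detection, and REM outlier elimination
with merging.
"""

import numpy as np

import sleepfusion as sf
from sleepfusion.hypnogram import WAKE, NREM, REM, STAGE_NAMES


def show(stages):
    return "".join(STAGE_NAMES[int(s)][0] for s in stages)


# 1. a single sleep epoch between two wake epochs cannot be real sleep
before = np.array([WAKE, NREM, WAKE, NREM, NREM, WAKE], dtype=np.int8)
after = sf.wrmenad_correction(before)
print("WRMEnAD sandwich rule:")
print(f"  {show(before)} -> {show(after)}   (lone N flipped, the N-N run kept)")

# 2. a long run of epochs with zero cycle-intensity means an empty/quiet bed
n = 130
stages = np.full(n, NREM, dtype=np.int8)
ci = np.ones(n)
se = np.full(n, 5)
ci[5:120] = 0.0   # 115 consecutive zero-CI epochs
se[5:120] = 0
out = sf.sound_wake_detection(stages, ci, se)
print("\nsound-based wake detection (zero-CI run of 115 epochs in [110, 170]):")
print(f"  epochs 5-119 relabelled WAKE: {(out[5:120] == WAKE).all()}")

# 3. REM periods shorter than 3 epochs are physiologically implausible
before = np.array([NREM, REM, REM, NREM, REM, REM, NREM, REM, NREM], dtype=np.int8)
after = sf.rem_outlier_elimination(before, merge_gap=1)
print("\nREM outlier elimination (merge_gap=1):")
print(f"  {show(before)} -> {show(after)}")
print("  (the two 2-epoch runs merged across one NREM epoch and survived;")
print("   the isolated single REM epoch became NREM)")
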