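"""Score a segmentation and summarize rater agreement.

Compares an automatic mask against a reference with TP/FP/FN volume
fractions, then computes Cronbach's alpha for two raters' binary
accept/reject grades over a batch of datasets.
"""

import numpy as np

from spectspine import BinaryVolume, cronbach_alpha, volume_fractions

# --- volume fractions -----------------------------------------------------
reference = np.zeros((4, 10, 10), dtype=np.uint8)
reference[1:3, 2:8, 2:8] = 1                       # 72 voxels of truth
automatic = reference.copy()
automatic[1, 2:8, 2] = 0                           # 6 voxels missed
automatic[3, 4:6, 4:6] = 1                         # 4 voxels invented

report = volume_fractions(
    BinaryVolume(bits=automatic, threshold_used=0),
    BinaryVolume(bits=reference, threshold_used=0))
tp, fp, fn = report.as_percent()
print(f"TP = {tp}%  FP = {fp}%  FN = {fn}%   (TP + FN = 100% always)")

# --- Cronbach's alpha -----------------------------------------------------
rng = np.random.default_rng(0)
quality = rng.random(46)                           # latent case difficulty
rater1 = (quality > 0.25).astype(float)            # lenient rater
rater2 = ((quality + rng.normal(0, 0.15, 46)) > 0.35).astype(float)
grades = np.vstack([rater1, rater2])               # raters x items

alpha = cronbach_alpha(grades)
print(f"rater 1 accepted {int(rater1.sum())}/46, "
      f"rater 2 accepted {int(rater2.sum())}/46")
print(f"Cronbach's alpha = {alpha:.3f}")
print("alpha >= 0.7 conventionally indicates acceptable inter-rater "
      "consistency for such binary grades.")
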