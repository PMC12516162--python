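"""Show the attention-masking rules on a toy patch.

The mask designates which candidate the network should classify: the EPI
magnitude channel is zeroed outside the target and doubled in its interior
(so only the target's central veins matter), while other candidates are
dimmed x0.1 on the remaining channels (context is kept but de-emphasized).
"""

import numpy as np

from rimvein.patches import EPIM_CHANNEL, apply_attention_mask

patch = np.ones((4, 8, 8, 8), np.float32)
crop = np.zeros((8, 8, 8), np.int32)
crop[2:5, 2:5, 2:5] = 1     # target candidate (interior voxel at 3,3,3)
crop[6:8, 6:8, 6:8] = 2     # competing candidate

masked = apply_attention_mask(patch, crop, target_candidate_id=1)

print("EPIm outside target:   1.0 ->", masked.data[EPIM_CHANNEL, 0, 0, 0])
print("EPIm target surface:   1.0 ->", masked.data[EPIM_CHANNEL, 2, 2, 2])
print("EPIm target interior:  1.0 ->", masked.data[EPIM_CHANNEL, 3, 3, 3])
print("FLAIR other candidate: 1.0 ->", masked.data[1, 6, 6, 6])
print("FLAIR background:      1.0 ->", masked.data[1, 0, 0, 0])
print("\nRules: outside-target EPIm -> 0; interior EPIm -> x2 (surface"
      " unchanged); other candidates -> x0.1 on T1w/FLAIR/EPIp.")
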