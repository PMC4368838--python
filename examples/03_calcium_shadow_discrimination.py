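"""Separate calcified arcs from bright struts by acoustic shadowing.

The phantom scene contains four bright strut blocks (no shadow) and one
40-degree calcified arc that attenuates everything radially behind it.
Highly echogenic components with a dark behind-region become CALCIFIED and
their shadow UNKNOWN; the rest become UPPER.
"""

import numpy as np

import ivusecho as iv
from ivusecho.classification import Tissue

pb = iv.generate_pullback(iv.PhantomConfig.discrimination_scenario(seed=4))
res = iv.analyze_pullback(pb.frames, pb.contours)

truth = pb.truth.label_maps[0]
print("per-class pixel recall against phantom ground truth:")
for tissue in (Tissue.UPPER, Tissue.CALCIFIED, Tissue.UNKNOWN):
    tmask = truth == int(tissue)
    recall = np.mean([(lm.labels[tmask] == int(tissue)).mean() for lm in res.label_maps])
    print(f"  {tissue.name:<10} {recall:6.1%}  ({int(tmask.sum())} truth px/frame)")

counts = res.label_maps[0].class_counts()
print(f"\nframe 0 labeled pixels: "
      f"hypo={counts[Tissue.HYPO]} hyper={counts[Tissue.HYPER]} "
      f"upper={counts[Tissue.UPPER]} calcified={counts[Tissue.CALCIFIED]} "
      f"unknown={counts[Tissue.UNKNOWN]}")

# Recall near 100% at this contrast: shadow casting alone separates calcium
# from shadowless bright polymer, and the shadow region itself is flagged
# unclassifiable rather than counted as dark tissue.
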