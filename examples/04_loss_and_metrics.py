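"""The compound loss and the confusion-count metrics on worked examples.

Every printed number can be verified by hand from the formulas: the Dice
ratio (2*overlap + eps)/(sums + eps), BCE at p = 0.5 equal to ln 2, and
the five confusion ratios.
"""

import numpy as np

from rmisnet import (
    ConfusionCounts,
    LossConfig,
    combined_loss,
    dice_coefficient,
    segmentation_metrics,
)

pred = np.array([1.0, 1.0, 0.0, 0.0])
target = np.array([1.0, 0.0, 1.0, 0.0])
print(f"Dice((1,1,0,0),(1,0,1,0), eps=1) = {dice_coefficient(pred, target, 1.0):.4f}")
print("  hand value: (2*1 + 1) / (2 + 2 + 1) = 0.6")

half = np.full(4, 0.5)
y = np.array([1.0, 1.0, 0.0, 0.0])
loss = combined_loss(half, y, LossConfig(bce_weight=0.5, epsilon=1.0))
print(f"loss(p=0.5, y=(1,1,0,0)) = {loss:.6f}")
print("  hand value: 0.5*ln(2) + (1 - 0.6) = 0.746574")

counts = ConfusionCounts(tp=8, fp=2, fn=2, tn=4)
metrics = segmentation_metrics(counts)
print(f"metrics for TP=8 FP=2 FN=2 TN=4:")
for name, value in metrics.items():
    print(f"  {name:10s} {value:.4f}")
print("  note F1 = 2*IoU/(1+IoU): ", 2 * metrics["iou"] / (1 + metrics["iou"]))
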