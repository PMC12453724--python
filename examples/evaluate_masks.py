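"""Mask overlap metrics and the Dice-IoU identity.

Builds a prediction that covers exactly half of the ground truth with no
false positives and verifies the hand-computable metric values.
"""

import numpy as np

from leafseg import mask_metrics

truth = np.zeros((10, 10), np.uint8)
truth.ravel()[:100] = 1  # 100 true pixels
pred = np.zeros((10, 10), np.uint8)
pred.ravel()[:50] = 1  # covers half, no false positives

s = mask_metrics(pred, truth)
print(f"IoU       : {s.iou:.4f}   (TP / (TP+FP+FN) = 50/100)")
print(f"Dice      : {s.dice:.4f}   (2TP / (2TP+FP+FN) = 100/150)")
print(f"precision : {s.precision:.4f}   (no false positives)")
print(f"recall    : {s.recall:.4f}   (half the lesion found)")
print(f"identity  : 2*IoU/(1+IoU) = {2 * s.iou / (1 + s.iou):.4f} == Dice")
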