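"""Segment a noisy pseudo-CT slice and score the result.

The baseline backend (multi-level Otsu threshold + hole filling + area
filter) isolates the bright bone from the soft-tissue halo and background;
Dice, mean IoU and pixel accuracy are computed against the known mask.
"""

from ctmorph import phantom
from ctmorph.imaging_io import BinaryMask
from ctmorph.mask_segmentation import evaluate_segmentation, segment_slice

ps = phantom.make_trochlea_phantom(140.0, 7.0, noise_sd=8.0, seed=5)
predicted = segment_slice(ps.image, backend="baseline")
metrics = evaluate_segmentation(predicted, BinaryMask(ps.mask))

print(f"Dice coefficient : {metrics.dice:.4f}")
print(f"mean IoU         : {metrics.mean_iou:.4f}")
print(f"pixel accuracy   : {metrics.pixel_accuracy:.4f}")
print(f"(foreground IoU {metrics.fg_iou:.4f}, background IoU {metrics.bg_iou:.4f})")

print("\nMean IoU averages foreground and background IoU, which is why it"
      "\ncan exceed Dice on background-dominated frames. Near-1.0 values"
      "\nhere reflect that bright-bone phantoms are an easy segmentation"
      "\ntask for a global threshold; arthritic CT is what the deep"
      "\nbackends exist for.")
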