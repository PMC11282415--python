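"""Train the 9-class slice classifier and retrieve landmark slices.

Six phantom patients provide annotated slice intervals; a curated,
laterality-balanced dataset is extracted, featurized and fed to the boosted
classifier.  On a held-out stack, a linear scan of the per-slice class
probabilities returns the best slice per target landmark.
"""

import numpy as np

from ctmorph import phantom
from ctmorph.landmark_classifier import (
    AnnotatedInterval,
    curate_dataset,
    extract_feature_matrix,
    fit_classifier,
    retrieve_landmark_slices,
)

stacks, intervals = {}, []
for i in range(6):
    pid = f"p{i}"
    stack, labels, _ = phantom.make_patient_stack(seed=300 + i, patient_id=pid)
    stacks[pid] = stack
    lab = np.asarray(labels)
    for k in range(9):
        idx = np.flatnonzero(lab == k)
        intervals.append(AnnotatedInterval(pid, k, int(idx.min()), int(idx.max())))

ds = curate_dataset(intervals, stacks, per_class_target=40, seed=0)
model = fit_classifier(extract_feature_matrix(ds.images), ds.labels, seed=0)
print(f"trained on {len(ds)} images ({len(ds) // 9} per class, flip-balanced)")

held_out, labels, truth = phantom.make_patient_stack(seed=999, patient_id="held-out")
hits = retrieve_landmark_slices(model, held_out)
names = {2: "trochlea", 4: "acetabulum", 6: "femoral neck", 8: "tibial tuberosity"}
for label, hit in sorted(hits.items()):
    center = truth.landmark_slice_index[label]
    print(f"class {label} ({names[label]:17s}): slice {hit.index:2d} "
          f"(p={hit.probability:.3f}, true interval centre {center})")

print("\nEach retrieved index should fall inside that landmark's true slice"
      "\ninterval - the classifier localizes the measurable anatomy within"
      "\nthe stack without any explicit position input.")
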