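"""Measure all five clinical parameters from a set of landmark masks.

A pseudo-patient defines ground truth for femoral version, acetabular
anteversion, sulcus angle, PCA angle and TT-TG distance; `measure_all`
computes the full report from the four landmark masks, mirroring what the
pipeline does after classification and segmentation.
"""

from ctmorph import phantom
from ctmorph.morphometry import measure_all

_, _, truth = phantom.make_patient_stack(
    version_deg=15.0, anteversion_deg=17.0, sulcus_deg=140.0,
    pca_deg=7.0, tttg_mm=10.0, seed=7)

report = measure_all(phantom.truth_masks(truth), laterality="right")

print(f"{'measurement':28s} {'truth':>8s} {'measured':>9s}")
rows = [
    ("femoral version (deg)", truth.version_deg, report.femoral_version_deg),
    ("acetabular anteversion (deg)", truth.anteversion_deg,
     report.acetabular_anteversion_deg),
    ("sulcus angle (deg)", truth.sulcus_deg, report.sulcus_angle_deg),
    ("PCA angle (deg)", truth.pca_deg, report.pca_angle_deg),
    ("TT-TG distance (mm)", truth.tttg_mm, report.tttg_mm),
]
for name, t, v in rows:
    print(f"{name:28s} {t:8.2f} {v:9.2f}")

print("\nAll five agree within a degree / millimetre: the contour geometry"
      "\n(best-fit line, hull defects, posterior tangents, projections)"
      "\nrecovers the construction parameters from the masks alone.")
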