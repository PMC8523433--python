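"""Place ROIs on the fovea-centered polar grid and look up detection radii.

Eccentricity in degrees of visual angle converts to retinal distance at
291 µm/deg; ROI centers fall on the four principal meridians, and the
cone-detection radius grows with eccentricity following inner-segment
diameter.
"""

from conemosaic import FoveaAnchor, deg_to_um, radius_for_eccentricity, roi_center

fovea = FoveaAnchor(x_um=3000.0, y_um=3000.0, laterality="OD")

print("ecc(deg)  dist(um)  radius(um)  temporal ROI center (x, y) um")
for ecc in (2.0, 3.0, 5.0, 7.0, 9.0):
    x, y = roi_center(fovea, ecc, "temporal")
    print(f"{ecc:7.0f} {deg_to_um(ecc):9.0f} {radius_for_eccentricity(ecc):10.2f}   ({x:7.0f}, {y:7.0f})")

# The distance column is ecc x 291; the radius column is the local-maxima
# suppression radius used by the detector at that eccentricity.
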