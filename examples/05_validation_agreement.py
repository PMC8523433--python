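"""Bland-Altman agreement between automated and 'manual' cone densities.

Automated densities come from the pipeline on a synthetic cohort; the
manual counts are emulated as the ground-truth densities of the same ROIs
(what a careful human marker would produce). The Bland-Altman analysis
reports the mean difference, 95% limits of agreement, and a regression of
difference on mean to detect proportional bias.
"""

import numpy as np

from conemosaic import ROISpec, bland_altman, metrics_from_cones
from conemosaic.detection import DetectionParams, crop_cones, detect_cones, to_16bit_sharpened
from conemosaic.geometry import radius_for_eccentricity
from conemosaic.synthetic import eccentricity_preset, generate_mosaic, render_image

auto, manual = [], []
for ecc in (2.0, 3.0, 5.0):
    for seed in range(8):
        spec = eccentricity_preset(ecc, seed=seed)
        truth = generate_mosaic(spec)
        det = detect_cones(to_16bit_sharpened(render_image(truth)),
                           DetectionParams(radius_um=radius_for_eccentricity(ecc)))
        roi = ROISpec(ecc, "temporal", 222.0)
        win = (9.0, 9.0, 231.0, 231.0)
        auto.append(metrics_from_cones(crop_cones(det, *win), roi).density_cones_per_mm2)
        manual.append(metrics_from_cones(crop_cones(truth.cones, *win), roi).density_cones_per_mm2)

r = bland_altman(np.array(auto), np.array(manual))
print(f"n pairs            : {r.n}")
print(f"mean difference    : {r.mean_diff:8.1f} cones/mm^2 (auto - manual)")
print(f"limits of agreement: ({r.loa_low:.1f}, {r.loa_high:.1f})")
print(f"proportional bias  : slope {r.prop_bias_slope:.4f}, p = {r.prop_bias_p:.3f}")

# A negative mean difference reflects the detector's known conservative
# bias (merged cone pairs); the proportional-bias slope tests whether that
# bias grows with density.
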