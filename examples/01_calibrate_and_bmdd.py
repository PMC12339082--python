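"""Calibrate a qBEI image and characterize its mineralization distribution.

Generates a small synthetic bone section, converts its 8-bit gray levels to
calcium weight-percent using the two-point carbon/aluminum standards
calibration, and computes the bone mineralization density distribution
(BMDD) of the metaphyseal compartment with its scalar descriptors.
"""

from osteoquant import (
    apply_calibration,
    bmdd_params,
    compute_bmdd,
    fit_calibration,
    generate_bone_image,
)
from osteoquant.synthetic import SyntheticConfig

cfg = SyntheticConfig(image_width_px=520, metaphysis_um=700.0, epiphysis_um=200.0)
raw, truth = generate_bone_image(cfg, seed=1)

# standards measured during the (simulated) imaging session
model = fit_calibration(cfg.carbon_gl, cfg.aluminum_gl)
camap = apply_calibration(raw, model, pixel_size=cfg.pixel_size)
print(f"calibration: {model.slope} wt%Ca per canonical gray step")

# BMDD of the metaphyseal zone (below the growth plate)
metaphysis = truth.zone_labels >= 4
curve = compute_bmdd(camap, region=metaphysis)
params = bmdd_params(curve)
print(f"metaphysis BMDD over {curve.n_pixels} mineralized pixels")
print(f"  CaMean  = {params.ca_mean:6.2f} wt%Ca   (planted zone mean 21.5)")
print(f"  CaPeak  = {params.ca_peak:6.2f} wt%Ca   (most frequent calcium content)")
print(f"  CaWidth = {params.ca_width:6.2f} wt%Ca  (FWHM ~ 2.355 x planted sd 2.0 = 4.71)")

# CaMean/CaPeak sit near the planted 21.5 wt%Ca Gaussian mean and CaWidth
# near its full width at half maximum: the gray-level detour is lossless up
# to the 0.17 wt%Ca resolution of the calcium scale.
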