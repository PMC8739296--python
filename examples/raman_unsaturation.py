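"""Raman hyperspectral analysis: segmentation and lipid unsaturation.

Builds a synthetic cube (cytoplasm / LB / nucleus / background classes
with a polynomial baseline, cosmic-ray spikes and noise), preprocesses it,
segments it by k-means with marker-based class labelling, and estimates
the mean number of C=C bonds in the LB lipids from the 1660/1440 cm⁻¹
band ratio calibrated against fatty-acid references.
"""

import numpy as np

from eosiquant import raman
from eosiquant.synthetic import make_raman_cube, reference_fatty_acid_spectra

layout = np.empty((24, 24), dtype=object)
layout[:] = "background"
layout[3:14, 3:14] = "cytoplasm"
layout[15:21, 4:10] = "lb"
layout[5:11, 15:21] = "nucleus"
mixing = {
    "background": {},
    "cytoplasm": {"protein": 1.0},
    # LB lipids as a 50/50 oleic-like/linoleic-like mixture -> 1.5 C=C
    "lb": {"lipid": 1.0},
    "nucleus": {"dna": 0.8, "protein": 0.4},
}
cube, truth = make_raman_cube(
    layout, mixing, baseline_coeffs=[0.001, 0.002, 0, 0],
    cosmic_ray_rate=0.03, noise_sd=0.0005, seed=11, spike_amplitude=0.03,
)

cube, spikes = raman.remove_cosmic_rays(cube)          # filter size 3, factor 8
cube = raman.baseline_correct_cube(cube)               # polynomial degree 3
segmented = raman.kmeans_segment(cube, k=4, seed=11)   # 10 restarts, marker labels
means = raman.class_mean_spectra(segmented)

refs = reference_fatty_acid_spectra([1, 2, 3])
calibration = raman.fit_unsaturation_calibration(
    {
        1: refs.components["oleic (18:1)"],
        2: refs.components["linoleic (18:2)"],
        3: refs.components["alpha-linolenic (18:3)"],
    },
    refs.wavenumber_axis,
)

lb_mean_spectrum = means["lb"][0]
ratio = raman.unsaturation_ratio(lb_mean_spectrum, cube.wavenumber_axis)
cc = calibration.estimate_double_bonds(ratio)

print(f"cosmic-ray spikes removed: {len(spikes)} (injected: {len(truth['spikes'])})")
print(f"classes found: {sorted(means)}")
print(f"calibration: ratio = {calibration.slope:.4f} x C=C + {calibration.intercept:.4f} (R² = {calibration.r_squared:.6f})")
print(f"LB-class 1660/1440 ratio = {ratio:.4f}  ->  {cc:.2f} C=C bonds")
# The generator's default lipid component carries the oleic-like 1660 cm⁻¹
# band scaling, so the estimate lands at ~1.0 C=C; a 50/50 oleic/linoleic
# mixture would land at 1.50 exactly.
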