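"""Count nuclei and BODIPY LB spots in fluorescence images; compare groups.

Four synthetic image pairs per condition emulate a plate experiment:
nuclei are counted in the Hoechst channel (area > 5 µm²), LB spots in the
BODIPY channel (area > 2 µm²), and the LBs/cell ratio is aggregated as
mean of image means ± SEM.  The two conditions are compared with the
exact Mann–Whitney U test.
"""

from eosiquant import fluor
from eosiquant.synthetic import PoissonLaw, make_fluorescence_scene

ratios = {}
for offset, (group, mean) in enumerate([("control", 2.35), ("stimulated", 3.08)]):
    per_image = []
    for i in range(4):
        (hoechst, bodipy), _ = make_fluorescence_scene(
            n_cells=60, lb_count_law=PoissonLaw(mean), pixel_size=0.65, seed=100 * i + 7 * offset
        )
        nuclei = fluor.find_nuclei(hoechst)
        spots = fluor.find_spots(bodipy, nuclei)
        per_image.append((len(spots), len(nuclei)))
    summary = fluor.lbs_per_cell_ratio(per_image)
    ratios[group] = summary
    print(f"{group:11s} LBs/cell = {summary.mean:.2f} ± {summary.sem:.2f} (mean of 4 image means ± SEM)")

test = fluor.mann_whitney_compare(
    ratios["control"].per_image_ratios, ratios["stimulated"].per_image_ratios
)
print(f"Mann-Whitney U = {test.U:.1f}, two-sided p = {test.p:.3f} {test.stars or '(n.s.)'}")
# With only 4 images per group the exact test cannot go below p = 1/35,
# so a consistent shift shows up as p ~ 0.03 ('*').
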