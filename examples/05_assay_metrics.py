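"""Quantify phage-defense assays: plaque opacity and adsorption.

Builds a synthetic plaque image (a dim spot on a bright lawn, plus a
fully opaque spot), computes plaque/lawn intensity ratios with replicate
mean +/- SD, and an adsorption time course from PFU counts. Ratio 1.0 =
no visible clearing (strong defense); adsorption percentages follow
(PFU_control - PFU_sample) / PFU_control x 100.
"""

import numpy as np

from randgene import (
    AdsorptionSeries,
    IntensityImage,
    adsorption_timecourse,
    plaque_lawn_ratio,
    replicate_ratio_stats,
)


def spot_image(spot_intensity, lawn_intensity=200.0):
    pixels = np.full((40, 40), lawn_intensity)
    plaque = np.zeros((40, 40), dtype=bool)
    plaque[15:25, 15:25] = True
    pixels[plaque] = spot_intensity
    return IntensityImage(pixels=pixels, plaque_mask=plaque, lawn_mask=~plaque)


clearing = plaque_lawn_ratio(spot_image(40.0))     # lysed, translucent spot
defended = plaque_lawn_ratio(spot_image(200.0))    # opaque, lawn-like spot
print(f"cleared plaque ratio : {clearing:.2f}  (effective infection)")
print(f"defended spot ratio  : {defended:.2f}  (near-complete defense)")

mean, sd = replicate_ratio_stats([0.82, 0.90, 0.86])
print(f"replicates           : {mean:.2f} +/- {sd:.2f} (mean +/- SD, n=3)")

series = AdsorptionSeries(
    timepoints=[0, 5, 10, 15, 20],
    pfu_control=[100, 100, 100, 100, 100],
    pfu_sample=[98, 80, 55, 35, 25],
)
print("\nadsorption time course:")
print(adsorption_timecourse(series).to_string(index=False))
# Rising percent_adsorbed means phages are binding cells; a defended
# strain keeps percent_remaining high by blocking receptor availability.
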