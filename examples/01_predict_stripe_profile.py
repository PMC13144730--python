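"""Predict the 4C-like contact enrichment of a condensin loading site.

Builds the loop-size distribution for a 150 kb-processivity extruder with a
partial roadblock, converts it into the expected viewpoint profile, and
prints the stripe enrichment P(s)/P0(s) at a few distances.
"""

import numpy as np

from stripefit import (
    ExtrusionParams,
    Roadblock,
    RoadblockSet,
    composite_loop_density,
    predict_ratio_profile,
)

params = ExtrusionParams(processivity_p=150.0, density_d=0.1)
blocks = RoadblockSet([Roadblock(position_l=120.0, pause_alpha=0.45)])

dist = composite_loop_density(params, blocks)
print(f"loop-size distribution: {dist.grid.size} bins, "
      f"atom at block = {dist.atoms[120.0]:.4f} "
      f"(fraction of extruders held at the 120 kb roadblock)")

s = np.arange(1.0, 501.0)
enrichment = predict_ratio_profile(params, blocks, s)
for probe in (10, 50, 120, 200, 400):
    print(f"  s = {probe:3d} kb: P(s)/P0(s) = {enrichment.values[probe - 1]:6.2f}")
print("The sharp maximum at 120 kb is the contact 'dot' of loops held at the")
print("roadblock; elsewhere the enrichment rises toward the processivity scale")
print("and relaxes to 1 once loops can no longer reach.")
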