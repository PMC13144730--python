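"""Full analysis on a synthetic contact matrix: extract, ratio, fit.

Generates a Poisson-sampled 1 kb matrix bearing one extrusion stripe,
extracts the smoothed viewpoint profile and six matched background
controls, forms the enrichment ratio and grid-fits processivity and
density with the measurement operator (window averaging + smoothing)
applied to the model.
"""

import warnings

from stripefit import (
    ExtrusionParams,
    FitConfig,
    RoadblockSet,
    SyntheticSpec,
    Viewpoint,
    average_controls,
    extract_profile,
    grid_fit,
    ratio,
    synth_matrix,
)

spec = SyntheticSpec(
    ExtrusionParams(processivity_p=150.0, density_d=0.10),
    arm_length=500.0, loading_site_kb=100.0, seed=42,
)
matrix = synth_matrix(spec)
print(f"synthetic matrix: {matrix.n_bins} x {matrix.n_bins} bins at 1 kb, "
      f"stripe from a loading site at 100 kb (true p=150 kb, d=0.10)")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    viewpoint = extract_profile(
        matrix, Viewpoint("synthetic", 100_500, window_kb=3.0, orientation="W"),
        smooth_kernel=39, smooth_order=2,
    )
    controls = average_controls([
        extract_profile(
            matrix, Viewpoint("synthetic", c * 1000 + 500, 3.0, "W"), 39, 2
        )
        for c in (40, 50, 60, 70, 80, 90)
    ])
    observed = ratio(viewpoint, controls)

config = FitConfig(
    known_blocks=RoadblockSet((), 500.0),
    viewpoint_window_kb=3.0, smooth_kernel_kb=39.0, smooth_order=2,
)
result = grid_fit(observed, config)
print(f"best fit: processivity = {result.best_p:.0f} kb, density = {result.best_d:.2f}")
print(f"minimum MSD = {result.msd_surface.min():.2e} over a "
      f"{result.p_grid.size} x {result.d_grid.size} (p, d) grid")
print("The fit recovers the generating parameters because the forward model")
print("passes through the same smoothing/averaging the extraction applied.")
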