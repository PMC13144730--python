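# Methods

## The scrunching model and its observables

`stripefit` models one-sided ("scrunching") loop extrusion at a discrete
loading site: a condensin binds at rate `k_b`, anchors one leg, translocates
the other at speed `v_e`, and unbinds at rate `k_u`. Stationary contact data
constrain only two combinations of these rates — the processivity
`p = v_e / k_u` (kb) and the bound density `d = k_b / (k_b + k_u)` — so the
simulator fixes `v_e = 1` by default and all inference is over `(p, d)`.

Free loops are exponential with mean `p`. A roadblock at distance `l_i`
engaged with probability `α_i` truncates the exponential and holds the
truncated mass at `l_i`; ordered blocks compose by survival products
(`∏_{k<i}(1−α_k) α_i`), reflecting that a non-engaged block is transparent
for the rest of that binding event. A block spread over a domain is treated
as a barrier placed uniformly on the grid points inside the domain, each
placement evaluated in full and the results averaged. Contacts follow the
Gaussian-polymer rules: background `P0(s) = A s^(−γ)` with γ = 1.5 (ideal
chain; γ is fixed, not fitted, and configurable for more compact regions),
within-loop contact `A [s(l−s)/l]^(−γ)`, exactly 1 at the closure point
`s = l`, and `A (s−l)^(−γ)` beyond the loop.

## Discretization and normalization

Everything lives on a uniform grid (default 1 kb, the Hi-C bin size). The
loop-size sum in the profile mixture is a discrete sum over grid bins; the
continuum within-loop integral would diverge at `l → s` for γ = 1.5, and the
unit closure contact at the `s = l` bin is the only finite reading. Two
numerical choices follow:

* **Exact bin masses.** The continuous part of every loop-size distribution
  stores exact integrals of the truncated exponential over bins centered on
  grid points (edge bins absorb the half-bin slivers); truncation tails are
  exact point atoms. Total mass is 1 to machine precision for any valid
  roadblock configuration — the normalization suite tests this at 1e-6.
* **One-bin floor on effective separations.** Adjacent to a loop closure the
  within-loop expression `s(l−s)/l` drops below the grid resolution and the
  continuum contact would exceed the closure contact itself; effective
  separations are floored at one bin so the closure point is the local
  maximum.

Loop-size support is capped at `min(10 p, terminal)`, where `terminal` is
the chromosome-arm end treated as an absorbing block (extrusion cannot
proceed past it); the capped tail sits in a terminal atom. With A = 1 (the
default throughout) the closure bins need no special amplitude handling;
for A ≠ 1 the amplitude cancels from ratio profiles except through those
closure-bin terms, because every distance bin contains the `l = s`
loop-size bin. True scale-free amplitude invariance of the ratio therefore
holds only for the non-closure part of the mixture, which the tests verify
term-exactly.

A consequence worth stating: the predicted enrichment `P(s)/P0(s)` is not
monotone in `s`. It rises from the viewpoint (the background decays faster
than the stripe), peaks near ~1.5 `p`, and relaxes to 1 only beyond the
loop-size support. Enrichment onset tens of kb from the viewpoint is a
feature of the model, not an artifact.

## Profile extraction

A viewpoint profile is the mean of the matrix rows covering the viewpoint
window (3 kb default), read outward in the viewpoint orientation (W =
toward increasing coordinates, C = toward decreasing), Savitzky–Golay
smoothed and re-normalized to sum 1. Kernel presets follow the analysis
conventions for this data type: 39 kb / order 2 for whole chromosomes,
9 kb / order 1 for zooms, and an unsmoothed preset (used for coarse-binned
viewpoints). Kernels given in kb are converted to bins and forced odd.
Filter ends are handled by polynomial fits on the shrunken window rather
than padding; NaN (filtered) bins are linearly interpolated for the filter
and masked back afterwards. Six matched control viewpoints are averaged
pointwise and the profile/control ratio is the experimental estimate of
`P(s)/P0(s)`. Replicates are processed as per-replicate ratios, then
mean ± SEM; LOWESS detrending (ratio divided by its smooth trend) is
available for flagging residual peaks.

## Fitting

`grid_fit` scans an exhaustive (p, d) grid — default 10–500 kb in 10 kb
steps × 0.01–0.30 in 0.01 steps — minimizing the mean squared deviation
between observed and predicted ratios over a fit window starting at 10 kb
(nearer bins are self-ligation and smoothing-edge dominated; the window is
configurable). The full MSD surface is retained; ties break toward smaller
p, then smaller d. Two details matter for unbiased estimates:

* **Normalization matching.** Experimental profiles are sum-to-1
  normalized, so the forward model normalizes `P` and `P0` over the same
  support before dividing; the raw ratio differs by a multiplicative
  constant that would bias `d` (by ~15% at d = 0.1 on a 500 kb arm).
* **Measurement operator.** For ratios extracted from matrices, the model
  prediction is passed through the identical viewpoint-window averaging and
  Savitzky–Golay filter before comparison. Without this, the smoothing
  alone biases `p` by ~20 kb and the window averaging by ~50 kb in the
  opposite direction.

Roadblocks are estimated post hoc: the residual (observed over the
no-extra-block prediction) is LOWESS-detrended, peaks at least 50% above
baseline and ≥ 3 kb wide at half prominence are taken largest-first, each
pause probability is refined by a bounded 1D search on the local MSD
(window ±20 kb or twice the peak width), and accepted blocks enter the
prediction before the next peak. Candidates refining below α = 0.05 — the
method's resolution at 10⁶-contact depth — are discarded. Because a strong
unmodeled block biases the base (p, d) fit, `fit_with_blocks` alternates
grid fit and block estimation (three rounds); for weak blocks (α ≲ 0.25)
a single pass already leaves (p, d) within one grid step.

## Synthetic data

The generator emulates the statistical structure of 1 kb balanced
intra-chromosomal Hi-C: a power-law background (exponent γ_bg, default γ),
an extrusion stripe on the rows covering a 3 kb loading element, multinomial
count noise at a fixed per-profile depth (default 10⁶ contacts — sampled
read pairs), Poisson noise per matrix cell, independent replicates (default
3, matching typical biological replication), and matched background-only
control viewpoints. The 500 kb default arm reflects the chromosome-arm
scale of the stripes being modeled. Condition presets carry the fitted
parameter combinations for the main experimental conditions (asynchronous
RE: p = 150, d = 0.06; asynchronous rDNA: 120, 0.11; G1 rDNA: 170, 0.11;
S-phase RE: 80, 0.09; condensin-depleted: 150, 0.02; inverted RE toward
the centromere: 170, 0.08 with α = 0.45 at the ~85 kb RE–CEN3 separation;
DSB construct: 170, 0.05 with α = 0.9 at 165 kb).

What the generator does **not** emulate: Rabl-configuration inter-arm
contacts, replication-coverage gradients, trans contacts, overdispersion
beyond multinomial/Poisson counting noise, and secondary stripe structure
off the loading row (loop-interior contacts between non-anchor loci).
Passing round trips therefore demonstrate correctness of the analysis
chain under counting noise, not robustness to every artifact of real maps.

## Validation and known limitations

The event-driven simulator is an independent oracle: it simulates the
binding/translocation process (per-binding Bernoulli block engagement,
exponential waits, growth capped by the first engaged block or the arm
end) and its stationary loop sizes match the analytic mixtures to KS
< 0.01 at 10⁵ samples across free, partial, impermeable, multi-block and
domain-block configurations, including the held-at-block atom mass.
Observations are thinned at 3/k_u, the bound-state correlation time scale.

Limitations worth knowing:

* **(p, d) ridge at large p.** When p approaches half the observed arm,
  the MSD surface develops a shallow anticorrelated ridge and single-seed
  estimates scatter by 2–3 grid steps at 10⁶-contact depth (e.g. ~65–70%
  one-step recovery at p = 250, d = 0.1 on a 500 kb arm, versus 100% for
  p ≤ 150 at d ≤ 0.1; ~91% pooled over the full recovery design). Longer
  arms or deeper sequencing sharpen the ridge.
* **Strong pauses couple into (p, d).** An α ≈ 0.45 block shifts the
  no-block fit by several grid steps; the alternating fit brings α back
  within ±0.10 but condition-level estimates are best reported as medians
  over datasets (as `scripts/acceptance.py` does).
* **Near-absolute blocks pin at the boundary.** For a true α = 0.9 the
  pass-through stripe is near the noise floor at 10⁶ contacts, so the
  bounded α search typically returns 0.98–1.0; the robust statement is the
  classification α ≥ 0.8.
* **Single extruder per site.** The analytic core models one anchored
  extruder; collisions, stacking, and two-sided extrusion appear only in
  the simulator's scenario rendering.
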