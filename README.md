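# stripefit

Inference of SMC loop-extrusion parameters from Hi-C contact stripes.

In budding yeast, condensin loaded at a discrete site (the recombination
enhancer *RE*, the rDNA flanks) reels chromatin through itself with one leg
anchored, leaving a characteristic *stripe* of enriched contacts in 1 kb
Hi-C maps. `stripefit` turns such stripes into numbers: the motor's
**processivity** `p = v_e / k_u` (mean loop size before unbinding, in kb),
the **density** `d = k_b / (k_b + k_u)` (probability that an extruder is
bound and holding a loop), and the **pause probability** `α` of cis-acting
roadblocks (centromeres, replication forks, highly transcribed genes, DNA
double-strand breaks).

## Model

The stationary loop-size distribution of a one-sided extruder is
exponential, `ρ0(l) = (1/p) e^(−l/p)`. An engaged roadblock at distance
`l_i` truncates it and concentrates the truncated mass into an atom,

```
ρ_i(l) = (1/p) e^(−l/p)   for l < l_i,
         e^(−l_i/p)       at l = l_i,
         0                 beyond,
```

and `n` ordered blocks with pause probabilities `α_i` mix these components
with weights `∏_{k<i}(1−α_k) α_i` (pass every earlier block, engage this
one). A Gaussian-polymer contact model converts loop sizes into contacts:
background `P0(s) = A s^(−γ)` (γ = 1.5 for an ideal chain), a fixed loop of
size `l` giving `P(s,l) = A [s(l−s)/l]^(−γ)` inside the loop, exactly 1 at
the closure point `s = l`, and `A (s−l)^(−γ)` beyond. The observable
viewpoint profile is the mixture

```
P(s) = (1 − d) P0(s) + d Σ_l ρ(l) P(s, l),
```

and its ratio to matched control viewpoints, `P(s)/P0(s)`, is what the
package predicts, extracts from data, and fits by an exhaustive
mean-squared-deviation scan over a (p, d) grid, with roadblock pauses
estimated from residual peaks. An independent event-driven stochastic
simulator validates the analytic distributions, and a synthetic-data
generator produces count-noised test inputs with known ground truth.

## Worked example

Fit a synthetic stripe-bearing matrix end to end
(`python examples/03_extract_and_fit_matrix.py`):

```
synthetic matrix: 600 x 600 bins at 1 kb, stripe from a loading site at 100 kb (true p=150 kb, d=0.10)
best fit: processivity = 150 kb, density = 0.10
minimum MSD = 3.53e-03 over a 50 x 30 (p, d) grid
```

The matrix is Poisson-sampled at ~10⁶ contacts on the viewpoint row; the
3 kb viewpoint window is extracted toward the arm end, Savitzky–Golay
smoothed (39 kb kernel, order 2), normalized to sum 1 and divided by the
mean of six background control viewpoints; the grid fit applies the same
window-averaging and smoothing to the model prediction and recovers the
generating parameters exactly. Roadblock estimation
(`python examples/04_estimate_roadblocks.py`) on data with a
centromere-like pause prints:

```
fitted: p = 180 kb, d = 0.07
roadblock: position 121 kb, pause probability 0.43, peak width 3 kb
```

i.e. the pause site is located to the bin and its engagement probability
(true 0.45) recovered to a few hundredths.

Other examples: `01_predict_stripe_profile.py` (analytic enrichment
profiles), `02_simulate_extrusion.py` (simulator vs closed form),
`05_loading_scenarios.py` (loading-geometry signatures at a DSB-like
block). A thin CLI wraps the same calls:

```sh
stripefit synth --preset async_RE --seed 1 --out demo/
stripefit fit --ratio demo/ratio.tsv --out-report report.json
stripefit run examples/demo_config.yaml --out out/
```

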