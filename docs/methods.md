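# Methods

This note documents the model, the defaults and why they were chosen,
the numerical choices, and what the synthetic benchmarks do and do not
establish.

## Kinetic model

A circuit is a directed signed graph of genes. Gene `i` evolves as

    dx_i/dt = G_i · ∏_{j→i} H(x_j; X0_ji, n_ji, λ_ji) − k_i x_i

where the product runs over regulators of `i` (empty product = 1) and
`H(x; X0, n, λ) = λ + (1−λ)/(1+(x/X0)^n)` is the shifted Hill function:
baseline 1 with no regulator bound, asymptote λ, value `(1+λ)/2` at
`x = X0`. Activating edges carry λ > 1; inhibitory edges sample a fold
λ ≥ 1 and store its reciprocal, so λ < 1 always weakens the target.
Time and expression are in arbitrary units; only ratios matter.

### Stochastic dynamics

Euler–Maruyama with additive Gaussian noise:

    x(t+dt) = max(0, x + f(x)·dt + D·sqrt(dt)·η),  η ~ N(0, I)

`D` is the *noise amplitude*; the implied diffusion constant is `D²/2`,
so an unregulated gene is an Ornstein–Uhlenbeck process with stationary
variance `D²/(2k)` (tested against that closed form). The amplitude
convention — rather than making `D` the diffusion constant — is what
makes the 0–50 noise range used throughout meaningful against
expression levels of order 1–1000: at `D ≈ 50` the stationary spread
(~`D/sqrt(2k)`) is comparable to typical expression levels and distinct
states merge, while at `D ≈ 1` it is a small perturbation. The same
convention, with the identical interpretation, drives the double-well
benchmarks (effective temperature `D²/2`).

Negative excursions are clamped to zero (expression is nonnegative; the
clamp acts as an absorbing-then-reflecting floor). With `D = 0` the
scheme is exactly forward Euler, and the code draws no random numbers,
so deterministic runs are bitwise reproducible regardless of seeding.

Defaults: `dt = 0.05`, `T = 50` for circuit ensembles (halving `dt`
changes converged terminal states by < 1e−3 relative); `dt = 0.02` for
the stiffer 1-D double wells.

## Random ensembles

Parameter ranges (uniform sampling):

| parameter | default range | note |
|---|---|---|
| production `G` | 1 – 100 | per gene |
| degradation `k` | 0.1 – 1 | per gene; timescales 1–10 |
| Hill `n` | integers 1 – 6 | cooperativity is integer-valued |
| fold-change λ (activation) | 1 – 100 | |
| fold-change (inhibition) | 1 – 100, stored as 1/λ | separate range configurable |
| threshold `X0` | (0.02 – 1.98) × M | half-functional rule |

`M` is the median unregulated level, estimated once as the median of
`G/k` over 10⁴ draws with a fixed internal seed (so ranges are a pure
function of the configuration). Drawing `X0` in a symmetric bracket
around `M` puts a typical regulator near its half-effect point; the
bracket midpoint 1.0 keeps the threshold median at `M`.

One range per parameter class is shared by all genes and edges — the
ensemble is exchangeable across genes, which is what makes
ensemble-level cluster structure attributable to topology rather than
to per-gene choices.

### Parametric variation

`P` (percent) rescales every range `(x_min, x_max)` about its midpoint:

    y_min/max = (x_max+x_min)/2 ∓ (x_max−x_min)/2 · P/100

`P = 100` is the identity (returned exactly, bypassing roundoff);
`P = 0` collapses each range to its midpoint, making every model
identical. The midpoint is conserved for every `P` and the width is
monotone in `P` (property-tested). Integer Hill coefficients are drawn
from the integers inside the scaled bounds, falling back to the rounded
midpoint if the scaled range contains none.

### Initial conditions

Per gene, log-uniform between 1 and `G_i/k_i × ∏ λ` over incoming
*activating* edges. The activation factor is essential, not cosmetic:
attractors of self-activating genes sit up to λ-fold above the
unregulated level, and an initial-condition ceiling of `max(G)/min(k)`
never reaches their basins — state enumeration then reports the ON
states as absent.

## Sampling protocols

* **SIC** — one long trajectory at fixed `D`, recorded every
  `record_interval` (after an optional burn-in). Correct but trapped in
  a single basin at low noise.
* **MIC** — independent short runs at fixed `D`, one terminal record
  each. For circuit ensembles each random model gets exactly one random
  initial condition: with thousands of models of similar parameters
  this covers the state repertoire, and enlarging the ensemble improves
  convergence faster than adding initial conditions per model.
* **SA** — the ensemble starts at the top of a decreasing noise ladder
  and relaxes `τ` time units per level, carrying terminal states
  downward; records are kept at every level, so one run yields a
  distribution per noise level. Default circuit ladder: 50 → 0 in 30
  linear levels, `τ = 5` (total cost 150 time units per model,
  comparable to a handful of MIC runs); double-well ladder: 0.8 → 0 in
  30 levels, `τ = 50`, slow enough that the shallow well empties before
  the ladder freezes.
* **Randomized-noise MIC** — `D` becomes one more random model
  parameter, uniform on (0, D_max); binning terminal records by `D`
  afterwards yields the global noise-bifurcation picture in one pass.
  Any other randomized parameter can serve as the binning axis.

## State analysis

**Normalization.** `log2(1 + x)`, then per-gene z-score against a
stored reference (the zero-noise or pooled ensemble), so different
noise slices share one scale. The pseudocount maps the zero-clamp atom
continuously onto genuinely low expression; a floor-then-log transform
instead produces a detached outlier mass tens of log-units away that
clustering mistakes for a state. Zero-variance genes fall back to unit
variance with a warning.

**State counting.** Gaussian mixtures for k = 1…6, full covariance,
seeded, BIC-selected — then two corrections that turn *components* into
*states*: (i) component pairs whose projected two-Gaussian mixture is
unimodal along the line joining their means are merged (BIC routinely
spends extra Gaussians describing one skewed cluster; a state is a
mode); (ii) clusters holding under 10% of records are folded into their
nearest cluster (an ensemble state is a cluster a non-negligible share
of models occupies). Requires ≥ 50 records.

For the toggle-switch merging readout the counter is applied to the
single-gene marginal — the same one-gene histogram in which the two
mutually exclusive states are classically displayed. The 2-D joint
distribution additionally resolves a co-expression cluster at low
noise, which is real but a different question.

**Bhattacharyya distance.** `BD(p,q) = −ln Σ√(p_i q_i)` on identical
binning; nonnegative, symmetric, zero iff equal, capped at 100 for
disjoint supports. Expression samples are compared per gene on 100
uniform bins spanning the pooled range, then averaged over genes —
keeping BD comparable across circuits of different size. Because the
binning is finite and sample-based, absolute BD values are
estimator-specific; orderings and trends are the meaningful output.

**Response time.** BD between the normalized expression distribution
at each recorded time and the end-of-run (T = 50) zero-noise
distribution of the same models and initial conditions. Saturation =
relaxation; noisier ensembles saturate earlier at a higher plateau.

**Noise robustness.** BD between the zero-noise terminal distribution
and the terminal distribution at each `D` on a small grid (same models,
same initial conditions). Headline index: BD at `D = 1`; secondary: the
low-noise slope, least squares through the origin on `D ≤ 1`.

**Embeddings.** PCA (first two components, deterministic full SVD,
signs fixed so each component's largest-magnitude loading is positive)
and average-linkage hierarchical clustering on Euclidean distances.

## Deterministic state enumeration and the quadrastable switch

Enumeration relaxes 100 random initial conditions per model at `D = 0`
(horizon 250 time units, per-row early stop once
`|dx/dt|/(1+|x|) < 1e−7`), discards non-converged end points (residual
≥ 1e−4), and greedily merges fixed points within 1% relative tolerance.
A JIT-compiled per-row kernel does this when numba is importable; a
vectorized NumPy path gives the same fixed points otherwise.

States are labeled low/high per gene against the geometric midpoint of
that model's fixed-point expression range. A model is *quadrastable*
when exactly four states carry the four labels LL, LH, HL, HH.

**Calibration.** The broad default ranges almost never produce
four-phenotype models: with mutual inhibition as strong as
self-activation the four combinations cannot coexist, and with basal
production at default levels the OFF state (which requires
`X0 ≳ 2λ^(1/n) ×` basal) is destroyed. `QUADRASTABLE_RANGES` therefore
emulates the engineered synthetic construct this experiment models: low
leaky basal production (1–10) with similar reporter stabilities
(degradation 0.5–1), strong cooperative inducible self-activation
(fold 20–100, Hill 4–6, thresholds 2–6× the basal median — OFF by
default, inducible ON), and comparatively weak mutual repression (fold
1–5). About 15% of random models are then quadrastable. Under these
conditions the package reproduces the basin/stability dissociation:
at zero noise MIC leaves a large share of models in LL (big basin),
while annealing leaves none there (no stability) and enriches HH.

**Induction.** An induction factor IF strengthens a gene's
self-activation link: fold-change × IF and activation threshold ÷ IF —
i.e., each activator molecule becomes IF-fold more potent, the natural
model of a drug that boosts an engineered activator. Scaling the
fold-change alone cannot destabilize the OFF state at zero noise (the
threshold never approaches basal), and the experiment's signature —
low-low driven to high-high by simultaneous induction, with hysteresis
on removal — is then unreachable. Stages are arbitrary
`{gene: IF}` schedules, so sequential, simultaneous, ramped and removal
protocols are all expressible; terminal states are labeled with the
enumeration thresholds.

## Double-well benchmarks

Langevin dynamics `dx = −V′(x)dt + D√dt·η` on four quartic variants
that factor basin width against depth: `a` symmetric; `b` = a − 0.1x
(equal basins, right well deeper); `c` a piecewise-stretched quartic
with minima at −0.5 and +1.5 and equal depths (basins 1:2 inside the
sampling domain (−1, 2)); `d` = c + 0.15x (narrow left well deeper;
the stronger tilt gives a depth contrast large enough for annealing to
resolve within the desk-scale schedule). Minima and saddles are refined
numerically and asserted to be critical points. Benchmark noise levels
1.0 / 0.45 / 0.14 give effective temperatures of 0.5 / 0.1 / 0.01
against well depths of ~0.25: free hopping, occasional hopping,
complete trapping.

These benchmarks establish that the schemes measure what they claim
(SIC trapping, MIC ∝ basin width, SA → deepest well, all schemes
agreeing at high noise) in a setting with known answers.

## Problem sizes and tolerances

Study-scale checks use 10,000-model ensembles (state merging,
quadrastable enumeration, relaxation time, robustness ordering); module
tests use 10²–10³ models. MIC basin occupancy on variant `c` is asserted
within ±0.06 of the 2/3 basin fraction at 2,000 particles (noise blurs
the basin boundary slightly); SA deep-well capture is asserted at ≥95%;
scheme agreement at high noise at BD < 0.05. The relaxation-time
criterion (BD < 0.01 from t = 15 onward at D = 0) is met with margin —
the measured crossing is t ≈ 8.

## What the synthetic setting does not show

* Parameters are sampled uniformly and independently; real kinetic
  constants are correlated and non-uniform. The ensemble's cluster
  *structure* is the robust readout, not absolute occupancy numbers.
* Noise is additive, white, and identical across genes. Transcriptional
  bursting, copy-number discreteness (Gillespie-level effects) and
  gene-specific noise scales are outside scope.
* Absolute Bhattacharyya distances depend on the binning estimator;
  only comparisons under the same estimator (orderings, trends over
  D or t) transfer.
* The quadrastable calibration is a documented package choice
  emulating an engineered construct, not inferred from data; the
  *procedure* (enumerate → select → anneal/induce) is the reusable
  artifact.
* One initial condition per model means basin estimates are ensemble
  aggregates; per-model basin volumes require the enumeration path
  (100 ICs/model), which is quadratically more expensive.
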