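# Methods

This note documents the models and numerical choices behind
`stochassembly`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
option existed.

## Founding-community model

A replicate community founded by pipetting from a source suspension with
composition p (relative abundances, Σp = 1) and total cell count T at
dilution d receives a multinomial draw of N = round(T·d) cells.  The
per-taxon founder count nᵢ ~ Binomial(N, pᵢ) marginally, so

    CV(nᵢ) = sqrt((1 − pᵢ) / (N pᵢ)),

which is the package's measure of initial stochasticity.  `founding_cv`
offers both this closed form and an empirical CV over `n_sim` simulated
inoculations (default 96, mirroring a 96-well replicate plate; the
simulated CV uses the ddof=1 sample SD, so it is asymptotically unbiased
but noisy at small `n_sim` — the analytic mode exists for exact work).
Taxa whose expected founder count N·pᵢ falls below one cell are flagged
(`below_one_cell`) rather than dropped, because founder loss is itself a
quantity of interest: `simulate_otu_loss` reports the per-draw count of
taxa receiving zero cells and the closed-form expectation Σᵢ(1 − pᵢ)^N.

Copy-number correction divides observed 16S copy counts by a
copies-per-genome vector and rounds half-up; inference of copy numbers is
out of scope (a user-supplied vector is expected).

## Multimodality: excess mass and its calibration

For values x₁…xₙ the excess-mass functional at penalty λ is
E_{n,m}(λ) = max over m disjoint closed intervals C of
Σ_C [Pₙ(C) − λ·|C|], and the statistic against a k-mode null is
D_{n,k} = max_λ [E_{n,k+1}(λ) − E_{n,k}(λ)].  Maximizing intervals always
have order statistics as endpoints, and the λ-profile only changes at
empirical density slopes, so the statistic is computed exactly over
intervals with data endpoints and the finite candidate grid
λ = (j − i)/(n(x₍ⱼ₎ − x₍ᵢ₎)).  The inner maximization is a dynamic
program, O(n·k) per λ (numba-compiled, with a pure-numpy fallback).  Above
8000 candidate slopes the grid is thinned to an evenly spaced subsample;
the profile is piecewise linear and flat near its maximum, so the effect
is negligible at the n where thinning activates (n ≳ 130).  For k = 1 the
statistic equals exactly twice Hartigan's dip; the dip is implemented
independently (iterative convex-minorant/concave-majorant refinement) and
the identity is used as a cross-check in the test suite.

p-values come from a calibrated smoothed bootstrap: the critical
bandwidth h_k (smallest Gaussian-KDE bandwidth with at most k modes,
found by bisection on a 512-point grid) defines the closest k-modal
smoothed version of the data; B resamples are drawn from it with
variance rescaling, and p = (1 + #{D* ≥ D})/(B + 1).  The reported
`n_modes` is the smallest k not rejected at α (searched up to 3 by
default).  Replicates are assigned to modes by cutting at the antimodes
of the k-modal KDE; the assignment bandwidth is floored at 2.5 grid
steps so that point-mass data (whose critical bandwidth is numerically
zero) still yield a resolved density, and ties at an antimode go to the
lower mode.  Defaults: B = 500, α = 0.05; B < 100 triggers a warning
flag, not an error.

Measured behaviour at the study scale (n = 96, B = 100, 100–200 seeds):
type-I rejection of unimodality ≈ 0.04–0.06 at nominal 0.05, and power
≈ 1.0 against an equal-weight mixture at ±5 SD.

## Within-mode variation

OTU level: replicate counts inside one mode are modelled as
X = Binomial(depth, p) + round(Normal(0, σ)).  The likelihood is the
discrete convolution of the binomial pmf with a CDF-discretized Gaussian
kernel truncated at ±6σ (σ < 1e-8 degenerates to a point mass).  (p, σ)
are estimated by maximum likelihood (Nelder–Mead on (logit p, σ) with
σ ∈ [0, 3·SD + 10], two starts).  σ̂ is reported in count units; fits
require ≥ 3 replicates, and the within-mode metric for an OTU is the
unweighted mean of σ̂ over modes with ≥ 3 members (smaller modes are
excluded and recorded).  Recovery at truth Binomial(2000, 0.3) + N(0, 80),
n = 96: median σ̂ within a few percent of 80 over 50 seeds.  CLR-transformed
abundances (pseudocount 0.5, half the minimum count unit) feed the
multimodality index and regressions; the mixture fit uses raw counts, as
the binomial requires.

Community level: the mixture is multinomial + normal.  Per replicate
cluster, a baseline dissimilarity distribution is simulated by `n_sim`
multinomial read draws from the cluster's mean relative-abundance profile
at the observed depths, and σ̂² = max(0, Var(observed within-cluster
dissimilarities) − Var(baseline)).  Variance moment-matching was chosen
over a full convolution MLE because it is deterministic given the
baseline, directly testable (injected compositional noise recovers
monotonically), and needs no distributional assumptions about pairwise
dependence; a full MLE is a possible extension.

The community multimodality p-value is calibrated at the replicate level:
because pairs sharing a replicate are dependent, B pseudo-datasets are
drawn by multinomial resampling of every replicate from the pooled mean
profile (the closest single-cluster model) and the pairwise statistic is
recomputed on each.  Mode counts beyond the first rejection fall back to
the value-level calibrated test, and replicates are mapped to modes by
cutting an average-linkage tree at the detected mode count.

"Commonly observed" OTUs are operationalized as nonzero in ≥ 50% of the
replicates of a setting (configurable).  Multimodality statistics are
min-max scaled to [0, 1] across a declared panel (per source × day in the
pipeline); scaling never affects p-values.

## Energy landscapes

Presence/absence states use a strict relative-abundance threshold
(default 0.001) with taxa present in < 5% or > 95% of samples dropped as
uninformative.  The orchestrated pipeline binarizes per source (presence
patterns are only comparable among samples sharing a species pool) and
raises the threshold to 0.05 with a (2%, 98%) prevalence band for the
synthetic experiment, whose coexisting tail otherwise keeps nearly every
taxon constantly present.  The pairwise maximum-entropy model
P(σ) ∝ exp(h·σ + Σ_{i<j} Jᵢⱼσᵢσⱼ) is fit either exactly — penalized
average log-likelihood over the 2^S enumeration (L2 penalty 0.01 on J
only; L-BFGS-B with analytic gradients to gradient norm < 1e-6; S capped
at 15 by prevalence closest to 50% when more taxa are supplied) — or by
node-wise logistic pseudolikelihood with symmetrization (J + Jᵀ)/2, which
matches exact fits to ≲ 0.15 RMSE at S = 6, n = 5000.  Energy is
E(σ) = −(h·σ + Σ Jσσ), i.e. the negative log modelled probability up to
log Z; only energy differences are interpreted.  Local minima are states
whose S single-flip neighbours all have strictly higher energy
(exhaustive enumeration, S ≤ 20); basins are found by steepest single-flip
descent with ties broken toward the lowest flipped index.  Framework 1
pools all dilutions per source; Framework 2 fits each source × dilution
setting separately.

The 2-D state-space view is metric MDS: SMACOF initialized from classical
scaling, reporting raw stress Σ(d − d̂)²/2.

## Dynamic regimes

Trajectories are per-replicate time-ordered point sequences, normally in
the mMDS plane (a full compositional-space mode exists).  The directed
distance from segment (p₀ → p₁) to a trajectory matches p₀ and p₁ to
positions on the trajectory that respect its ordering: endpoints may land
on different segments (earlier for p₀, later for p₁); within one segment
an ordered matching is enforced, solving a 1-D convex minimization when
the unconstrained projections would reverse direction.  Trajectory
dissimilarity is the symmetrized mean of directed segment distances.
Coordinates are rescaled so the largest pairwise state distance is 1,
which keeps all regime metrics in [0, 1].

* dDis = Σᵢ d_iα / m — the reference's own zero distance is included,
  matching the 1/m normalization of the printed formula.
* dBD = mean of d_ij over unordered pairs.
* dEve — minimum spanning tree over the trajectory dissimilarity matrix;
  with EW_c the normalized edge weights,
  dEve = [Σ_c min(EW_c, 1/(m−1)) − 1/(m−1)] / [1 − 1/(m−1)]
  (the functional-evenness form).  All-zero dissimilarities return 1 by
  convention, with a warning.

Representative-trajectory criteria: `average_depth` (default; highest
mean Gaussian-KDE density of its states over the pooled state cloud),
`density` (highest summed density), `medoid` (lowest summed
dissimilarity), `size` (most observed states), `length` (greatest path
length); ties fall back to the medoid ordering, and the selected
trajectory is always one of the inputs.

## Synthetic-data generator

The generator emulates the statistical structure of a
2-source × 4-dilution × 96-replicate × 4-time-point serial-transfer
experiment:

1. **Source pools.**  A taxon-rich "soil"-like pool (12 taxa,
   2.59 × 10⁶ cells in the ×1 suspension) and a low-diversity
   "freshwater"-like pool (8 taxa, 2.30 × 10⁵ cells) with uneven
   abundances, so that ×1/1000 founding draws reach the few-hundred- to
   few-thousand-cell range where multinomial noise can flip the dominant
   competitor.
2. **Inoculation** is a multinomial draw of round(T·d) cells.
3. **Dynamics** are discrete-time generalized Lotka–Volterra,
   dxᵢ/dt = xᵢ(rᵢ − Σⱼ aᵢⱼxⱼ), Euler-integrated at dt = 0.05 day with a
   serial transfer (keep 10% of the culture) every 2 days; samples are
   taken just before each transfer.  The default motif has growth rate
   8 day⁻¹, carrying capacity 10⁸, a mutually exclusive taxon pair
   (cross-inhibition 2.0× self-limitation) whose winner is decided by the
   founding ratio, and a tail of weaker competitors (0.85× among
   themselves, suppressed at 0.95× by the pair) that persists alongside
   either winner.  Every attractor is therefore monodominant with a
   coexisting low-abundance tail — replicate communities at low dilution
   vary continuously rather than collapsing to identical monocultures.
4. **Demographic noise**: at each transfer the inoculum is
   Poisson-resampled (integer drift that vanishes for large populations)
   and given mild lognormal jitter (`process_noise_sd`, default 0.05);
   setting it to 0 makes a run fully deterministic.  Extinct taxa stay
   extinct.
5. **Sequencing** is a multinomial read draw (default depth 5000).

All randomness flows from one master seed via
`SeedSequence([seed, source, dilution, replicate])`, so any single
replicate is reproducible in isolation and regenerated tables are
byte-identical.

With these defaults the minority-attractor fraction among 96 replicates
rises monotonically along the dilution series (≈ 0 at ×1 to ≈ 0.2–0.3 at
×1/1000 for the freshwater-like pool), day-8 dissimilarity distributions
go from unimodal to clearly bimodal, and dDis/dBD rise while dEve falls
from ×1 to ×1/1000 — the qualitative pattern the analysis modules are
designed to detect.  What the generator does **not** emulate: real
taxonomic richness (tens to hundreds of OTUs), chimeras and other
sequencing artifacts, copy-number variation, environmental fluctuations,
plate-position effects, or mechanistic resource competition.  Passing
tests therefore demonstrate that the statistical machinery detects the
intended signals under the assumed sampling models, not that those models
exhaust the behaviour of real communities.

The experimental transfer fraction is not derivable from the emulated
design; the default (0.1) is an arbitrary but conventional serial-dilution
choice and is configurable.

## Problem sizes and numerical conventions

The orchestrated demo (`RunConfig`) defaults to 24 replicates per
setting, bootstrap B = 200, n_sim = 96, FDR 0.05 — chosen as the smallest
scale at which every qualitative contrast above is comfortably resolved;
the test suite and acceptance script use 12–24 replicates and B = 100 for
the same reason.  Sequencing depths enter the binomial/multinomial models
as the observed per-sample read totals.  Degenerate inputs are handled
explicitly: constant samples have statistic 0 and one mode; clusters or
modes below 3 members are excluded from σ̂ with a record; all-zero samples
are rejected by name at I/O and dissimilarity boundaries; the all-zero
community state has energy 0 by construction (only differences matter).

## Known limitations

* The excess-mass bootstrap tests k sequentially without multiplicity
  adjustment across k; `n_modes` is a point decision, not an inference.
* Community-level σ̂ by moment matching is truncated at 0 and inherits
  Monte-Carlo error from the baseline simulation.
* Pseudolikelihood Ising fits are consistent but less efficient than
  exact fits; exact mode is capped at 15–20 taxa by enumeration.
* At 24 replicates per setting, a minority attractor occupied by ~20% of
  replicates is often not resolved as a separate local minimum of the
  fitted pairwise model — landscape fits at this scale reliably show the
  single-basin structure of low-dilution settings but under-count basins
  at high dilution.  Divergence and regime metrics, not basin counts,
  carry the dilution contrast at desk scale.
* The directed segment distance is a semimetric; the triangle inequality
  is not guaranteed and not relied upon.
* Five representative-trajectory criteria can disagree on strongly
  asymmetric regimes; dDis should be read together with the criterion
  used (the `size` criterion is the least stable on equal-length
  designs).
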