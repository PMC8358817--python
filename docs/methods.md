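# Methods

## Flow measures on binary trees

A vascular tree is a rooted binary tree of vessel segments (root =
generation 0); dichotomous division means every internal segment has
exactly two daughters, and volumetric flow conserves at every bifurcation.
The object analysed is not the tree geometry but the *flow measure*: the
distribution of flow over the cross-section of each generation.

Real trees are pruned — branches stop bifurcating at different depths — so
cross-sections of the raw tree do not conserve total flow. The
**carry-forward convention** restores conservation: a segment terminating
at generation *n* is included, with its full flow, in every cross-section
beyond *n*. Under this convention the cross-section at generation *n*
partitions the root flow over a nominal N(n) = 2ⁿ cells (the number of
cells a complete tree would have; an absent branch is simply a cell of zero
flow, which never enters the entropy sums). The equivalent one-dimensional
picture is a repeated bisection of an interval: every generation halves the
cell size whether or not each half contains flow, which is why N(n) is 2ⁿ
and not the number of segments actually present.

With flow probabilities p_i = Q_i / Q_root:

- cross-section entropy S(n) = −Σ p_i ln p_i;
- **flow information dimension** D_Q: OLS slope (with intercept) of S(n)
  against n·ln 2;
- **multifractal spectrum**: for each moment order q, normalised weights
  μ_i(q) = p_i^q / Σ p_j^q are formed per cross-section, and f(q), α(q)
  are the OLS slopes of −Σ μ_i ln μ_i and −Σ μ_i ln p_i against n·ln 2.
  Δα = α_max − α_min over the q grid measures the degree of
  multifractality; f_max = f(0) is the structural height.

All logarithms are natural; every reported quantity is a ratio of
logarithms so the base cancels. At q = 1 the weights reduce to the
probabilities, so f(1) = α(1) = D_Q identically — the implementation
preserves this by fitting all three slopes over the same generation range.

Sign convention: the scaling sums are *negated* entropies regressed on the
growing log-cell-count, so that dimensions come out in [0, 1] with 1 for
even splitting. This is the information-dimension convention (entropy over
log of resolution); defining the slopes without the negation flips every
sign and would make spectra non-positive.

### Scaling-range selection

On a finite pruned tree the entropy curve saturates: once most of the flow
rests in carried-forward terminals the cross-sections stop changing and
S(n) is asymptotically constant (bounded by the entropy of the terminal
flow distribution). Generations beyond that point carry no scaling
information — they are the analogue of counting boxes smaller than the
pixels of an image — and including them biases the slope toward zero, with
the bias growing with tree depth, destroying the depth-invariance that
distinguishes D_Q from CV in the first place.

The estimators therefore fit generations n = 1..n*, where n* is the last
generation at which still-bifurcating (non-terminal) segments carry at
least half of the total flow (`active_flow_fraction` in the generation
table; threshold configurable, default 0.5, with a floor of two fitted
generations). Generation 0 is excluded since it contributes only the
trivial point (0, 0). On a perfect binary tree every generation lies on the
same line, so the restriction leaves those slopes exactly unchanged; on
pruned trees it confines the fit to the regime where the measure is still
being refined. All entropy points are reported alongside the fitted slope,
together with R² and a `ScaleRangeWarning` whenever the fitted span covers
fewer than three decades of cell counts (n* < 10) — the conventional span
demanded for asserting scale invariance — as a diagnostic, never an error.

The default q grid is −5 to 5 in steps of 0.25. Δα necessarily depends on
the grid (the spectrum endpoints are approached only as |q| → ∞), so the
grid bounds are carried in every exported result. Extreme orders are
evaluated in the log domain (log-sum-exp); weights that underflow to zero
contribute zero to μ ln μ.

### Closed forms used as oracles

For a constant split ratio r on a perfect tree, S(n) = n·H with H the
binary entropy of the split fractions 1/(1+r) and r/(1+r), giving
D_Q(r) = [(1+r)ln(1+r) − r ln r]/[ln 2 (1+r)], strictly increasing from 0
(r → 0) to 1 (r = 1). The same cascade is the classical binomial
multifractal, whose α(q) and f(q) have elementary closed forms; the test
suite holds the estimators to these to 1e−6 (the regressions are exact —
every generation lies on the line). The whole-tree CV of the same tree has
the closed form CV² = (2^{G+1} − 1)·Σ_g (p²+q²)^g / (G+1)² − 1, which at
depth G = 9 spans 10.1 (r → 0) down to 4.4 (r = 1) — the CV is also an
explicit function of depth G, the contrast that motivates the fractal
description.

## Tree construction

Trees grow breadth-first from a root diameter (default 300 μm, arteriole
scale) to a capillary cutoff (default 10 μm). At each bifurcation the
daughter diameters follow the power-law bifurcation rule d₀ᵏ = d₁ᵏ + d₂ᵏ
with asymmetry λ = d₂/d₁ ≤ 1, i.e. d₁ = d₀(1+λᵏ)^{−1/k}, d₂ = λd₁;
segment length is the empirical l = 7.4 (d/2)^{1.15} (μm). A segment
bifurcates iff **both** sampled daughters are at or above the cutoff — the
termination rule consistent with the reference ensemble statistics (a
symmetric k = 2.7 tree then stops exactly at generation 13 with 2¹⁴−1
segments; "bifurcate while own diameter ≥ cutoff" would give 14, and a
larger-daughter-only rule gives far deeper trees than observed.)

k and λ are drawn independently at every bifurcation from normal
distributions truncated by rejection (not clipping, which would pile mass
on the bounds): k within [2.0, 3.5] — spanning the physiologically reported
range from near area-preserving branching to beyond Murray's cube law — and
λ within (0, 1] by definition. Defaults k ~ N(2.7, 0.1) and
λ ~ N(0.8, 0.05): the means sit at the literature's central values and the
spreads keep ensemble standard deviations of vessel counts and maximal
generations at the magnitudes reported for comparable constructed-tree
ensembles. Sampling order is fixed (parent before children, larger daughter
first), so a seed fully determines a tree; ensembles spawn independent
per-tree streams from one seed.

Note the λ = 1 boundary: with λ_mean = 1 rejection truncation keeps only
the sub-unity half of the distribution, so the effective mean asymmetry is
≈ 0.96 and trees remain mildly pruned — D_Q and f_max still round to 1.00
but Δα stays slightly positive.

## Hemodynamics

Each segment is a Poiseuille resistance R = 128 μ l / (π d⁴) (d, l in μm,
μ in Pa·s, pressures in Pa, flows in μm³/s; viscosities are computed in
mPa·s and converted). Apparent viscosity follows the Pries in-vivo model:

- reference in-vitro curve μ₀.₄₅(d) = 220 e^{−1.3d} + 3.2 −
  2.44 e^{−0.06 d^{0.645}} (the Fåhræus–Lindqvist decline toward small
  diameters, re-rising below the red-cell scale, asymptote 3.2);
- hematocrit dependence μ_vitro = 1 + (μ₀.₄₅ − 1)·[(1−H_d)^C − 1] /
  [(1−0.45)^C − 1] with the usual shape exponent C(d);
- endothelial surface layer: a saturating width W_as (0 below
  d_off = 2.4 μm, → W_max = 2.6 μm in large vessels) plus a peaked width
  W_peak (linear rise to E_amp = 1.1 μm at d_crit = 10.5 μm, exponential
  decay at rate E_width = 0.03 μm⁻¹ beyond). The two components combine as
  W_eff = W_as + W_peak(1 + H_d·E_HD) (E_HD = 1.18) and
  W_ph = W_as + W_peak·E_peak (E_peak = 0.6). The
  in-vivo viscosity evaluates the in-vitro formula at the physical diameter
  d_ph = d − 2W_ph and multiplies by (d/d_eff)⁴ with d_eff = d − 2W_eff.

Discharge hematocrit is uniform across the tree (no phase
separation/plasma skimming) with default H_d = 0.45, the reference value of
the in-vitro fit; it is a configurable parameter. Only relative flows enter
the fractal measures, so boundary-pressure and unit choices cancel — a
property asserted as a test (scaling covariance).

The pressure field solves one conductance-weighted conservation equation
per internal junction, with the inlet node clamped at 1 mmHg
(133.322 Pa) and every terminal outlet at 0 mmHg, as a sparse symmetric
positive-definite system via direct LU factorisation (a tree's junction
graph is a tree; fill-in is negligible) followed by two iterative-
refinement sweeps. Refinement matters on deep asymmetric trees whose
resistances span many orders of magnitude: it keeps the *per-junction*
relative Kirchhoff residual at machine level (~1e−15 observed; 1e−9
enforced). An independent O(n) equivalent-resistance collapse of the tree
serves as the solver's cross-check in the test suite, never as the
implementation.

## Problem sizes and reproducibility

Ensemble experiments use 10 trees per (k_mean, λ_mean) cell: the λ sweep
at k = 2.7 (λ = 0.60..1.00 step 0.05), the k sweep at λ = 0.80
(k = 2.3..3.0 step 0.1), and their union (16 unique cells, ~1.8 million
segments in total) for the pooled flow–diameter regression — sizes at
which the ensemble means are stable to the second decimal across seeds
while a full run stays below a minute on one core. Every experiment is a
pure function of (configuration, seed); result tables carry the seed, the
q-grid bounds, a configuration hash and the package version.

## What the synthetic trees do and do not emulate

The generator reproduces dichotomous branching with physiological diameter
ratios, depth/vessel-count statistics and their monotone trends (deeper
trees with stronger asymmetry, denser trees with larger k), and flow
fields that obey conservation and plausible diameter–flow scaling. It does
not place vessels in space (no lengths-to-geometry embedding, no
tortuosity), has no anastomoses or trifurcations, no flow-adaptive
diameter remodelling, uniform hematocrit, rigid vessels and steady
pressure boundary conditions (resistance-only: no compliance, inertia or
pulsatility). Passing tests therefore validate the estimators and the
network solver on trees with realistic branching statistics; they do not
certify the hemodynamic realism of any particular organ's vasculature.

## Known limitations

- Δα (and to a lesser degree f_max) depends on the q grid and on the
  scaling-range rule; comparisons are meaningful only at a fixed grid and
  rule. Under the defaults, Δα responds strongly to asymmetry (≈ 0.67 at
  λ_mean = 0.60 vs ≈ 0.09 at λ_mean = 1.00) but only weakly to the
  bifurcation exponent.
- The pooled flow–diameter exponent of the default ensemble is ≈ 2.96,
  the upper range of the sampled bifurcation exponents: segment-weighted
  pooling is dominated by the densest (high-k) trees, and asymmetric flow
  splits steepen per-cell slopes by ~0.2–0.4 above k. Empirical coronary
  datasets report exponents nearer 2.0–2.5; matching them would require
  either lower sampled k or flow-adaptive remodelling, both outside the
  present model.
- The CV closed form and endpoints are specific to constant-split perfect
  trees; on stochastic trees CV additionally reflects depth and pruning.
- The solver assumes a tree topology; looped networks (anastomoses) are
  rejected at validation rather than solved.
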