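# Methods

This note records the models implemented in poomkit, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the study sizes used by the validation suite.

## Two-pool burial kinetics

Organic carbon deposited in sediment is split into a labile pool g₁ and a
POOM (partially oxidized organic matter) pool g₂, with first-order decay
throughout. During oxygen exposure (t ≤ t_ox) the system is

    dg₁/dt = −(k₁ + k₁₂) g₁
    dg₂/dt = k₁₂ g₁ − k₂ g₂

with g₁(0) = (1−a)g₀, g₂(0) = a g₀. After t_ox, g₂ is frozen (anoxic
protection) and g₁ continues to decay at k₁ until it is entirely
remineralized; burial efficiency is therefore g₂(t_ox)/g₀. The closed
form, with D = k₂ − k₁ − k₁₂, is

    g₂(t)/g₀ = e^{−k₂ t} [ a + k₁₂ (1−a) (e^{D t} − 1)/D ].

**Parameters.** g₀ (mass, arbitrary units) > 0; a ∈ [0, 1] the initial
POOM fraction; rate constants in inverse time, with time dimensionless
internally — users supply any consistent unit, and reports use the
dimensionless product k₁·t_ox. The model assumption k₂ < k₁ (POOM is the
recalcitrant pool) is enforced at construction; `allow_k2_ge_k1=True`
lifts it, since the closed form itself does not require it.

**Feedback regime.** The initial slope of burial efficiency in t_ox is
proportional to k₁₂(1−a) − a k₂, so the positive-feedback threshold is
k\* = a k₂/(1−a), classified with a strict inequality (the boundary
counts as negative feedback — the slope there is exactly zero). In the
positive regime the maximum sits at

    t_ox* = log[ k₂ (a k₂ − a k₁ − k₁₂) / ((a−1) k₁₂ (k₁₂ + k₁)) ] / D.

**Numerical choices.** The removable singularity at D = 0 (possible only
when k₂ ≥ k₁ is allowed) is evaluated via the analytic limit
e^{−k₂ t}(a + k₁₂(1−a)t) whenever |D| < 10⁻⁹·k₁. The ODE cross-check uses
an explicit high-order Runge–Kutta integrator (DOP853, rtol 10⁻¹⁰,
atol 10⁻¹²) split at t_ox so the rate discontinuity never sits inside a
step. Numeric derivatives of burial efficiency use central differences
with step 10⁻⁶/k₁; because the closed form is entire in t, the centered
stencil is applied even at t_ox = 0 via analytic continuation to small
negative t, keeping the truncation error O(step²) — a one-sided stencil
at 0 would pick up the O(t) curvature term and mask the vanishing slope
at the threshold.

## Chronograms and posterior ensembles

Ages are in Ma before present, increasing into the past; branch lengths
are durations in Myr; extant tips sit at age 0. Trees are taken as rooted
as given (no rerooting). Ultrametricity is validated within a relative
tolerance (default 10⁻⁶ of the root age, configurable, since serialized
chronograms accumulate rounding); non-branch-length annotations are
ignored on read. Multi-tree files are one Newick per line; a NEXUS trees
block is accepted read-only. A posterior ensemble drops the first
floor(f·n) trees, f = 0.20 by default, matching standard MCMC burn-in
practice; all trees must share one leaf set.

The calibration-prior helper converts an (older, younger) age interval
into a normal prior: mean at the midpoint, standard deviation equal to
the half-range divided by 2.0 by default (the two-sigma reading of a 95%
interval, which turns the 4400–3400 Ma habitability interval into
mean 3900 Ma, sd 250 Ma); a divisor of 1.96 gives the exact normal
quantile convention. The mean is divisor-independent.

## HGT event ages

Reconciliation replicates give each event a set of (donor, recipient)
mappings with replicate counts. Weighting rules: recipients are weighted
by their fraction of replicates; leaf recipients are deleted and the
remaining internal recipients renormalized (a leaf pins no divergence
age); events whose donors are leaves still contribute their recipients.
An event with only leaf recipients has no age distribution and is
reported as such (flagged, never a silent zero). When leaf donors co-occur
with several recipients, those recipients' ages enter with the same
fractional weights — the rule set does not distinguish this case further.

For each posterior tree and retained recipient, the recipient node's age
is a sample of the event's younger bound and its parent's age a sample of
the older bound; each (tree, recipient) pair carries weight
(recipient weight)/(number of post-burn-in trees). Weighted percentiles
use the inclusive cumulative-weight definition (first age whose
cumulative weight reaches q). Window overlap defaults to the joint
reading: bounds sampled from the same tree are paired, and a pair
intersects the window iff younger ≤ window.older and older ≥
window.younger; a marginal mode treating the two bound distributions as
independent is also provided (the intersection probability then
factorizes). Event windows are user configuration; none are hard-coded.
The support filter defaults to 0.80.

## Diversification rates and null tests

N(t) is the lineages-through-time count: the mean, over post-burn-in
trees, of the number of lineages of the focal clade crossing age t. This
is the quantity whose log-slope is the per-lineage diversification rate;
a "nodes" mode counting cumulative divergences is available as an
alternative. Counts are taken at bin edges spaced Δt = 100 Myr (default),
zero bins older than every root are trimmed, and the series is ordered
oldest-to-youngest (calendar order) so that autocorrelation lags have a
consistent sign; spectra are order-invariant. Rates are
rᵢ = log(Nᵢ₊₁/Nᵢ)/Δt at bin midpoints, defined only where both counts
are positive; r̄ is their mean.

**Fluctuations.** The default fluctuation series is the detrended
increment xᵢ = Δt·(rᵢ − r̄), which is zero-mean and white under a
constant-rate null. A literal alternative that subtracts r̄ times the
elapsed absolute time from each single-bin increment is exposed as mode
`"as-printed"`; it is not zero-mean under the null (the subtracted trend
grows with elapsed time while each increment does not), so the detrended
form is the default used by the tests.

**Null model.** Starting from one lineage, every extant lineage splits
with probability r̄·δt per step (δt = 10 Myr default; validity requires
r̄·δt < 1, and the analysis bin width must be an integer multiple of δt).
Counts are non-decreasing and ≥ 1, so log-ratios are always defined; the
expected trajectory is e^{r̄t}.

**Spectral peak test.** Statistic: max(P)/Σ(P) over the power spectrum
(squared modulus of the DFT) of the mean-centered series, zero frequency
excluded. Null replicates are full pipeline re-runs — simulated null
counts of the same series length, each detrended by its own mean rate —
and the Monte-Carlo p-value uses the add-one estimator
p = (1 + #{null ≥ observed})/(1 + n_reps), which cannot return zero. A
zero-variance series returns p = 1 (no spectrum, no evidence).

**Ljung–Box test.** Q statistics and chi-square p-values at lags
1..max_lag (default 25) via statsmodels; a zero-variance series returns
p = 1 at all lags. On raw single-lineage null count series at r̄·T ≈ 1
the p-values are strongly discrete (a ~37% atom of never-branching
replicates, and most others carrying one or two events), making the test
conservative there rather than uniform; its nominal calibration is
verified on Gaussian white noise of matched length, where the asymptotic
sampling distribution applies.

## Synthetic data

The generator emulates the shape of real inputs: dated posterior
ensembles of a few-hundred-tip tree spanning up to ~3 Gyr (default
fixtures use ~1000–3000 Ma root ages, tens to low hundreds of tips, and
100 trees so suites run in seconds; the real-data scale of ~1000
posterior samples is reachable by configuration), and HGT tables whose
replicate counts sum to 100.

* **Tree simulation** is an exact event-driven (Gillespie) pure-birth
  process with piecewise-constant per-lineage rates, run forward from a
  single stem lineage at the root age; exponential waiting times are
  restarted at epoch boundaries, which is exact by memorylessness. Trees
  are ultrametric with tips at 0; a realization with no branching is
  returned as a flagged degenerate single tip.
* **Posterior-style ensembles** keep one topology and jitter node ages:
  each internal node's gap above its oldest child is scaled by an
  independent unit-mean lognormal factor with coefficient of variation
  `age_jitter_cv` (default 0.05), and the node age is the jittered
  children's maximum plus the jittered gap. Ordering holds by
  construction and ensemble mean ages track the generating ages — exactly
  at cherries, and up to the small max-over-children effect elsewhere.
  Age-multiplicative jitter with resampling on order violations was
  rejected: per-node resampling truncates the noise from below and
  biases tightly spaced node ages upward, and joint rejection has
  vanishing acceptance on realistic topologies.
* **HGT tables** draw one to three internal non-root recipients per event
  with Dirichlet-multinomial replicate counts (each ≥ 1, summing to 100)
  and, with probability `leaf_mix` (default 0.3), an additional leaf
  recipient to exercise the leaf-deletion rule. Brute-force ground truth
  (renormalized weights and expected weighted mean age) is emitted
  alongside, so tests never re-derive it from the fixtures.
* **Independent forests** (one fresh realization per ensemble member) are
  used where ensemble averaging is meant to estimate process
  expectations, e.g. the burst-recovery study: jittered copies of a
  single topology carry no independent information about the generating
  rates, whereas the mean lineage count of a forest does.

**What the generator does not emulate:** topology uncertainty within an
ensemble (real posteriors mix topologies; here each ensemble has one),
correlated node-age errors from shared clock parameters, non-ultrametric
tips (fossil tips are supported by the reader tolerance but not
generated), and reconciliation ambiguity structure beyond random
donor/recipient draws. Passing tests therefore demonstrate correctness of
the estimators on known processes, not robustness to these real-data
features.

## Validation study sizes

The validation studies regenerate all inputs from a seed and run at sizes
chosen to give tight Monte-Carlo error while keeping the whole suite in
tens of seconds: 100 parameter sets for closed-form/ODE agreement
(tolerance 10⁻⁶ relative), 1000 for feedback sign agreement, 100 for the
threshold boundary (derivative < 10⁻⁸) and the critical-time grid check
(within one step of a 20001-point randomized-span grid), 1000 trials ×
199 null replicates for spectral type-I calibration (95% binomial band
around 0.05), 1000 trials for Ljung–Box calibration, 100 seeds × 100
trees for burst recovery (baseline 0.001/Myr, 3× burst in 1200–1000 Ma,
detection = higher mean rate inside the burst epoch than outside), and 20
events × 100 trees for HGT weighted-age recovery (exact to rounding).

## Known limitations

* The kinetics module treats t_ox as exogenous; no coupling to an
  atmospheric oxygen box model or redox multiple-equilibria dynamics.
* Lineage counts assume the focal clade is monophyletic in every
  posterior tree; clade specifiers resolve by MRCA, so a non-monophyletic
  sample silently widens the clade.
* The null model is a pure-birth process — no extinction, no sampling
  fraction — matching the constant-probability branching null it is
  meant to represent, not a general birth–death alternative.
* Weighted percentiles are step-function quantiles (no interpolation),
  which is visible for small ensembles.
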