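# Methods

`laketempo` analyzes collections of short annual ecological time series —
the motivating case is satellite-derived lake chlorophyll-a (CHL), 34 annual
values per lake — along two complementary streams, *process* (is the series
predictable, are its dynamics nonlinear, and does climate cause it?) and
*pattern* (what shape does the series trace, and which lakes share it?), and
then integrates the two into climate-response types. This note records the
models, the numerical choices, and what the synthetic validation does and
does not establish.

## Quality control and preprocessing

A series enters the analysis only if it has at most 5 missing years with no
two adjacent (`preprocess.qc_filter`). Interior gaps are infilled with the
mean of the two neighboring years; a missing first or last year copies its
single neighbor. Because gaps are guaranteed nonconsecutive, both neighbors
of any interior gap are observed, so the neighbor-mean rule applies to every
accepted record, not only singleton gaps.

Two preprocessing paths are computed (`preprocess.prepare`):

* **z path** — within-lake z-score (mean 0, SD 1, population SD). Used for
  clustering, anomalies, and breakpoints, so pattern analysis compares shape
  rather than magnitude.
* **EDM path** — z-scored, then OLS-detrended against the time index, then
  re-standardized. Detrending removes the secular component that would
  otherwise dominate state-space reconstruction; re-standardizing makes the
  S-map locality parameter comparable across lakes. The detrend-then-rescale
  order is a package choice; the z path is never detrended.

A zero-variance series (or one that detrends to a constant, e.g. a perfect
ramp) is flagged degenerate: it skips EDM, causality, and clustering, and is
assigned the "no pattern" class.

## Climate metrics

Monthly climate tables (mean air temperature, total precipitation, a drought
index, an ENSO index) are aggregated into 16 annual metrics: 4 categories x
4 windows — water year (Oct of year-1 through Sep), spring (Feb–Apr), summer
(May–Sep), preceding winter (Nov of year-1 through Jan). Precipitation is
the window total; the other categories are window means, matching the
conventions of the source products these metrics emulate. Metrics are
z-scored before causality testing; a zero-variance metric is excluded and
flagged rather than standardized.

## Predictability and nonlinearity (EDM)

The scalar series is embedded in lagged coordinates with dimension E chosen
in 1..10 by leave-one-out simplex-projection skill (Pearson rho of
predictions vs. observations, ties to the smallest E). All prediction is
one-step-ahead leave-one-out with an exclusion radius: the target vector and
every vector sharing a time index with it (|Δt| < E) are removed from the
neighbor/library set, which prevents self-matching leakage in 34-point
series. At n = 34 this makes E above ~8 infeasible (not enough admissible
neighbors); such E simply drop out of the scan.

**Forecast skill** is the LOO S-map rho at the selected E, maximized over the
locality grid θ ∈ {0, 0.01, 0.1, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 5, 6, 7,
8} (log-ish spacing, dense near the linear end where the MAE curve moves
fastest). S-map local regressions use weights exp(−θ·d/d̄) and a ridge of
1e-8 on the normal equations, because 34-point embeddings produce
near-duplicate neighborhoods; at θ = 0 with the exclusion disabled the S-map
reduces exactly to OLS on the embedded matrix (a tested identity).

**Significance of skill** is assessed against a permutation null: the
identical select-E-then-scan-θ procedure applied to time-shuffled copies of
the series (default 100), with the add-one estimator
p = (1 + #{null ≥ observed}) / (n+1). A parametric (Fisher-z) test on the
maximized skill is anticonservative — the maximization over E and θ inflates
its type-I error to ~26% on iid noise at n = 34 — whereas the permutation
test is exact under an exchangeable null and measures 5.0% (pilot, 200
sims). Power is unaffected where it matters: short deterministic signals
(period-8 sine + noise, chaotic maps) are flagged predictable essentially
always; AR(1) series are detected at a rate rising steeply with persistence
(~24% at φ = 0.5, ~76% at φ = 0.8).

**Nonlinearity** (state dependence) is judged by ΔMAE: the θ = 0 (global
linear) MAE minus the minimum MAE over the θ grid, which is ≥ 0 by
construction. The null distribution is the same statistic on
phase-randomized surrogates — same amplitude spectrum (hence the same
autocorrelation function, by Wiener–Khinchin) and mean, independent uniform
Fourier phases, conjugate-symmetric so surrogates are real; for even n the
Nyquist coefficient keeps its magnitude with a random sign. p is the add-one
estimator; a series is nonlinear iff ΔMAE > 0 strictly and p < α. The
pipeline default is 1,000 surrogates; the validation suite uses 200, at
which the measured type-I error on AR(1) series of study length is within
0.05 ± 0.02.

## Causality

The causality method follows the series' linearity class; a lake is never
tested with both. Unpredictable or degenerate lakes are not tested at all.

**Nonlinear series — convergent cross mapping (CCM).** The driver is
estimated from the response's shadow manifold (E+1 nearest neighbors,
exponential weights), the direction in which information about a true cause
is recoverable. Two criteria must both hold:

1. *Skill significantly above chance.* The full-library cross-map skill is
   compared against skill on phase-randomized copies of the driver (100
   surrogates, add-one p). The surrogate null absorbs skill that arises from
   the driver's autocorrelation alone; a parametric Fisher-z alternative
   measured a 9% false-positive rate on independent chaotic pairs vs. 3.5%
   for the surrogate null at identical (100%) power.
2. *Convergence.* Libraries of nominal sizes 20 and 500 are sampled with
   replacement (100 draws each) — the only reading under which a 500-point
   library is computable from ~30 embedded vectors. The mean skill at the
   largest library must exceed the 95th percentile of the sampled skills at
   the smallest. A bare "larger mean wins" comparison is a coin flip under
   the null; the one-sided form separates cleanly on the standard
   unidirectionally coupled logistic-map benchmark (convergence gain +0.52
   in the true direction vs. 0.00 ± 0.05 reverse and independent).

**Linear-stochastic series — VAR(1).** A bivariate VAR with one lag is fit
by equation-wise OLS (statsmodels). Granger causality is the F test that the
driver's lag coefficient in the response equation is zero; instantaneous
causality is the Wald test of zero residual cross-covariance. A driver is
causal if either p < α, uncorrected — two tests at α = 0.05 give a measured
joint null rate of ~9.5%, accepted deliberately to preserve power on
34-point series (the same trade the original analysis states it makes). A
lake is *climate-causal* if any of its 16 metrics tests causal; with 16
uncorrected metric tests per lake this any-metric rate is itself liberal,
which is inherent to the design being reproduced.

## Temporal pattern

**Anomalies** are years whose within-lake z-score strictly exceeds ±1. Note
the base-rate implication: ~31% of years in a Gaussian z-scored series
exceed ±1, so per-lake anomaly lists are dense and meaningful mainly in
aggregate (which years do many lakes share?).

**Breakpoints** fit a piecewise-constant (mean-shift) model by dynamic
programming: globally minimal RSS for each candidate number of breaks
subject to a minimum segment of ceil(0.15·n) years (6 at n = 34), with the
number of breaks chosen by BIC, n·log(RSS/n) + (3k+2)·log n. Break positions
are charged twice relative to regular parameters (MDL-style), because they
are searched over the whole series; with the plain (2k+2) charge a spurious
second break appeared on ~6% of planted single shifts. A breakpoint year is
the last year of the segment it ends. The DP agrees with exhaustive
enumeration of all admissible placements (tested).

**Trend** is the Mann-Kendall test: S = Σ sign(x_j − x_i) over ordered
pairs, tie-corrected variance, continuity correction, two-sided normal
p-value, tau-b for direction. Exact agreement with an all-pairs oracle and
with scipy's tau is tested.

**Clustering** is agglomerative with Ward linkage on Euclidean distance
between z-scored series (scipy), cut at k clusters (default 16, any k
accepted).

**Ecological classes.** Clusters are reduced to ecological temporal classes
by classifying each cluster's *mean z-profile* — the synchronized pattern
its members share, in which idiosyncratic noise has averaged out. Five
structural models compete by BIC: constant, linear, single step, constant
plus single-year impulse, and step plus impulse (event positions again
charged twice; impulses must also exceed the ±1 anomaly threshold in profile
units). The winner maps onto the six base classes: step → abrupt-persistent,
impulse → abrupt-temporary, both → abrupt-mixed, significant-MK linear →
monotonic (by sign), otherwise no pattern. Clusters with the same base class
whose peak event years fall within ±1 year merge regardless of magnitude;
abrupt clusters with distinct peak years stay separate; trend and no-pattern
clusters merge by class alone. Classifying at the cluster level is the
package's codification of a judgment step: the per-lake six-class rule alone
cannot produce trend or no-pattern classes, because the literal |z| > 1 rule
marks anomalies in essentially every series. The per-lake rule
(`pattern.base_class`) is still provided and reported per lake.

A deliberate consequence of the single-step candidate: a monotone staircase
profile reads as trend-like rather than abrupt. At cluster level that
ambiguity is real, and the single-shift archetype is what the class system
distinguishes.

## Integration

Per lake: E if unpredictable; D if predictable but no causal metric; among
climate-causal lakes, A if its (abrupt) class is in the configured A-set, B
for other abrupt classes, C for nonabrupt classes. The A/B split is
data-derived in the motivating study, so it is configuration here; the
default A-set is the two largest abrupt classes. Summaries report the
linearity composition overall and per class, % causal per class, causal
counts per climate category, the multi-metric share among causal lakes, and
the predictable → linearity → causal flow counts.

## Synthetic data

The generator emulates the study conditions: 34-year annual series (an
extended mode supports longer series for consistency checks of the EDM
machinery), four dynamical archetypes (iid noise; AR(1); climate-coupled
AR(1) at lag 0 or 1; driver-forced logistic map in the chaotic regime,
r = 3.8, the canonical CCM benchmark), and overlays applied in the fixed
order trend → shift → spike, each scaled by the pre-overlay series SD so
truth labels are unambiguous. Monthly climate has a seasonal temperature
cycle with optional linear warming (the annual-mean OLS slope equals the
injected trend exactly), non-negative precipitation, an AR-persistent
drought index, and a slow oscillation standardized to mean 0 / SD 1 as the
ENSO-like index. Inside the logistic map the driver is min-max mapped to
[0, 1] so the forced map stays in its domain.

Default ensemble archetypes (counts of 10 each): noise; ENSO-coupled AR(1)
(φ = 0.5, coupling 1.5, noise SD 0.5 — a strongly climate-forced, persistent
lake whose oscillatory forcing makes it predictable and its driver
recoverable); level shift of 3.5 SD at year 17; single-year spike of 4.5 SD
at year 28; trends of ±0.15 SD/yr. These sizes were chosen so archetypes are
well separated in z-space: a z-scored ramp and a z-scored step are
geometrically close (Ward will happily merge them), so "recoverable by
construction" requires planted structure to dominate within-archetype noise.

What the synthetic validation shows: the pipeline recovers planted classes
(~92% mean over seeds), finds planted drivers in strongly coupled lakes
(~95%), and its tests are calibrated on their null models. What it does not
show: performance on real CHL retrievals, whose noise is non-Gaussian,
heteroskedastic, and spatially correlated across lakes, whose drivers are
shared rather than independent per lake, and whose class structure is not a
clean mixture of archetypes. The recovery numbers are properties of the
generator's separability, not estimates of field performance.

## Problem sizes and determinism

Pipeline defaults: 1,000 nonlinearity surrogates, 100 predictability
permutations, 100 CCM library draws per size, α = 0.05 everywhere, k = 16.
The validation suite and the acceptance script run the same code at reduced
but stated sizes (100–200 surrogates, 3 × 60-lake ensembles, 200–500
simulation replicates per calibration), chosen as the smallest sizes at
which binomial error is well inside the tolerances being checked. All
randomness flows from explicit seeds (one master seed per run, recorded in
the manifest; per-lake and per-stage seeds derived deterministically), and a
rerun with the same inputs and configuration is bit-identical — a tested
contract.

## Known limitations

* 34 points is very short for state-space methods; E selection is noisy and
  predictability has limited power against weakly persistent alternatives.
  This mirrors the constraint of the motivating analysis rather than a
  removable defect.
* CCM with bootstrap libraries honors the nominal 20/500 sizes but cannot
  manufacture information beyond the ~30 embedded vectors; convergence at
  these sizes is a weaker signal than on long series.
* The uncorrected any-of-16 causality rule has a high per-lake false-positive
  rate under the null by design.
* The 16 → 9-style class reduction is an algorithmic codification of a
  judgment step; it is deterministic and tested on synthetic archetypes but
  is not claimed to replicate any particular manual classification.
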