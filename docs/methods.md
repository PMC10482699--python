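# Methods

This note records the models, default conditions, numerical choices and
known limitations of `pyrotraits`, in the spirit of a statistical methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Beta-binomial differential relative abundance

### Model

For one taxon in one two-arm contrast, counts Wᵢ out of library totals nᵢ
are beta-binomial:

    Wᵢ ~ BetaBinomial(nᵢ, μᵢ, φ),   logit μᵢ = xᵢᵀβ,
    αᵢ = μᵢ(1−φ)/φ,  βᵢ = (1−μᵢ)(1−φ)/φ,

so Var(Wᵢ/nᵢ) = μᵢ(1−μᵢ)(1+(nᵢ−1)φ)/nᵢ.  The design is intercept + group
indicator + centred covariates (pH always; centring makes fold changes
refer to mean covariate values).  Dispersion is intercept-only: the
simplest model consistent with the analysis being reproduced; a
covariate-modelled dispersion is deliberately out of scope.

### Estimation

Maximum likelihood over (β, logit φ) by bounded L-BFGS-B with an analytic
gradient, three starts (moment estimate, null-effect start, jittered
moment estimate), |β| ≤ 30 and logit φ ∈ [−18, 6].  The covariance is the
inverse of the analytic observed information; when φ sits on its boundary
or a covariate is degenerate, the β block (or its pseudo-inverse) is used.
Finite-difference Hessians proved numerically unreliable at these data
scales (likelihood magnitudes ~10⁴ with near-boundary dispersion), which
is why the Hessian is coded analytically and verified in the test suite
against finite differences of the analytic gradient.

The effect summary is log₂FC = log₂[μ(group=1)/μ(group=0)] at centred
covariates, with a delta-method standard error.

### Inference and small-sample calibration

The group test is a Wald test on β_g.  Two small-sample corrections are
applied, both standard for dispersion-estimated models:

* the ML dispersion estimate is biased low by roughly (n−p)/n — the exact
  analogue of the ML residual-variance bias in linear regression — so the
  standard error is inflated by √(n/(n−p));
* the statistic is referred to a t distribution with n−p−1 degrees of
  freedom (p mean parameters plus one dispersion parameter estimated).

With a plain normal reference the test rejects a true null far too often
at n = 16 (the acceptance suite measures the corrected test's type-I error
and requires it inside [0.025, 0.075]).  Under complete separation (taxon
present in one arm only) the Wald statistic degenerates — the
Hauck–Donner effect — so the per-taxon driver falls back to the
likelihood-ratio test for separated fits; the LRT is also available as an
explicit cross-check.

Taxa present in fewer than 3 samples of a contrast are not tested
(prevalence floor; the emulated analysis states none, so this is a
documented package choice).  P-values are Benjamini–Hochberg adjusted per
experiment × horizon; missing values are excluded from the number of
tests.  An optional site fixed effect exists nowhere: site enters only
through pairing of the experimental design, and random effects are out of
scope.

## 2. Trait assignment

Three contrasts define the traits; all use DNA relative abundance,
organic and mineral horizons separately, pH as covariate, and the
q < 0.05 ∧ log₂FC > 0 gate:

| trait | arm 1 | arm 0 | extra filter |
|---|---|---|---|
| survivor | burned, 24 h | unburned, 24 h | RNA:DNA ratio ≥ 1 |
| fast_grower | burned, 5 wk | burned, 24 h | — |
| postfire_affinity | burned, 6 mo (autoclaved, re-inoculated) | unburned, 6 mo | — |

**Burn-exposure filter.**  Burned cores must have exceeded 50 °C
(strictly; a core at exactly 50 °C is excluded) at the thermocouple; each
retained burned core brings its site's control core (matched by site,
horizon, timepoint).  Moist burns generally stay below this threshold and
drop out.

**Viability filter.**  The RNA:DNA ratio is computed from aggregate means
— mean RNA relative abundance over the burned retained 24-h samples of the
horizon, divided by mean DNA relative abundance over the same samples —
rather than per sample, which is robust to sparse detection of rare taxa
in individual libraries.  Ratio ≥ 1 is kept (boundary inclusive); absence
from the RNA table means ratio 0.

**Effect-size filter.**  Among the significant positive responders of one
experiment × horizon, the threshold is mean(log₂FC) − sd(log₂FC); calls
below it are dropped.  Computing the mean/sd over significant responders
per horizon (rather than all tested taxa, pooled) is a documented choice
where the described analysis is ambiguous; both the filter and its scope
are arguments of `call_trait`.  With < 2 responders the filter is the
identity.  The filter can only shrink the catalogue (monotonicity is a
test).

The catalogue is the union over horizons and contrasts; traits are
non-exclusive sets and every (taxon, trait) entry carries the horizon,
log₂FC and q it was called from.  The pipeline has no internal randomness:
identical inputs give identical catalogues.

The pH covariate deserves a remark: dry burns raise pH by ~2.7 units while
site baselines vary by ~0.7, so in burned-vs-unburned contrasts pH and the
group arm are strongly collinear (r ≈ 0.86).  Controlling for pH therefore
costs a ~4× variance inflation on the group coefficient.  This is a
property of the experimental design being emulated, not of the estimator;
it is why the burned-vs-unburned contrasts need larger effects than the
within-burned growth contrast to reach the same power.

## 3. Two-pool decay model

Remaining carbon (fraction of initial total C) is
M(t) = M₁e^(−k₁t) + M₂e^(−k₂t); the package fits the cumulative
mineralization curve 1 − M(t), obtained from measured fluxes by the
trapezoidal rule from t = 0 (an initial gap before the first reading is
filled by holding the first flux constant).  Cumulative fitting is the
package's choice where the emulated analysis does not state whether flux
or cumulative data were fitted; it matches how trap-based CO₂ measurements
accumulate.  M₁ + M₂ = 1 by default ("fractional pool sizes");
`constrain_total=False` fits the pool sum freely.

Parameterization: (logit M₁, log k₁, log k₂), pools relabelled after the
fit so k₁ ≥ k₂.  Initialization is data-driven — k₂ from a log-linear fit
to the apparent flux over the last 30 % of the series, k₁ from the early
excess flux after removing that slow component, M₁ from the early
cumulative fraction — plus a coarse grid fallback and five deterministic
jittered restarts; the lowest-RSS solution wins, with an early exit once a
start interpolates the data to machine precision.  Tolerances are set to
machine precision (xtol = ftol = gtol = 1e−15) because the acceptance
recoveries demand ~1 % coefficient accuracy on ill-conditioned curves.

**Identifiability.**  When k₁ and k₂ are within a small factor of each
other the model is close to single-pool and M₁ lies on a near-flat
likelihood ridge.  The unburned coefficient regime (k₁ only ~3× k₂) is of
exactly this kind at 35–180-day horizons: noiseless curves still recover
the generating coefficients exactly (the acceptance script demonstrates
this), but with 5 % flux noise the fitted unburned M₁ scatters widely and
is biased on the ridge.  Consequently the package validates the
treatment-comparison machinery (site-paired Wilcoxon signed-rank, exact
for small n, p = 1 at all-zero differences, flagged below 5 pairs) on
coefficient ensembles with the reported treatment separation, and
documents that end-to-end M₁ detection from noisy unburned fits at these
horizons is power-limited by identifiability, not by the test.  Fitting
log-flux instead of the cumulative curve was evaluated and does not
resolve the ridge.

Time units are days throughout; fits are invariant to unit conversion
(verified to 1e−6 relative).

## 4. Synthetic-data generator

The generator defines the study conditions for every statistical claim the
test suite makes.  Conditions taken from the emulated study: 19 sites;
three cores per site (unburned, moist burn, dry burn) × organic/mineral
horizons; unburned organic pH ~ N(4.5, 0.7) with +2.7 ± 0.3 for dry burns
(moist +0.2); moist-burn peak temperatures capped below 45 °C, dry burns
N(330, 150) °C so a few fall under the 50 °C exposure threshold;
treatment-mean decay coefficients (unburned 0.096/0.0036/0.0013, moist
0.027/0.16/0.0017, dry 0.027/0.16/0.00098) with lognormal(σ=0.2)
core-level jitter; 5 % multiplicative lognormal flux noise.

Conditions chosen by the package (the study reports none):

* **Count model** — Dirichlet-multinomial with total concentration 50, so
  each taxon's marginal is beta-binomial with φ ≈ 1/51 ≈ 0.02, matching
  the differential-abundance model and giving realistic overdispersion.
* **Libraries** — Poisson around 50 000 reads (library-size distributions
  are not reported; the value is arbitrary and documented as such).
* **Baseline composition** — lognormal(σ=1) species-abundance profile,
  jittered between horizons.
* **Spike sizes** — per-trait: 5 log₂ units for survivors and post-fire
  affinity, 3 for fast growers.  Burned-vs-unburned responders in this
  system are dominated by taxa rising from trace backgrounds to percent
  levels (single survivor taxa reach ~13 % of reads immediately
  post-burn), i.e. effects well above 5 log₂ units, while five-week growth
  enrichment is more moderate.  Spiked taxa are drawn from the abundance
  window where the spike is compositionally realizable (spiked expected
  share ≤ 10 %) and detectable (baseline ≥ 2×10⁻⁴); a ground-truth fold
  change that cannot exist in a composition is not a usable truth.
* **Spike persistence** — the survivor (and relic-DNA) pulse persists
  through the 5-week incubation of the same cores, so it cancels in the
  5wk-vs-24h growth contrast; the 6-month experiment starts from
  autoclaved, re-inoculated soil, which erases the pulse and leaves only
  the affinity spike.  This keeps each spiked taxon differential in
  exactly the contrast its trait implies and makes all compositional
  closure artifacts negative (removed by the log₂FC > 0 gate).
* **RNA** — the 24-h RNA library equals the DNA expectation except that
  relic-DNA decoys (default 4 taxa, spiked like survivors in DNA) are
  multiplied by 0.1 and true survivors by 2.0.  Survivors being
  metabolically active (ratio clearly above the boundary 1) is the
  biological premise of the viability filter; without it, truly viable
  taxa would sit exactly on the filter boundary and be deleted at random.
* **Field design** — vegetation (3 classes) × horizon × year (1, 5)
  strata, one matched unburned (severity 0) plus four burned samples per
  stratum, severities uniform on (0.5, 5].  Expected trait-group totals
  equal baseline + slope × severity exactly (the trait and background
  profiles are renormalized separately), with default year-1/year-5 slopes
  0.004/0.004 (survivor), 0.040/0.003 (fast grower), 0.008/0.003
  (affinity) — the fast-grower pattern mirrors a strong first-year bloom
  that vanishes by year five.  80 % of field taxa share lab sequences
  (always including the trait taxa); the rest are novel.
* **Copy numbers** — 1 + Gamma(2, 0.5) (mean 2) for most taxa,
  1 + Gamma(6, 0.6) (mean ~4.6) for fast growers, encoding the
  copy-number/growth-rate association that motivates community-weighted
  means and copy-number normalization.

What the generator does **not** emulate: sequencing error, chimeras,
taxonomy, phylogenetic correlation among taxa, spatial autocorrelation of
sites, and pH effects on composition beyond the burn shift.  Passing the
recovery tests therefore shows the pipeline recovers planted signals under
the assumed count model — not that real post-fire soils meet these
assumptions.

All randomness derives from a single seed via independent numpy
SeedSequence streams per stage; identical configurations are byte-identical
on disk.

## 5. Field quantification

Relative abundances are used for Bray–Curtis (removing library-size
effects; the normalization is a package choice).  BC(x, y) = Σ|xᵢ−yᵢ| /
Σ(xᵢ+yᵢ); per burned sample the mean over all matched unburned samples of
its vegetation × horizon × year stratum is reported, and a missing stratum
is an error rather than a silent skip.  "Any trait" totals count
multi-trait taxa once so they remain ≤ 1 and comparable across samples.
Copy-number normalization divides counts by predicted copy number and
renormalizes columns; taxa without predictions default to 1.  The severity
regression is OLS of trait total on severity (continuous, 0–5), year
(categorical) and their interaction; the interaction is dropped iff its
p ≥ 0.05 (the drop threshold is configurable), and per-year slopes and
intercepts, adjusted R² and the overall F p-value are reported.  With
exactly collinear data residual variance is zero and the interaction
p-value degenerates to 0 (retained), which the exact-recovery test relies
on.  Horizon can be used as an additional stratifier by filtering the
records before the regression; it is not a model term by default.

## 6. Problem sizes

Defaults are desk-scale by design: 200 taxa × 114 lab samples per table,
60 field samples, 57 flux series of 36–61 points.  The statistical
calibration checks in the acceptance suite use 500 null and 200
alternative simulations at n = 16 samples, 100 noisy decay replicates, and
trait-catalogue recovery pooled over three generator replicates — sizes at
which every stage's behavior is measurable in minutes on one core while
keeping Monte-Carlo error well below the tested margins.
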