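# Methods

## The mass-balance model

A lake is modelled as a continuously stirred tank reactor at hydrologic and
chemical steady state. Terrestrial DOC enters with the inflow at a
flow-weighted concentration `c_in` and leaves by exactly two routes: a
single first-order in-lake sink with rate constant σ (d⁻¹) and advection
through the outlet at the flushing rate ρ (d⁻¹). The retained fraction is
R = σ/(σ+ρ), the outflow concentration `c_in·(1−R)`, and an areal load
q_s·c_in splits exactly into an available (retained) and an advected flux.
Mass conservation — available + advected = loading — is enforced to 1e−9
relative and property-tested.

Assumptions worth stating plainly: steady state (no seasonality, no storage
dynamics); a single lumped sink (no partitioning among photolysis,
bacterial respiration and flocculation/sedimentation); complete mixing; and
σ independent of concentration and residence time. The equivalent
"apparent settling velocity" form v/(v+q_s), with v = σ·(1000·z̄) in
mm d⁻¹, is provided and tested to agree with the (σ, ρ) form exactly.

Unit conventions: q_s in L m⁻² d⁻¹ (numerically mm d⁻¹), depths in m, all
rates in d⁻¹, fluxes in mg C m⁻² d⁻¹, 1 yr = 365 d exactly. A
`LakeHydrology` record may be built from any two of {q_s, z̄, HRT}; a
redundant third value must agree to 0.1% or construction fails.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| σ (t-DOC loss) | 0.0009 ± 0.0004 | d⁻¹ | long-term whole-lake input/output budgets, given precedence over shorter incubation estimates |
| σ truncation floor | 0.0001 | d⁻¹ | negative or zero loss is unphysical; truncated-normal resampling, not clipping |
| q_s quantile model | 45.8·x/(1−x), x ≤ 0.999 | L m⁻² d⁻¹ | published sigmoid fit to a 305-lake hydraulic dataset; the cap bounds the pole at x = 1 |
| HRT distribution | lognormal, median 0.58 yr, σ_ln ≈ 2.61 | yr | pinned to the published median and 25th percentile (0.1 yr); implies ~58% of lakes under 1 yr, matching the published 58% |
| stream t-DOC | lognormal, mean 11.1, SD 7.4 | mg C L⁻¹ | moment-matched to the published survey mean/SD (implied median 9.24) |
| t-POC flux | lognormal, median 11, IQR 8–17 | mg C m⁻² d⁻¹ | published compilation median/IQR |
| available t-DOC | lognormal, median 34, IQR 11–78 | mg C m⁻² d⁻¹ | published compilation median/IQR (marginal mode) |
| primary production | lognormal, median 253, IQR 115–546 | mg C m⁻² d⁻¹ | published compilation median/IQR |
| BP model | 2.15·PPr^0.649, RMSE_log10 0.348 | mg C m⁻² d⁻¹ | published cross-system fit (n = 379); stochastic mode multiplies by 10^ε, ε ~ N(0, 0.348) |
| FQI_allo | N(0.102, 0.055) on (0.005, 1] | — | fitted food-quality index of terrestrial matter; floor keeps the index positive |
| FQI_auto | 1 (fixed) | — | algal baseline |
| BGE on t-DOC | 0.10 | — | bacterial growth efficiency on terrestrial substrate |
| ingestible t-POC | 0.40 | — | fraction of t-POC small enough to graze |
| pelagic PPr | 0.40–0.70 | — | pelagic share of whole-lake production in oligo/mesotrophic lakes |
| high-loading threshold | 1000 | mg C m⁻² d⁻¹ | defines the high-loading subset |
| scenario sizes | 305 lakes × 10 reps; 10,000 MC draws | — | the study conditions; replicate spread is the simulation CI |

The TP → primary-production regression is displayed in its source as an
equation image; this package represents it as a quadratic in log10 space
whose three coefficients are recovered, at construction, from the four
published anchor predictions (TP = 5, 10, 15, 20 µg L⁻¹ → 199, 312, 399,
471 mg C m⁻² d⁻¹). The curve reproduces every anchor to the printed integer
and is validated to be strictly increasing on TP ∈ [1, 100]; a failing
anchor table raises at construction.

## The synthetic lake population

The generators replace compiled field datasets, so what they do and do not
emulate determines what passing tests mean.

q_s is drawn by inverse transform through the published quantile function on
Uniform(0, 0.999). HRT is *not* drawn independently: the analysis depends on
high-loading lakes being fast-flushing. Since ln HRT = ln(1000·z̄) − ln q_s,
mean depth is given the residual log-variance
(σ²_ln,depth = σ²_ln,HRT − Var[ln q_s], with Var[ln q_s] = the truncated-
logistic variance ≈ 3.2, computed by deterministic quadrature) and centred
so the HRT median lands on 0.58 yr. Both published marginals are then
honoured — q_s exactly, HRT approximately (the log-logistic + lognormal
convolution is slightly heavier-tailed than lognormal) — at the cost of an
*induced* depth distribution (median ≈ 9.7 m, very wide) about which the
sources publish nothing. Input t-DOC concentration is attached
independently of q_s, matching the random-pairing construction of the
original scenarios.

Known, accepted departures from the published numbers:

* **Absolute loading runs high.** The median simulated load is
  median(q_s)·median(c_in) ≈ 45.8 × 9.24 ≈ 423 mg C m⁻² d⁻¹, versus the
  published 303. The published figure comes from bootstrapping the
  *observed* q_s values, whose median (38) is ~20% below the fitted
  quantile-function coefficient (45.8) used here as the sampler. This is a
  real limitation of the quantile-function stand-in and is left visible in
  the test suite rather than recalibrated away.
* **Retention upper quartile runs high.** At fixed σ = 0.0009 d⁻¹ the
  implied retention IQR is ≈(3%, 52%) versus the published (3%, 45%): the
  lognormal HRT tail is heavier than the source dataset's. The median (~15%)
  and the high-loading advection statistic are unaffected.
* **Asymmetric quartiles.** The lognormal flux stand-ins match each
  published median and the IQR *width* in log space; where the published
  quartile pairs are log-asymmetric (8–17 about 11; 11–78 about 34) the
  individual quartiles deviate by 5–15%. A warning is emitted when a
  user-supplied summary is asymmetric beyond 10% of the IQR width.

The fatty-acid generator builds two *synthetic* end-member profiles over 8
named fatty acids — ω3:ω6 exactly 11.7 (algal) and 1.6 (terrestrial),
mutual r² ≈ 0.16 — mixes them with realized source weights
w_auto = d_auto·U/(d_auto·U + d_allo) (U the preferential-utilization
factor), applies proportional noise, renormalizes, and reports the ω-ratio
from the mixed pools. These profiles emulate the *structure* of the
feeding-trial data (strong preference, near-orthogonal end-members,
intermediate ω-ratios), not any measured composition.

## Allochthony estimation

The forward model, its exact inverse (round-trip tested at 1e−12), and a
Monte-Carlo estimator that randomly pairs t-POC, available t-DOC, primary
production and FQI draws (default n = 10,000). Available t-DOC can come
either from the calibrated marginal (median 34, IQR 11–78) or from the
coupled loading/retention pipeline (bootstrap-resampled per-lake available
fluxes); the full-analysis default is the coupled path, the marginal is
used where a self-contained MC is wanted. A particulate-only bookkeeping
mode (10% BGE on available t-DOC, 40% ingestible t-POC, 40–70% pelagic PPr)
is provided for the stricter comparison; it indicates *less* allochthony
and is not the headline estimator.

FQI fitting minimises the error sum of squares between observed and
predicted allochthonous contributions over FQI ∈ (0, 1] by bounded scalar
minimisation (objective tolerance 1e−10), with FQI_auto fixed at 1 and an
optional restriction to treatments with dietary terrestrial share < 50%.
For noise-free gradients built with utilization factor U the fit returns
exactly 1/U, the reciprocal relation between preference and quality.

Two ω3:ω6 mixing conventions are implemented because ratio mixing is not
physically linear: linear-in-ratio (default) and component-linear pool
mixing under an equal-total-PUFA convention. They agree at the end-members,
are both monotone, and are reported distinctly.

## Numerical choices

* Retention is held as a fraction everywhere; percent formatting (and
  half-to-even rounding to printed precision) happens only at reporting.
* σ = ρ = 0 is an undefined budget and raises; negative rates are domain
  errors naming the offending field.
* Boundary diets/weights make the utilization odds ratio undefined — they
  raise rather than returning 0 or infinity, and are excluded from
  gradient averages.
* All generators accept either a seed or a `numpy.random.Generator`;
  scenario replicates use `SeedSequence.spawn`, so every summary is
  byte-stable for a fixed seed (tested).
* The MC allochthony median is cross-checked against a deterministic
  tensor-product quadrature oracle (24 quantile midpoints per input, 5%
  relative tolerance).

## Limitations

Beyond the calibration departures above: no covariance between input t-DOC
concentration and hydraulic loading; no seasonal or time-stepped dynamics;
no mechanistic partitioning of the in-lake sink; no taxon-specific
allochthony; and the synthetic generators cannot validate conclusions about
any *particular* lake — they show the pipeline reproduces the
population-scale statistics implied by the published summaries, not that
those summaries are right.
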