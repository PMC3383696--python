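# lakeflux

Mass-flux analysis of terrestrial carbon in lakes: how much terrestrially
derived organic carbon actually stays in a lake, and how much of zooplankton
production it can plausibly support.

Lakes receive terrestrial dissolved and particulate organic carbon (t-DOC,
t-POC) from their watersheds, and it is often claimed these inputs rival or
exceed in-lake primary production as a food source for the pelagic food web.
`lakeflux` implements the quantitative counter-analysis: a steady-state
continuously-stirred-tank-reactor (CSTR) mass balance for t-DOC retention
versus advection, empirical flux models, Monte-Carlo scenario analyses of
loading and availability across a realistic lake population, and a
food-quality-weighted estimator of zooplankton allochthony (the fraction of
herbivore production supported by terrestrial carbon). It is written for
limnologists and ecosystem modellers who want these budget calculations as a
tested, scriptable library rather than a spreadsheet.

## The model

**Retention vs advection.** Treating a lake as a CSTR at steady state, input
t-DOC is either removed in-lake by a first-order sink (rate σ ≈ 0.0009 ±
0.0004 d⁻¹, combining photolysis, bacterial metabolism and flocculation) or
advected through the outlet at the flushing rate ρ = q_s / (1000·z̄), where
q_s is the areal hydraulic load (L m⁻² d⁻¹) and z̄ the mean depth (m):

    R = σ / (σ + ρ)          (retained fraction)
    available flux = q_s · DOC_in · R
    advected  flux = q_s · DOC_in · (1 − R)

Only the retained ("available") flux can support in-lake food webs. Because
lakes with high areal t-DOC loading are also fast-flushing, high-loading
lakes advect almost all of their t-DOC.

**Allochthony.** Terrestrial matter is poor zooplankton food. Weighting each
resource flux by a food-quality index (FQI, algal baseline 1; terrestrial
FQI ≈ 0.102 ± 0.055, estimated from *Daphnia* diet-gradient fatty-acid
profiles via two-end-member mixing):

    A = Allo·FQI_allo / (Allo·FQI_allo + Auto·FQI_auto)

gives the expected allochthonous share A of herbivore production. The
closed-form inverse answers "how dominant would terrestrial inputs have to
be" for a target allochthony.

All empirical distributions the scenarios consume (hydraulic loading,
residence times, stream t-DOC, basal-resource fluxes, FQI, diet-gradient
fatty-acid profiles) are generated by seeded synthetic generators calibrated
to published summary statistics — see `docs/methods.md`.

## Worked example

```python
from lakeflux import (LakeHydrology, budget_for_lake,
                      monte_carlo_allochthony, mean_required_share)

lake = LakeHydrology.from_components(qs=38.0, mean_depth=8.1)
b = budget_for_lake(lake, c_in=8.0)
print(f"flushing rho = {lake.rho:.6f} d^-1, HRT = {lake.hrt_years:.2f} yr")
print(f"loading = {b.loading:.0f}, retention = {100*b.retention:.1f}%, "
      f"available = {b.available_flux:.1f}, advected = {b.advected_flux:.1f}")

mc = monte_carlo_allochthony(n=10_000, seed=0).summary
print(f"allochthonous resource share median: {100*mc['allo_share']['median']:.1f}%")
print(f"expected allochthony median:         {100*mc['allochthony']['median']:.1f}%")
print(f"required share for 30-70% allochthony: {100*mean_required_share(seed=0):.0f}%")
```

prints

```
flushing rho = 0.004691 d^-1, HRT = 0.58 yr
loading = 304, retention = 16.1%, available = 48.9, advected = 255.1
allochthonous resource share median: 17.3%
expected allochthony median:         1.9%
required share for 30-70% allochthony: 90%
```

A median lake (q_s = 38 L m⁻² d⁻¹, z̄ = 8.1 m, input t-DOC 8 mg L⁻¹)
retains only ~16% of a 304 mg C m⁻² d⁻¹ t-DOC load; across the Monte Carlo,
available terrestrial carbon is ~17% of basal resources, which — once its
low food quality is accounted for — supports only ~2% of herbivore
production. Terrestrial inputs would need to be ~90% of all resources to
support the 30–70% allochthony some field studies infer.

The same operations are exposed on the command line:

```sh
lakeflux models --eval ppr_tp=10 --eval bp=253
lakeflux gen lakes --n 305 --seed 1 --out lakes.csv
lakeflux retention
lakeflux allochthony --n 10000 --seed 1 --required-share
lakeflux run --seed 1 --out results/
```

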