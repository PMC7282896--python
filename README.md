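# riversubsidy

Tools for quantifying terrestrial–aquatic resource subsidies from large
mammalian herbivores and their effects on stream ecosystem function.

In many savannah river systems, dung deposited by animals such as
hippopotamus and cattle is a major transfer of organic matter and nutrients
from land to water. This package implements the computational chain used to
study that transfer and its consequences:

- **`loading`** — a herbivore dung-loading model: per-capita river loads
  from daily defaecation and deposition behaviour (time-apportioned for
  briefly watering grazers, a fixed behavioural fraction for river-dwelling
  hippos), population-scale loads per reach, species shares, element (C, N,
  P) fluxes and stoichiometric enrichment between dung types.
- **`metabolism`** — an inverse diel dissolved-oxygen model for estimating
  daily gross primary production (GPP), ecosystem respiration (ER) and
  reaeration in a well-mixed mesocosm from 1-min DO/temperature/light
  records, based on the single-station balance
  `dO/dt = GPP(t) − ER(t) + k·(O_sat(T) − O)` with `ER(t) = ER₂₀·θ^(T−20)`
  and light-proportional GPP. Includes θ-sensitivity analysis and weekly
  GPP/ER/NEP summaries with trophic state.
- **`growthfit`** — three-parameter sigmoid Gompertz fits
  `Y(t) = K·e^(−lag·e^(−rate·t))` of daily GPP/ER trajectories, the analytic
  time-to-fraction inverse, and linear+quadratic trend contrasts of the
  fitted parameters along an experimental treatment gradient.
- **`doccomp`** — dissolved-organic-carbon composition analytics: a
  sample × excitation × emission fluorescence (EEM) tensor model, PARAFAC by
  multi-start alternating least squares with non-negativity, optical indices
  (HIX, FIX, β:α, SUVA₂₅₄, E2:E3), SEC size-fraction summaries, z-scored
  PCA, and the multivariate trajectory path-length statistic (summed
  Euclidean distance through full PC space over time).
- **`synthdata`** — a seeded generator for a complete synthetic mesocosm
  experiment (18 recirculating flumes: six hippo→cattle dung replacement
  treatments × three blocks, 44 days) with stored ground truth, so every
  inverse method can be tested end to end without field data.
- **`io`** — CSV readers/writers (diel logger files, EEM matrices with a
  manifest), validated configuration and a `run_pipeline` driver.

The package is a library: import it from Python. The `examples/` directory
holds one short script per capability.

## Worked example

```bash
python examples/metabolism_inverse.py
```

```
true vs estimated (g O2 m^-3 day^-1; k in day^-1)
  GPP : 6.00  vs  5.948
  ER20: 4.00  vs  3.983
  k   : 5.00  vs  4.950
  NEP = GPP - ER = 1.773; fit SSE 14.130
```

A mesocosm-day is simulated with known daily GPP (6), ER at 20 °C (4) and
reaeration k (5 d⁻¹), 0.1 mg l⁻¹ Gaussian optode noise is added to the 1-min
DO record, and the inverse model recovers all three parameters within ~1%.
The fit exploits the fact that, for fixed k, the simulated DO trace is
affine in (GPP, ER₂₀): those two are profiled out by non-negative least
squares against unit-response simulations, leaving only a 1-D search over k.

```bash
python examples/synthetic_experiment.py
```

```
theta sensitivity (rank correlation of treatment means across theta = 1.045 vs 1.1085): GPP 1.00, ER 0.94
Gompertz K(GPP) vs % cattle: slope 0.0514 (t = 38.6)
Gompertz K(ER) vs % cattle: slope -0.00008 (t = -0.3)
stream-weeks heterotrophic in week 1: 100%
stream-weeks autotrophic in weeks 2-6: 100%
PARAFAC explained variance: 99.9%
```

On a full synthetic experiment the pipeline recovers the built-in treatment
structure: the GPP asymptote climbs with the cattle-dung share (slope ≈ 0.05
per percentage point), ER shows no treatment trend, all flumes flip from net
heterotrophy in week 1 to net autotrophy afterwards, and the conclusion is
insensitive to the ER temperature coefficient θ.

## Acceptance script

```bash
python scripts/acceptance.py --seed 42 --out results/acceptance.json
```

Runs the complete pipeline on a seeded synthetic experiment — loading table,
diel-DO inversion for every mesocosm-day, θ sensitivity, Gompertz treatment
trends, nutrient series, PARAFAC decomposition and PCA trajectory lengths —
prints the run summary, writes stage outputs next to `--out`, and writes the
results JSON to `--out`.
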