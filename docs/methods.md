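# Methods

This note documents the models implemented in `riversubsidy`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not establish.

## Dung-loading model

Per-capita river load is `daily_defaecation_wet_kg × deposition_fraction`.
Two deposition behaviours are supported:

- **uniform-rate** (grazers that visit the river briefly): defaecation is
  assumed uniform over the 24-h day, so the river fraction is
  `time_in_river_min / 1440`. The default cattle profile (265 kg, 12.5 kg
  wet dung day⁻¹, 10 min in river) yields 0.0868 kg day⁻¹ per head (0.70% of
  daily output).
- **fixed fraction** (hippos, which rest in the river and concentrate
  defaecation in water): default 0.5, yielding 8.7 kg day⁻¹ per head from
  17.4 kg day⁻¹ total.

Population loads are linear in head count; shares are percentages of the
summed load. Element fluxes convert wet loads through a dry-matter fraction
and per-dry-mass element fractions. Stoichiometric enrichment compares two
C:N:P triples (normalised to P = 1) per unit carbon:
`100·((N_a/C_a)/(N_b/C_b) − 1)`, and analogously for P. The reference
compositions give cattle dung ≈13% more N and ≈68% more P per unit C than
hippo dung.

Intermediate intake parameters (dry-matter intake, egestion fraction) vary
across literatures, so profiles take wet defaecation directly;
`daily_defaecation_from_intake` is a derivation hook for users who prefer to
start from intake. Reach-level population counts are inputs, not constants;
the reference loading table in the pipeline uses a synthetic landscape whose
head counts are back-calculated from round total loads, labelled as such.

## Diel-oxygen metabolism model

State equation for a closed, well-mixed volume (all rates g O₂ m⁻³ day⁻¹,
time in days):

    dO/dt = GPP(t) − ER(t) + k · (O_sat(T(t)) − O)

- `GPP(t)`: by default proportional to light, scaled so the trapezoidal
  integral over each day equals the daily total `gpp_daily` exactly; a
  saturating P–I alternative `pmax·tanh(α·L/pmax)` is available.
- `ER(t) = ER₂₀ · θ^(T−20)` with θ ≥ 1; ER is reported as the positive
  day-integrated magnitude, NEP = GPP − ER.
- `O_sat`: Benson–Krause freshwater saturation at 1 atm, zero salinity
  (pressure correction out of scope).
- Integration: classic fixed-step RK4 on the logger grid (≤ 5 min), drivers
  linearly interpolated to half steps.

**Inversion.** The balance is linear in O, so for fixed k the simulated
trace is exactly affine in (`gpp_daily`, `er20`) — also under RK4, which is
a linear map for linear ODEs. Each day window is therefore fitted by
variable projection: three unit-response simulations (no-metabolism
baseline, unit GPP, unit ER₂₀) and a non-negative least-squares solve give
the best pair for any k; k itself (when fitted) is found by a coarse
log-spaced grid over 0.2–60 day⁻¹ refined with bounded scalar minimisation.
This replaces generic multi-start nonlinear optimisation: it is
deterministic, has no convergence failures on the linear-in-O model, and
recovers noise-free parameters to ~1e-8. Days with zero light integral force
GPP to zero (nocturnal-decline estimation of ER). Windows are
midnight-to-midnight, half-open [d, d+1), day 1 starting at t = 0.

θ-sensitivity refits all series under two temperature coefficients
(conventional 1.045 and the higher 1.1085 used for these mesocosm fits) and
reports the Spearman rank correlation of treatment-level mean GPP and ER
across the pair; a value near 1 means the treatment response does not depend
on the θ choice. At T ≡ 20 °C the estimates are θ-invariant by construction.

## Gompertz growth fits

`Y(t) = K·exp(−lag·exp(−rate·t))`: asymptote K (maximum GPP or ER), rate
(day⁻¹), dimensionless location lag. Fitting is trust-region nonlinear least
squares with a heuristic start (K₀ = 1.05·max y; rate₀/lag₀ from a
log-linear regression of `log(−log(y/K₀))` on t) and bounds
K ∈ (0, 10·max y], rate ∈ (0, 10], lag ∈ (0, 10⁶] — the lag bound is
deliberately generous because sparse early data can push the location
estimate very high, and bound hits are flagged rather than hidden.
Constant or overall-decreasing series are rejected with an explanation
(flagged fit, not an exception). The analytic inverse
`t = −ln(−ln f / lag)/rate` gives the time to reach fraction f of K, defined
for f ∈ (e^(−lag), 1).

Parameter-vs-treatment trends use an OLS linear + quadratic contrast;
curvature is flagged when the quadratic term's |t| > 2. The reported slope
comes from a pure-linear refit so an uncentred quadratic cannot absorb it.
Smoothing-spline regression of parameters on treatment is out of scope; the
polynomial contrast is the in-package substitute.

## DOC composition

**PARAFAC.** `X ≈ Σ_r a_r ∘ b_r ∘ c_r` fitted by alternating least squares
with optional row-wise NNLS for non-negativity; multi-start with a
deterministic HOSVD-based first start (leading singular vectors of each
unfolding) plus seeded random restarts. The objective is monotone
non-increasing by construction and asserted every iteration (with a float
round-off allowance at the noise floor of near-exact fits). Spectral modes
are normalised to unit maximum and the magnitude moved into the sample mode,
so scores are absolute fluorescence intensities comparable across samples.
Convergence: relative fit change ≤ 1e-8 (default), max 2500 iterations.
Component matching against reference spectra uses Tucker congruence with
Hungarian assignment, handling the inherent permutation ambiguity. The
number of components R is user-chosen; split-half validation and core
consistency are out of scope.

**Optical indices.** HIX uses the normalised (Ohno) variant bounded in
[0, 1] — `Σem(435–480) / (Σem(300–345) + Σem(435–480))` at ex 254 nm — with
the unnormalised variant available as `hix_zsolnay`; FIX = em470/em520 at
ex 370; β:α = em380 / max em(420–435) at ex 310; SUVA₂₅₄ = a(254)/DOC;
E2:E3 = a(250)/a(365). Band sums are trapezoids on the native emission grid;
excitation slices are nearest-neighbour within 10 nm. Missing spectral
coverage yields NaN for that index with a warning rather than an error.

**PCA and trajectories.** Features are z-scored (ddof = 1, constant columns
dropped with a warning) and decomposed by SVD; loadings are orthonormal,
axis signs fixed by making the largest-magnitude loading positive. The
trajectory statistic sums Euclidean distances between consecutive time
points per stream in the full PC space; with all axes retained this equals
the path length in the z-scored feature space (rotation isometry), which the
tests assert to 1e-10. Treatment means average replicate streams.

## Synthetic experiment

The generator emulates a replacement-design mesocosm experiment: 18 flumes
(six treatments, 0–100% cattle dung in 20% steps × three blocks), 44 days,
a single 120 g wet dung dose (1.7 g l⁻¹ in 70.6 l), 12-h half-sinusoid
light (peak 80 000 lux), sinusoidal temperature 21 ± 2.5 °C peaking 3 h
after solar noon. Desk-scale default logs DO every 5 min; the original
1-min cadence is a config switch.

Stated effect structure (chosen once; not fitted to any outcome):

- GPP follows a Gompertz curve per stream with K = 2 + 0.05·pct (linear
  rise with cattle share), rate = 0.18 + 0.30·e^(−pct/40) (nonlinear
  decline) and lag = 10 + 8·e^(−pct/40) (nonlinear decline), with 5%
  lognormal stream-level jitter.
- ER development is identical across treatments — Gompertz (K 0.95,
  rate 0.35, lag 2.5) shared by all streams — sized so every flume is net
  heterotrophic in week 1 and autotrophic from week 2 on.
- Reaeration k ≈ 8 day⁻¹ per flume (±5% lognormal), θ = 1.1085.
- DO observation noise: 0.1 mg l⁻¹ i.i.d. Gaussian.
- Nutrients: leachate pulses scale linearly with % cattle; first-order
  decay empties SRP by >90% and ammonium by >56% within two weeks (in
  expectation); nitrite declines after week 2 while nitrate rises; DOC
  climbs 70% over the run. Lognormal noise σ_log = 0.1.
- EEMs: four Gaussian-band components (two humic-like, one reduced
  humic-like, one protein-like) with distinct kinetics — a humic buildup
  hump whose amplitude grows with % cattle, leachate decay, an early
  microbial hump and a steady autochthonous rise — so the sample mode stays
  well conditioned for trilinear recovery. Additive noise 1% of tensor
  maximum; zero noise gives an exactly rank-R tensor.

Noise magnitudes are not taken from any measured dataset (none is
available); they were chosen once to make recovery non-trivial but reliable
and are exposed as parameters.

**What a green test establishes.** Recovery tests on this generator show
the estimators are correct and adequately powered for the stated effect
sizes and noise; they do not validate the original field measurements, the
instrument corrections real EEMs need (scatter excision, inner-filter,
Raman normalisation — only a synthetic-data masking utility is provided),
or effect sizes in real experiments. Single-run treatment orderings of the
trajectory path length are noise-sensitive; only its expectation is pinned
by construction.

**Computational note.** Re-fitting every mesocosm-day across many seeds is
made feasible by the variable-projection fitter (~1 ms per day with fixed
k). The end-to-end recovery tests fix k at the generator's true per-flume
value — recirculating flumes have a stable, known gas exchange — while
k-fitting is exercised separately on the parameter-grid recovery tests.
`daily_metabolism_table` additionally provides a cheap truth-plus-noise
stand-in for the inversion output where full DO fitting is not the point.

## Numerical conventions

- Time: days internally, integer minutes in files; half-open day windows.
- CSV: UTF-8, comma-separated, 6 significant digits.
- Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives stage seeds from one master seed via `SeedSequence` and reruns are
  byte-identical.
- Validation errors raise `ValueError` with the offending quantity named;
  per-day fit failures and rejected growth fits are flagged on the result
  object instead of raising, so batch runs degrade gracefully.

## Known limitations

- Single-station, volumetric metabolism only; no two-station or
  state-space (process-error) estimation.
- The loading model ignores urine, hydrologic washoff of terrestrial dung
  and seasonal population movements (multiple scenario configs can emulate
  the latter).
- PARAFAC component count is user-chosen; no automated model selection.
- The Gompertz model assumes monotone growth; declining series are rejected
  rather than fitted with alternative sigmoids.
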