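# Methods

## The models

`bodycomp` implements two cross-sectional relationships between fat-free
mass (FFM, kg) and fat mass (FM, kg) and the machinery built on top of
them.

**Covariate polynomial class.** For each of the four (race, sex) groups —
African American (AA) and non-African-American (NAA), female and male —
FFM is a fourth-order polynomial in FM with age A (years) and height H
(cm) as covariates, on the fixed 12-term basis

```
{1, F, A, H, F·A, F·H, F², F²·A, F³, F⁴, F²·H, F³·H}
```

The coefficient rows were fitted to the NHANES DXA reference population
(about 11,000 adults); only an African American indicator survived model
selection, so every other ethnic group is pooled into NAA. Selection in
the original analysis retained terms at P < 0.001 while keeping R² above
0.86; the `cohort` module reproduces that procedure on synthetic data.

**Forbes family.** The classical log-linear model
`FFM = s·ln(FM) + b + D`, with s = 10.4, b = 14.2 for women and
s = 13.8, b = 16.9 for men. `D` is a vertical translate: an individual's
longitudinal data travel a shifted member of the parallel family, so `D`
is calibrated through the measured baseline composition
(`D = FFM_b − s·ln FM_b − b`). Because parallel curves share secant
slopes, predicted FFM *changes* are invariant to `D`; predicted FFM
*levels* are not, which is why the polynomial class (which needs no
per-individual calibration) exists.

## Coefficient registry and the corrected AA-female row

Coefficients ship as a versioned plain-text table
(`src/bodycomp/data/coefficients_v1.tsv`) with three variants:

* `printed` — the literal transcription of the published table. Two terms
  are typographically anomalous and are read literally: the NAA-female
  row's `−0.002·A` (folded into the A coefficient, leaving no F·A term)
  and the AA-male row's trailing `−0.000002·F·H` (folded into F·H,
  leaving no F³·H term).
* `normalized` — the two anomalies replaced by the pattern-consistent
  `−0.002·F·A` and `−0.000002·F³·H` forms.
* `corrected` — the package default; identical to `normalized` except for
  the AA-female row.

The AA-female row needs more than normalization. As transcribed it fails
three independent checks: (i) it does not reproduce the published
inversion example (it gives FM = 59.28 kg where 27.75 kg is printed);
(ii) its `0.3·H` coefficient breaks the cross-row `0.7·H` pattern and
makes the zero-fat FFM negative below ~190 cm at age 20, contradicting
the models' own nonnegative-intercept property; (iii) its mid-band slope
dFFM/dFM ≈ 0.75 is far from the ~0.43 implied by the published example
and by the Forbes tangent s/FM. The corrected row therefore (a) restores
`0.7·H`, which fixes the zero-fat behaviour without touching any
F-bearing term, and (b) applies the minimum-relative-norm adjustment of
the nine F-bearing coefficients that makes the row interpolate the two
published inversion points exactly (a 2-constraint weighted least-norm
problem; the polynomial is linear in its coefficients). The construction
is reproducible with `scripts/derive_corrected_coefficients.py`. The
resulting row has mid-band slope 0.42, positive zero-fat intercept and a
strictly increasing total-mass function — the behaviour the published
example demonstrates. Coefficient repair is deliberately a data change:
the registry loader accepts user-supplied tables, and `solve_fm` and
`dfm_dt` take explicit coefficient rows.

`printed` and `normalized` remain available behind the `variant` flag of
every API call and CLI subcommand; nothing is silently discarded.

## Mass-balance inversion

Total mass obeys `W = FM + FFM` exactly, so composition follows from W
and covariates by solving `g(F) = F + FFM(F) − W = 0`. `g` is sampled at
512 points on [0, W]; the physiological solution branch is the initial
strictly increasing segment of `g`. For the male rows the `−2·10⁻⁶·F⁴`
term makes `g` turn over near F ≈ 90–116 kg at tall stature; beyond that
point an added kilogram of body mass would have to remove more than a
kilogram of lean tissue, i.e. the quartic has left its fitted band, and
roots there are rejected. A root on the increasing branch is unique and
refined by Brent's method to 10⁻¹⁰ kg absolute (tight enough that printed
two-decimal values are path-independent). If the branch holds no root,
all roots on [0, W] are reported in an ambiguity error; if W does not
exceed the zero-fat FFM, an infeasibility error reports that bound.

Longitudinal prediction solves FM at the baseline and final weights with
covariates frozen at baseline (age does not advance over the study
interval, matching how the published example uses a single age), so
`ΔFM + ΔFFM = ΔW` holds to machine precision. Error summaries report
mean ± sample SD (n−1) of predicted − measured; the sign convention is
stated in the output because conventions differ between reports.

## Zero-fat analysis

At FM = 0 only the intercept, A and H terms survive, and
`BMI₀(H) = FFM(0)/(H/100)²` estimates the lowest theoretical BMI at a
given stature. With `FFM(0) = a + bH − 0.04A` (a < 0, b > 0),
`dBMI₀/dH ∝ −bH − 2(a − 0.04A)` is positive and the second derivative
negative throughout the human height range, so the curves are strictly
increasing and concave down. The package checks the claim by first and
second finite differences on a 1-cm grid rather than symbolically — the
rational-function form makes the sign check exact at this resolution —
and counts zero differences as violations because the claim is strict.
Age enters only through `−0.04A`, so curves at two ages differ by exactly
`0.04·ΔA` kg of FFM at every height (in BMI units the offset varies with
height). As a plausibility corridor, the NAA-female zero-fat BMI over
ages 30–40 and heights 160–170 cm stays within 14–17 kg/m², the band
bracketing mean BMI observed in famine survivors; this is a containment
check, not a fit.

## Synthetic cohorts and refitting

The generator emulates the cross-sectional structure the regression
assumes, per (race, sex) group: age uniform on [18, 85] y; height normal
with the survey's sex-specific moments (174.3 ± 7.9 cm men,
160.6 ± 7.2 cm women), truncated to the valid 120–220 cm range by
resampling; fat mass gamma with shape/scale moment-matched to the
survey's sex-specific mean ± SD (24.2 ± 10.4 kg men, 30.6 ± 12.3 kg
women) — right-skewed and positive, like real adiposity; and
`FFM = polynomial(FM; A, H) + N(0, σ)` with σ = 1 kg by default, a
residual magnitude consistent with R² > 0.86 on the survey's FFM spread.
What the generator does **not** emulate: survey weights, measurement-
device bias, age–height–adiposity correlations, and within-band
heteroscedasticity. Passing recovery tests therefore demonstrate that the
fitting machinery is correct under the model's own assumptions, not that
the shipped rows are optimal for any real cohort.

Fitting is OLS of FFM on the 12-term basis, independently per group
(the published table gives four rows; any pooled shared-coefficient
structure is not recoverable from it). The quartic basis spans eight
orders of magnitude, so the design is column-scaled to unit RMS before
the fit and estimates are scaled back; p-values and R² are invariant.
Screening keeps terms with p < 0.001 in a single pass; an optional
backward-elimination loop drops the worst term iteratively (intercept
always kept). Full best-subset search over all interactions is out of
scope.

## Energy-balance coupling

With FFM = φ(FM), the balance `c_f·dFM/dt + c_l·dFFM/dt = I − E` reduces
to `dFM/dt = (I − E(FM, φ(FM)))/(c_f + c_l·φ′(FM))`, using the analytic
φ′. The denominator must stay positive — it fails only where φ′ < −1,
i.e. in the quartic tail outside the model's band — and is guarded.
`c_l` and `c_f` (kcal per kg of lean and fat tissue) have **no shipped
defaults**: the source model class does not fix them, so they are
explicit user inputs everywhere (tests use 1800 and 9400 kcal/kg, the
standard tissue energy densities, as explicit values). The expenditure
function E(FM, FFM) is pluggable; a linear reference form
`E = K + γ_ffm·FFM + γ_f·FM` ships for testing and examples only, with
all constants caller-supplied.

Integration is classical fixed-step fourth-order Runge–Kutta (default
dt = 1 day): the dynamics are smooth and one-dimensional, and a fixed
step makes runs bit-reproducible, which adaptive stepping would not.
FFM is re-evaluated from the model at every sample, so
`total = FM + φ(FM)` holds exactly along the trajectory, and the defining
identity `c_f·ΔFM + c_l·ΔFFM = ∫(I−E)dt` is verified in the tests to
0.1% over 100-day runs. If FM leaves [0, 250] kg the trajectory is
truncated at the crossing step with a warning.

## Numerical choices and problem sizes

* Root tolerance 10⁻¹⁰ kg absolute (Brent); bisection oracles in the
  tests use 200 iterations.
* Derivative checks: central differences, step 10⁻⁴ kg, tolerance 10⁻⁶.
* Monotonicity of g is asserted on [0, 88] kg — the largest FM below
  every quartic turnover on the covariate grid.
* Recovery experiments use 5,000 records per group and 100 replicates at
  1 kg noise (each coefficient within ±4 SE in ≥ 95 replicates);
  distribution-moment checks use 2,000–4,000 records. These sizes give
  stable verdicts for the properties tested while keeping the default
  suite under a minute.
* All randomness flows through seeded `numpy` generators; hypothesis
  property tests run derandomized.

## Known limitations

* The corrected AA-female row is constrained by only two published
  points; away from the mid-band (very low or very high FM) it is a
  minimal-norm interpolant, not a refit of survey data.
* The polynomial class is valid on the fitted band only; the solver's
  increasing-branch policy and the covariate range checks (age 8–110 y,
  height 120–220 cm) enforce that boundary rather than extrapolate.
* Physical activity is not a covariate; athletic and post-surgical
  populations sit systematically off the band.
* No survey-design weighting, no DXA file parsing, no multi-compartment
  dynamics (glycogen/water, adaptive thermogenesis) — the coupling is
  deliberately the one-dimensional reduction.
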