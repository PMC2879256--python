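# bodycomp

Body-composition modelling for energy-balance applications: fat-free mass
(FFM) as a function of fat mass (FM) with age, height, sex and race
covariates, inversion of the mass-balance identity, Forbes curves,
zero-fat BMI analysis, synthetic-cohort refitting, and coupling to a
one-dimensional energy-balance differential equation.

## The problem

Dynamic models of human body weight need FFM expressed as a function of
FM so that a single differential equation can track total mass. The
classical Forbes model, `FFM = 10.4·ln(FM) + 14.2` for women (13.8/16.9
for men), predicts *changes* in FFM well but requires calibrating a
vertical translate `D` to each individual's baseline, and misbehaves at
low FM. A class of fourth-order polynomials fitted to the NHANES DXA
reference population replaces the translate with observable covariates:

```
FFM = c₁ + c_F·F + c_A·A + c_H·H + c_FA·F·A + c_FH·F·H + c_F2·F²
      + c_F2A·F²·A + c_F3·F³ + c_F4·F⁴ + c_F2H·F²·H + c_F3H·F³·H
```

with one coefficient row per (race, sex) group (African American vs all
other ethnic groups pooled). Because total mass satisfies
`W = FM + FFM(FM; A, H)` exactly, body composition follows from weight
alone by bracketed root finding, longitudinal ΔFFM follows from two such
solves, and the chain rule reduces the energy balance
`c_f·dFM/dt + c_l·dFFM/dt = I − E` to one ODE in FM.

The package is aimed at researchers in obesity and nutrition modelling
who need these curves, their inversions, and their ODE coupling as
reusable, validated components.

Coefficients live in a versioned plain-text registry with three
variants: `printed` (literal transcription of the published table),
`normalized` (two typographical anomalies replaced by their
pattern-consistent forms) and `corrected` (the default; the AA-female
row additionally repaired so that it reproduces the published worked
inversion example and keeps a positive zero-fat intercept — see
`docs/methods.md` and `scripts/derive_corrected_coefficients.py`).

## Worked example

An African American woman, age 34, height 165 cm, weighs 75 kg and loses
10 kg. What was her body composition, and how much of the loss is lean
tissue?

```sh
$ bodycomp solve --weight 75 --age 34 --height 165 --sex F --race AA
fm_kg: 27.75
ffm_kg: 47.25
ffmi_kg_m2: 17.3554
fmi_kg_m2: 10.1928

$ bodycomp delta --weight 75 --delta-weight -10 --age 34 --height 165 --sex F --race AA
fm_baseline_kg: 27.75
fm_final_kg: 20.74
ffm_baseline_kg: 47.25
ffm_final_kg: 44.26
delta_fm_kg: -7.01
delta_ffm_kg: -2.99
```

At 75 kg the model attributes 27.75 kg to fat (fat-mass index
10.2 kg/m²); after the 10 kg loss, fat accounts for 7.01 kg of the change
and lean tissue for 2.99 kg — about 30%, typical for moderate weight loss
at this starting composition.

The same library calls are `solve_fm`, `delta_ffm_nhanes`,
`delta_ffm_forbes` (translate-calibrated Forbes prediction),
`zero_fat_curve`/`curve_shape_report` (minimal BMI versus height at zero
fat), `generate_cohort`/`fit_group`/`screen_terms` (synthetic cohorts and
per-group OLS refitting at the P < 0.001 screen) and
`simulate_trajectory` (RK4 integration of the coupled energy-balance
equation with user-supplied energy constants and expenditure function).
Other CLI subcommands: `eval`, `evaluate`, `zerofat`, `simulate`, `fit`,
`ode`.

```sh
$ bodycomp zerofat --sex F --race NAA --age 30 --hmin 160 --hmax 166 --step 2
age_y,height_cm,bmi_kg_m2
30,160,15.1172
30,162,15.2797
30,164,15.4298
30,166,15.5683
# shape age=30 increasing=True concave_down=True
```

The zero-fat BMI — the theoretical floor implied by the model — rises
with height and is concave down, consistent with the lowest BMI values
recorded in famine survivors.

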