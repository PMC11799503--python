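# tiaprop

Dispersion of time-integrated activity under reduced imaging schedules in
radionuclide-therapy dosimetry.

## The problem

Patient-specific dosimetry in radionuclide therapy (e.g. ¹⁷⁷Lu-DOTA-TATE)
estimates the activity in an organ at a handful of imaging time-points,
fits a time-activity curve (TAC), and integrates it to a time-integrated
activity (TIA), which is proportional to absorbed dose.  Because each
imaging session is expensive, there is strong interest in dropping
time-points — but every activity estimate carries a random error, and
fewer, worse-placed points let those errors blow up the TIA.

`tiaprop` provides closed-form, first-order (GUM law-of-propagation-of-
uncertainty) answers to two questions, for mono-exponential TACs
`A(t) = A0·exp(−(λ_phys + λ_biol)t)` with a fixed coefficient of variation
*r* of the activity estimates and inverse-square weighted least-squares
fitting:

1. **How precise is a TIA estimate from a given schedule?**  With schedule
   moments *n*, *t̄*, *s²* (mean and divisor-*n* variance of the
   time-points) and the population moments E[τ], V[τ] of the time constant
   τ = 1/(λ_phys + λ_biol),

       V[ε] = (r²/n) · (1 + (t̄ − E[τ])²/s² + V[τ]/s²)

   where ε is the relative TIA error.  Precision is best for many,
   widely-dispersed time-points centred on E[τ].

2. **How much will a reduced schedule's TIA differ from the full one's?**
   For a reduced schedule nested in the full one (moments *m*, *t̄″*,
   *s″²*), the two estimates are positively correlated (correlation
   sd_full/sd_reduced) and

       V[δ] = r² · { (1/m)(1 + (t̄″−E[τ])²/s″²) − (1/n)(1 + (t̄−E[τ])²/s²)
                     + V[τ]/(m·s″²) − V[τ]/(n·s²) }

   where δ is the relative difference between the reduced- and
   full-schedule estimates.  Ratios of sd(δ) between candidate reduced
   schedules are independent of *r*, so schedules can be ranked without
   knowing the measurement CV.

The package also contains the general matrix propagation engine these
forms collapse from (`tiaprop.lpu`), the bounded weighted least-squares
estimator itself (`tiaprop.fitting`), Monte-Carlo verification sweeps
(`tiaprop.mc`), a cohort-level schedule-comparison pipeline
(`tiaprop.cohort`) and a synthetic-cohort generator (`tiaprop.synthetic`).

## Worked example

Rank two-point reduced schedules for a right-kidney-like population
(E[τ] = 78 h, CV(τ) = 20%) imaged at 21, 93 and 165 h post injection,
with a 10% measurement CV:

```python
import numpy as np
import tiaprop as tp

full = tp.Schedule([21, 93, 165])
pop = tp.PopulationTauStats.from_mean_cv(78.0, 0.20)
for red in ([21, 93], [93, 165], [21, 165]):
    rep = tp.compare_schedules(full, tp.Schedule(red), pop, 0.10)
    print(f"reduced {red}: sd(delta) = {100*rep.sd_delta:.2f}%")
r12 = tp.sd_ratio_prediction(full, tp.Schedule([21,93]), tp.Schedule([21,165]), pop)
r23 = tp.sd_ratio_prediction(full, tp.Schedule([93,165]), tp.Schedule([21,165]), pop)
print(f"sd12/sd13 = {r12:.2f}   sd23/sd13 = {r23:.2f}")
```

prints

```
reduced [21, 93]: sd(delta) = 6.21%
reduced [93, 165]: sd(delta) = 11.04%
reduced [21, 165]: sd(delta) = 4.08%
sd12/sd13 = 1.52   sd23/sd13 = 2.70
```

i.e. keeping the first and last time-points (sd(δ) ≈ 4%) is the safest
two-point reduction for this population — its mean is closest to E[τ] and
its dispersion is largest — and dropping the first point instead would
nearly triple the spread.  Fitting one noisy series with the estimator the
predictions describe:

```python
tac = tp.MonoExpTAC.from_half_lives(100.0, 50.0, 159.5)  # 177Lu, T_eff = 50 h
t = np.array([24.0, 96.0, 168.0])
rng = np.random.default_rng(0)
values = tac.activity(t) * tp.sample_lognormal(1.0, 0.10, 3, rng)
print(tp.MonoExpModel(t, values, tac.lambda_phys).fit().summary())
```

```
Mono-exponential TAC fit (weighted NLS, inverse-square weights)
---------------------------------------------------------------
n points                       3
A0_hat                   98.1168  MBq
lambda_biol_hat         0.009161  1/h
effective half-life       51.320  h
TIA_hat                  7264.46  MBq h
converged                   True
at bound                   False
residual CV (r_hat)       0.0423
```

## Command line

The `tiaprop` console script exposes the same machinery as subcommands:
`predict` (closed-form schedule comparison), `simulate-fixed` /
`simulate-population` (Monte-Carlo verification sweeps, tidy CSV output),
`linearity` (linearization diagnostic), `synth-cohort` (synthetic cohort
CSV + truth sidecar) and `compare` (cohort-level ratio tables with an
ordinal agreement count).  Every run writes a `config.json` with the
resolved parameters and seed next to its outputs.

```sh
tiaprop predict --full 21,93,165 --reduced 21,93 --reduced 21,165 \
    --mean-tau 78 --cv-tau 0.20 --out out/predict
tiaprop simulate-population --fixture scenario2:24_96 --seed 1 --out out/sweep --plots
```

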