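# pkbias

Accuracy analysis of compartmental pharmacokinetic simulation against
measured plasma drug concentrations.

Open-loop PK simulators (the engines behind target-controlled infusion
models) are routinely used to predict the plasma concentration of
anesthetic opioids such as fentanyl from the dosing record. How far the
*measured* concentration sits from that prediction — and whether the gap
depends on the surgical procedure and on time into the case — is a
clinical question for anesthesiologists and pharmacometricians.
`pkbias` implements that evaluation as a tested pipeline:

1. **Simulate.** A linear three-compartment (mammillary) model with
   central volume `V1` and micro rate constants `k10, k12, k21, k13,
   k31` predicts plasma concentration from each patient's bolus/infusion
   schedule via the closed-form tri-exponential superposition
   `c(t) = Σ dose·aᵢ e^(−λᵢ(t−t_dose))`, with an independent numerical
   ODE oracle for cross-validation. The published adult fentanyl
   parameter set of Shafer and colleagues is packaged
   (`shafer_fentanyl`).
2. **Pair.** Measured samples pass the study exclusion rules — drop
   pre-dose controls, samples drawn within 10 min of a bolus, and
   values below the 0.05 ng/mL quantitation limit — then join with the
   prediction at the sampling time and bin into 90-min stages of elapsed
   time since the first dose.
3. **Quantify.** Fixed bias (mean measured−predicted, ng/mL) with
   Student-t 95% CIs, performance error
   `PE = (measured − predicted)/predicted × 100%` and its median
   absolute value (MDAPE), ±0.5 ng/mL exceedance counts, Pearson/OLS
   regression of measured on predicted and of the difference on elapsed
   time, and the Fisher-z sample-size calculation
   `n = ⌈((z₁₋α/2 + z_power)/atanh r)² + 3⌉`.

A fully synthetic two-arm cohort generator (30 mastectomy + 20
laparoscopic prostatectomy patients, 30-min arterial sampling,
procedure-specific injected bias, LLOQ censoring) makes the pipeline
testable end to end without any patient data; see `docs/methods.md`.

## Worked example

```sh
pkbias synth --seed 1 --out demo/data
pkbias analyze --patients demo/data/patients.csv --doses demo/data/doses.csv \
               --samples demo/data/samples.csv --out demo/analysis
```

prints the pipeline accounting

```
synth: 50 patients, 366 doses, 433 samples -> demo/data
analyze: excluded 100 pre-dose, 4 post-bolus, 0 below LLOQ; 329 usable
```

and `demo/analysis/summary.txt` contains

```
usable pairs: 329
measured vs predicted: r = 0.715, y = 0.824x + 0.542 (n = 329, P = 8.24e-53)
overall difference (measured - predicted): 0.22 ± 0.50 ng/mL [range -1.30, 1.70]
samples beyond ±0.5 ng/mL: 92 over, 24 under (35.3%)
difference vs elapsed time: r = -0.280, y = -0.002x + 0.452 (n = 329, P = 2.47e-07)
  mastectomy: r = 0.078, y = 0.001x + 0.261 (n = 159, P = 0.33)
  prostatectomy: r = -0.374, y = -0.002x + 0.466 (n = 170, P = 4.96e-07)
```

Reading this: the simulation correlates strongly with measurement
(r = 0.715) but over a third of samples miss by more than 0.5 ng/mL.
The short procedure (mastectomy) shows a flat positive bias — measured
runs ≈ 0.3 ng/mL above predicted at every stage — while in the long
procedure (prostatectomy) the bias drifts downward by ≈ 0.002 ng/mL per
minute, crossing from positive to negative late in the case, exactly the
structure the generator injected. `demo/analysis/table2.csv` holds the
per-(procedure, stage) breakdown (n, means, fixed bias with CI,
exceedance counts, MDAPE):

```
procedure,stage,n,...,mean_difference,sd_difference,ci_low,ci_high,...,mdape_pct
mastectomy,1,60,...,0.29,0.47,0.17,0.41,...,30
mastectomy,2,81,...,0.34,0.44,0.24,0.43,...,26
```

The power calculation used to size such a study:

```sh
$ pkbias power --r 0.5 --simulate 5000 --seed 1
minimum n = 38 (r > 0.5, power 0.9, alpha 0.05)
empirical power at n = 38: 0.911 (5000 replicates)
```

The library mirrors the CLI: `pkbias.predict_concentration`,
`pkbias.filter_samples`, `pkbias.build_stage_table`,
`pkbias.generate_cohort`, `pkbias.recover_bias`, etc.

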