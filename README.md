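# feverscreen

A validation toolkit for noncontact infrared fever screening. It answers the
question a hospital entrance-screening program has to answer before trusting
a handheld infrared thermometer (NCIT): *how far do its readings sit below a
reference method, how much do they scatter, and what screening threshold
should be used to catch fever at an acceptable sensitivity/specificity
trade-off?*

The package is aimed at biostatisticians and infection-prevention teams
validating thermometry devices, and implements:

- **Bland–Altman method agreement** between NCIT readings and a
  temporal-artery (TAT) reference: bias Δμ = mean(T_NCIT − T_TAT), 95%
  limits of agreement Δμ ± 1.96·s, with t-based confidence intervals,
- a **measurement-offset model** ΔT ~ N(Δμ, ρ²) with ρ = LOA/1.96, used to
  simulate NCIT readings for any reference cohort,
- **diagnostic accuracy** of NCIT screening thresholds
  T*_IR = T* + Δμ + δT (δT ∈ [−LOA, +LOA]) against referent fever
  T ≥ 100.0 °F: confusion matrices, sensitivity/specificity sweeps, ROC
  curves with AUC and the equal-error operating point,
- **normality screening** (Lilliefors with seeded Monte-Carlo p-values;
  Anderson–Darling with the small-sample adjustment) that, together with
- the **distance-to-spot geometry** of infrared optics
  (spot = distance / D:S; target must be ≥ 2× spot) and Stefan–Boltzmann
  radiometry (M = ε·σ·T⁴), gates which measurement distances are valid at
  all, and
- **synthetic-data generators** for a paired 51-subject device study and a
  578,522-subject reference cohort, so every analysis is runnable without
  access to subject-level data.

See `docs/methods.md` for the statistical details and the generators'
assumptions.

## Worked example

Generate a synthetic device study plus a 100,000-subject reference cohort,
then run the stages:

```sh
$ feverscreen simulate --seed 7 --out demo --cohort-n 100000
wrote 51 paired records and a 100000-subject cohort to demo

$ feverscreen agreement --study demo/study.csv --distance 1ft
bias -5.81 F  LOA [-8.09, -3.54] F  rho 1.16 F

$ feverscreen device --distance 6ft --ds 12
spot diameter 6.00 in at 6ft (D:S 12:1); target 3 in -> INADEQUATE (margin 0.50, need >= 2)

$ feverscreen screen --cohort demo/cohort.csv --seed 17 --thresholds 91.1,93.9,96.7
T*_IR  91.1 F: SE  97.88%  SP  17.54%  TP 4297 FP 78842 TN 16768 FN 93
T*_IR  93.9 F: SE  55.47%  SP  79.66%  TP 2435 FP 19444 TN 76166 FN 1955
T*_IR  96.7 F: SE   4.01%  SP  99.55%  TP 176 FP 433 TN 95177 FN 4214
```

Reading the output: at 1 ft the simulated device reads on average 5.8 °F
below the reference, with 95% of differences within the LOA band. A 12:1
device at 6 ft has a 6 in measurement spot — twice a typical forehead — so
6-ft readings are invalid regardless of their statistics. Screening the
cohort at the low threshold 91.1 °F catches 97.9% of febrile subjects but
flags 82% of afebrile ones; the high threshold 96.7 °F almost never
false-alarms but misses 96% of fevers. The mid threshold (the expected NCIT
reading of a subject exactly at the fever cut) sits between.

The full pipeline chains every stage from one seed and writes a JSON report
plus CSV tables:

```sh
$ feverscreen pipeline --seed 7 --out demo/run
gate kept: 1ft
offset model: delta_mu -6.59 F, rho 1.28 F
equal-error point: 92.96 F at 71.5%
report written to demo/run
```

The same operations are available as a library:

```python
from feverscreen import (OffsetModel, CohortGenSpec,
                         generate_reference_cohort, simulate_ncit, classify)

cohort = generate_reference_cohort(CohortGenSpec(seed=1))      # n = 578,522
sim = simulate_ncit(cohort.temps, OffsetModel(), seed=2)       # Δμ=-6.15, ρ=1.45
print(classify(cohort.temps, sim, t_star=100.0, t_star_ir=93.9))
```

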