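# meridian

Simulation and analysis toolkit for studies of **meridional anisotropy**
in spatial vision — orientation-dependent deficits in contrast
sensitivity (CS) and in the steady-state visual evoked potential
(ssVEP), as arise in high with-the-rule astigmatism.

The package implements, as tested and reusable components, the complete
measurement-and-analysis chain of such a study, together with a
synthetic cohort generator so every stage can be exercised end to end
without human data:

- **`meridian.cohort`** — simulated observers in two groups (highly
  astigmatic, HAS, cylinder ≤ −2.00 D; non-astigmatic, NAS,
  |cylinder| ≤ 0.50 D), each with a ground-truth log-parabola CSF per
  orientation, a Weibull 4AFC psychometric function
  P(c) = γ + (1−γ−λ)(1−exp(−(c/α)^β)) with γ = 0.25, and a generative
  ssVEP model (15 Hz component over 1/f + 50 Hz line + white noise).
- **`meridian.staircase`** — transformed up-down (3-down-1-up) adaptive
  staircase in dB (20·log10 contrast): 1.5 dB initial step, 0.3/0.5 dB
  steps after the first reversal, termination at 12 reversals, threshold
  from the mean of the last 8, logCS = −dB/20.
- **`meridian.csf`** — least-squares parabola fit of logCS on log10
  spatial frequency; closed-form area under the log CSF (AULCSF) over
  0.6–12 cpd with clipping at logCS = 0; high-frequency cutoff at the
  larger real root of the quadratic.
- **`meridian.ssvep`** — zero-phase 3–100 Hz band-pass and 50 Hz notch,
  coherent averaging of the four 8.53 s segments per trial, single-sided
  DFT amplitude spectrum, signal at 15 Hz over the mean of the 14/16 Hz
  neighbor bins, and inclusive SNR ≥ 3 trial gating.
- **`meridian.stats`** — split-plot mixed repeated-measures ANOVA
  (group × spatial frequency × orientation) with Mauchly's test,
  Greenhouse–Geisser correction and partial η², simple main effects with
  stratum-specific error terms, Holm–Bonferroni step-down adjustment,
  paired/unpaired t-tests (including a summary-statistics entry point)
  and Pearson correlation.
- **`meridian.pipeline`** — one seeded configuration drives cohort →
  staircases → CSF fits → ssVEP trials → statistics, reproducing the
  study's full result structure deterministically.

## Worked example

```python
from meridian.pipeline import StudyConfig, run_study

report = run_study(StudyConfig(seed=1))
print(report.anovas["cs"][["effect", "F", "p", "gg_epsilon", "p_report", "eta2p"]])
```

```
                  effect      F         p  gg_epsilon  p_report   eta2p
                   group  0.596    0.4462         NaN    0.4462 0.01948
                      sf  671.3 4.377e-81      0.6564 4.311e-54  0.9572
             orientation  20.54 8.697e-05           1 8.697e-05  0.4064
              group × sf  2.124    0.0819      0.6564    0.1117 0.06613
     group × orientation   12.8  0.001199       1      0.001199  0.2991
        sf × orientation 0.8796    0.4784      0.6046    0.4367 0.02849
group × sf × orientation  1.331    0.2623      0.6046    0.2717 0.04249
```

The simulated cohort carries a horizontal-orientation logCS deficit in
the HAS group only (0.15 log units by default), and the ANOVA on the
recovered thresholds shows exactly that structure: a strong spatial
frequency effect (the CSF itself), an orientation effect, and a
group × orientation interaction, with the group main effect null. The
within-group simple effects localize the deficit:

```python
print(report.cs_simple_effects.query("group == 'HAS'"))
```

```
group  sf     F        p  p_adjusted  eta2p
  HAS 0.6 61.87 1.06e-06   5.299e-06 0.8049
  HAS 1.3 8.194  0.01186     0.03558 0.3533
  HAS   3  1.94    0.184       0.184 0.1145
  HAS   6 13.04 0.002568     0.01027  0.465
  HAS  12 5.161  0.03825      0.0765  0.256
```

Each F compares horizontal vs vertical logCS within one HAS spatial
frequency against that stratum's own error term; `p_adjusted` is
Holm-corrected over the five frequencies. `report.ssvep_trials` holds
the per-trial 15 Hz amplitudes, noise estimates and SNR verdicts
(`report.rejection_rate` was 0.0 here — at the default noise level
essentially every trial clears SNR ≥ 3), and `report.demographics`
summarizes the truncated-normal refraction draws per group
(mean ± SEM and range).

A command-line interface wraps the same pipeline:

```sh
meridian run --config study.yaml --seed 1 --out results/
meridian cohort --seed 3 --out cohort/
meridian ssvep --manifest waves/manifest.csv --out snr.csv
```

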