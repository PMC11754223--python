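# Methods

`meridian` simulates and analyzes a two-group study of meridional
anisotropy in spatial vision: contrast sensitivity (CS) measured
psychophysically with an adaptive staircase, and the steady-state visual
evoked potential (ssVEP) measured electrophysiologically, both on a
5 spatial frequency × 2 orientation grid. This note records the models,
the defaults and why, the numerical choices, and what the simulations do
and do not establish.

## Observer model

Human observers are replaced by a stochastic ideal observer. Each
simulated participant carries, per grating orientation, a ground-truth
log contrast sensitivity function

    logCS(x) = a·x² + b·x + c,   x = log10(spatial frequency in cpd),

and answers the four-alternative detection task through a Weibull
psychometric function

    P(correct | c) = γ + (1 − γ − λ)·(1 − exp(−(c/α)^β)),

with guess rate γ = 0.25 (fixed by the 4AFC geometry), lapse rate λ
(drawn from a truncated normal, mean 0.015, range [0, 0.06]), slope β
(mean 3.0, range [2, 5]) and threshold α anchored to the true CSF:
α = 10^(−logCS). Spatial 4AFC geometry (quadrant placement, feedback) is
not modelled; the observer abstraction answers correct/incorrect directly.

Because an up-down staircase does not estimate α itself, recovery tests
compare against the *analytic convergence target*: the contrast at which
the psychometric function crosses the staircase's tracked probability.
`ObserverProfile.convergence_log_cs` computes it in closed form from
(α, β, γ, λ).

### Default CSF shape

The baseline parabola (a, b, c) = (−1.3, 1.17, 1.737) peaks near 3 cpd
at logCS ≈ 2.0 and crosses logCS = 0 near 49 cpd — an ordinary young
adult CSF. Between-observer variability is an additive normal shift of c
(SD 0.12 log units) plus an independent per-orientation jitter (SD 0.04).
The group effect is a downward shift of the highly-astigmatic (HAS)
group's *horizontal* curve: a scalar (default 0.15 log units, shifting c)
or a per-frequency mapping when the deficit should be confined to
particular frequencies. The non-astigmatic (NAS) group gets no deficit.

### Refraction and demographics

Sphere, cylinder, axis and age are drawn from normal distributions
truncated (by inverse-CDF sampling) to each group's inclusion range —
HAS: cylinder ≤ −2.00 D (parent mean −2.80, SD 1.12), NAS:
−0.50 ≤ cylinder ≤ 0 (parent mean −0.234, SD 0.20); spheres within
[−6, 0] D. The parent means and SDs reproduce the emulated demographic
table (SD = SEM·√16); truncation pulls the realized HAS cylinder mean
below the parent mean (to ≈ −3.3 D), which is the correct behaviour of a
truncated distribution, not a calibration target.

## Staircase

A transformed up-down (3-down-1-up) track in decibels,
dB = 20·log10(contrast): three consecutive correct responses step the
contrast down, any error steps it up. Starting contrasts are 20%
(0.6/1.3/3 cpd) and 25% (6/12 cpd). The step is 1.5 dB until the first
reversal (the move that produces that reversal still uses it), then
+0.3 dB for increases and −0.5 dB for decreases. A run ends at 12
reversals; the threshold is the arithmetic mean of the last 8 reversal
levels *in dB* (the track is symmetric on that scale), and
logCS = −threshold_db/20 identically. Each condition is measured twice
and averaged in logCS.

Which of 0.3/0.5 dB applies to up vs down moves is genuinely ambiguous
in the protocol wording; the default reads "positive" as the step after
an error. `swap_small_steps` flips the assignment.

**Convergence.** With equal steps a 3-down-1-up rule tracks
p³ = 0.5 → 79.37% correct. With unequal steps the zero-drift point of
the walk moves to p³ = S_up/(S_up + S_down) = 0.375 (≈ 72% correct) —
about 0.8 dB below the Wetherill point for β = 3. Empirically, however,
the mean of the last 8 reversal levels over full 12-reversal runs sits
within 0.2–0.4 dB of the 79.37% contrast across β ∈ [2, 5]: reversal
averaging of the asymmetric walk plus the approach from above offset
most of the drift-equilibrium shift. The acceptance suite checks the
0.6 dB band at 500 runs per slope.

**Degenerate observers.** An observer that always (or never) responds
correctly produces a monotone track pinned at a contrast bound with no
reversals; `run_staircase` raises a non-convergence error after a trial
cap rather than returning a silent estimate. Direction flips at a clamped
bound do count as reversals, so noisy observers near a bound still
terminate.

## CSF summaries

A second-degree polynomial in x = log10(sf) is fit by ordinary least
squares to the five (sf, logCS) points per observer and orientation.

- **AULCSF** integrates the fitted curve over [0.6, 12] cpd on the
  log-frequency axis, in closed form from the quadratic antiderivative,
  clipping at logCS = 0 by splitting the integral at the real roots.
  Clipping and the bounds are configurable; both choices are stated with
  the output.
- **Cutoff** is the high-frequency crossing of logCS = 0, i.e. 10^x₊ at
  the larger real root. It is a *missing value* (NaN), not an error, when
  the vertex lies below zero or no real root exists; an upward-opening
  fit is flagged as non-physiological with a warning. Missing cutoffs
  propagate listwise into the statistics (participants with incomplete
  cells are dropped from that ANOVA, with a logged count).

## ssVEP chain

Each trial is four 8.53 s segments. The sampling rate is not part of the
emulated recording specification; the default is 512 Hz (configurable,
must exceed 200 Hz so the 3–100 Hz analysis band is comfortably inside
Nyquist).

Per segment: zero-phase Butterworth band-pass 3–100 Hz (order 4) and
zero-phase 50 Hz notch (Q = 35). Zero-phase (forward–backward)
application squares the magnitude response, giving ≥ 20 dB attenuation
at 0.5 Hz and 150 Hz and ≥ 20 dB at 50 Hz while the 15 Hz analysis
frequency passes within 2% (within 1% for the notch). The four segments
are averaged coherently in the time domain (the 15 Hz component is
phase-locked across a trial's segments), cutting broadband noise
amplitude by √4; one DFT of the average follows.

The amplitude spectrum is single-sided with sinusoid-amplitude
normalization (2|X_k|/N; DC and Nyquist not doubled), so an exact-bin
sinusoid of amplitude A reads A. At the 8.53 s duration the bins fall
every ≈ 0.117 Hz and 14/15/16 Hz map to nearest bins (worst-case centre
offset < 0.06 Hz, leakage loss < 1%); an exact-bin duration (e.g. 8 s)
is available for analytic tests. Signal = amplitude at 15 Hz; noise =
mean of the 14 and 16 Hz bin amplitudes; SNR = signal/noise, and trials
with SNR ≥ 3 are kept (the boundary is inclusive, compared with a 1e−9
relative tolerance so an exactly-boundary case is not lost to floating
point). The condition summary is the mean of log10 amplitude over kept
trials — equivalently the log of the geometric mean, which is the
reading adopted for the ambiguous "geometric mean of the logarithmic
amplitudes".

### Synthetic EEG

Segments are the 15 Hz sinusoid (amplitude 10^logA, logA set per group ×
orientation × frequency) plus 1/f background noise (spectrally shaped
Gaussian, time-domain SD 2 µV), 50 Hz line noise (5 µV, random phase)
and white noise (1 µV). Per-observer amplitude offsets are normal with
SD 0.10 log10 units. The default amplitude grid (≈ 2–5 µV, lower for
horizontal gratings in both groups and for HAS at 12 cpd) gives SNR ≈
20–100, so the SNR ≥ 3 gate rejects essentially nothing at baseline —
mirroring the near-zero rejection rate such recordings show — while a
silenced signal is rejected ≈ 96% of the time. The noise model contains
no blinks, drifts, or artifacts beyond these three terms, so passing
recovery tests demonstrates correctness of the analysis chain, not
robustness to real EEG artifacts.

## Statistics

The design is split-plot: one between-subject factor (group) crossed
with one or two within-subject factors. Sums of squares come from the
balanced cell-mean decomposition (Types I–III coincide; unbalanced or
incomplete tables are rejected with the offending participant named).
Each within effect is tested against its own effect × subject-within-
group error; partial η² = SS_effect/(SS_effect + SS_error).

Sphericity is assessed per within-subject contrast set (orthonormalized
Helmert contrasts; Kronecker products for interactions) on the covariance
pooled within groups (error df = N − g): Mauchly's W with the chi-square
approximation, and Greenhouse–Geisser ε = tr(T)²/(m·tr(T²)), clamped to
[1/m, 1]. A two-level factor gives W = ε = 1 exactly. GG-corrected
p-values are always reported; the `p_report` column applies the
correction only when Mauchly rejects at 0.05 (configurable to always or
never).

Simple main effects use stratum-specific error terms (a one-way
repeated-measures F within each stratum for a within factor, a one-way
between-subjects F for the group factor), Holm-adjusted over the family
of strata (five frequencies). Planned AULCSF orientation comparisons are
paired t-tests with plain Bonferroni over the two groups. CS–ssVEP
correlations are Pearson, Holm-adjusted within each group over its ten
conditions. Holm is the standard step-down: sort, multiply the i-th
smallest by (m − i + 1), enforce the running maximum, cap at 1.

Degenerate inputs: a constant table yields zero SS everywhere, F and p
reported missing (0/0), η² = 0; zero-variance t-tests report t = 0,
p = 1 when the difference is identically zero and a missing statistic
otherwise.

## Problem sizes and verification

The default study (32 observers, 2 staircases × 10 conditions, 30 ssVEP
trials/observer of 4 × 8.53 s segments at 512 Hz) runs in a few seconds;
pipeline tests use a scaled cohort (4/group, 256 Hz, 4 s segments) and
verify bit-identical reruns under a fixed seed. Monte-Carlo checks use
500 staircase runs per slope (convergence), 200 simulated trials
(amplitude recovery, averaging gain), 1,000–2,000 replicates (Mauchly
calibration, ANOVA type-I error), and three effect sizes × 500
replicates (power monotonicity), with observer-level Gaussian simulation
standing in for the full chain where only the statistics are under test.
The ANOVA is validated against a brute-force textbook-formula oracle, a
frozen R `aov` split-plot reference, and pingouin (one-within designs;
sphericity in the single-group case, where pooling conventions coincide).

## Known limitations

- The parabola is the only CSF model (no truncated log-parabola/qCSF),
  by design.
- The generator draws per-observer effects independently; real CS and
  ssVEP share subject-level variance only through the imposed group
  structure, so simulated CS–ssVEP correlations are null by construction.
- Sphericity handling offers Greenhouse–Geisser only (no Huynh–Feldt).
- The 7.5 reversals-per-second stimulus convention vs the 15 Hz analysis
  frequency is resolved by placing simulated signal power at 15 Hz, the
  frequency actually analyzed.
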