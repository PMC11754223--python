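"""Synthetic observer cohorts for meridional-anisotropy simulations.

Generates two groups of observers — highly astigmatic (HAS, cylinder
<= -2.00 D) and non-astigmatic (NAS, |cylinder| <= 0.50 D) — each with a
ground-truth contrast sensitivity function per grating orientation, a
Weibull psychometric function for the 4AFC detection task, and a
steady-state EEG signal model (15 Hz response on 1/f + 50 Hz line +
white noise).  Everything is driven by a single seed so a cohort, its
trial-by-trial responses, and its EEG epochs regenerate bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ORIENTATIONS",
    "SPATIAL_FREQUENCIES",
    "GUESS_RATE_4AFC",
    "TruncNormal",
    "ObserverProfile",
    "SSVEPSignalModel",
    "SSVEPEffects",
    "CohortSpec",
    "Cohort",
    "make_cohort",
    "weibull_p",
    "contrast_at_p",
    "simulate_response",
    "synthesize_trial",
    "segment_samples",
    "write_cohort_tables",
]

ORIENTATIONS = ("H", "V")
SPATIAL_FREQUENCIES = (0.6, 1.3, 3.0, 6.0, 12.0)
GUESS_RATE_4AFC = 0.25


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mean, sd) truncated to [lo, hi] (sampled by inverse CDF)."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if not self.lo < self.hi:
            raise ValueError(f"lo must be < hi, got [{self.lo}, {self.hi}]")

    def sample(self, rng: np.random.Generator, size=None):
        if self.sd == 0:
            return np.full(size, self.mean) if size else self.mean
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return _sps.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )


@dataclass(frozen=True)
class ObserverProfile:
    """Ground truth for one simulated participant.

    ``true_csf`` maps orientation ("H"/"V") to quadratic coefficients
    (a, b, c) of log10 contrast sensitivity as a function of
    x = log10(spatial frequency in cpd).  The detection task is modelled
    by a Weibull psychometric function with slope ``psycho_slope``,
    lapse rate ``lapse`` and the 4AFC guess rate 0.25; its threshold
    parameter alpha is anchored to the true CSF.
    """

    participant_id: str
    group: str  # "HAS" | "NAS"
    age: float
    sphere: float  # D
    cylinder: float  # D
    axis: float  # degrees
    true_csf: Mapping[str, Tuple[float, float, float]]
    psycho_slope: float
    lapse: float
    guess: float = GUESS_RATE_4AFC
    #: optional per-orientation, per-sf additive logCS adjustments (used when
    #: a group effect is confined to particular spatial frequencies)
    csf_adjustments: Mapping[str, Mapping[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.group not in ("HAS", "NAS"):
            raise ValueError(f"group must be HAS or NAS, got {self.group!r}")
        if self.guess != GUESS_RATE_4AFC:
            raise ValueError("guess rate must be exactly 0.25 for the 4AFC task")
        if not 0 <= self.lapse < 1 - self.guess:
            raise ValueError(f"lapse must be in [0, {1 - self.guess}), got {self.lapse}")
        if self.psycho_slope <= 0:
            raise ValueError("psycho_slope must be positive")
        for orientation, (a, _b, _c) in self.true_csf.items():
            if a >= 0:
                raise ValueError(
                    f"CSF parabola must open downward (a < 0); "
                    f"got a={a} for orientation {orientation!r}"
                )
        if self.group == "HAS" and self.cylinder > -2.0:
            raise ValueError(
                f"HAS inclusion requires cylinder <= -2.00 D, got {self.cylinder}"
            )
        if self.group == "NAS" and abs(self.cylinder) > 0.5:
            raise ValueError(
                f"NAS inclusion requires |cylinder| <= 0.50 D, got {self.cylinder}"
            )

    def log_cs_true(self, sf: float, orientation: str) -> float:
        """True log10 contrast sensitivity at (sf, orientation)."""
        if sf <= 0:
            raise ValueError(f"sf must be positive, got {sf}")
        a, b, c = self.true_csf[orientation]
        x = math.log10(sf)
        adj = self.csf_adjustments.get(orientation, {}).get(float(sf), 0.0)
        return a * x * x + b * x + c + adj

    def threshold_contrast(self, sf: float, orientation: str) -> float:
        """Weibull alpha: contrast at which the true CSF places threshold."""
        return 10.0 ** (-self.log_cs_true(sf, orientation))

    def convergence_log_cs(self, sf: float, orientation: str, p: float) -> float:
        """-log10 of the contrast yielding proportion-correct ``p``.

        This is the quantity an up-down staircase tracking ``p`` actually
        estimates; use it as the recovery target instead of the raw alpha.
        """
        c = contrast_at_p(
            p,
            self.threshold_contrast(sf, orientation),
            self.psycho_slope,
            self.guess,
            self.lapse,
        )
        return -math.log10(c)


def weibull_p(
    contrast: float, alpha: float, beta: float, gamma: float = GUESS_RATE_4AFC,
    lapse: float = 0.0,
) -> float:
    """P(correct) = gamma + (1 - gamma - lapse) * (1 - exp(-(c/alpha)**beta))."""
    return gamma + (1.0 - gamma - lapse) * (1.0 - math.exp(-((contrast / alpha) ** beta)))


def contrast_at_p(
    p: float, alpha: float, beta: float, gamma: float = GUESS_RATE_4AFC,
    lapse: float = 0.0,
) -> float:
    """Inverse of :func:`weibull_p` in contrast."""
    top = gamma + (1.0 - gamma - lapse)
    if not gamma < p < top:
        raise ValueError(f"p={p} outside the attainable range ({gamma}, {top})")
    q = (p - gamma) / (1.0 - gamma - lapse)
    return alpha * (-math.log(1.0 - q)) ** (1.0 / beta)


def simulate_response(
    observer: ObserverProfile,
    sf: float,
    orientation: str,
    contrast: float,
    rng: np.random.Generator,
) -> bool:
    """One Bernoulli 4AFC response at the given grating condition."""
    if not 0 < contrast <= 1:
        raise ValueError(f"contrast must be in (0, 1], got {contrast}")
    p = weibull_p(
        contrast,
        observer.threshold_contrast(sf, orientation),
        observer.psycho_slope,
        observer.guess,
        observer.lapse,
    )
    return bool(rng.random() < p)


@dataclass(frozen=True)
class SSVEPSignalModel:
    """Generative model of one steady-state EEG epoch segment.

    ``log_amp`` maps (group, orientation, sf) to the true log10 amplitude
    (log10 microvolts) of the 15 Hz steady-state component.  Background
    noise is 1/f**pink_exponent with time-domain SD ``pink_scale``, plus a
    50 Hz mains component of amplitude ``line_amp`` (random phase) and
    white noise of SD ``white_sd``; all amplitudes in microvolts.
    """

    log_amp: Mapping[Tuple[str, str, float], float]
    pink_exponent: float = 1.0
    pink_scale: float = 2.0
    line_amp: float = 5.0
    line_freq: float = 50.0
    white_sd: float = 1.0
    fs: float = 512.0
    segment_duration: float = 8.53
    signal_freq: float = 15.0

    def __post_init__(self) -> None:
        if self.fs <= 200:
            raise ValueError(f"fs must exceed 200 Hz, got {self.fs}")
        if self.segment_duration <= 0:
            raise ValueError("segment_duration must be positive")
        for name in ("pink_scale", "line_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def segment_samples(model: SSVEPSignalModel) -> int:
    return int(round(model.fs * model.segment_duration))


@dataclass(frozen=True)
class SSVEPEffects:
    """Condition-level parameterization of the ssVEP amplitude grid.

    ``base_log_amp`` gives the NAS vertical-grating log10 amplitude per
    spatial frequency; horizontal gratings are lower by
    ``orientation_deficit`` in both groups (the horizontal-effect-like
    bias), and the HAS group carries an extra high-frequency loss
    ``has_sf_deficits`` (per-sf mapping, default only at 12 cpd).
    """

    base_log_amp: Mapping[float, float] = field(
        default_factory=lambda: {0.6: 0.70, 1.3: 0.65, 3.0: 0.60, 6.0: 0.45, 12.0: 0.30}
    )
    orientation_deficit: float = 0.08
    has_sf_deficits: Mapping[float, float] = field(
        default_factory=lambda: {12.0: 0.15}
    )
    subject_sd: float = 0.10  # between-observer SD of log10 amplitude

    def grid(self) -> Dict[Tuple[str, str, float], float]:
        out: Dict[Tuple[str, str, float], float] = {}
        for sf, base in self.base_log_amp.items():
            for group in ("HAS", "NAS"):
                for orientation in ORIENTATIONS:
                    v = base
                    if orientation == "H":
                        v -= self.orientation_deficit
                    if group == "HAS":
                        v -= self.has_sf_deficits.get(sf, 0.0)
                    out[(group, orientation, sf)] = v
        return out


def _default_refraction() -> Dict[str, Dict[str, TruncNormal]]:
    # Group means/SEMs follow the demographic table of the emulated design
    # (n = 16 per group, SD = SEM * 4); ranges are the inclusion criteria.
    return {
        "HAS": {
            "age": TruncNormal(21.1, 2.0, 18.0, 35.0),
            "sphere": TruncNormal(-2.55, 1.64, -6.0, 0.0),
            "cylinder": TruncNormal(-2.80, 1.12, -6.0, -2.0),
            "axis": TruncNormal(180.0, 8.0, 160.0, 200.0),
        },
        "NAS": {
            "age": TruncNormal(21.3, 0.8, 18.0, 35.0),
            "sphere": TruncNormal(-1.50, 1.56, -6.0, 0.0),
            "cylinder": TruncNormal(-0.234, 0.20, -0.5, 0.0),
            "axis": TruncNormal(90.0, 60.0, 0.0, 180.0),
        },
    }


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw a cohort: sizes, refraction distributions,
    true CSF shape and group effect, psychometric parameters, ssVEP effects.

    The default CSF parabola (on x = log10 sf) peaks near 3 cpd at
    logCS ~ 2 with a high-frequency cutoff near 50 cpd; the HAS group's
    horizontal meridian is shifted down by ``horizontal_deficit`` log
    units (an additive shift of the c coefficient).
    """

    n_per_group: int = 16
    seed: int = 0
    refraction: Mapping[str, Mapping[str, TruncNormal]] = field(
        default_factory=_default_refraction
    )
    csf_baseline: Tuple[float, float, float] = (-1.3, 1.17, 1.737)
    csf_subject_sd: float = 0.12
    csf_orientation_sd: float = 0.04
    horizontal_deficit: float = 0.15
    psycho_slope_dist: TruncNormal = TruncNormal(3.0, 0.4, 2.0, 5.0)
    lapse_dist: TruncNormal = TruncNormal(0.015, 0.01, 0.0, 0.06)
    ssvep: SSVEPEffects = field(default_factory=SSVEPEffects)
    pink_exponent: float = 1.0
    pink_scale: float = 2.0
    line_amp: float = 5.0
    white_sd: float = 1.0
    fs: float = 512.0
    segment_duration: float = 8.53

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")
        a = self.csf_baseline[0]
        if a >= 0:
            raise ValueError(f"csf_baseline must have a < 0, got a={a}")
        for sd_name in ("csf_subject_sd", "csf_orientation_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        for group in ("HAS", "NAS"):
            if group not in self.refraction:
                raise ValueError(f"refraction distributions missing group {group!r}")


@dataclass(frozen=True)
class Cohort:
    observers: Tuple[ObserverProfile, ...]
    signal_model: SSVEPSignalModel
    #: per-observer additive offset of log10 ssVEP amplitude
    log_amp_offsets: Mapping[str, float]
    spec: CohortSpec

    def by_group(self, group: str) -> Tuple[ObserverProfile, ...]:
        return tuple(o for o in self.observers if o.group == group)


def make_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full cohort deterministically from ``spec.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    a0, b0, c0 = spec.csf_baseline
    observers = []
    offsets: Dict[str, float] = {}
    for group in ("HAS", "NAS"):
        dists = spec.refraction[group]
        for i in range(spec.n_per_group):
            pid = f"{group}{i + 1:02d}"
            age = float(dists["age"].sample(rng))
            sphere = float(dists["sphere"].sample(rng))
            cylinder = float(dists["cylinder"].sample(rng))
            axis = float(dists["axis"].sample(rng))
            c_subject = c0 + rng.normal(0.0, spec.csf_subject_sd)
            true_csf = {}
            adjustments: Dict[str, Dict[float, float]] = {}
            for orientation in ORIENTATIONS:
                c_or = c_subject + rng.normal(0.0, spec.csf_orientation_sd)
                if group == "HAS" and orientation == "H":
                    deficit = spec.horizontal_deficit
                    if isinstance(deficit, Mapping):
                        # deficit confined to particular spatial frequencies
                        adjustments[orientation] = {
                            float(sf): -float(d) for sf, d in deficit.items()
                        }
                    else:
                        c_or -= deficit
                true_csf[orientation] = (a0, b0, c_or)
            observers.append(
                ObserverProfile(
                    participant_id=pid,
                    group=group,
                    age=age,
                    sphere=sphere,
                    cylinder=cylinder,
                    axis=axis,
                    true_csf=true_csf,
                    psycho_slope=float(spec.psycho_slope_dist.sample(rng)),
                    lapse=float(spec.lapse_dist.sample(rng)),
                    csf_adjustments=adjustments,
                )
            )
            offsets[pid] = float(rng.normal(0.0, spec.ssvep.subject_sd))
    model = SSVEPSignalModel(
        log_amp=spec.ssvep.grid(),
        pink_exponent=spec.pink_exponent,
        pink_scale=spec.pink_scale,
        line_amp=spec.line_amp,
        white_sd=spec.white_sd,
        fs=spec.fs,
        segment_duration=spec.segment_duration,
    )
    return Cohort(
        observers=tuple(observers),
        signal_model=model,
        log_amp_offsets=offsets,
        spec=spec,
    )


def _pink_noise(
    n: int, exponent: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f**exponent noise, scaled to time-domain SD ``scale``."""
    if scale == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)  # normalized; only relative shape matters
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def synthesize_trial(
    model: SSVEPSignalModel,
    group: str,
    orientation: str,
    sf: float,
    rng: np.random.Generator,
    n_segments: int = 4,
    log_amp_offset: float = 0.0,
) -> list:
    """Simulate one ssVEP trial: ``n_segments`` epoch waveforms (microvolts).

    The 15 Hz steady-state component is phase-locked across the trial's
    segments (one phase drawn per trial); pink, line and white noise are
    independent between segments.  Returns a list of 1-D arrays of
    ``round(fs * segment_duration)`` samples.
    """
    key = (group, orientation, float(sf))
    if key not in model.log_amp:
        raise KeyError(f"unknown condition {key!r}; not in the signal model grid")
    n = segment_samples(model)
    t = np.arange(n) / model.fs
    amp = 10.0 ** (model.log_amp[key] + log_amp_offset)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    segments = []
    for _ in range(n_segments):
        wave = amp * np.sin(2.0 * np.pi * model.signal_freq * t + phase)
        wave = wave + _pink_noise(n, model.pink_exponent, model.pink_scale, rng)
        if model.line_amp > 0:
            wave = wave + model.line_amp * np.sin(
                2.0 * np.pi * model.line_freq * t + rng.uniform(0.0, 2.0 * np.pi)
            )
        if model.white_sd > 0:
            wave = wave + rng.normal(0.0, model.white_sd, n)
        segments.append(wave)
    return segments


def write_cohort_tables(cohort: Cohort, out_dir) -> None:
    """Persist the participants table and the ground-truth CSF table as CSV."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "participant": o.participant_id,
                "group": o.group,
                "age": o.age,
                "sphere": o.sphere,
                "cylinder": o.cylinder,
                "axis": o.axis,
                "psycho_slope": o.psycho_slope,
                "lapse": o.lapse,
            }
            for o in cohort.observers
        ]
    ).to_csv(out / "participants.csv", index=False)
    pd.DataFrame(
        [
            {
                "participant": o.participant_id,
                "orientation": orientation,
                "a": abc[0],
                "b": abc[1],
                "c": abc[2],
            }
            for o in cohort.observers
            for orientation, abc in o.true_csf.items()
        ]
    ).to_csv(out / "ground_truth_csf.csv", index=False)
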