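"""Transformed up-down (3-down-1-up) adaptive staircase for 4AFC contrast thresholds.

Contrast levels are tracked in decibels with the psychophysical convention
``dB = 20 * log10(contrast)``, so a 1.5 dB step multiplies contrast by
``10**(1.5/20) ~= 1.19``.  A run terminates after a fixed number of direction
reversals and the threshold is the arithmetic mean (in dB) of the last
``reversals_averaged`` reversal levels.  Log contrast sensitivity follows as
``logCS = -threshold_db / 20``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "ThresholdEstimate",
    "INITIAL_CONTRASTS",
    "db_from_contrast",
    "contrast_from_db",
    "init_staircase",
    "update",
    "estimate_threshold",
    "run_staircase",
    "run_condition",
    "convergence_probability",
    "wetherill_probability",
]

#: Default starting contrast per spatial frequency (cpd): 20% for the three
#: lowest frequencies, 25% for the two highest.
INITIAL_CONTRASTS = {0.6: 0.20, 1.3: 0.20, 3.0: 0.20, 6.0: 0.25, 12.0: 0.25}


def db_from_contrast(contrast: float) -> float:
    """Michelson contrast (0, 1] -> level in dB re unit contrast."""
    if contrast <= 0:
        raise ValueError(f"contrast must be positive, got {contrast}")
    return 20.0 * math.log10(contrast)


def contrast_from_db(level_db: float) -> float:
    return 10.0 ** (level_db / 20.0)


@dataclass(frozen=True)
class StaircaseConfig:
    """Rule and step-size parameters of the transformed up-down track.

    ``rule_down`` consecutive correct responses lower the contrast,
    every incorrect response raises it.  The first reversal switches the
    track from ``initial_step_db`` to the small asymmetric steps:
    ``step_up_db`` for increases (after an error) and ``step_down_db``
    for decreases (after a correct triplet).  Set ``swap_small_steps``
    to use the opposite assignment of the two small steps.
    """

    rule_down: int = 3
    rule_up: int = 1
    initial_step_db: float = 1.5
    step_up_db: float = 0.3
    step_down_db: float = 0.5
    max_reversals: int = 12
    reversals_averaged: int = 8
    contrast_floor: float = 1e-3
    contrast_ceiling: float = 1.0
    swap_small_steps: bool = False

    def __post_init__(self) -> None:
        if self.rule_down < 1 or self.rule_up != 1:
            raise ValueError("rule_down must be >= 1 and rule_up must be 1")
        for name in ("initial_step_db", "step_up_db", "step_down_db"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reversals_averaged > self.max_reversals:
            raise ValueError("reversals_averaged cannot exceed max_reversals")
        if not (0 < self.contrast_floor < self.contrast_ceiling <= 1.0):
            raise ValueError("need 0 < contrast_floor < contrast_ceiling <= 1")

    @property
    def small_step_up_db(self) -> float:
        return self.step_down_db if self.swap_small_steps else self.step_up_db

    @property
    def small_step_down_db(self) -> float:
        return self.step_up_db if self.swap_small_steps else self.step_down_db


@dataclass
class StaircaseState:
    """Mutable state of one adaptive track."""

    config: StaircaseConfig
    contrast_db: float
    consecutive_correct: int = 0
    last_direction: str = "none"  # none | up | down
    reversal_levels_db: list = field(default_factory=list)
    trial_log: list = field(default_factory=list)  # (contrast, correct, reversal_flag)
    terminated: bool = False

    @property
    def contrast(self) -> float:
        return contrast_from_db(self.contrast_db)

    @property
    def n_trials(self) -> int:
        return len(self.trial_log)

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_levels_db)


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold_contrast: float
    threshold_db: float
    log_cs: float
    n_trials: int


def init_staircase(
    sf: float,
    config: Optional[StaircaseConfig] = None,
    initial_contrast: Optional[float] = None,
) -> StaircaseState:
    """Start a track at the spatial-frequency-appropriate contrast.

    ``sf`` must be one of the study frequencies unless ``initial_contrast``
    is given explicitly.
    """
    config = config or StaircaseConfig()
    if initial_contrast is None:
        if sf <= 0:
            raise ValueError(f"sf must be positive, got {sf}")
        try:
            initial_contrast = INITIAL_CONTRASTS[float(sf)]
        except KeyError:
            raise ValueError(
                f"no default initial contrast for sf={sf} cpd; "
                "pass initial_contrast explicitly"
            ) from None
    if not (config.contrast_floor < initial_contrast <= config.contrast_ceiling):
        raise ValueError(
            f"initial_contrast {initial_contrast} outside "
            f"({config.contrast_floor}, {config.contrast_ceiling}]"
        )
    return StaircaseState(config=config, contrast_db=db_from_contrast(initial_contrast))


def _move(state: StaircaseState, direction: str) -> None:
    """Apply one step in ``direction``, logging a reversal on a flip."""
    cfg = state.config
    reversal = state.last_direction not in ("none", direction)
    if reversal:
        # Reversal level = level at which the track changed direction,
        # i.e. the contrast of the trial that triggered the flip.
        state.reversal_levels_db.append(state.contrast_db)
        state.trial_log[-1] = state.trial_log[-1][:2] + (True,)
        if len(state.reversal_levels_db) >= cfg.max_reversals:
            state.terminated = True
            return
    # The large initial step is in force until the first reversal has been
    # logged; the move that produces that reversal still uses it.
    before = len(state.reversal_levels_db) - (1 if reversal else 0)
    if before == 0:
        step = cfg.initial_step_db
    else:
        step = cfg.small_step_up_db if direction == "up" else cfg.small_step_down_db
    new_db = state.contrast_db + (step if direction == "up" else -step)
    lo = db_from_contrast(cfg.contrast_floor)
    hi = db_from_contrast(cfg.contrast_ceiling)
    state.contrast_db = min(max(new_db, lo), hi)
    state.last_direction = direction


def update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the track by one trial response (mutates and returns ``state``).

    Raises if called on a terminated track.
    """
    if state.terminated:
        raise RuntimeError("staircase already terminated after "
                           f"{state.n_reversals} reversals")
    state.trial_log.append((state.contrast, bool(correct), False))
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= state.config.rule_down:
            state.consecutive_correct = 0
            _move(state, "down")
    else:
        state.consecutive_correct = 0
        _move(state, "up")
    return state


def estimate_threshold(state: StaircaseState) -> ThresholdEstimate:
    """Mean of the last ``reversals_averaged`` reversal levels, in dB."""
    if not state.terminated:
        raise RuntimeError("cannot estimate threshold before termination")
    tail = state.reversal_levels_db[-state.config.reversals_averaged:]
    threshold_db = sum(tail) / len(tail)
    contrast = contrast_from_db(threshold_db)
    return ThresholdEstimate(
        threshold_contrast=contrast,
        threshold_db=threshold_db,
        log_cs=-threshold_db / 20.0,
        n_trials=state.n_trials,
    )


def run_staircase(
    respond: Callable[[float], bool],
    state: StaircaseState,
    max_trials: int = 10_000,
) -> StaircaseState:
    """Drive a track to termination using ``respond(contrast) -> correct``.

    ``max_trials`` guards against a non-converging responder; hitting it
    raises rather than returning a silent partial run.
    """
    for _ in range(max_trials):
        if state.terminated:
            return state
        update(state, respond(state.contrast))
    if not state.terminated:
        raise RuntimeError(f"staircase did not terminate within {max_trials} trials")
    return state


def run_condition(
    observer,
    sf: float,
    orientation: str,
    rng,
    n_runs: int = 2,
    config: Optional[StaircaseConfig] = None,
    initial_contrast: Optional[float] = None,
) -> float:
    """Mean logCS over ``n_runs`` independent staircases for one condition.

    ``observer`` is anything accepted by
    :func:`meridian.cohort.simulate_response`.  Averaging is done in logCS.
    """
    from .cohort import simulate_response  # local import to avoid a cycle

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    log_cs_values = []
    for _ in range(n_runs):
        state = init_staircase(sf, config=config, initial_contrast=initial_contrast)
        run_staircase(
            lambda c: simulate_response(observer, sf, orientation, c, rng), state
        )
        log_cs_values.append(estimate_threshold(state).log_cs)
    return sum(log_cs_values) / len(log_cs_values)


def convergence_probability(config: Optional[StaircaseConfig] = None) -> float:
    """Asymptotic percent-correct tracked by the configured rule and steps.

    Zero-drift balance of an n-down-1-up walk with up step ``S_up`` and down
    step ``S_down`` gives ``p**n = S_up / (S_up + S_down)``; with equal steps
    this reduces to Wetherill's ``p = 0.5**(1/n)`` (~0.794 for n = 3).
    """
    config = config or StaircaseConfig()
    s_up = config.small_step_up_db
    s_down = config.small_step_down_db
    return (s_up / (s_up + s_down)) ** (1.0 / config.rule_down)


def wetherill_probability(rule_down: int = 3) -> float:
    """Equal-step fixed point of an n-down-1-up rule: p**n = 0.5."""
    return 0.5 ** (1.0 / rule_down)
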