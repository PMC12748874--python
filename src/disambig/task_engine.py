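"""Generative rules of the credit-assignment task.

A session consists of four blocks, one game each.  Every block runs through
three signalled phases: a Self-Other phase (16 trials, true control level
instructed), four Self-only trials (full control, feedback = own score) and
a Control-Other phase (16 trials, own level known, control and the new
other player unknown).  The single feedback score per trial is the
control-weighted sum of the two performances::

    feedback = self * control + other * (1 - control)

The other player's trial-wise score is drawn around a scheduled level
(SD 6.5) that changes unannounced on the 12th within-phase trial.  Objective
game errors map onto the 0-100 self-performance scale through a calibrated
logistic; errors beyond an extremity threshold count as active
disambiguation (AD) and force a self score of zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PHASE_SELF_OTHER",
    "PHASE_SELF_ONLY",
    "PHASE_CONTROL_OTHER",
    "PHASE_ORDER",
    "OTHER_CHANGE_TRIAL",
    "PhaseSpec",
    "BlockSpec",
    "Schedule",
    "ScheduleConfig",
    "MappingCalibration",
    "TRIAL_COLUMNS",
    "compute_feedback",
    "map_performance",
    "calibrate_mapping",
    "generate_schedule",
    "generate_schedule_variants",
    "draw_other_score",
    "validate_trial_table",
]

PHASE_SELF_OTHER = "self_other"
PHASE_SELF_ONLY = "self_only"
PHASE_CONTROL_OTHER = "control_other"
PHASE_ORDER = (PHASE_SELF_OTHER, PHASE_SELF_ONLY, PHASE_CONTROL_OTHER)

#: 1-based within-phase trial from which the other's level changes unannounced.
OTHER_CHANGE_TRIAL = 12

#: Canonical column order of a trial table (one row per trial).
TRIAL_COLUMNS = [
    "block",
    "phase_label",
    "trial_in_phase",
    "trial_in_block",
    "self_rating",
    "other_rating",
    "control_rating",
    "objective_error",
    "self_score",
    "other_score",
    "is_ad",
    "is_switch",
    "feedback",
    "true_self",
    "true_other_level",
    "true_control",
]


@dataclass(frozen=True)
class PhaseSpec:
    """One phase of a block.

    ``other_level_late`` replaces ``other_level_early`` from within-phase
    trial :data:`OTHER_CHANGE_TRIAL` onward.  Self-only phases have
    ``true_control = 1`` and their other levels are never used.
    """

    phase_label: str
    n_trials: int
    true_control: float
    other_level_early: float | None = None
    other_level_late: float | None = None
    other_sd: float = 6.5

    def __post_init__(self) -> None:
        if self.phase_label not in PHASE_ORDER:
            raise ValueError(f"unknown phase label {self.phase_label!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.true_control <= 1.0:
            raise ValueError("true_control must lie in [0, 1]")
        if self.phase_label == PHASE_SELF_ONLY and self.true_control != 1.0:
            raise ValueError("Self-only phases must have true_control = 1")
        if self.other_sd < 0:
            raise ValueError("other_sd must be >= 0")
        if self.phase_label != PHASE_SELF_ONLY:
            for lvl in (self.other_level_early, self.other_level_late):
                if lvl is None or not 0.0 <= lvl <= 100.0:
                    raise ValueError("other levels must lie in [0, 100]")

    def other_level(self, trial_in_phase: int) -> float:
        """True other level on a 1-based within-phase trial."""
        if self.phase_label == PHASE_SELF_ONLY:
            return float("nan")
        if trial_in_phase >= OTHER_CHANGE_TRIAL:
            return self.other_level_late
        return self.other_level_early


@dataclass(frozen=True)
class BlockSpec:
    game_id: str
    true_self: float
    phase_specs: tuple[PhaseSpec, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_self <= 100.0:
            raise ValueError("true_self must lie in [0, 100]")
        labels = tuple(p.phase_label for p in self.phase_specs)
        if labels != PHASE_ORDER:
            raise ValueError(f"phases must be ordered {PHASE_ORDER}, got {labels}")

    @property
    def n_trials(self) -> int:
        return sum(p.n_trials for p in self.phase_specs)


@dataclass(frozen=True)
class Schedule:
    """Pre-determined schedule of true self, other and control levels."""

    blocks: tuple[BlockSpec, ...]

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Schedule":
        raw = json.loads(text)
        blocks = tuple(
            BlockSpec(
                game_id=b["game_id"],
                true_self=b["true_self"],
                phase_specs=tuple(PhaseSpec(**p) for p in b["phase_specs"]),
            )
            for b in raw["blocks"]
        )
        return cls(blocks=blocks)


@dataclass(frozen=True)
class ScheduleConfig:
    """Configuration for :func:`generate_schedule`.

    When ``explicit_blocks`` is given it is passed through unchanged;
    otherwise levels are randomized within the stated ranges, subject to a
    minimum jump between the early and late other level so the unannounced
    change is detectable.
    """

    n_blocks: int = 4
    n_self_other: int = 16
    n_self_only: int = 4
    n_control_other: int = 16
    self_range: tuple[float, float] = (30.0, 80.0)
    other_range: tuple[float, float] = (20.0, 80.0)
    control_levels: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65, 0.8)
    min_other_jump: float = 15.0
    other_sd: float = 6.5
    explicit_blocks: tuple[BlockSpec, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.self_range[0] > self.self_range[1]:
            raise ValueError("self_range must be ordered")
        if self.other_range[0] > self.other_range[1]:
            raise ValueError("other_range must be ordered")
        span = self.other_range[1] - self.other_range[0]
        if self.min_other_jump > span:
            raise ValueError("min_other_jump exceeds the other-level range")
        if not all(0.0 <= c <= 1.0 for c in self.control_levels):
            raise ValueError("control_levels must lie in [0, 1]")


def compute_feedback(self_score: float, other_score: float, control: float) -> float:
    """Feedback as the control-weighted sum of self and other scores.

    ``feedback = self * control + other * (1 - control)``; with full
    control the feedback equals the self score exactly.
    """
    self_score = float(self_score)
    other_score = float(other_score)
    control = float(control)
    if not (math.isfinite(self_score) and math.isfinite(control)):
        raise ValueError("self_score and control must be finite")
    if not 0.0 <= self_score <= 100.0:
        raise ValueError(f"self_score {self_score} outside [0, 100]")
    if not 0.0 <= control <= 1.0:
        raise ValueError(f"control {control} outside [0, 1]")
    if control == 1.0:
        # Self-only identity; the other score may legitimately be undefined.
        return self_score
    if not (math.isfinite(other_score) and 0.0 <= other_score <= 100.0):
        raise ValueError(f"other_score {other_score} outside [0, 100]")
    return self_score * control + other_score * (1.0 - control)


@dataclass(frozen=True)
class MappingCalibration:
    """Calibrated logistic mapping from objective error to self score.

    Non-AD scores follow ``score(e) = amplitude * sigmoid(-slope * (e -
    midpoint))``; errors at or beyond ``ad_threshold`` count as AD and map
    to a score of zero.  ``amplitude`` is chosen by
    :func:`calibrate_mapping` so the expected non-AD score equals
    ``target_mean``, putting the mean on the schedule while preserving the
    trial-wise rank order of objective performance.
    """

    midpoint: float
    slope: float
    ad_threshold: float
    target_mean: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not np.isfinite(self.midpoint):
            raise ValueError("midpoint must be finite")
        if self.ad_threshold <= 0:
            raise ValueError("ad_threshold must be > 0")
        if not 0.0 < self.target_mean < 100.0:
            raise ValueError("target_mean must lie in (0, 100)")
        if not 0.0 < self.amplitude <= 100.0 / _sigmoid(self.slope * self.midpoint):
            raise ValueError("amplitude leaves the 0-100 score range")


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def map_performance(
    objective_error: float, calib: MappingCalibration
) -> tuple[float, bool]:
    """Map an objective game error onto the self-performance score scale.

    Returns ``(score, is_ad)``.  Errors at or beyond the AD threshold are
    detected as active disambiguation and yield a score of exactly zero;
    otherwise the calibrated logistic applies, strictly decreasing in the
    error.
    """
    objective_error = float(objective_error)
    if not math.isfinite(objective_error):
        raise ValueError("objective_error must be finite")
    if objective_error < 0:
        raise ValueError("objective_error must be >= 0")
    if objective_error >= calib.ad_threshold:
        return 0.0, True
    score = calib.amplitude * float(
        _sigmoid(-calib.slope * (objective_error - calib.midpoint))
    )
    return float(np.clip(score, 0.0, 100.0)), False


def _nonad_error_quadrature(error_sd: float, ad_threshold: float, n: int = 400):
    """Nodes and weights of the non-AD error distribution.

    Normal play errors are half-normal with scale ``error_sd``; conditioning
    on not triggering AD truncates them below ``ad_threshold``.
    """
    edges = np.linspace(0.0, ad_threshold, n + 1)
    nodes = 0.5 * (edges[:-1] + edges[1:])
    cdf = stats.halfnorm.cdf(edges, scale=error_sd)
    weights = np.diff(cdf)
    weights /= weights.sum()
    return nodes, weights


def calibrate_mapping(
    target_mean: float,
    error_sd: float,
    target_score_sd: float = 5.0,
    slope: float | None = None,
    ad_threshold_sds: float = 2.5,
) -> MappingCalibration:
    """Calibrate the logistic mapping for an agent's error distribution.

    The amplitude is pinned to the full score scale (100); the midpoint
    solves ``E[score(e) | e < ad_threshold] = target_mean`` so the mean
    non-AD score follows the scheduled self level, and (unless an explicit
    ``slope`` is given) the slope solves ``SD[score] = target_score_sd`` so
    trial-wise self scores vary by about the performance variability the
    observer models assume true (5 score units), while still preserving
    the rank order of objective performance.
    """
    if error_sd <= 0:
        raise ValueError("error_sd must be > 0")
    if not 0.0 < target_mean < 100.0:
        raise ValueError("target_mean must lie in (0, 100)")
    ad_threshold = ad_threshold_sds * error_sd
    nodes, weights = _nonad_error_quadrature(error_sd, ad_threshold)

    def solve_midpoint(s):
        span = 40.0 / s  # sigmoid saturates well within +-40 logits
        return float(optimize.brentq(
            lambda m: float(np.sum(weights * _sigmoid(-s * (nodes - m)))) * 100.0
            - target_mean,
            -span,
            ad_threshold + span,
        ))

    def score_sd(s):
        m = solve_midpoint(s)
        sc = 100.0 * _sigmoid(-s * (nodes - m))
        mu = float(np.sum(weights * sc))
        return float(np.sqrt(np.sum(weights * (sc - mu) ** 2)))

    if slope is None:
        if target_score_sd <= 0:
            raise ValueError("target_score_sd must be > 0")
        lo, hi = 1e-4, 2.0
        if not score_sd(lo) < target_score_sd < score_sd(hi):
            raise ValueError(
                f"target score SD {target_score_sd} outside the reachable range"
            )
        slope = float(optimize.brentq(lambda s: score_sd(s) - target_score_sd, lo, hi))
    midpoint = solve_midpoint(slope)
    return MappingCalibration(
        midpoint=midpoint,
        slope=slope,
        ad_threshold=ad_threshold,
        target_mean=target_mean,
        amplitude=100.0,
    )


def draw_other_score(level: float, sd: float, rng: np.random.Generator, size=None):
    """Draw the other player's trial score: Normal(level, sd) on [0, 100]."""
    if not 0.0 <= level <= 100.0:
        raise ValueError("level must lie in [0, 100]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return level if size is None else np.full(size, float(level))
    a, b = (0.0 - level) / sd, (100.0 - level) / sd
    draw = stats.truncnorm.rvs(a, b, loc=level, scale=sd, size=size, random_state=rng)
    return float(draw) if size is None else draw


def generate_schedule(
    config: ScheduleConfig | None = None, seed: int | None = None
) -> Schedule:
    """Build a schedule, randomizing levels where the config does not fix them.

    With the default config this yields 4 blocks of 16 Self-Other, 4
    Self-only and 16 Control-Other trials (144 in total), a constant true
    self level per block, and an unannounced other-level change of at least
    ``min_other_jump`` score units at the 12th within-phase trial.
    """
    config = config or ScheduleConfig()
    if config.explicit_blocks is not None:
        return Schedule(blocks=tuple(config.explicit_blocks))
    rng = np.random.default_rng(seed)

    # Self levels are stratified across blocks (one block per equal-width
    # stratum of self_range, in shuffled order) and paired-phase control
    # levels are sampled without replacement where possible: the schedule's
    # purpose is to decorrelate self, other and control across the session.
    lo, hi = config.self_range
    edges = np.linspace(lo, hi, config.n_blocks + 1)
    self_levels = rng.uniform(edges[:-1], edges[1:])
    rng.shuffle(self_levels)
    levels = np.asarray(config.control_levels, dtype=float)
    reps = int(np.ceil(config.n_blocks / levels.size))

    def _control_pool():
        pool = np.concatenate([rng.permutation(levels) for _ in range(reps)])
        return iter(pool[: config.n_blocks].tolist())

    control_iters = {PHASE_SELF_OTHER: _control_pool(),
                     PHASE_CONTROL_OTHER: _control_pool()}

    blocks = []
    for b in range(config.n_blocks):
        true_self = float(self_levels[b])
        phases = []
        for label, n in (
            (PHASE_SELF_OTHER, config.n_self_other),
            (PHASE_SELF_ONLY, config.n_self_only),
            (PHASE_CONTROL_OTHER, config.n_control_other),
        ):
            if label == PHASE_SELF_ONLY:
                phases.append(PhaseSpec(label, n, true_control=1.0))
            else:
                early, late = _rand_other_pair(rng, config)
                control = float(next(control_iters[label]))
                phases.append(
                    PhaseSpec(
                        label,
                        n,
                        true_control=control,
                        other_level_early=early,
                        other_level_late=late,
                        other_sd=config.other_sd,
                    )
                )
        blocks.append(
            BlockSpec(game_id=f"game{b + 1}", true_self=true_self, phase_specs=tuple(phases))
        )
    return Schedule(blocks=tuple(blocks))


def generate_schedule_variants(
    n_variants: int = 4,
    config: ScheduleConfig | None = None,
    seed: int | None = None,
) -> list[Schedule]:
    """Counterbalanced schedule variants for a cohort.

    Self levels are stratified across blocks as in :func:`generate_schedule`;
    the paired-phase control levels are assigned by cyclic rotation over the
    variant set (a latin-square layout), so that across variants every self
    stratum co-occurs with every control level and self, other and control
    are decorrelated by design.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    config = config or ScheduleConfig()
    rng = np.random.default_rng(seed)
    levels = np.asarray(config.control_levels, dtype=float)
    # one control level per block, evenly spread over the available set
    pick = np.unique(
        np.round(np.linspace(0, levels.size - 1, config.n_blocks)).astype(int)
    )
    base = levels[pick]
    if base.size < config.n_blocks:
        base = np.resize(base, config.n_blocks)
    lo, hi = config.self_range
    edges = np.linspace(lo, hi, config.n_blocks + 1)

    variants = []
    for k in range(n_variants):
        self_levels = rng.uniform(edges[:-1], edges[1:])
        order = rng.permutation(config.n_blocks)
        blocks = []
        for b in range(config.n_blocks):
            stratum = int(order[b])
            true_self = float(self_levels[stratum])
            so_control = float(base[(stratum + k) % config.n_blocks])
            co_control = float(base[(stratum + k + 1) % config.n_blocks])
            phases = []
            for label, n, control in (
                (PHASE_SELF_OTHER, config.n_self_other, so_control),
                (PHASE_SELF_ONLY, config.n_self_only, 1.0),
                (PHASE_CONTROL_OTHER, config.n_control_other, co_control),
            ):
                if label == PHASE_SELF_ONLY:
                    phases.append(PhaseSpec(label, n, true_control=1.0))
                    continue
                early, late = _rand_other_pair(rng, config)
                phases.append(
                    PhaseSpec(
                        label,
                        n,
                        true_control=control,
                        other_level_early=early,
                        other_level_late=late,
                        other_sd=config.other_sd,
                    )
                )
            blocks.append(
                BlockSpec(
                    game_id=f"game{b + 1}", true_self=true_self, phase_specs=tuple(phases)
                )
            )
        variants.append(Schedule(blocks=tuple(blocks)))
    return variants


def _rand_other_pair(rng, config: ScheduleConfig) -> tuple[float, float]:
    lo, hi = config.other_range
    for _ in range(1000):
        early, late = rng.uniform(lo, hi, size=2)
        if abs(late - early) >= config.min_other_jump:
            return float(early), float(late)
    raise RuntimeError("could not satisfy min_other_jump")


def validate_trial_table(table, atol: float = 1e-6) -> None:
    """Check every trial-table invariant; raise ``ValueError`` on violation.

    Checks: column presence, rating/score scales, ``self_score = 0`` on AD
    trials, the feedback identity, and ``feedback = self_score`` on
    Self-only trials.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    t = table
    if not t["self_rating"].between(0, 100).all():
        raise ValueError("self_rating outside [0, 100]")
    other_rated = t["other_rating"].dropna()
    if not other_rated.between(0, 100).all():
        raise ValueError("other_rating outside [0, 100]")
    control_rated = t["control_rating"].dropna()
    if not control_rated.between(0, 1).all():
        raise ValueError("control_rating outside [0, 1]")
    if (t.loc[t["is_ad"], "self_score"] != 0).any():
        raise ValueError("AD trial with nonzero self_score")
    if (t["objective_error"] < 0).any():
        raise ValueError("negative objective_error")
    self_only = t["phase_label"] == PHASE_SELF_ONLY
    if not np.allclose(
        t.loc[self_only, "feedback"], t.loc[self_only, "self_score"], atol=atol
    ):
        raise ValueError("Self-only feedback must equal self_score")
    paired = t.loc[~self_only]
    expected = paired["self_score"] * paired["true_control"] + paired[
        "other_score"
    ] * (1.0 - paired["true_control"])
    if not np.allclose(paired["feedback"], expected, atol=atol):
        raise ValueError("feedback violates the weighting equation")


def default_schedule(seed: int = 0) -> Schedule:
    """Convenience wrapper: the default randomized schedule for a seed."""
    return generate_schedule(ScheduleConfig(), seed=seed)
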