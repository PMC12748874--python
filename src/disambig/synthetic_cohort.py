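"""Agent-based simulation of participants performing the task.

Each simulated participant carries an Active-learner belief state (see
:mod:`disambig.belief_models`) through every phase and reads its posterior
means out as ratings, with truncated Gaussian read-out noise.  Active
disambiguation (AD) is a stochastic policy whose probability increases
with the current belief uncertainty and is strongly suppressed on
Self-only trials, where feedback reflects the agent alone and AD carries
no information.  Objective game errors are half-Normal; extreme errors
(deliberate or accidental) trip the AD detector and zero the self score.

The cohort layer draws heterogeneous agent parameters, simulates ``n``
independent participants from per-participant child seeds of one master
seed, and records a debrief-style self-report of AD usage (true per-game
AD count plus rounded Gaussian noise).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from disambig.belief_models import (
    VARIANT_ACTIVE,
    VARIANTS,
    GridLearner,
    GridSettings,
    PriorSpec,
)
from disambig.task_engine import (
    PHASE_CONTROL_OTHER,
    PHASE_SELF_ONLY,
    PHASE_SELF_OTHER,
    TRIAL_COLUMNS,
    Schedule,
    calibrate_mapping,
    compute_feedback,
    draw_other_score,
    generate_schedule_variants,
    map_performance,
)

__all__ = [
    "AgentParams",
    "CohortManifest",
    "simulate_participant",
    "simulate_cohort",
    "default_params_prior",
    "refit_learners",
    "as_model_table",
]


@dataclass(frozen=True)
class AgentParams:
    """Behavioural policy parameters of one simulated participant.

    ``ad_base_rate`` and ``ad_uncertainty_gain`` set the AD policy
    ``P(AD) = clip(base + gain * uncertainty/100, 0, 1)``, multiplied by
    ``self_only_ad_factor`` on Self-only trials.  ``error_sd`` scales the
    half-Normal objective-error distribution (arbitrary game units);
    ``debrief_noise_sd`` corrupts the reported per-game AD count.
    """

    rating_noise_sd: float = 5.0
    control_rating_noise_sd: float = 0.05
    ad_base_rate: float = 0.08
    ad_uncertainty_gain: float = 0.40
    error_sd: float = 30.0
    debrief_noise_sd: float = 1.5
    self_only_ad_factor: float = 0.1
    prior_rating_sd: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "rating_noise_sd",
            "control_rating_noise_sd",
            "debrief_noise_sd",
            "prior_rating_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ad_base_rate <= 1.0:
            raise ValueError("ad_base_rate must lie in [0, 1]")
        if self.error_sd <= 0:
            raise ValueError("error_sd must be > 0")


@dataclass
class CohortManifest:
    n_participants: int
    seed: int
    params: list[AgentParams]
    reported_ad_count: list[float]
    #: counterbalanced schedule variants; participant i runs variant i mod k
    schedules: list[Schedule]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_participants": self.n_participants,
                "seed": self.seed,
                "params": [asdict(p) for p in self.params],
                "reported_ad_count": self.reported_ad_count,
                "schedules": [json.loads(s.to_json()) for s in self.schedules],
            },
            indent=2,
        )


def _noisy(rng, value, sd, lo, hi):
    """Truncated Gaussian read-out noise around a value."""
    if sd == 0:
        return float(np.clip(value, lo, hi))
    for _ in range(100):
        draw = rng.normal(value, sd)
        if lo <= draw <= hi:
            return float(draw)
    return float(np.clip(value, lo, hi))


def simulate_participant(
    schedule: Schedule,
    params: AgentParams,
    seed,
    settings: GridSettings | None = None,
    return_beliefs: bool = False,
):
    """Simulate one participant; returns a trial table (and belief fits).

    The agent rates the posterior means of its Active-learner belief state
    (first-trial ratings are noisy gut-feeling priors that also seed the
    learner), decides on AD from the current uncertainty, plays (drawing an
    objective error), observes the feedback and updates its beliefs.
    """
    settings = settings or GridSettings()
    rng = np.random.default_rng(seed)
    rows = []
    beliefs: dict = {}

    for block_idx, block in enumerate(schedule.blocks, start=1):
        calib = calibrate_mapping(block.true_self, params.error_sd)
        trial_in_block = 0
        learned_self = None  # posterior mean carried between phases
        for phase in block.phase_specs:
            label = phase.phase_label
            # --- gut-feeling first-trial ratings seed the learner's prior
            if label == PHASE_SELF_OTHER:
                self0 = _noisy(rng, 50.0, params.prior_rating_sd, 0, 100)
                other0 = _noisy(rng, 50.0, params.prior_rating_sd, 0, 100)
                prior = PriorSpec(
                    self_mean=self0, other_mean=other0, control_mean=phase.true_control
                )
                clamped = {"control": phase.true_control}
            elif label == PHASE_SELF_ONLY:
                center = learned_self if learned_self is not None else 50.0
                self0 = _noisy(rng, center, params.rating_noise_sd, 0, 100)
                prior = PriorSpec(self_mean=self0)
                clamped = {}
            else:  # Control-Other: self level known, control and other reset
                other0 = _noisy(rng, 50.0, params.prior_rating_sd, 0, 100)
                control0 = _noisy(rng, 0.5, 0.15, 0, 1)
                prior = PriorSpec(other_mean=other0, control_mean=control0)
                clamped = {"self": block.true_self}
            learner = GridLearner(
                label, prior, variant=VARIANT_ACTIVE, clamped=clamped, settings=settings
            )

            for i in range(1, phase.n_trials + 1):
                trial_in_block += 1
                state = learner.history[-1]  # belief before this trial's feedback
                # --- ratings
                if label == PHASE_SELF_OTHER:
                    self_rating = (
                        self0 if i == 1
                        else _noisy(rng, state["self_mean"], params.rating_noise_sd, 0, 100)
                    )
                    other_rating = (
                        other0 if i == 1
                        else _noisy(rng, state["other_mean"], params.rating_noise_sd, 0, 100)
                    )
                    control_rating = phase.true_control  # instructed slider
                elif label == PHASE_SELF_ONLY:
                    self_rating = (
                        self0 if i == 1
                        else _noisy(rng, state["self_mean"], params.rating_noise_sd, 0, 100)
                    )
                    other_rating = np.nan
                    control_rating = np.nan
                else:
                    self_rating = _noisy(
                        rng, block.true_self, params.rating_noise_sd, 0, 100
                    )
                    other_rating = (
                        other0 if i == 1
                        else _noisy(rng, state["other_mean"], params.rating_noise_sd, 0, 100)
                    )
                    control_rating = (
                        control0 if i == 1
                        else _noisy(
                            rng,
                            state["control_mean"],
                            params.control_rating_noise_sd,
                            0,
                            1,
                        )
                    )
                # --- AD policy
                p_ad = np.clip(
                    params.ad_base_rate
                    + params.ad_uncertainty_gain * state["uncertainty"] / 100.0,
                    0.0,
                    1.0,
                )
                if label == PHASE_SELF_ONLY:
                    p_ad *= params.self_only_ad_factor
                deliberate = rng.random() < p_ad
                if deliberate:
                    err = calib.ad_threshold + abs(rng.normal(0.0, params.error_sd))
                else:
                    err = abs(rng.normal(0.0, params.error_sd))
                self_score, is_ad = map_performance(err, calib)
                # --- outcome
                if label == PHASE_SELF_ONLY:
                    other_score = np.nan
                    true_other = np.nan
                    feedback = compute_feedback(self_score, np.nan, 1.0)
                else:
                    true_other = phase.other_level(i)
                    other_score = draw_other_score(true_other, phase.other_sd, rng)
                    feedback = compute_feedback(
                        self_score, other_score, phase.true_control
                    )
                try:
                    learner.update(feedback, is_ad)
                except Exception as exc:
                    raise RuntimeError(
                        f"belief update failed (block {block_idx}, {label}, "
                        f"trial {i}): {exc}"
                    ) from exc
                rows.append(
                    {
                        "block": block_idx,
                        "phase_label": label,
                        "trial_in_phase": i,
                        "trial_in_block": trial_in_block,
                        "self_rating": self_rating,
                        "other_rating": other_rating,
                        "control_rating": control_rating,
                        "objective_error": err,
                        "self_score": self_score,
                        "other_score": other_score,
                        "is_ad": is_ad,
                        "is_switch": False,  # filled below
                        "feedback": feedback,
                        "true_self": block.true_self,
                        "true_other_level": true_other,
                        "true_control": phase.true_control,
                        # agent's belief uncertainty going into this trial
                        "uncertainty": state["uncertainty"],
                        "p_ad": float(p_ad),
                    }
                )
            learned_self = learner.history[-1]["self_mean"]
            if return_beliefs:
                beliefs[(block_idx, label)] = pd.DataFrame(learner.history)

    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS + ["uncertainty", "p_ad"])
    grp = table.groupby(["block", "phase_label"], sort=False)["is_ad"]
    table["is_switch"] = (grp.shift(1).notna()) & (grp.shift(1) != table["is_ad"])
    if return_beliefs:
        return table, beliefs
    return table


def default_params_prior(rng: np.random.Generator) -> AgentParams:
    """Moderately heterogeneous agent parameters for cohort simulation."""
    return AgentParams(
        rating_noise_sd=float(rng.uniform(3.0, 8.0)),
        control_rating_noise_sd=float(rng.uniform(0.03, 0.08)),
        ad_base_rate=float(np.clip(rng.normal(0.08, 0.03), 0.0, 0.3)),
        ad_uncertainty_gain=float(np.clip(rng.normal(0.40, 0.10), 0.05, 1.0)),
        error_sd=float(rng.uniform(20.0, 40.0)),
        debrief_noise_sd=1.5,
    )


def simulate_cohort(
    n: int,
    schedule: Schedule | None = None,
    params_prior=None,
    seed: int | None = None,
    settings: GridSettings | None = None,
    n_schedule_variants: int = 4,
):
    """Simulate ``n`` independent participants on counterbalanced schedules.

    As in the study design, a handful of schedule variants is rotated
    across the cohort (participant ``i`` runs variant ``i mod k``) so that
    the level combinations are not confounded with a single draw; pass an
    explicit ``schedule`` to put everyone on the same one.  Returns
    ``(manifest, tables)`` where ``tables`` maps participant ids (``p01``
    ...) to trial tables.  Per-participant randomness comes from child
    seeds spawned from the master seed, so any cohort is reproducible from
    ``seed`` alone.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params_prior = params_prior or default_params_prior
    master = np.random.SeedSequence(seed if seed is not None else 0)
    param_seed, *child_seeds = master.spawn(n + 1)
    param_rng = np.random.default_rng(param_seed)
    if schedule is not None:
        schedules = [schedule]
    else:
        base = int(master.generate_state(1)[0] % 2**31)
        schedules = generate_schedule_variants(
            n_variants=max(1, n_schedule_variants), seed=base
        )

    tables: dict[str, pd.DataFrame] = {}
    all_params: list[AgentParams] = []
    reported: list[float] = []
    for i, child in enumerate(child_seeds, start=1):
        params = params_prior(param_rng)
        all_params.append(params)
        pid = f"p{i:02d}"
        sched = schedules[(i - 1) % len(schedules)]
        table = simulate_participant(sched, params, child, settings=settings)
        tables[pid] = table
        per_game_ad = table["is_ad"].sum() / len(sched.blocks)
        # true per-game count plus rounded report noise, floored at zero
        noise = round(param_rng.normal(0.0, params.debrief_noise_sd))
        reported.append(float(max(0.0, per_game_ad + noise)))
    manifest = CohortManifest(
        n_participants=n,
        seed=int(seed if seed is not None else 0),
        params=all_params,
        reported_ad_count=reported,
        schedules=schedules,
    )
    return manifest, tables


def refit_learners(
    table: pd.DataFrame,
    variants=VARIANTS,
    phases=(PHASE_CONTROL_OTHER,),
    settings: GridSettings | None = None,
) -> pd.DataFrame:
    """Refit observer models to a recorded trial table.

    All variants see the identical feedback / AD sequence the participant
    observed, with priors seeded from the recorded first-trial ratings.
    Returned estimates are rating-aligned: the row for trial ``t`` holds
    the posterior after trials ``1..t-1``, i.e. the belief held when rating
    at the start of trial ``t``.
    """
    settings = settings or GridSettings()
    out = []
    for (block, label), grp in table.groupby(["block", "phase_label"], sort=False):
        if label not in phases:
            continue
        grp = grp.sort_values("trial_in_phase")
        first = grp.iloc[0]
        if label == PHASE_SELF_OTHER:
            prior = PriorSpec(
                self_mean=first["self_rating"],
                other_mean=first["other_rating"],
                control_mean=first["true_control"],
            )
            clamped = {"control": float(first["true_control"])}
        elif label == PHASE_CONTROL_OTHER:
            prior = PriorSpec(
                other_mean=first["other_rating"], control_mean=first["control_rating"]
            )
            clamped = {"self": float(first["true_self"])}
        else:
            prior = PriorSpec(self_mean=first["self_rating"])
            clamped = {}
        for variant in variants:
            learner = GridLearner(
                label, prior, variant=variant, clamped=clamped, settings=settings
            )
            history = [learner.history[0]]
            for fb, ad in zip(grp["feedback"], grp["is_ad"]):
                history.append(learner.update(float(fb), bool(ad)))
            for t, row in zip(grp["trial_in_phase"], history[:-1]):
                out.append(
                    {
                        "block": block,
                        "phase_label": label,
                        "trial_in_phase": int(t),
                        "variant": variant,
                        "self_est": row["self_mean"],
                        "other_est": row["other_mean"],
                        "control_est": row["control_mean"],
                        "uncertainty": row["uncertainty"],
                        "prior_only": row["prior_only"],
                    }
                )
    return pd.DataFrame(out)


def as_model_table(
    table: pd.DataFrame, estimates: pd.DataFrame, variant: str
) -> pd.DataFrame:
    """Trial table with ratings replaced by a learner's belief estimates.

    Wherever the given variant has estimates for a phase, the self, other
    and control ratings (and the uncertainty column) are substituted with
    the rating-aligned posterior means, leaving everything else (feedback,
    AD flags, schedule truth) untouched.  The result feeds the same
    behavioural pipeline as participant tables, which is how the observer
    models are compared against behaviour.
    """
    e = estimates.loc[estimates["variant"] == variant]
    m = table.merge(
        e[
            [
                "block",
                "phase_label",
                "trial_in_phase",
                "self_est",
                "other_est",
                "control_est",
                "uncertainty",
            ]
        ].rename(columns={"uncertainty": "model_uncertainty"}),
        on=["block", "phase_label", "trial_in_phase"],
        how="left",
    )
    has = m["control_est"].notna() | m["self_est"].notna()
    so = m["phase_label"] == PHASE_SELF_OTHER
    co = m["phase_label"] == PHASE_CONTROL_OTHER
    m.loc[has & (so | (m["phase_label"] == PHASE_SELF_ONLY)), "self_rating"] = m[
        "self_est"
    ]
    m.loc[has & co, "self_rating"] = m.loc[has & co, "true_self"]
    m.loc[has & (so | co), "other_rating"] = m["other_est"]
    m.loc[has & co, "control_rating"] = m["control_est"]
    if "uncertainty" in m.columns:
        m.loc[m["model_uncertainty"].notna(), "uncertainty"] = m["model_uncertainty"]
    else:
        m["uncertainty"] = m["model_uncertainty"]
    m["self_rating"] = m["self_rating"].clip(0, 100)
    m["other_rating"] = m["other_rating"].clip(0, 100)
    m["control_rating"] = m["control_rating"].clip(0, 1)
    return m.drop(columns=["self_est", "other_est", "control_est", "model_uncertainty"])
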