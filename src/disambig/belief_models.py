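"""Sequential Bayesian observer models of the credit-assignment task.

Three observers share one update rule and differ only in how they treat
active-disambiguation (AD) trials:

* **Active learner** — knows when AD occurred and models its feedback
  correctly (self contribution removed).
* **Ignorant learner** — treats every trial, AD included, as a normal trial.
* **Passive learner** — knows when AD occurred but discards those trials.

On a normal trial the feedback is modelled as Normal with mean
``self*control + other*(1-control)`` and SD
``sqrt(sigma_self^2*control^2 + sigma_other^2*(1-control)^2)``; on an AD
trial the self term drops out.  Priors are Normal, centred on the
first-trial ratings (SD 30 for performances, 0.3 for control) with
half-Normal(5) priors on the performance variabilities.  All estimates live
on bounded supports (0-100 for performances, 0-1 for control).

The default inference backend is a deterministic dense-grid filter: the
joint posterior over the free parameters is tracked on a fixed lattice and
updated trial by trial, which reproduces the repeated refit to trials
``1..t`` exactly (the posterior after ``t`` trials is the prior times the
product of the first ``t`` likelihoods).  From the 12th within-phase trial
the other player is re-estimated as a new player: the other dimension is
re-initialised with a fresh prior centred on the most recent posterior
mean (SD reset to 30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from disambig.task_engine import (
    OTHER_CHANGE_TRIAL,
    PHASE_CONTROL_OTHER,
    PHASE_SELF_ONLY,
    PHASE_SELF_OTHER,
)

__all__ = [
    "VARIANTS",
    "PriorSpec",
    "GridSettings",
    "GridLearner",
    "fit_learner",
    "credible_interval_width",
    "compute_uncertainty",
]

VARIANT_ACTIVE = "active"
VARIANT_IGNORANT = "ignorant"
VARIANT_PASSIVE = "passive"
VARIANTS = (VARIANT_ACTIVE, VARIANT_IGNORANT, VARIANT_PASSIVE)

PARAMS = ("self", "other", "control", "sigma_self", "sigma_other")


@dataclass(frozen=True)
class PriorSpec:
    """Priors before the first feedback of a phase.

    Means come from the first-trial ratings; the SDs are fixed task
    constants (30 score units for performances, 0.3 for control).
    ``sigma_scale`` is the scale of the half-Normal priors on the
    performance variabilities.
    """

    self_mean: float = 50.0
    other_mean: float = 50.0
    control_mean: float = 0.5
    self_sd: float = 30.0
    other_sd: float = 30.0
    control_sd: float = 0.3
    sigma_scale: float = 5.0
    #: SD of the re-initialised other prior from the unannounced change.
    new_other_sd: float = 30.0

    def __post_init__(self) -> None:
        for name in ("self_sd", "other_sd", "control_sd", "sigma_scale", "new_other_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class GridSettings:
    """Lattice resolution of the grid inference backend."""

    n_perf: int = 101
    n_control: int = 41
    n_sigma: int = 16
    sigma_lo: float = 0.25
    sigma_hi: float = 15.0
    ci_level: float = 0.90
    #: Feedback display granularity (score units), added in quadrature to the
    #: modelled SD.  Keeps the likelihood bounded where the modelled feedback
    #: becomes deterministic (sigma -> 0, or control -> 1 on AD trials).
    obs_sd_floor: float = 1.0

    def perf_axis(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_perf)

    def control_axis(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_control)

    def sigma_axis(self) -> np.ndarray:
        return np.linspace(self.sigma_lo, self.sigma_hi, self.n_sigma)


def credible_interval_width(posterior, level: float = 0.9) -> float:
    """Width of the central credible interval of a posterior.

    ``posterior`` may be a frozen scipy distribution (closed-form
    quantiles), a 1-D array of samples, or a ``(values, weights)`` pair
    describing a grid marginal.  A degenerate posterior yields 0 with a
    warning.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    lo_q, hi_q = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    if hasattr(posterior, "ppf"):
        width = float(posterior.ppf(hi_q) - posterior.ppf(lo_q))
    elif isinstance(posterior, tuple):
        values, weights = posterior
        lo, hi = _weighted_quantiles(np.asarray(values, float),
                                     np.asarray(weights, float), (lo_q, hi_q))
        width = float(hi - lo)
    else:
        samples = np.asarray(posterior, dtype=float)
        width = float(np.quantile(samples, hi_q) - np.quantile(samples, lo_q))
    if width <= 0.0:
        warnings.warn("degenerate posterior: credible interval width 0")
        return 0.0
    return width


def _weighted_quantiles(values, weights, qs):
    w = weights / weights.sum()
    cdf = np.cumsum(w) - 0.5 * w  # mass centred on each lattice point
    return np.interp(qs, cdf, values)


def compute_uncertainty(ci_widths: dict, phase_label: str) -> float:
    """Trial-wise uncertainty: phase-dependent average of 90% CI widths.

    Self-Other: mean of the self and other widths.  Control-Other: mean of
    the other width and the control width rescaled onto the 0-100 scale.
    Self-only trials carry only a self belief, so its width is used alone.
    """

    def _get(name):
        v = ci_widths.get(name)
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing CI width for {name!r} in {phase_label}")
        return float(v)

    if phase_label == PHASE_SELF_OTHER:
        return (_get("self") + _get("other")) / 2.0
    if phase_label == PHASE_CONTROL_OTHER:
        return (100.0 * _get("control") + _get("other")) / 2.0
    if phase_label == PHASE_SELF_ONLY:
        return _get("self")
    raise ValueError(f"unknown phase label {phase_label!r}")


class GridLearner:
    """Sequential grid-filter posterior for one phase and one observer type.

    Free parameters depend on the phase context: in Self-Other the control
    level is clamped to the instructed value and (self, other, sigma_self,
    sigma_other) are inferred; in Control-Other the true self level is
    clamped (with sigma_self = 5) and (other, control, sigma_other) are
    inferred; on Self-only trials only (self, sigma_self) remain.
    """

    def __init__(
        self,
        phase_label: str,
        prior: PriorSpec,
        variant: str = VARIANT_ACTIVE,
        clamped: dict | None = None,
        settings: GridSettings | None = None,
        new_other_trial: int | None = OTHER_CHANGE_TRIAL,
    ) -> None:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        self.phase_label = phase_label
        self.variant = variant
        self.prior = prior
        self.settings = settings or GridSettings()
        self.clamped = dict(clamped or {})
        self.new_other_trial = new_other_trial
        self.t = 0
        self.n_used = 0  # trials that actually entered the likelihood
        s = self.settings

        if phase_label == PHASE_SELF_OTHER:
            if "control" not in self.clamped:
                raise ValueError("Self-Other context requires clamped control")
            self.axes = {
                "self": s.perf_axis(),
                "other": s.perf_axis(),
                "sigma_self": s.sigma_axis(),
                "sigma_other": s.sigma_axis(),
            }
        elif phase_label == PHASE_CONTROL_OTHER:
            if "self" not in self.clamped:
                raise ValueError("Control-Other context requires clamped self")
            self.clamped.setdefault("sigma_self", 5.0)
            self.axes = {
                "other": s.perf_axis(),
                "control": s.control_axis(),
                "sigma_other": s.sigma_axis(),
            }
        elif phase_label == PHASE_SELF_ONLY:
            self.clamped.setdefault("control", 1.0)
            self.axes = {"self": s.perf_axis(), "sigma_self": s.sigma_axis()}
        else:
            raise ValueError(f"unknown phase label {phase_label!r}")

        self.names = list(self.axes)
        self.logp = self._log_prior()
        self._history: list[dict] = [self._summarize()]

    # ----- prior construction -------------------------------------------------

    def _axis_log_prior(self, name: str) -> np.ndarray:
        x = self.axes[name]
        p = self.prior
        if name == "self":
            return stats.norm.logpdf(x, p.self_mean, p.self_sd)
        if name == "other":
            return stats.norm.logpdf(x, p.other_mean, p.other_sd)
        if name == "control":
            return stats.norm.logpdf(x, p.control_mean, p.control_sd)
        # half-Normal scale priors for the performance variabilities
        return stats.halfnorm.logpdf(x, scale=p.sigma_scale)

    def _log_prior(self) -> np.ndarray:
        lp = np.zeros([len(a) for a in self.axes.values()])
        for i, name in enumerate(self.names):
            shape = [1] * lp.ndim
            shape[i] = -1
            lp = lp + self._axis_log_prior(name).reshape(shape)
        return lp - lp.max()

    # ----- likelihood ---------------------------------------------------------

    def _broadcast(self, name: str) -> np.ndarray:
        """Axis values broadcast to the grid shape, or the clamped scalar."""
        if name in self.names:
            i = self.names.index(name)
            shape = [1] * len(self.names)
            shape[i] = -1
            return self.axes[name].reshape(shape)
        return np.asarray(self.clamped[name], dtype=float)

    def _log_likelihood(self, feedback: float, ad_model: bool) -> np.ndarray:
        other = self._broadcast("other") if self.phase_label != PHASE_SELF_ONLY else 0.0
        control = self._broadcast("control")
        sigma_other = (
            self._broadcast("sigma_other")
            if self.phase_label != PHASE_SELF_ONLY
            else 0.0
        )
        floor = self.settings.obs_sd_floor ** 2
        if ad_model:
            mean = other * (1.0 - control)
            sd = np.sqrt((sigma_other * (1.0 - control)) ** 2 + floor)
        else:
            self_ = self._broadcast("self")
            sigma_self = self._broadcast("sigma_self")
            mean = self_ * control + other * (1.0 - control)
            sd = np.sqrt(
                (sigma_self * control) ** 2
                + (sigma_other * (1.0 - control)) ** 2
                + floor
            )
        z = (feedback - mean) / sd
        return -np.log(sd) - 0.5 * z * z

    # ----- sequential update --------------------------------------------------

    def _reset_other(self) -> None:
        """Re-initialise the other-player dimension as a new player."""
        if "other" not in self.names:
            return
        i = self.names.index("other")
        current_mean = self._history[-1]["other_mean"]
        p = np.exp(self.logp - self.logp.max())
        marg = p.sum(axis=i, keepdims=True)
        with np.errstate(divide="ignore"):
            lp = np.log(marg)
        shape = [1] * len(self.names)
        shape[i] = -1
        lp = lp + stats.norm.logpdf(
            self.axes["other"], current_mean, self.prior.new_other_sd
        ).reshape(shape)
        self.logp = lp - lp.max()

    def update(self, feedback: float, is_ad: bool) -> dict:
        """Incorporate one trial's feedback and return the posterior summary."""
        self.t += 1
        if self.new_other_trial is not None and self.t == self.new_other_trial:
            self._reset_other()

        skip = False
        ad_model = False
        if is_ad:
            if self.variant == VARIANT_PASSIVE:
                skip = True
            elif self.variant == VARIANT_ACTIVE:
                ad_model = True
            # the Ignorant learner models AD feedback as a normal trial
        if self.phase_label == PHASE_SELF_ONLY and is_ad and not skip:
            # With full control an AD trial yields feedback 0 deterministically
            # and carries no information about the self level.
            skip = True

        if not skip:
            if not np.isfinite(feedback):
                raise ValueError(f"non-finite feedback at trial {self.t}")
            self.logp = self.logp + self._log_likelihood(float(feedback), ad_model)
            self.logp -= self.logp.max()
            self.n_used += 1
        summary = self._summarize()
        self._history.append(summary)
        return summary

    # ----- summaries ----------------------------------------------------------

    def _summarize(self) -> dict:
        p = np.exp(self.logp - self.logp.max())
        p /= p.sum()
        out: dict = {"t": self.t, "prior_only": self.n_used == 0}
        widths: dict = {}
        for name in PARAMS:
            if name in self.names:
                i = self.names.index(name)
                w = np.apply_over_axes(
                    np.sum, p, [j for j in range(p.ndim) if j != i]
                ).ravel()
                x = self.axes[name]
                mean = float(np.sum(w * x))
                sd = float(np.sqrt(max(np.sum(w * (x - mean) ** 2), 0.0)))
                lo_q = (1.0 - self.settings.ci_level) / 2.0
                lo, hi = _weighted_quantiles(x, w, (lo_q, 1.0 - lo_q))
            elif name in self.clamped:
                mean = float(self.clamped[name])
                sd = 0.0
                lo = hi = mean
            else:
                mean = sd = lo = hi = float("nan")
            out[f"{name}_mean"] = mean
            out[f"{name}_sd"] = sd
            out[f"{name}_ci_lo"] = float(lo)
            out[f"{name}_ci_hi"] = float(hi)
            widths[name] = float(hi - lo) if np.isfinite(hi) else float("nan")
        out["uncertainty"] = compute_uncertainty(widths, self.phase_label)
        return out

    @property
    def history(self) -> list[dict]:
        """Posterior summaries after 0, 1, ..., t trials."""
        return list(self._history)


def fit_learner(
    feedback,
    is_ad,
    variant: str,
    phase_label: str,
    prior: PriorSpec,
    clamped: dict | None = None,
    settings: GridSettings | None = None,
    new_other_trial: int | None = OTHER_CHANGE_TRIAL,
) -> pd.DataFrame:
    """Fit one observer to a phase's feedback sequence.

    Returns a frame with one row per number of observed trials (row ``t=0``
    is the prior), holding posterior means, SDs and 90% credible bounds for
    every parameter plus the trial-wise uncertainty.  The sequential filter
    makes the repeated refit to trials ``1..t`` exact under the grid
    approximation.  A Passive learner that has seen only AD trials so far
    reports its prior with ``prior_only=True``.
    """
    feedback = np.asarray(feedback, dtype=float)
    is_ad = np.asarray(is_ad, dtype=bool)
    if feedback.shape != is_ad.shape:
        raise ValueError("feedback and is_ad must have equal length")
    if feedback.size < 1:
        raise ValueError("need at least one trial")
    learner = GridLearner(
        phase_label,
        prior,
        variant=variant,
        clamped=clamped,
        settings=settings,
        new_other_trial=new_other_trial,
    )
    for t, (fb, ad) in enumerate(zip(feedback, is_ad), start=1):
        try:
            learner.update(fb, ad)
        except Exception as exc:  # attach the trial index for diagnosis
            raise RuntimeError(f"belief update failed at trial {t}: {exc}") from exc
    out = pd.DataFrame(learner.history)
    out["variant"] = variant
    out["phase_label"] = phase_label
    return out
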