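"""ROI time-course GLM machinery.

Works on an already-extracted ROI time series (one value per volume, TR
1.36 s by default).  The series is z-scored, upsampled twenty-fold with
cubic splines and epoched into 17-s peristimulus windows (2 s before to
15 s after each event).  At every timepoint an ordinary least squares GLM
with standardized trial regressors is fitted across events, giving a beta
time course per regressor and participant.  Group read-out uses a
leave-one-out (LOO) peak procedure: each participant's read-out timepoint
is the peak (of the absolute mean beta time course, 4-10 s window) across
the *other* participants, and the collected held-out betas are tested
against zero with a two-tailed one-sample t-test.

Seven regression designs are registered, mirroring the behavioural
analyses (control and its update; the two directional feedback-difference
terms with inverse self; sPE / oPE and their tPE + control counterpart;
feedback and feedback change).  A forward model (:func:`synth_bold`)
generates synthetic BOLD by convolving injected effects with a canonical
double-gamma HRF, for validation of the whole chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy import stats

from disambig.behaviour_pipeline import add_derived_measures, standardize
from disambig.task_engine import PHASE_CONTROL_OTHER, PHASE_SELF_OTHER

__all__ = [
    "DEFAULT_TR",
    "HRFParams",
    "double_gamma_hrf",
    "DesignSpec",
    "ROI_GLMS",
    "build_design",
    "BoldRun",
    "synth_bold",
    "EpochedTimecourse",
    "epoch_and_upsample",
    "BetaTimecourse",
    "timepoint_glm",
    "loo_peak_test",
]

logger = logging.getLogger(__name__)

DEFAULT_TR = 1.36
UPSAMPLE = 20
WINDOW = (-2.0, 15.0)


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma response: peak 6 s, undershoot 16 s, ratio 6."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0


def double_gamma_hrf(t, params: HRFParams | None = None) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak height."""
    p = params or HRFParams()
    t = np.asarray(t, dtype=float)
    # shape = delay/dispersion + 1 puts the gamma mode exactly at the delay
    pos = stats.gamma.pdf(t, p.peak_delay / p.peak_disp + 1.0, scale=p.peak_disp)
    neg = stats.gamma.pdf(
        t, p.undershoot_delay / p.undershoot_disp + 1.0, scale=p.undershoot_disp
    )
    h = pos - neg / p.ratio
    h[t < 0] = 0.0
    peak = h.max()
    return h / peak if peak > 0 else h


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """One ROI-GLM: regressor names plus a trial-selection rule."""

    glm_id: str
    terms: tuple[str, ...]
    selection: str  # human-readable trial-selection rule


def _sel_control_other(t):
    return t["phase_label"] == PHASE_CONTROL_OTHER


def _sel_co_switch(t):
    return _sel_control_other(t) & t["is_switch"].astype(bool) & t[
        "feedback_difference"
    ].notna() & t["next_control_rating"].notna()


def _sel_so_normal(t):
    return (t["phase_label"] == PHASE_SELF_OTHER) & ~t["is_ad"].astype(bool)


def _sel_normal_after_normal(t):
    return (
        t["phase_label"].isin([PHASE_SELF_OTHER, PHASE_CONTROL_OTHER])
        & ~t["is_ad"].astype(bool)
        & (t["prev_ad"] == 0.0)
        & t["feedback_change"].notna()
    )


def _terms_glm1(d):
    return pd.DataFrame(
        {"control": d["next_control_rating"], "control_update": d["control_update_next"]},
        index=d.index,
    )


def _terms_glm2(d):
    to_normal = (~d["is_ad"].astype(bool)).astype(float)
    return pd.DataFrame(
        {
            "fbdiff_ad_to_normal": d["feedback_difference"] * to_normal,
            "fbdiff_normal_to_ad": d["feedback_difference"] * (1.0 - to_normal),
            "inverse_self": d["inverse_self"],
            "ad": d["is_ad"].astype(float),
        },
        index=d.index,
    )


ROI_GLMS: dict[str, DesignSpec] = {
    "glm1": DesignSpec("glm1", ("control", "control_update"), "all Control-Other trials"),
    "glm2": DesignSpec(
        "glm2",
        ("fbdiff_ad_to_normal", "fbdiff_normal_to_ad", "inverse_self", "ad"),
        "Control-Other switch trials",
    ),
    "glm3": DesignSpec("glm3", ("spe",), "normal Self-Other trials"),
    "glm4": DesignSpec("glm4", ("ope",), "normal Self-Other trials"),
    "glm5": DesignSpec("glm5", ("spe", "ope"), "normal Self-Other trials"),
    "glm6": DesignSpec("glm6", ("tpe", "control"), "normal Self-Other trials"),
    "glm7": DesignSpec(
        "glm7", ("feedback", "feedback_change"), "normal trials following normal trials"
    ),
}


def build_design(table: pd.DataFrame, glm_id: str) -> pd.DataFrame:
    """Trial selection + regressor construction for one registered ROI-GLM.

    Returns a frame indexed like the (selected rows of the) trial table
    with one column per parametric term, un-standardized; standardization
    happens inside :func:`timepoint_glm` on the analysed subset.
    """
    if glm_id not in ROI_GLMS:
        raise KeyError(f"unknown ROI-GLM {glm_id!r}; options: {sorted(ROI_GLMS)}")
    t = table if "feedback_difference" in table.columns else add_derived_measures(table)
    t = t.copy()
    g = t.groupby(["block", "phase_label"], sort=False)
    t["control_update_next"] = g["control_rating"].shift(-1) - t["control_rating"]

    if glm_id == "glm1":
        d = t.loc[_sel_control_other(t) & t["next_control_rating"].notna()
                  & t["control_update_next"].notna()]
        return _terms_glm1(d)
    if glm_id == "glm2":
        return _terms_glm2(t.loc[_sel_co_switch(t)])
    if glm_id in ("glm3", "glm4", "glm5", "glm6"):
        d = t.loc[_sel_so_normal(t)]
        cols = {"spe": d["spe"], "ope": d["ope"], "tpe": d["tpe"],
                "control": d["true_control"]}
        return pd.DataFrame(
            {name: cols[name] for name in ROI_GLMS[glm_id].terms}, index=d.index
        )
    d = t.loc[_sel_normal_after_normal(t)]
    return pd.DataFrame(
        {"feedback": d["feedback"], "feedback_change": d["feedback_change"]},
        index=d.index,
    )


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

@dataclass
class BoldRun:
    """A synthetic ROI run: sampled signal plus event onsets and design."""

    times: np.ndarray  # volume acquisition times (s)
    signal: np.ndarray
    onsets: np.ndarray  # event onset times (s), aligned with design rows
    design: pd.DataFrame
    tr: float = DEFAULT_TR


def synth_bold(
    design: pd.DataFrame,
    injected_betas: dict[str, float],
    noise_sd: float,
    seed,
    tr: float = DEFAULT_TR,
    isi: float = 12.0,
    event_duration: float = 1.0,
    pad: float = 30.0,
    hrf_params: HRFParams | None = None,
) -> BoldRun:
    """Generate a synthetic ROI signal with known injected effects.

    Each event contributes ``sum_k beta_k * z(term_k)`` as a boxcar of
    ``event_duration`` at its onset, convolved with the double-gamma HRF;
    white noise of ``noise_sd`` is added on the volume grid.  Events are
    spaced ``isi`` seconds apart.
    """
    unknown = set(injected_betas) - set(design.columns)
    if unknown:
        raise ValueError(f"injected betas for unknown terms: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_events = len(design)
    if n_events == 0:
        raise ValueError("empty design")
    onsets = pad + isi * np.arange(n_events)
    total = onsets[-1] + pad + abs(WINDOW[1])
    dt = 0.1  # neural-resolution grid for convolution
    grid = np.arange(0.0, total, dt)
    neural = np.zeros_like(grid)
    amplitudes = np.zeros(n_events)
    for term, beta in injected_betas.items():
        amplitudes += beta * standardize(design[term].to_numpy())
    for onset, amp in zip(onsets, amplitudes):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + event_duration) / dt))
        neural[i0:i1] += amp
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt), hrf_params)
    conv = np.convolve(neural, hrf)[: grid.size] * dt
    times = np.arange(0.0, total, tr)
    signal = np.interp(times, grid, conv)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=times.size)
    return BoldRun(times=times, signal=signal, onsets=onsets, design=design.copy(), tr=tr)


# ---------------------------------------------------------------------------
# epoching and per-timepoint GLM
# ---------------------------------------------------------------------------

@dataclass
class EpochedTimecourse:
    """Per-event peristimulus windows on the upsampled grid."""

    data: np.ndarray  # (n_events, n_timepoints)
    rel_times: np.ndarray  # seconds relative to event onset
    kept: np.ndarray  # indices into the original event list
    n_dropped: int


def epoch_and_upsample(
    signal,
    onsets,
    tr: float = DEFAULT_TR,
    window: tuple[float, float] = WINDOW,
    upsample: int = UPSAMPLE,
) -> EpochedTimecourse:
    """Normalize, spline-upsample and epoch a sampled ROI signal.

    The signal (one sample per TR) is z-scored, interpolated with a cubic
    spline and evaluated on a ``tr / upsample`` grid from ``window[0]`` to
    ``window[1]`` seconds around each onset.  Events whose window exceeds
    the recording are dropped (counted and logged).
    """
    signal = np.asarray(signal, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("empty onset list")
    if signal.ndim != 1 or signal.size < 4:
        raise ValueError("signal must be a 1-D array with >= 4 samples")
    z = (signal - signal.mean()) / (signal.std() or 1.0)
    times = tr * np.arange(signal.size)
    spline = CubicSpline(times, z)
    rel = np.arange(window[0], window[1] + 1e-9, tr / upsample)
    kept, rows = [], []
    for i, onset in enumerate(onsets):
        lo, hi = onset + rel[0], onset + rel[-1]
        if lo < times[0] or hi > times[-1]:
            continue
        kept.append(i)
        rows.append(spline(onset + rel))
    n_dropped = onsets.size - len(kept)
    if n_dropped:
        logger.info("dropped %d events without a full epoch window", n_dropped)
    if not kept:
        raise ValueError("no event has a complete epoch window")
    return EpochedTimecourse(
        data=np.vstack(rows),
        rel_times=rel,
        kept=np.asarray(kept, dtype=int),
        n_dropped=n_dropped,
    )


@dataclass
class BetaTimecourse:
    """OLS beta weight per regressor at every upsampled timepoint."""

    betas: pd.DataFrame  # rows = rel_times, columns = terms (+ const)
    rel_times: np.ndarray
    glm_id: str = ""

    def term(self, name: str) -> np.ndarray:
        return self.betas[name].to_numpy()


def timepoint_glm(
    epochs: EpochedTimecourse, design: pd.DataFrame, glm_id: str = ""
) -> BetaTimecourse:
    """Independent OLS fit at each peristimulus timepoint.

    The design (one row per kept event) is standardized per term and a
    constant is appended; betas for all timepoints come from a single
    pseudoinverse application.
    """
    d = design.iloc[epochs.kept] if len(design) != len(epochs.kept) else design
    n_events, n_terms = len(d), len(d.columns)
    if n_events < n_terms + 3:
        raise ValueError(
            f"need at least {n_terms + 3} events for {n_terms} terms, got {n_events}"
        )
    X = np.column_stack(
        [standardize(d[c].to_numpy()) for c in d.columns] + [np.ones(n_events)]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        degenerate = [c for c in d.columns if standardize(d[c].to_numpy()).std() == 0]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"suspect terms: {degenerate or list(d.columns)}"
        )
    B = np.linalg.pinv(X) @ epochs.data  # (n_terms+1, n_timepoints)
    betas = pd.DataFrame(B.T, columns=list(d.columns) + ["const"])
    return BetaTimecourse(betas=betas, rel_times=epochs.rel_times, glm_id=glm_id)


# ---------------------------------------------------------------------------
# leave-one-out peak read-out
# ---------------------------------------------------------------------------

def _loo_collect(tc: np.ndarray, win_idx: np.ndarray):
    """Held-out beta at each participant's LOO absolute-mean peak."""
    n = tc.shape[0]
    total = tc.sum(axis=0)
    loo = np.abs((total[None, :] - tc) / (n - 1))[:, win_idx]  # (n, n_win)
    j = np.argmax(loo, axis=1)
    values = tc[np.arange(n), win_idx[j]]
    return j, values


def loo_peak_test(
    timecourses: np.ndarray,
    rel_times: np.ndarray,
    window: tuple[float, float] = (4.0, 10.0),
    inference: str = "sign_flip",
    n_flips: int = 1000,
    seed: int | None = 0,
) -> dict:
    """Leave-one-out peak read-out and group test for one regressor.

    ``timecourses`` is (n_participants, n_timepoints).  For each held-out
    participant the peak of the absolute leave-one-out mean time course
    within ``window`` (default 4-10 s) picks the read-out timepoint; the
    held-out beta at that time is the participant's peak value and the
    group statistic is a two-tailed one-sample t against zero.

    Although each held-out value has mean zero under the null, the values
    share the selection and are cross-correlated, which makes the plain
    t reference distribution anti-conservative when the null time courses
    contain many comparable peaks.  The default inference therefore
    calibrates the observed t against a sign-flip permutation distribution
    (each participant's whole time course flipped with probability 1/2 and
    the full LOO statistic recomputed), which is exact for sign-symmetric
    noise.  ``inference="t"`` gives the plain t-test p-value instead; both
    are always reported (``p_flip`` / ``p_t``).

    A flat mean time course falls back to the earliest window point
    (warned).
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[0] < 3:
        raise ValueError("need at least 3 participants for the LOO procedure")
    if inference not in ("sign_flip", "t"):
        raise ValueError("inference must be 'sign_flip' or 't'")
    rel_times = np.asarray(rel_times, dtype=float)
    in_win = (rel_times >= window[0]) & (rel_times <= window[1])
    if not in_win.any():
        raise ValueError("window outside the epoch")
    win_idx = np.flatnonzero(in_win)
    n = tc.shape[0]

    flat = np.ptp(np.abs(tc.mean(axis=0))[win_idx]) == 0.0
    if flat:
        warnings.warn("flat LOO mean time course; using earliest window point")
        j = np.zeros(n, dtype=int)
        values = tc[:, win_idx[0]]
    else:
        j, values = _loo_collect(tc, win_idx)
    peak_times = rel_times[win_idx[j]]

    def _tstat(v):
        sd = v.std(ddof=1)
        return 0.0 if sd == 0 else v.mean() / (sd / np.sqrt(n))

    t_obs = _tstat(values)
    p_t = float(stats.ttest_1samp(values, 0.0).pvalue)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_flips):
        signs = rng.choice([-1.0, 1.0], size=n)
        _, v = _loo_collect(signs[:, None] * tc, win_idx)
        if abs(_tstat(v)) >= abs(t_obs):
            exceed += 1
    p_flip = (1.0 + exceed) / (n_flips + 1.0)
    return {
        "peak_times": peak_times,
        "values": values,
        "mean": float(values.mean()),
        "t": float(t_obs),
        "p": float(p_flip if inference == "sign_flip" else p_t),
        "p_flip": float(p_flip),
        "p_t": p_t,
        "n": n,
    }
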