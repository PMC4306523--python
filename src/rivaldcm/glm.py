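"""First-level GLM: four-regressor design, RT-corrected switch events, OLS.

The design matrix holds a fixation boxcar, a visual-stimulation boxcar and
two impulse regressors (spontaneous rivalry switches, stimulus-driven replay
switches), all convolved with a canonical double-gamma HRF at microtime
resolution and decimated to the TR grid. Switch onsets are button presses
shifted earlier by the mean reaction time estimated from replay trials. The
contrast of interest is rivalry-switch > replay-switch per region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from .forward import BOLDSeries, InputTimeline

__all__ = [
    "HRFSpec",
    "GLMFit",
    "FirstLevelGLM",
    "read_events_tsv",
    "write_events_tsv",
    "trim_initial_volumes",
    "derive_switch_events",
    "estimate_mean_rt",
    "correct_event_times",
    "canonical_hrf",
    "build_design_matrix",
    "fit_glm",
    "contrast_rivalry_gt_replay",
    "group_contrast_ttest",
    "events_to_input_timeline",
    "mean_dominance_from_events",
]

SWITCH_TYPES = ("rivalry_switch", "replay_switch")
PRESS_TYPES = ("press_toward", "press_away", "press_mixed")
STIM_TYPES = ("stimulation_rivalry", "stimulation_replay")


# ---------------------------------------------------------------------------
# events I/O and bookkeeping
# ---------------------------------------------------------------------------

def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a",
                  float_format="%.4f")


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    return df


def _validate_events(events: pd.DataFrame) -> None:
    if not (np.diff(events["onset"].to_numpy()) >= -1e-9).all():
        raise ValueError("event onsets must be non-decreasing")
    if (events["duration"].to_numpy() < 0).any():
        raise ValueError("event durations must be non-negative")


def trim_initial_volumes(
    bold: BOLDSeries, events: pd.DataFrame, n_discard: int = 5
) -> tuple[BOLDSeries, pd.DataFrame]:
    """Discard the first ``n_discard`` volumes and shift the event clock.

    Events that end before the new origin are dropped; straddling events are
    clipped at zero.
    """
    t0 = n_discard * bold.TR
    out = BOLDSeries(y=bold.y[n_discard:], TR=bold.TR,
                     region_labels=bold.region_labels)
    ev = events.copy()
    ends = ev["onset"] + ev["duration"]
    ev = ev[ends > t0].copy()
    new_onset = (ev["onset"] - t0).clip(lower=0.0)
    ev["duration"] = np.minimum(ev["onset"] + ev["duration"] - t0,
                                ev["duration"])
    ev["onset"] = new_onset
    return out, ev.reset_index(drop=True)


def derive_switch_events(events: pd.DataFrame) -> pd.DataFrame:
    """Switch events (at button-press times, uncorrected) from raw events.

    A switch is a press whose exclusive-percept label differs from the
    previous exclusive press within the same stimulation block; the first
    press of a block and mixed-percept presses never count as switches.
    """
    _validate_events(events)
    out = []
    stim = events[events["trial_type"].isin(STIM_TYPES)]
    presses = events[events["trial_type"].isin(PRESS_TYPES)]
    for _, block in stim.iterrows():
        t0, t1 = block["onset"], block["onset"] + block["duration"]
        sw_type = ("rivalry_switch"
                   if block["trial_type"] == "stimulation_rivalry"
                   else "replay_switch")
        inside = presses[(presses["onset"] >= t0) & (presses["onset"] < t1)]
        prev_label = None
        for _, press in inside.iterrows():
            if press["trial_type"] == "press_mixed":
                continue
            label = press["trial_type"]
            if prev_label is not None and label != prev_label:
                out.append({"onset": press["onset"], "duration": 0.0,
                            "trial_type": sw_type,
                            "response_time": press["response_time"]})
            prev_label = label
    return pd.DataFrame(out, columns=["onset", "duration", "trial_type",
                                      "response_time"])


def estimate_mean_rt(events: pd.DataFrame) -> float:
    """Mean reaction time from replay-trial presses (press minus stimulus
    change, recorded in the response_time column)."""
    stim = events[events["trial_type"] == "stimulation_replay"]
    presses = events[events["trial_type"].isin(PRESS_TYPES)]
    rts = []
    for _, block in stim.iterrows():
        t0, t1 = block["onset"], block["onset"] + block["duration"]
        inside = presses[(presses["onset"] >= t0) & (presses["onset"] < t1)]
        rts.extend(inside["response_time"].dropna().tolist())
    if not rts:
        raise ValueError("no replay press with a recorded response time")
    return float(np.mean(rts))


def correct_event_times(events: pd.DataFrame, mean_rt: float) -> pd.DataFrame:
    """Shift switch-event onsets earlier by the mean RT (clipped at 0)."""
    if mean_rt < 0:
        raise ValueError("mean_rt must be non-negative")
    out = events.copy()
    mask = out["trial_type"].isin(SWITCH_TYPES)
    out.loc[mask, "onset"] = (out.loc[mask, "onset"] - mean_rt).clip(lower=0.0)
    return out.sort_values("onset", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# HRF and design matrix
# ---------------------------------------------------------------------------

@dataclass
class HRFSpec:
    """Canonical double-gamma HRF parameterization.

    The kernel is gampdf(t; delay/dispersion, dispersion) minus
    gampdf(t; u_delay/u_dispersion, u_dispersion)/ratio, evaluated over
    ``length`` seconds. Defaults are the standard SPM parameterization.
    """

    delay: float = 6.0
    undershoot_delay: float = 16.0
    dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0
    microtime_bins: int = 16

    def __post_init__(self) -> None:
        if self.dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.length <= self.delay:
            raise ValueError("kernel length must cover the response gamma")


def canonical_hrf(spec: HRFSpec, dt: float) -> np.ndarray:
    """Sampled double-gamma kernel; positive peak near ``delay - dispersion``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0, spec.length + dt / 2, dt)
    peak = scipy.stats.gamma.pdf(t, spec.delay / spec.dispersion,
                                 scale=spec.dispersion)
    under = scipy.stats.gamma.pdf(
        t, spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion)
    return peak - under / spec.ratio


def build_design_matrix(
    events: pd.DataFrame,
    hrf: HRFSpec | None = None,
    n_vols: int = 0,
    TR: float = 2.1,
    nuisance: pd.DataFrame | None = None,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Four task regressors convolved with the HRF, sampled at the TR grid.

    Stimulus functions are built at microtime resolution (TR /
    ``hrf.microtime_bins``): boxcars for fixation and stimulation (rivalry
    and replay merged), unit impulses at the corrected switch times.
    """
    hrf = hrf or HRFSpec()
    if n_vols <= 0:
        raise ValueError("n_vols must be positive")
    run_end = n_vols * TR
    late = events[events["onset"] > run_end]
    if len(late):
        offenders = ", ".join(
            f"{r.trial_type}@{r.onset:.2f}s" for r in late.itertuples())
        raise ValueError(f"events beyond run end ({run_end:.1f} s): {offenders}")
    dt = TR / hrf.microtime_bins
    T = int(np.ceil(run_end / dt)) + 1
    kernel = canonical_hrf(hrf, dt)

    def conv(stim: np.ndarray) -> np.ndarray:
        full = np.convolve(stim, kernel)[:T]
        vol_idx = (np.arange(n_vols) * hrf.microtime_bins)
        return full[vol_idx]

    cols = {}
    for name, types, kind in [
        ("fixation", ("fixation",), "boxcar"),
        ("stimulation", STIM_TYPES, "boxcar"),
        ("rivalry_switch", ("rivalry_switch",), "impulse"),
        ("replay_switch", ("replay_switch",), "impulse"),
    ]:
        stim = np.zeros(T)
        sel = events[events["trial_type"].isin(types)]
        for _, ev in sel.iterrows():
            a = int(round(ev["onset"] / dt))
            if kind == "boxcar":
                b = int(round((ev["onset"] + ev["duration"]) / dt))
                stim[a:max(b, a + 1)] = 1.0
            else:
                if a < T:
                    stim[a] = 1.0
        cols[name] = conv(stim)
    X = pd.DataFrame(cols)
    if nuisance is not None:
        if len(nuisance) != n_vols:
            raise ValueError("nuisance rows must match n_vols")
        for c in nuisance.columns:
            X[f"nuisance_{c}"] = np.asarray(nuisance[c])
    if add_intercept:
        X["intercept"] = 1.0
    return X


# ---------------------------------------------------------------------------
# OLS fit and contrasts
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Per-region OLS estimates for one run/subject."""

    columns: list[str]
    region_labels: list[str]
    coef: np.ndarray          # (n_cols, n_regions)
    coef_se: np.ndarray
    t: np.ndarray
    sigma2: np.ndarray        # per region residual variance
    df_resid: int
    xtx_inv: np.ndarray

    def contrast(self, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Contrast estimate and t statistic per region."""
        c = np.asarray(c, dtype=float)
        est = c @ self.coef
        var = float(c @ self.xtx_inv @ c) * self.sigma2
        return est, est / np.sqrt(var)


class FirstLevelGLM(BaseEstimator):
    """Ordinary-least-squares fit of a design matrix to ROI time series.

    ``fit(X, Y)`` takes the design matrix (DataFrame from
    :func:`build_design_matrix`) and the (n_vols, n_regions) BOLD array.
    Fitted attributes: ``coef_`` (n_cols, n_regions), ``t_``, ``sigma2_``,
    ``df_resid_``, ``residuals_``.
    """

    def __init__(self, check_rank: bool = True):
        self.check_rank = check_rank

    def fit(self, X: pd.DataFrame, Y) -> "FirstLevelGLM":
        if isinstance(Y, BOLDSeries):
            region_labels = list(Y.region_labels)
            Y = Y.y
        else:
            Y = np.atleast_2d(np.asarray(Y, dtype=float))
            region_labels = [f"roi{i}" for i in range(Y.shape[1])]
        Xv = X.to_numpy(dtype=float)
        if Xv.shape[0] != Y.shape[0]:
            raise ValueError(
                f"design has {Xv.shape[0]} rows but BOLD has {Y.shape[0]} volumes")
        rank = np.linalg.matrix_rank(Xv)
        if self.check_rank and rank < Xv.shape[1]:
            # name the columns involved in the deficiency via pivoted QR
            from scipy.linalg import qr
            _, _, piv = qr(Xv, mode="economic", pivoting=True)
            bad = [X.columns[i] for i in piv[rank:]]
            raise ValueError(f"design matrix is rank deficient; "
                             f"collinear columns include: {bad}")
        beta, _, _, _ = np.linalg.lstsq(Xv, Y, rcond=None)
        resid = Y - Xv @ beta
        df = Y.shape[0] - rank
        sigma2 = (resid ** 2).sum(axis=0) / df
        xtx_inv = np.linalg.pinv(Xv.T @ Xv)
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        self.columns_ = list(X.columns)
        self.region_labels_ = region_labels
        self.coef_ = beta
        self.coef_se_ = se
        self.t_ = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        self.sigma2_ = sigma2
        self.df_resid_ = df
        self.residuals_ = resid
        self.xtx_inv_ = xtx_inv
        return self

    def to_fit(self) -> GLMFit:
        return GLMFit(columns=self.columns_, region_labels=self.region_labels_,
                      coef=self.coef_, coef_se=self.coef_se_, t=self.t_,
                      sigma2=self.sigma2_, df_resid=self.df_resid_,
                      xtx_inv=self.xtx_inv_)


def fit_glm(bold, X: pd.DataFrame) -> GLMFit:
    """OLS fit of the design to ROI BOLD; see :class:`FirstLevelGLM`."""
    return FirstLevelGLM().fit(X, bold).to_fit()


def contrast_rivalry_gt_replay(fit: GLMFit) -> tuple[np.ndarray, np.ndarray]:
    """Per-region rivalry-switch > replay-switch contrast value and t."""
    for name in SWITCH_TYPES:
        if name not in fit.columns:
            raise ValueError(f"design has no {name} column")
    c = np.zeros(len(fit.columns))
    c[fit.columns.index("rivalry_switch")] = 1.0
    c[fit.columns.index("replay_switch")] = -1.0
    return fit.contrast(c)


def group_contrast_ttest(contrasts: np.ndarray) -> pd.DataFrame:
    """One-sample t-test across subjects per region (rows: regions)."""
    contrasts = np.atleast_2d(contrasts)
    res = scipy.stats.ttest_1samp(contrasts, popmean=0.0, axis=0)
    return pd.DataFrame({
        "mean_contrast": contrasts.mean(axis=0),
        "t": res.statistic,
        "p": res.pvalue,
        "df": contrasts.shape[0] - 1,
    })


# ---------------------------------------------------------------------------
# bridges to the DCM stage
# ---------------------------------------------------------------------------

def events_to_input_timeline(
    events: pd.DataFrame,
    duration: float,
    mean_rt: float | None = None,
    dt: float = 0.05,
    pulse_width: float = 1.0,
) -> InputTimeline:
    """DCM input timeline (fixation/stimulation boxcars + RT-corrected switch
    pulses) from a raw events table."""
    if mean_rt is None:
        mean_rt = estimate_mean_rt(events)
    switches = correct_event_times(derive_switch_events(events), mean_rt)
    boxcars = {
        "fixation": [(e.onset, e.duration) for e in
                     events[events["trial_type"] == "fixation"].itertuples()],
        "stimulation": [(e.onset, e.duration) for e in
                        events[events["trial_type"].isin(STIM_TYPES)].itertuples()],
    }
    pulses = {
        name: switches[switches["trial_type"] == name]["onset"].tolist()
        for name in SWITCH_TYPES
    }
    return InputTimeline.from_events(boxcars=boxcars, pulses=pulses,
                                     duration=duration, dt=dt,
                                     pulse_width=pulse_width)


def mean_dominance_from_events(events: pd.DataFrame) -> float:
    """Observed mean exclusive-percept duration across rivalry trials.

    Epoch durations are intervals between consecutive presses within a
    rivalry stimulation block, starting from each exclusive press; the final
    (censored) epoch of each block is excluded, as are mixed epochs.
    """
    stim = events[events["trial_type"] == "stimulation_rivalry"]
    presses = events[events["trial_type"].isin(PRESS_TYPES)]
    durs = []
    for _, block in stim.iterrows():
        t0, t1 = block["onset"], block["onset"] + block["duration"]
        inside = presses[(presses["onset"] >= t0) & (presses["onset"] < t1)]
        times = inside["onset"].to_numpy()
        labels = inside["trial_type"].to_numpy()
        for i in range(len(times) - 1):
            if labels[i] != "press_mixed":
                durs.append(times[i + 1] - times[i])
    if not durs:
        raise ValueError("no complete exclusive-percept epochs in events")
    return float(np.mean(durs))
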