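"""Synthetic multi-subject experiments with known ground truth.

Emulates the bistable structure-from-motion paradigm: alternating exclusive
percepts with gamma-distributed dominance durations (mean 4.50 s, SD 0.99 s
by default), a small mixed-percept fraction (2.23% of stimulus time), button
presses lagging percept onsets by a positive reaction time (mean 0.90 s, SD
0.43 s), trials of 31.5 s stimulation + 11 s fixation at TR 2.1 s, runs of
10 trials split 5/5 between rivalry and replay (replay trials replay an
earlier rivalry sequence of the same run), and ROI BOLD generated from a
known three-region bilinear DCM with additive white noise.

A built-in linear linking rule ties each subject's mean dominance duration to
their modulatory-coupling difference (rivalry minus replay),

    mean_duration_i = gamma0 + sum_c gamma_c * dB_ic + eps_i,

so that the downstream regression stage has a recoverable ground truth. The
rule is a construction of this package for recovery testing, not an
empirical claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .forward import (
    BOLDSeries,
    DCMParameters,
    HemodynamicParams,
    InputTimeline,
    parameters_from_masks,
    sample_and_noise,
    simulate_bold,
)
from .model_space import (
    Connection,
    DCMModelSpec,
    MODULABLE_CONNECTIONS,
    enumerate_model_space,
)

__all__ = [
    "BehavioralProfile",
    "SubjectGroundTruth",
    "CohortConfig",
    "PerceptTimeline",
    "RunData",
    "SubjectData",
    "Cohort",
    "simulate_percept_timeline",
    "simulate_subject",
    "simulate_cohort",
    "winning_model",
]

EXCLUSIVE_PERCEPTS = ("toward", "away")
EVENT_COLUMNS = ("onset", "duration", "trial_type", "response_time")


def winning_model() -> DCMModelSpec:
    """The bidirectional structure with all four modulations and V5-only
    switch input (model_id 15 in the canonical enumeration)."""
    return enumerate_model_space()[15]


@dataclass
class BehavioralProfile:
    """Percept-dynamics parameters for one subject.

    Dominance durations are gamma distributed with the given mean/SD;
    reaction times are gamma distributed (positive support) with the given
    mean/SD; ``mixed_fraction`` is the target fraction of stimulus time spent
    in mixed percepts.
    """

    mean_duration: float = 4.50
    sd_duration: float = 0.99
    mixed_fraction: float = 0.0223
    rt_mean: float = 0.90
    rt_sd: float = 0.43

    def __post_init__(self) -> None:
        if self.mean_duration <= 0 or self.sd_duration <= 0:
            raise ValueError("duration mean and SD must be positive")
        if not 0 <= self.mixed_fraction <= 0.1:
            raise ValueError("mixed_fraction must lie in [0, 0.1]")
        if self.rt_mean <= 0 or self.rt_sd <= 0:
            raise ValueError("RT mean and SD must be positive")

    @property
    def gamma_shape(self) -> float:
        return (self.mean_duration / self.sd_duration) ** 2

    @property
    def gamma_scale(self) -> float:
        return self.sd_duration ** 2 / self.mean_duration

    def draw_duration(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.gamma_shape, self.gamma_scale))

    def draw_rt(self, rng: np.random.Generator) -> float:
        shape = (self.rt_mean / self.rt_sd) ** 2
        scale = self.rt_sd ** 2 / self.rt_mean
        return float(rng.gamma(shape, scale))

    @property
    def mean_mixed_duration(self) -> float:
        """Mixed-epoch mean giving the target mixed fraction of stimulus time."""
        if self.mixed_fraction == 0:
            return 0.0
        return self.mixed_fraction * self.mean_duration / (1 - self.mixed_fraction)


@dataclass
class SubjectGroundTruth:
    """Generating parameters for one subject.

    Rivalry and replay share A and C and differ only in the B entries of the
    two switch inputs; ``delta_b`` holds B_rivalry - B_replay per modulated
    connection in the order of :data:`MODULABLE_CONNECTIONS`.
    """

    subject_id: str
    params: DCMParameters
    profile: BehavioralProfile
    delta_b: dict[Connection, float]
    true_mean_duration: float


@dataclass
class CohortConfig:
    """Study-design and population parameters for a synthetic cohort."""

    n_subjects: int = 18
    n_runs: int = 6
    trials_per_run: int = 10
    rivalry_per_run: int = 5
    stim_s: float = 31.5
    fix_s: float = 11.0
    lead_in_s: float = 10.5
    TR: float = 2.1
    dt: float = 0.05
    pulse_width: float = 1.0
    noise_sd: float = 0.3
    # generating model and population parameters
    model: DCMModelSpec = field(default_factory=winning_model)
    a_values: dict = field(default_factory=lambda: {
        ("r-V5", "r-pSPL"): 0.35, ("r-pSPL", "r-V5"): 0.15,
        ("r-pSPL", "r-aSPL"): 0.35, ("r-aSPL", "r-pSPL"): 0.15,
    })
    c_stim: float = 0.04
    c_switch: float = 0.15
    b_replay_mean: float = 0.30
    b_replay_sd: float = 0.08
    delta_b_mean: float = 0.15
    delta_b_sd: float = 0.15
    # population B draws are truncated to this range: couplings beyond it
    # destabilize the pulse-modulated dynamics and are not physiological
    b_range: tuple[float, float] = (-0.2, 0.75)
    # linking rule: mean duration = gamma0 + sum_c gamma_c dB_c + eps
    gamma0: float = 4.50
    gamma_c: tuple[float, float, float, float] = (0.0, -3.0, 0.0, 3.0)
    linking_noise_sd: float = 0.30
    duration_floor: float = 1.0
    # behavioral defaults shared across subjects (mean_duration is overridden
    # by the linking rule; SD scales with the default coefficient of variation)
    profile: BehavioralProfile = field(default_factory=BehavioralProfile)
    suitability_range: tuple[float, float] | None = None  # e.g. (3.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rivalry_per_run * 2 != self.trials_per_run:
            # replay trials replay earlier rivalry trials 1:1
            raise ValueError("trials_per_run must be twice rivalry_per_run")

    @property
    def trial_s(self) -> float:
        return self.stim_s + self.fix_s

    @property
    def run_duration(self) -> float:
        return self.lead_in_s + self.trials_per_run * self.trial_s

    @property
    def n_volumes(self) -> int:
        """Volumes per run as actually sampled from the fine grid."""
        T = int(round(self.run_duration / self.dt)) + 1
        step = int(round(self.TR / self.dt))
        return (T - 1) // step + 1


@dataclass
class PerceptTimeline:
    """Percept epochs within one stimulation period (trial-local times)."""

    epochs: list[tuple[str, float, float]]   # (label, onset, duration)
    switch_times: list[tuple[float, str]]    # exclusive-percept changes

    @property
    def exclusive_durations(self) -> list[float]:
        return [d for lab, _, d in self.epochs if lab in EXCLUSIVE_PERCEPTS]

    @property
    def mixed_time(self) -> float:
        return sum(d for lab, _, d in self.epochs if lab == "mixed")


def simulate_percept_timeline(
    profile: BehavioralProfile,
    duration: float,
    seed: int | np.random.Generator | None = None,
) -> PerceptTimeline:
    """Alternating exclusive percepts with gamma durations and optional short
    mixed epochs at each transition, truncated at ``duration``."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    epochs: list[tuple[str, float, float]] = []
    switches: list[tuple[float, str]] = []
    current = EXCLUSIVE_PERCEPTS[int(rng.integers(2))]
    t = 0.0
    first = True
    while t < duration:
        d = profile.draw_duration(rng)
        d = min(d, duration - t)
        epochs.append((current, t, d))
        if not first:
            switches.append((t, current))
        first = False
        t += d
        if t >= duration:
            break
        m = profile.mean_mixed_duration
        if m > 0:
            md = min(float(rng.exponential(m)), duration - t)
            if md > 0:
                epochs.append(("mixed", t, md))
                t += md
        current = EXCLUSIVE_PERCEPTS[1 - EXCLUSIVE_PERCEPTS.index(current)]
    return PerceptTimeline(epochs=epochs, switch_times=switches)


@dataclass
class RunData:
    """One simulated run: events, BOLD and the generating switch times."""

    run_id: int
    events: pd.DataFrame
    bold: BOLDSeries
    true_switch_times: dict[str, list[float]]   # run-global, by input label
    trial_order: list[str]                      # "rivalry"/"replay" per trial


@dataclass
class SubjectData:
    subject_id: str
    truth: SubjectGroundTruth
    runs: list[RunData]

    def mean_dominance_duration(self) -> float:
        """Mean exclusive-percept duration across all rivalry trials/runs."""
        durs: list[float] = []
        for run in self.runs:
            durs.extend(run.events.attrs["rivalry_exclusive_durations"])
        return float(np.mean(durs))


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectData]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject": s.subject_id,
                   "true_mean_duration_s": s.truth.true_mean_duration}
            for conn in MODULABLE_CONNECTIONS:
                row[f"delta_b[{conn}]"] = s.truth.delta_b[conn]
            rows.append(row)
        return pd.DataFrame(rows)


def _trial_order(cfg: CohortConfig, rng: np.random.Generator) -> list[str]:
    """Pseudo-random order: starts with rivalry; every replay trial has an
    earlier unreplayed rivalry trial in the same run (prefix condition)."""
    n_r, n_p = cfg.rivalry_per_run, cfg.trials_per_run - cfg.rivalry_per_run
    while True:
        tail = ["rivalry"] * (n_r - 1) + ["replay"] * n_p
        rng.shuffle(tail)
        order = ["rivalry"] + tail
        r = p = 0
        ok = True
        for t in order:
            r += t == "rivalry"
            p += t == "replay"
            if p > r:
                ok = False
                break
        if ok:
            return order


def _subject_parameters(cfg: CohortConfig, rng: np.random.Generator
                        ) -> tuple[DCMParameters, dict[Connection, float]]:
    b_values = {}
    delta_b = {}
    b_mask = cfg.model.b_mask
    regions = cfg.model.regions
    for conn in MODULABLE_CONNECTIONS:
        i, j = regions.index(conn.target), regions.index(conn.source)
        if not b_mask[2, i, j]:
            delta_b[conn] = 0.0
            continue
        lo, hi = cfg.b_range
        b_rep = float(np.clip(rng.normal(cfg.b_replay_mean, cfg.b_replay_sd),
                              lo, hi))
        b_riv = float(np.clip(b_rep + rng.normal(cfg.delta_b_mean,
                                                 cfg.delta_b_sd), lo, hi))
        b_values[("replay_switch", conn.source, conn.target)] = b_rep
        b_values[("rivalry_switch", conn.source, conn.target)] = b_riv
        delta_b[conn] = b_riv - b_rep  # realized (possibly truncated) difference
    c_values = {("stimulation", "r-V5"): cfg.c_stim}
    for region in cfg.model.c_regions_switch:
        c_values[("rivalry_switch", region)] = cfg.c_switch
        c_values[("replay_switch", region)] = cfg.c_switch
    params = parameters_from_masks(cfg.model, a_values=cfg.a_values,
                                   b_values=b_values, c_values=c_values)
    return params, delta_b


def _simulate_run(truth: SubjectGroundTruth, cfg: CohortConfig, run_id: int,
                  rng: np.random.Generator,
                  hemo: HemodynamicParams) -> RunData:
    order = _trial_order(cfg, rng)
    events = []
    fix_boxcars = [(0.0, cfg.lead_in_s)]
    stim_boxcars = []
    switch_times = {"rivalry_switch": [], "replay_switch": []}
    rivalry_pool: list[PerceptTimeline] = []
    rivalry_durs: list[float] = []
    t0 = cfg.lead_in_s
    events.append({"onset": 0.0, "duration": cfg.lead_in_s,
                   "trial_type": "fixation", "response_time": np.nan})
    for cond in order:
        stim_boxcars.append((t0, cfg.stim_s))
        if cond == "rivalry":
            tl = simulate_percept_timeline(truth.profile, cfg.stim_s, rng)
            rivalry_pool.append(tl)
            rivalry_durs.extend(tl.exclusive_durations)
            label = "stimulation_rivalry"
            sw_key = "rivalry_switch"
        else:
            tl = rivalry_pool.pop(0)   # replay the earliest unreplayed trial
            label = "stimulation_replay"
            sw_key = "replay_switch"
        events.append({"onset": t0, "duration": cfg.stim_s,
                       "trial_type": label, "response_time": np.nan})
        # button presses: one per exclusive-percept onset (incl. the first),
        # plus mixed-percept reports; reports are serial, so a press never
        # precedes the previous one; presses after stimulus offset are lost
        last_press = -np.inf
        for ep_label, onset, _dur in tl.epochs:
            rt = truth.profile.draw_rt(rng)
            press_t = max(t0 + onset + rt, last_press + 0.05)
            if press_t >= t0 + cfg.stim_s:
                continue
            last_press = press_t
            if ep_label == "mixed":
                ttype = "press_mixed"
            else:
                ttype = f"press_{ep_label}"
            events.append({
                "onset": press_t, "duration": 0.0, "trial_type": ttype,
                # replay presses respond to a known stimulus change
                "response_time": rt if cond == "replay" else np.nan,
            })
        for sw_t, _new in tl.switch_times:
            switch_times[sw_key].append(t0 + sw_t)
        events.append({"onset": t0 + cfg.stim_s, "duration": cfg.fix_s,
                       "trial_type": "fixation", "response_time": np.nan})
        fix_boxcars.append((t0 + cfg.stim_s, cfg.fix_s))
        t0 += cfg.trial_s

    timeline = InputTimeline.from_events(
        boxcars={"fixation": fix_boxcars, "stimulation": stim_boxcars},
        pulses=switch_times,
        duration=cfg.run_duration,
        dt=cfg.dt,
        pulse_width=cfg.pulse_width,
    )
    y_fine = simulate_bold(truth.params, timeline, hemo)
    bold = sample_and_noise(
        y_fine, cfg.dt, cfg.TR, noise_sd=cfg.noise_sd, seed=rng,
        region_labels=cfg.model.regions.labels,
    )
    ev = pd.DataFrame(events, columns=list(EVENT_COLUMNS))
    ev = ev.sort_values("onset", kind="stable").reset_index(drop=True)
    ev.attrs["rivalry_exclusive_durations"] = rivalry_durs
    return RunData(run_id=run_id, events=ev, bold=bold,
                   true_switch_times=switch_times, trial_order=order)


def simulate_subject(truth: SubjectGroundTruth, cfg: CohortConfig,
                     seed: int | np.random.Generator | None = None,
                     hemo: HemodynamicParams | None = None) -> SubjectData:
    """Simulate all runs for one subject from their ground-truth parameters."""
    truth.params.validate_masks(cfg.model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hemo = hemo or HemodynamicParams()
    runs = [_simulate_run(truth, cfg, r, rng, hemo) for r in range(cfg.n_runs)]
    return SubjectData(subject_id=truth.subject_id, truth=truth, runs=runs)


def simulate_cohort(cfg: CohortConfig,
                    hemo: HemodynamicParams | None = None) -> Cohort:
    """Simulate a full cohort; a pure function of the config (incl. seed)."""
    if cfg.n_subjects < 5:
        raise ValueError("need at least 5 subjects")
    subjects = []
    for i in range(cfg.n_subjects):
        # per-subject streams derive deterministically from (seed, index)
        for attempt in range(100):
            rng = np.random.default_rng(
                np.random.SeedSequence((cfg.seed, i, attempt)))
            params, delta_b = _subject_parameters(cfg, rng)
            db_vec = np.array([delta_b[c] for c in MODULABLE_CONNECTIONS])
            mean_dur = (cfg.gamma0 + float(np.dot(cfg.gamma_c, db_vec))
                        + rng.normal(0.0, cfg.linking_noise_sd))
            if mean_dur > cfg.duration_floor:
                break
            warnings.warn(
                f"subject {i}: linking rule gave mean duration "
                f"{mean_dur:.2f} s <= floor; resampling")
        else:  # pragma: no cover - pathological configs only
            raise RuntimeError("could not sample a subject above the floor")
        prof = cfg.profile
        cv = prof.sd_duration / prof.mean_duration
        profile = BehavioralProfile(
            mean_duration=mean_dur, sd_duration=cv * mean_dur,
            mixed_fraction=prof.mixed_fraction,
            rt_mean=prof.rt_mean, rt_sd=prof.rt_sd)
        truth = SubjectGroundTruth(
            subject_id=f"sub-{i + 1:02d}", params=params, profile=profile,
            delta_b=delta_b, true_mean_duration=mean_dur)
        subjects.append(simulate_subject(truth, cfg, seed=rng, hemo=hemo))
    if cfg.suitability_range is not None:
        lo, hi = cfg.suitability_range
        subjects = [s for s in subjects
                    if lo <= s.mean_dominance_duration() <= hi]
    return Cohort(config=cfg, subjects=subjects)
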