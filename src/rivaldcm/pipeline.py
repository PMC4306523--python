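"""End-to-end orchestration: simulate -> glm -> invert -> bms -> regress.

A run is a pure function of its :class:`RunConfig` (including the master
seed): every stage writes its artifacts under the output directory and a
manifest records the config hash, seeds, per-stage status and timing.
Stages can be toggled; with the simulation stage off, user-supplied events
and BOLD tables in the same layout are consumed from the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import BehavioralProfile, Cohort, CohortConfig, simulate_cohort
from .forward import BOLDSeries
from .glm import (
    HRFSpec,
    build_design_matrix,
    contrast_rivalry_gt_replay,
    correct_event_times,
    derive_switch_events,
    estimate_mean_rt,
    events_to_input_timeline,
    fit_glm,
    group_contrast_ttest,
    mean_dominance_from_events,
    read_events_tsv,
    trim_initial_volumes,
    write_events_tsv,
)
from .individual import compute_delta_b, fit_dominance_regression
from .inversion import PriorSpec, SubjectTimeseries, evidence_table, invert_dcm
from .model_space import (
    enumerate_model_space,
    model_space_table,
    partition_families,
    save_model_space,
)
from .selection import select_winning

log = logging.getLogger("rivaldcm")

__all__ = ["RunConfig", "run_pipeline"]


def _connection_map_to_yaml(d: dict) -> dict:
    return {f"{src}->{tgt}": float(v) for (src, tgt), v in d.items()}


def _connection_map_from_yaml(d: dict) -> dict:
    out = {}
    for key, v in d.items():
        src, tgt = key.split("->")
        out[(src, tgt)] = float(v)
    return out


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    hrf: HRFSpec = field(default_factory=HRFSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    inversion_dt: float | None = None      # defaults to cohort.dt
    discard_initial_volumes: int = 5
    bms_prior_alpha: float = 1.0
    bms_n_samples: int = 1_000_000
    cooks_threshold: float = 1.0
    out_dir: str = "rivaldcm_run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "glm", "invert", "bms", "regress")

    def __post_init__(self) -> None:
        self.cohort.seed = self.seed

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["a_values"] = _connection_map_to_yaml(self.cohort.a_values)
        d["cohort"]["gamma_c"] = list(self.cohort.gamma_c)
        d["cohort"]["model"] = self.cohort.model.to_record()
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cd = dict(d.pop("cohort"))
        cd["a_values"] = _connection_map_from_yaml(cd["a_values"])
        cd["gamma_c"] = tuple(cd["gamma_c"])
        from .model_space import DCMModelSpec
        cd["model"] = DCMModelSpec.from_record(cd["model"])
        cd["profile"] = BehavioralProfile(**cd["profile"])
        if cd.get("suitability_range") is not None:
            cd["suitability_range"] = tuple(cd["suitability_range"])
        cfg = cls(
            cohort=CohortConfig(**cd),
            hrf=HRFSpec(**d.pop("hrf")),
            priors=PriorSpec(**d.pop("priors")),
            **{k: (tuple(v) if k == "stages" else v) for k, v in d.items()},
        )
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> Cohort:
    cohort = simulate_cohort(cfg.cohort)
    for subj in cohort.subjects:
        sdir = out / "cohort" / subj.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        for run in subj.runs:
            write_events_tsv(run.events,
                             sdir / f"run-{run.run_id:02d}_events.tsv")
            run.bold.to_tsv(sdir / f"run-{run.run_id:02d}_bold.tsv")
    cohort.truth_table().to_csv(out / "cohort" / "ground_truth.tsv",
                                sep="\t", index=False)
    return cohort


def _load_runs(cfg: RunConfig, out: Path, subject_id: str):
    sdir = out / "cohort" / subject_id
    runs = []
    for ev_path in sorted(sdir.glob("run-*_events.tsv")):
        run_id = ev_path.name.split("_")[0]
        bold = BOLDSeries.from_tsv(sdir / f"{run_id}_bold.tsv")
        events = read_events_tsv(ev_path)
        runs.append((run_id, events, bold))
    if not runs:
        raise FileNotFoundError(f"no runs found under {sdir}")
    return runs


def _subject_ids(out: Path) -> list[str]:
    return sorted(p.name for p in (out / "cohort").iterdir()
                  if p.is_dir() and p.name.startswith("sub-"))


def _pooled_mean_rt(cfg: RunConfig, out: Path) -> float:
    """Mean RT pooled over all subjects' replay presses (after trimming)."""
    frames = []
    for sid in _subject_ids(out):
        for _, events, bold in _load_runs(cfg, out, sid):
            _, ev = trim_initial_volumes(bold, events,
                                         cfg.discard_initial_volumes)
            frames.append(ev)
    return estimate_mean_rt(pd.concat(frames, ignore_index=True))


def _stage_glm(cfg: RunConfig, out: Path) -> dict:
    mean_rt = _pooled_mean_rt(cfg, out)
    per_subject = []
    for sid in _subject_ids(out):
        contrasts = []
        for run_id, events, bold in _load_runs(cfg, out, sid):
            bold_t, ev_t = trim_initial_volumes(bold, events,
                                                cfg.discard_initial_volumes)
            ev_full = pd.concat(
                [ev_t, correct_event_times(derive_switch_events(ev_t), mean_rt)],
                ignore_index=True).sort_values("onset", kind="stable")
            X = build_design_matrix(ev_full, cfg.hrf, n_vols=bold_t.n_volumes,
                                    TR=bold_t.TR)
            fit = fit_glm(bold_t, X)
            est, _t = contrast_rivalry_gt_replay(fit)
            contrasts.append(est)
        per_subject.append(np.mean(contrasts, axis=0))
    region_labels = BOLDSeries.from_tsv(
        next((out / "cohort" / _subject_ids(out)[0]).glob("*_bold.tsv"))
    ).region_labels
    group = group_contrast_ttest(np.array(per_subject))
    group.insert(0, "region", list(region_labels))
    group.to_csv(out / "glm_group_contrast.tsv", sep="\t", index=False)
    contrast_df = pd.DataFrame(np.array(per_subject), columns=region_labels)
    contrast_df.insert(0, "subject", _subject_ids(out))
    contrast_df.to_csv(out / "glm_subject_contrasts.tsv", sep="\t", index=False)
    return {"mean_rt": mean_rt,
            "group_t": dict(zip(region_labels, group["t"].tolist()))}


def _subject_timeseries(cfg: RunConfig, out: Path) -> list[SubjectTimeseries]:
    mean_rt = _pooled_mean_rt(cfg, out)
    dt = cfg.inversion_dt or cfg.cohort.dt
    subjects = []
    for sid in _subject_ids(out):
        bolds, inputs = [], []
        for run_id, events, bold in _load_runs(cfg, out, sid):
            bold_t, ev_t = trim_initial_volumes(bold, events,
                                                cfg.discard_initial_volumes)
            duration = (bold_t.n_volumes - 1) * bold_t.TR + bold_t.TR
            tl = events_to_input_timeline(
                ev_t, duration=duration, mean_rt=mean_rt, dt=dt,
                pulse_width=cfg.cohort.pulse_width)
            bolds.append(bold_t)
            inputs.append(tl)
        subjects.append(SubjectTimeseries(sid, bolds, inputs))
    return subjects


def _stage_invert(cfg: RunConfig, out: Path) -> dict:
    models = enumerate_model_space()
    save_model_space(models, out / "model_space.json")
    model_space_table(models).to_csv(out / "model_space.tsv", sep="\t",
                                     index=False)
    subjects = _subject_timeseries(cfg, out)
    E, _ = evidence_table(subjects, models, priors=cfg.priors, progress=False)
    E.to_tsv(out / "evidence.tsv")
    if E.non_converged:
        with open(out / "evidence_nonconverged.json", "w") as fh:
            json.dump([list(x) for x in E.non_converged], fh)
    return {"n_subjects": len(subjects), "n_models": len(models),
            "n_nonconverged": len(E.non_converged)}


def _stage_bms(cfg: RunConfig, out: Path) -> dict:
    from .inversion import EvidenceMatrix
    E = EvidenceMatrix.from_tsv(out / "evidence.tsv")
    models = enumerate_model_space()
    partition = partition_families(models)
    fam, mid, fam_res, model_res = select_winning(
        E, partition, prior_alpha=cfg.bms_prior_alpha,
        n_samples=cfg.bms_n_samples, seed=cfg.seed)
    result = {
        "winning_family": fam,
        "winning_model": int(mid),
        "family_level": {
            "labels": fam_res.labels,
            "alpha": fam_res.alpha.tolist(),
            "expected_freq": fam_res.expected_frequencies.tolist(),
            "exceedance": fam_res.exceedance.tolist(),
        },
        "model_level": {
            "model_ids": [int(m) for m in model_res.labels],
            "alpha": model_res.alpha.tolist(),
            "expected_freq": model_res.expected_frequencies.tolist(),
            "exceedance": model_res.exceedance.tolist(),
        },
        "n_samples": cfg.bms_n_samples,
        "seed": cfg.seed,
    }
    with open(out / "bms.json", "w") as fh:
        json.dump(result, fh, indent=1)
    return {"winning_family": fam, "winning_model": int(mid)}


def _stage_regress(cfg: RunConfig, out: Path) -> dict:
    with open(out / "bms.json") as fh:
        winning = int(json.load(fh)["winning_model"])
    model = enumerate_model_space()[winning]
    if not model.b_connections:
        raise RuntimeError(
            f"winning model {winning} carries no modulatory parameters; "
            "the coupling-difference regression is undefined")
    subjects = _subject_timeseries(cfg, out)
    fits = {}
    durations = {}
    for subj in subjects:
        fits[subj.subject_id] = invert_dcm(subj.bold_runs, subj.input_runs,
                                           model, priors=cfg.priors)
        evs = pd.concat([read_events_tsv(p) for p in sorted(
            (out / "cohort" / subj.subject_id).glob("run-*_events.tsv"))],
            ignore_index=True)
        durations[subj.subject_id] = mean_dominance_from_events(evs)
    table = compute_delta_b(fits, durations, connections=model.b_connections)
    table.to_csv(out / "delta_b.tsv", sep="\t", index=False)
    report = fit_dominance_regression(table,
                                      cooks_threshold=cfg.cooks_threshold)
    report.to_json(out / "regression.json")
    return {"r_squared": report.r_squared,
            "adj_r_squared": report.adj_r_squared,
            "f_df": list(report.f_df),
            "excluded": report.excluded_subjects}


_STAGES = {
    "simulate": _stage_simulate,
    "glm": _stage_glm,
    "invert": _stage_invert,
    "bms": _stage_bms,
    "regress": _stage_regress,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest.

    A stage failure is recorded in the manifest and the remaining stages are
    skipped rather than run on missing inputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest: dict = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    failed = False
    for name in cfg.stages:
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
        if failed:
            manifest["stages"][name] = {"status": "skipped"}
            continue
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            summary = _STAGES[name](cfg, out)
            if name == "simulate":
                summary = {"n_subjects": len(summary.subjects)}
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 3),
                "summary": summary,
            }
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            log.exception("stage %s failed", name)
            manifest["stages"][name] = {
                "status": "failed",
                "seconds": round(time.time() - t0, 3),
                "error": f"{type(exc).__name__}: {exc}",
            }
            failed = True
        log.info("stage %s: %s", name, manifest["stages"][name]["status"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
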