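"""End-to-end study replica on synthetic data.

Stages: simulate stimuli -> build nested inputs -> simulate cohort BOLD
from the reference winning-model parameters -> invert a model space per
subject -> fixed-effects BMS -> Bayesian parameter averaging -> report.
Each stage writes its artifacts under the output directory and is skipped
when they already exist, so a run can resume from cached upstream results.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .bms import (
    BMSResult,
    EvidenceTable,
    bayesian_parameter_average,
    corrected_intervals,
    ffx_bms,
    report_markdown,
)
from .design import InputSet, build_inputs, read_inputs, write_inputs
from .forward import noise_sd_for_snr, read_bold, simulate_bold, write_bold
from .invert import Posterior, default_priors, invert
from .spaces import (
    ModelSpace,
    build_demo_space,
    build_main_space,
    build_preselect1_space,
)
from .stimuli import (
    DEFAULT_HAZARD_RATE,
    FrameGeometry,
    ScheduleConfig,
    build_session,
    schedule_to_frame,
    simulate_session,
)

__all__ = ["StudyConfig", "run_pipeline", "simulate_cohort", "invert_cohort"]

_SPACES = {
    "demo": build_demo_space,
    "main": build_main_space,
    "preselect1": build_preselect1_space,
}


@dataclass
class StudyConfig:
    """Configuration of one synthetic-study run.

    Defaults reproduce the study's design dimensions: 30 blocks over three
    predictability conditions, 512 scans at TR 1.8 s, three regions and
    three nested inputs; the generating parameters are the reference
    active-run winning-model estimates at SNR 3.
    """

    n_subjects: int = 10
    seed: int = 1
    snr: float = 3.0
    n_scans: int = 512
    tr: float = 1.8
    hazard_rate: float = DEFAULT_HAZARD_RATE
    model_space: str = "demo"  # demo | main | preselect1
    occam_threshold: float = 0.01
    correction_k: int = 13
    alpha: float = 0.05
    max_iter: int = 96

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.model_space not in _SPACES:
            raise ValueError(f"unknown model space {self.model_space!r}")
        if self.snr <= 0 or self.tr <= 0 or self.n_scans < 1:
            raise ValueError("invalid scan parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def subject_rng(self, subject: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, subject))


def _subj_dir(out: Path, s: int) -> Path:
    d = out / f"sub-{s:02d}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_stimuli(cfg: StudyConfig, out: Path) -> None:
    """Per subject: counterbalanced schedule + direction-change events."""
    for s in range(1, cfg.n_subjects + 1):
        d = _subj_dir(out, s)
        if (d / "schedule.tsv").exists():
            continue
        rng = cfg.subject_rng(s)
        design = build_session(ScheduleConfig(), rng)
        events = simulate_session(design, FrameGeometry(), cfg.hazard_rate, rng)
        schedule_to_frame(design).to_csv(d / "schedule.tsv", sep="\t", index=False)
        events.to_csv(d / "events.tsv", sep="\t", index=False)


def stage_inputs(cfg: StudyConfig, out: Path) -> None:
    for s in range(1, cfg.n_subjects + 1):
        d = _subj_dir(out, s)
        if (d / "inputs.csv").exists():
            continue
        sched = pd.read_csv(d / "schedule.tsv", sep="\t")
        from .stimuli import Block, Condition, SessionDesign

        blocks = [
            Block(Condition(r.trial_type), r.duration, 0.0, r.onset)
            for r in sched.itertuples()
        ]
        design = SessionDesign(blocks, [0.0] * len(blocks))
        inputs = build_inputs(design, n_scans=cfg.n_scans, tr=cfg.tr)
        write_inputs(inputs, d / "inputs.csv")


def stage_bold(cfg: StudyConfig, out: Path) -> None:
    """Simulate each subject's BOLD from the reference generating model."""
    for s in range(1, cfg.n_subjects + 1):
        d = _subj_dir(out, s)
        if (d / "bold.csv").exists():
            continue
        inputs = read_inputs(d / "inputs.csv")
        params = reference.active_winner_params()
        params.noise_sd = noise_sd_for_snr(params, inputs, cfg.snr)
        # noise drawn from the tail of the subject stream, after design use
        rng = cfg.subject_rng(s)
        _ = build_session(ScheduleConfig(), rng)  # advance identically to stage_stimuli
        series = simulate_bold(params, inputs, seed=rng)
        write_bold(series, d / "bold.csv", meta={"snr": cfg.snr, "subject": s})


def _space(cfg: StudyConfig) -> ModelSpace:
    return _SPACES[cfg.model_space]()


def stage_invert(cfg: StudyConfig, out: Path) -> EvidenceTable:
    """Invert every model of the space for every subject (cached per pair)."""
    space = _space(cfg)
    inv_dir = out / "inversions"
    inv_dir.mkdir(parents=True, exist_ok=True)
    F = np.zeros((cfg.n_subjects, len(space)))
    for j, model in enumerate(space):
        priors = default_priors(model)
        for i in range(cfg.n_subjects):
            s = i + 1
            pfile = inv_dir / f"sub-{s:02d}_model-{model.model_id}.json"
            if pfile.exists():
                F[i, j] = json.loads(pfile.read_text())["free_energy"]
                continue
            inputs = read_inputs(_subj_dir(out, s) / "inputs.csv")
            y = read_bold(_subj_dir(out, s) / "bold.csv")
            post = invert(model, priors, y, inputs, max_iter=cfg.max_iter)
            F[i, j] = post.free_energy
            pfile.write_text(json.dumps(_post_to_dict(post), indent=1))
    ev = EvidenceTable(F, [m.model_id for m in space], [m.family for m in space])
    ev.to_frame().to_csv(out / "evidence.csv", index=False)
    return ev


def _post_to_dict(post: Posterior) -> dict:
    return {
        "names": post.names,
        "mean": post.mean.tolist(),
        "cov": post.cov.tolist(),
        "free_energy": post.free_energy,
        "n_iter": post.n_iter,
        "converged": post.converged,
        "noise_log_precision": (
            post.noise_log_precision.tolist() if post.noise_log_precision is not None else None
        ),
    }


def _post_from_dict(d: dict) -> Posterior:
    return Posterior(
        names=d["names"],
        mean=np.array(d["mean"]),
        cov=np.array(d["cov"]),
        free_energy=d["free_energy"],
        n_iter=d["n_iter"],
        converged=d["converged"],
        noise_log_precision=(
            np.array(d["noise_log_precision"]) if d.get("noise_log_precision") else None
        ),
    )


def stage_bms(cfg: StudyConfig, out: Path) -> BMSResult:
    ev = EvidenceTable.from_frame(
        pd.read_csv(out / "evidence.csv"),
        [m.family for m in _space(cfg)],
    )
    res = ffx_bms(ev, occam_threshold=cfg.occam_threshold)
    (out / "bms.json").write_text(json.dumps(res.to_dict(), indent=1))
    return res


def stage_bpa(cfg: StudyConfig, out: Path, res: BMSResult):
    winner = res.winner
    posts = []
    for s in range(1, cfg.n_subjects + 1):
        pfile = out / "inversions" / f"sub-{s:02d}_model-{winner}.json"
        posts.append(_post_from_dict(json.loads(pfile.read_text())))
    bpa = bayesian_parameter_average(posts)
    ivals = corrected_intervals(bpa, k=cfg.correction_k, alpha=cfg.alpha, seed=cfg.seed)
    (out / "bpa.json").write_text(json.dumps(bpa.to_dict(), indent=1))
    ivals.to_csv(out / "bpa_intervals.csv")
    return bpa, ivals


def run_pipeline(cfg: StudyConfig, out_dir: str | Path) -> dict:
    """Run every stage; returns a summary dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    stage_stimuli(cfg, out)
    stage_inputs(cfg, out)
    stage_bold(cfg, out)
    stage_invert(cfg, out)
    res = stage_bms(cfg, out)
    bpa, ivals = stage_bpa(cfg, out, res)
    (out / "report.md").write_text(report_markdown(res, bpa, ivals))
    summary = {
        "winner": res.winner,
        "winner_posterior": float(res.posterior_prob.max()),
        "occam_set": res.occam_set(),
        "generating_model": reference.active_winner_spec().model_id,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


# -- convenience used by tests and the acceptance script --------------------


def simulate_cohort(cfg: StudyConfig) -> list[tuple]:
    """In-memory cohort: list of (BOLDSeries, InputSet) per subject."""
    out = []
    for s in range(1, cfg.n_subjects + 1):
        rng = cfg.subject_rng(s)
        design = build_session(ScheduleConfig(), rng)
        inputs = build_inputs(design, n_scans=cfg.n_scans, tr=cfg.tr)
        params = reference.active_winner_params()
        params.noise_sd = noise_sd_for_snr(params, inputs, cfg.snr)
        out.append((simulate_bold(params, inputs, seed=rng), inputs))
    return out


def invert_cohort(cfg: StudyConfig, cohort, space: ModelSpace) -> EvidenceTable:
    F = np.zeros((len(cohort), len(space)))
    for j, model in enumerate(space):
        priors = default_priors(model)
        for i, (y, inputs) in enumerate(cohort):
            F[i, j] = invert(model, priors, y, inputs, max_iter=cfg.max_iter).free_energy
    return EvidenceTable(F, [m.model_id for m in space], [m.family for m in space])
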