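"""Cohort-level validation study: simulate -> sync -> segment -> agreement -> report.

:func:`run_validation_study` emulates the full validation campaign on a
synthetic cohort: for every task and participant it generates a paired
session (two sessions for bilateral tasks, one per side), runs each
through the processing pipeline, pools sides when a paired pre-test finds
no significant side difference, reduces each participant to a mean ROM
per system, and feeds the per-participant pairs to the agreement suite.
It emits the three summary tables of a validation report (per-task ROM /
accuracy / RMSE / MCID; per-task correlations; misplacement sensitivity),
the per-repetition ROM table they are recomputable from, Bland-Altman
plot data, and a JSON manifest with the configuration and seed.

Seeds are split per (task, participant, side, arm) from the master seed
through ``numpy``'s ``SeedSequence``, so any single session can be
regenerated in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import AgreementReport, PairedROMSample, build_report
from .pipeline import PipelineParams, process_session
from .reference import REFERENCE_ROM, TASKS
from .segment import ROMEstimate, pool_sides, side_difference_p
from .sensitivity import MisplacementComparison, misplacement_comparison
from .synth import DEFAULT_MISPLACEMENT_DEG, SimConfig, generate_session, make_template

__all__ = ["RunConfig", "StudyResult", "run_validation_study", "write_report"]

log = logging.getLogger("kinagree")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one simulated validation study.

    ``rom_bias`` maps task -> mean device-minus-reference ROM discrepancy
    (degrees); each participant's own discrepancy is drawn around it with
    SD ``rom_bias_sd``. ``between_subject_sd`` spreads the participants'
    true task amplitudes around the task target. The remaining fields
    forward to :class:`SimConfig` / :class:`PipelineParams`.
    """

    tasks: tuple[str, ...] = TASKS
    n_participants: int = 21
    seed: int = 0
    between_subject_sd: float = 5.0  # degrees
    rom_bias: dict[str, float] = field(default_factory=dict)
    rom_bias_sd: float = 2.0  # degrees
    mocap_noise_sd: float = 0.5
    imu_noise_sd: float = 1.0
    inter_system_offset: float = 2.0
    lag: float = 0.5  # seconds
    params: PipelineParams = PipelineParams()
    run_sensitivity: bool = True
    misplacement_theta: float = DEFAULT_MISPLACEMENT_DEG
    sensitivity_tasks: tuple[str, ...] = ("hip_flexion", "hip_extension")

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        unknown = [t for t in self.tasks if t not in TASKS]
        if unknown:
            raise ValueError(f"unknown task(s) {unknown}; valid: {list(TASKS)}")

    @classmethod
    def with_reference_biases(cls, **kw) -> "RunConfig":
        """Config whose per-task device biases equal the reference cohort's
        printed IMU-minus-MoCap mean differences."""
        bias = {
            t: REFERENCE_ROM[t].imu_mean - REFERENCE_ROM[t].mocap_mean for t in TASKS
        }
        return cls(rom_bias=bias, **kw)


@dataclass(frozen=True)
class StudyResult:
    reports: dict[str, AgreementReport]
    rom_table: pd.DataFrame  # task, system, participant, side, rep, rom_deg
    summary_table: pd.DataFrame  # one row per task, ROM/accuracy/RMSE/MCID columns
    correlation_table: pd.DataFrame  # one row per task, PCC/CCC columns
    ba_table: pd.DataFrame  # task, participant, mean, diff
    sensitivity: dict[str, MisplacementComparison]
    sensitivity_table: pd.DataFrame | None
    config: RunConfig


def _session_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _participant_config(cfg: RunConfig, task: str, t_idx: int, pid: int, side_idx: int,
                        target: float, bias: float) -> SimConfig:
    template = make_template(task, target_rom=target)
    return SimConfig(
        template=template,
        mocap_noise_sd=cfg.mocap_noise_sd,
        imu_noise_sd=cfg.imu_noise_sd,
        inter_system_offset=cfg.inter_system_offset,
        lag=cfg.lag,
        imu_rom_bias=bias,
        rng_seed=_session_seed(cfg.seed, t_idx, pid, side_idx),
    )


def run_validation_study(cfg: RunConfig) -> StudyResult:
    """Simulate and analyze a full cohort; deterministic under ``cfg.seed``."""
    reports: dict[str, AgreementReport] = {}
    rom_rows: list[dict] = []
    ba_rows: list[dict] = []

    for t_idx, task in enumerate(cfg.tasks):
        template = make_template(task)
        task_bias = cfg.rom_bias.get(task, 0.0)
        imu_means, mocap_means = [], []
        for pid in range(cfg.n_participants):
            prng = np.random.default_rng(_session_seed(cfg.seed, t_idx, pid, 999))
            target = max(5.0, template.target_rom + prng.normal(0.0, cfg.between_subject_sd))
            bias = task_bias + prng.normal(0.0, cfg.rom_bias_sd)
            sides = ("left", "right") if template.bilateral else ("",)
            per_side: list[tuple[ROMEstimate, ROMEstimate]] = []
            for s_idx, side in enumerate(sides):
                sim = _participant_config(cfg, task, t_idx, pid, s_idx, target, bias)
                session = generate_session(sim)
                res = process_session(session, params=cfg.params, side=side)
                per_side.append((res.rom_imu, res.rom_mocap))
            if len(per_side) == 2:
                p_side = side_difference_p(per_side[0][1], per_side[1][1])
                log.debug("%s participant %d side pre-test p=%.3f", task, pid, p_side)
                if p_side > 0.05:
                    rom_imu = pool_sides(per_side[0][0], per_side[1][0])
                    rom_mocap = pool_sides(per_side[0][1], per_side[1][1])
                else:
                    # significant side difference: keep the first side only
                    rom_imu, rom_mocap = per_side[0]
            else:
                rom_imu, rom_mocap = per_side[0]
            for est in (rom_imu, rom_mocap):
                for rep, rom in enumerate(est.per_rep_rom):
                    rom_rows.append(
                        dict(task=task, system=est.system, participant=pid,
                             side=est.side, rep=rep, rom_deg=rom)
                    )
            imu_means.append(rom_imu.mean_rom)
            mocap_means.append(rom_mocap.mean_rom)
        sample = PairedROMSample(np.array(imu_means), np.array(mocap_means), task)
        reports[task] = build_report(sample)
        for pid, (a, b) in enumerate(zip(sample.imu, sample.mocap)):
            ba_rows.append(dict(task=task, participant=pid, mean=(a + b) / 2, diff=a - b))
        log.info(
            "%s: accuracy %.1f%%, RMSE %.2f deg, PCC %.2f, CCC %.2f",
            task, reports[task].accuracy, reports[task].rmse,
            reports[task].pcc, reports[task].ccc,
        )

    summary = pd.DataFrame(
        [
            dict(
                task=r.task_name, n=r.n,
                rom_imu_mean=r.mean_rom_imu, rom_imu_sd=r.sd_imu,
                rom_mocap_mean=r.mean_rom_mocap, rom_mocap_sd=r.sd_mocap,
                abs_diff=r.abs_diff, accuracy_pct=r.accuracy, rmse=r.rmse,
                mcid=r.mcid, mcid_exceeded=r.mcid_exceeded,
            )
            for r in reports.values()
        ]
    )
    correlation = pd.DataFrame(
        [
            dict(task=r.task_name, pcc=r.pcc, pcc_p=r.pcc_p, ccc=r.ccc,
                 normality_p=r.normality_p)
            for r in reports.values()
        ]
    )

    sensitivity: dict[str, MisplacementComparison] = {}
    sens_table = None
    if cfg.run_sensitivity:
        sens_rows = []
        for t_idx, task in enumerate(cfg.sensitivity_tasks):
            template = make_template(task)
            sim = SimConfig(
                template=template,
                mocap_noise_sd=cfg.mocap_noise_sd,
                imu_noise_sd=cfg.imu_noise_sd,
                inter_system_offset=cfg.inter_system_offset,
                lag=cfg.lag,
                rng_seed=_session_seed(cfg.seed, 7000 + t_idx),
            )
            comp = misplacement_comparison(
                sim, theta_deg=cfg.misplacement_theta, params=cfg.params
            )
            sensitivity[task] = comp
            sens_rows.append(
                dict(
                    task=task,
                    rom_correct=comp.rom_correct.mean_rom,
                    sd_correct=comp.rom_correct.sd_rom,
                    rom_medial=comp.rom_medial.mean_rom,
                    sd_medial=comp.rom_medial.sd_rom,
                    rom_lateral=comp.rom_lateral.mean_rom,
                    sd_lateral=comp.rom_lateral.sd_rom,
                    rmse_medial=comp.rmse_medial,
                    rmse_lateral=comp.rmse_lateral,
                )
            )
        sens_table = pd.DataFrame(sens_rows)

    return StudyResult(
        reports=reports,
        rom_table=pd.DataFrame(rom_rows),
        summary_table=summary,
        correlation_table=correlation,
        ba_table=pd.DataFrame(ba_rows),
        sensitivity=sensitivity,
        sensitivity_table=sens_table,
        config=cfg,
    )


def write_report(result: StudyResult, out_dir) -> Path:
    """Write the report bundle (CSV tables + JSON manifest) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.2f"
    result.summary_table.to_csv(out / "rom_summary.csv", index=False, float_format=fmt)
    result.correlation_table.to_csv(out / "correlations.csv", index=False, float_format="%.4f")
    result.rom_table.to_csv(out / "rom_per_repetition.csv", index=False, float_format="%.4f")
    result.ba_table.to_csv(out / "bland_altman.csv", index=False, float_format="%.4f")
    if result.sensitivity_table is not None:
        result.sensitivity_table.to_csv(out / "misplacement.csv", index=False, float_format=fmt)
    cfg = asdict(result.config)
    cfg["params"] = asdict(result.config.params)
    manifest = {
        "config": cfg,
        "seed": result.config.seed,
        "tasks": list(result.config.tasks),
        "reports": {k: v.to_dict() for k, v in result.reports.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
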