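"""End-to-end orchestration, configuration and table I/O.

``run_all`` chains the stages — simulate (or ingest) → segment →
extract → fit → report — into one run directory with a manifest
(seed, config hash, per-file checksums), so a rerun with the same
config and seed is bit-identical for tables and JSON outputs.

The demo configuration couples a reduced voxel-level branch (one
subject, a few sessions, through registration, fusion and feature
extraction) with a full-length tabular simulation for the trajectory
stage; the voxel branch demonstrates the segmentation ensemble at
desk scale while the trajectory models see the full 3 x 20-session
design.  When a directory of real image/label pairs plus a session
table is supplied, the simulate stage is skipped and the pipeline is
identical from segmentation onward (untested against the original
study scans, which are request-only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import fusion, gamm, synthetic
from .volumes import ANTERIOR, POSTERIOR, ImageVolume, LabelMap

log = logging.getLogger("pitgrowth")

REQUIRED_TABLE_COLUMNS = ["subject_id", "session_id", "weeks"]


@dataclass
class PipelineConfig:
    """Everything a reproducible demo run needs; YAML round-trippable."""

    seed: int = 0
    # tabular generator
    n_subjects: int = 3
    sessions_per_subject: int = 20
    rho: float = 0.34
    residual_sd: float = 0.45
    subject_intercept_sd: float = 0.3
    trajectory_shape: str = "default"  # "default" | "flat"
    # voxel branch
    imaging_subjects: int = 1
    imaging_sessions: int = 5
    grid_size: int = 48
    voxel_size_mm: float = 0.8
    noise_sd: float = 10.0
    deformation_scale_mm: float = 0.5
    # segmentation
    registration_mode: str = "affine+deformable"
    include_native: bool = True
    # trajectory model
    k: int = 10
    bonferroni_m: int = 2
    grid_step_weeks: float = 0.1
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def truth(self) -> synthetic.TrajectoryTruth:
        f = (
            synthetic.flat_trajectory()
            if self.trajectory_shape == "flat"
            else synthetic.make_default_trajectory()
        )
        return synthetic.TrajectoryTruth(
            f_true=f,
            subject_intercept_sd=self.subject_intercept_sd,
            residual_sd=self.residual_sd,
            rho=self.rho,
            n_subjects=self.n_subjects,
            sessions_per_subject=self.sessions_per_subject,
            seed=self.seed,
        )

    def phantom(self) -> synthetic.PhantomSpec:
        return synthetic.PhantomSpec(
            grid_shape=(self.grid_size,) * 3,
            voxel_size_mm=self.voxel_size_mm,
            noise_sd=self.noise_sd,
            deformation_scale_mm=self.deformation_scale_mm,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# session-table I/O
# ---------------------------------------------------------------------------


def write_session_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"session table missing required columns: {missing}")
    table.to_csv(path, index=False)


def read_session_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"session table missing required columns: {missing}")
    table["weeks"] = pd.to_numeric(table["weeks"])
    dup = table.duplicated(subset=["subject_id", "session_id"])
    if dup.any():
        pairs = table.loc[dup, ["subject_id", "session_id"]].to_records(index=False)
        raise ValueError(f"duplicate (subject, session) rows: {list(pairs)}")
    same_week = table.duplicated(subset=["subject_id", "weeks"])
    if same_week.any():
        warnings.warn("repeated observation weeks within a subject", stacklevel=2)
    return table


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, run_dir: Path) -> dict:
    truth = config.truth()
    table = synthetic.simulate_feature_table(truth)
    write_session_table(table, run_dir / "sim_features.csv")

    spec = config.phantom()
    img_dir = run_dir / "images"
    img_dir.mkdir(exist_ok=True)
    imaging_truth = dataclasses.replace(
        truth, sessions_per_subject=config.imaging_sessions
    )
    voxel_series = {}
    for s in range(config.imaging_subjects):
        sessions = synthetic.simulate_image_series(spec, imaging_truth, subject=s)
        sub = f"sub-{s + 1:02d}"
        for sess in sessions:
            stem = f"{sub}_{sess['session_id']}"
            sess["image"].save(img_dir / f"{stem}_T1.nii.gz")
            sess["labels"].save(img_dir / f"{stem}_labels.nii.gz")
        voxel_series[sub] = sessions
    return {"table": table, "voxel_series": voxel_series}


def stage_segment(config: PipelineConfig, run_dir: Path, voxel_series: dict) -> dict:
    qc_rows = []
    fused_series = {}
    for sub, sessions in voxel_series.items():
        images = [s["image"] for s in sessions]
        labels = [s["labels"] for s in sessions]
        fused = []
        for t in range(len(sessions)):
            result = fusion.fuse_target_session(
                images, labels, t,
                mode=config.registration_mode,
                include_native=config.include_native,
            )
            fused.append(result)
            result.fused.save(
                run_dir / "images" / f"{sub}_{sessions[t]['session_id']}_fused.nii.gz"
            )
            qc_rows.append(
                {
                    "subject_id": sub,
                    "session_id": sessions[t]["session_id"],
                    "n": result.n,
                    "ties": result.tie_voxels,
                    "dice_anterior": result.dice_vs_native[ANTERIOR],
                    "dice_posterior": result.dice_vs_native[POSTERIOR],
                    "vol_anterior_mm3": result.volumes_mm3[ANTERIOR],
                    "vol_posterior_mm3": result.volumes_mm3[POSTERIOR],
                }
            )
        fused_series[sub] = fused
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(run_dir / "fusion_qc.csv", index=False)
    return {"qc": qc, "fused_series": fused_series}


def stage_extract(
    config: PipelineConfig, run_dir: Path, voxel_series: dict, fused_series: dict
) -> pd.DataFrame:
    frames = []
    for sub, sessions in voxel_series.items():
        rows = [
            {
                "session_id": s["session_id"],
                "weeks": s["weeks"],
                "phase": synthetic.phase_of_week(s["weeks"]),
                "image": s["image"],
                "fused": fused_series[sub][i].fused,
            }
            for i, s in enumerate(sessions)
        ]
        frames.append(feat.build_feature_table(rows, sub))
    table = pd.concat(frames, ignore_index=True)
    table = feat.add_person_centered_columns(table)
    write_session_table(table, run_dir / "imaging_features.csv")
    return table


def stage_fit(config: PipelineConfig, run_dir: Path, table: pd.DataFrame) -> dict:
    table = feat.add_person_centered_columns(table)
    summaries = {}
    responses = ["z_vol_anterior", "z_vol_posterior"]
    for resp in responses:
        fit = gamm.fit_gamm(table, resp, k=config.k)
        band = gamm.derivative_inference(fit, grid_step=config.grid_step_weeks)
        ext = gamm.principal_extrema(band)
        diag = gamm.residual_diagnostics(fit)
        loso = gamm.loso_cv(table, resp, k=config.k)
        summaries[resp] = {
            "edf": fit.edf,
            "adj_r2": fit.adj_r2,
            "f_stat": fit.f_stat,
            "p_smooth": fit.f_pvalue,
            "p_smooth_bonf": min(1.0, fit.f_pvalue * config.bonferroni_m),
            "rho": fit.rho,
            "sigma_e": float(np.sqrt(fit.sigma2_e)),
            "sigma_b": float(np.sqrt(fit.sigma2_b)),
            "lambda": fit.lam,
            "aic": fit.aic,
            "converged": fit.converged,
            "extrema": {
                key: (
                    None
                    if val is None
                    else {"week": val["week"], "value_sd": val["value_sd"]}
                )
                for key, val in ext.items()
            },
            "significant_intervals": band.significant_intervals,
            "loso": loso,
            "diagnostics": diag,
        }
        pd.DataFrame(
            {
                "weeks": band.grid,
                "deriv": band.deriv,
                "lower": band.lower,
                "upper": band.upper,
            }
        ).to_csv(run_dir / f"derivative_{resp}.csv", index=False)
    for window, name in ((gamm.EARLY_WINDOW, "early"), (gamm.LATE_WINDOW, "late")):
        wfit = gamm.fit_window_lmm(table, *window, response_column="z_vol_anterior")
        summaries[f"window_{name}"] = {
            "lo_week": wfit.lo_week,
            "hi_week": wfit.hi_week,
            "slope_sd_per_week": wfit.slope,
            "slope_se": wfit.slope_se,
            "pvalue": wfit.pvalue,
            "n_obs": wfit.n_obs,
        }
    (run_dir / "fit_summaries.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True)
    )
    _plot_trajectories(config, run_dir, table)
    return summaries


def _plot_trajectories(config: PipelineConfig, run_dir: Path, table: pd.DataFrame):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharex=True)
    for ax, resp, title in zip(
        axes, ["z_vol_anterior", "z_vol_posterior"], ["Anterior lobe", "Posterior lobe"]
    ):
        fit = gamm.fit_gamm(table, resp, k=config.k)
        grid = np.linspace(table["weeks"].min(), table["weeks"].max(), 400)
        ax.plot(grid, fit.predict(grid), color="k", lw=2)
        for sub, g in table.groupby("subject_id"):
            ax.plot(g["weeks"], g[resp], "o", ms=4, alpha=0.6, label=sub)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(title)
        ax.set_xlabel("weeks relative to conception")
        ax.set_ylabel("person-centred volume (SD)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(run_dir / "trajectories.png", dpi=120)
    plt.close(fig)


def run_all(config: PipelineConfig, out_dir) -> Path:
    """Execute the full pipeline into ``out_dir`` and write a manifest."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    config.to_yaml(run_dir / "config.yaml")

    stage = "simulate"
    try:
        sim = stage_simulate(config, run_dir)
        stage = "segment"
        seg = stage_segment(config, run_dir, sim["voxel_series"])
        stage = "extract"
        stage_extract(config, run_dir, sim["voxel_series"], seg["fused_series"])
        stage = "fit"
        stage_fit(config, run_dir, sim["table"])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    cfg_text = (run_dir / "config.yaml").read_text()
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "files": {
            str(p.relative_to(run_dir)): _sha256(p)
            for p in sorted(run_dir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return run_dir
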