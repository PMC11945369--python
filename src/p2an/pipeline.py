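"""Experiment orchestration: simulate -> train -> evaluate, from one config.

A single seeded :class:`ExperimentConfig` (YAML on disk) drives the whole
study: synthetic geometry and transfer matrix, the healthy standard TMP,
training corpora and the four evaluation datasets (ischemia, hypertrophy,
and their noisy variants), training of the attention model and of the two
baselines, and the metric/statistics tables.  Every random draw derives
from the one top-level seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh as _trimesh
import yaml
from scipy.io import mmread, mmwrite

from . import baselines as bl
from . import metrics as mt
from . import simulate as sim
from .geometry import (ElectrodeArray, TransferMatrix, TriMesh,
                       build_transfer_matrix, generate_electrodes,
                       generate_sphere_mesh)
from .model import ModelConfig, P2ANModel, Scaler, make_scaler, train

log = logging.getLogger("p2an")

SOLVERS = ("p2an", "ista_net", "ffnn")


@dataclass
class ExperimentConfig:
    # geometry
    m_nodes: int = 128
    n_electrodes: int = 64
    heart_radius: float = 50.0
    torso_radius: float = 200.0
    # simulator
    dt: float = 4.0                 # ms
    duration: float = 480.0         # ms
    pacing_node: int = 0
    conduction_velocity: float = 2.0  # mm/ms
    apd: float = 250.0
    lesion_radius: float = 15.0
    # datasets
    n_eval_cases: int = 20
    n_train_cases: int = 200
    snr_levels_db: tuple[float, ...] = sim.NOISE_SNR_LEVELS_DB
    tasks: tuple[str, ...] = (sim.MI, sim.VH)
    # solvers
    p2an: dict = field(default_factory=dict)     # ModelConfig overrides
    ista: dict = field(default_factory=dict)     # ISTAConfig overrides
    ffnn: dict = field(default_factory=dict)     # FFNNConfig overrides
    solvers: tuple[str, ...] = SOLVERS
    # lesion-detection thresholds
    threshold_frac: float = 0.85
    threshold_delay: float = 10.0
    # bookkeeping
    seed: int = 0
    outdir: str = "runs/default"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("snr_levels_db", "tasks", "solvers"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        for key in ("p2an", "ista", "ffnn"):
            d = getattr(cfg, key)
            for k, v in d.items():
                if isinstance(v, list):
                    d[k] = tuple(v)
        bad = [s for s in cfg.solvers if s not in SOLVERS]
        if bad:
            raise ValueError(f"unregistered solvers {bad}; known: {SOLVERS}")
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("snr_levels_db", "tasks", "solvers"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def model_config(self) -> ModelConfig:
        return ModelConfig(**{"seed": self.seed + 11, **self.p2an})

    def ista_config(self) -> bl.ISTAConfig:
        return bl.ISTAConfig(**{"seed": self.seed + 12, **self.ista})

    def ffnn_config(self) -> bl.FFNNConfig:
        return bl.FFNNConfig(**{"seed": self.seed + 13, **self.ffnn})


def study_config(seed: int = 0) -> ExperimentConfig:
    """The configuration used to reproduce the headline experiments.

    Full spatial scale (128 source nodes, 64 electrodes, 20 evaluation cases
    per task, 200 training cases) with the time grid at 4 ms over 480 ms and
    compact training schedules -- sizes chosen so the whole two-task study
    runs on a single CPU in minutes; see the methods note.
    """
    return ExperimentConfig(
        seed=seed,
        p2an={"epochs": 35, "batch_size": 10, "d_ff": 128},
        ista={"epochs": 6, "learning_rate": 1e-2},
        ffnn={"epochs": 40},
    )


@dataclass
class Environment:
    """Shared physical setting of one experiment."""

    mesh: TriMesh
    electrodes: ElectrodeArray
    H: TransferMatrix
    time_grid: np.ndarray
    std_params: list
    U_std: np.ndarray
    scaler: Scaler


def build_environment(config: ExperimentConfig) -> Environment:
    mesh = generate_sphere_mesh(config.m_nodes, config.heart_radius)
    electrodes = generate_electrodes(
        config.n_electrodes, config.torso_radius, seed=config.seed + 1
    )
    H = build_transfer_matrix(mesh, electrodes)
    time_grid = sim.default_time_grid(config.dt, config.duration)
    U_std, std_params = sim.standard_tmp(
        mesh,
        pacing_node=config.pacing_node,
        conduction_velocity=config.conduction_velocity,
        apd=config.apd,
        time_grid=time_grid,
    )
    scaler = make_scaler(U_std, H.entries, std_params)
    return Environment(mesh, electrodes, H, time_grid, std_params, U_std, scaler)


# ---------------------------------------------------------------------------
# dataset + training orchestration
# ---------------------------------------------------------------------------

def simulate_task(config: ExperimentConfig, env: Environment, task: str):
    """Evaluation dataset (with noisy variants) + disjoint training corpus."""
    kind = 3 if task == sim.MI else 4   # kinds 3/4 carry the noisy BSP too
    eval_seed = config.seed + (2 if task == sim.MI else 3)
    eval_cases = sim.build_dataset(
        kind, config.n_eval_cases, env.mesh, env.H, env.std_params,
        env.U_std, env.time_grid, seed=eval_seed,
        lesion_radius=config.lesion_radius,
        snr_levels_db=config.snr_levels_db,
    )
    eval_centers = np.array([c.lesion.center_node for c in eval_cases])
    train_cases = sim.build_training_corpus(
        task, config.n_train_cases, env.mesh, env.H, env.std_params,
        env.U_std, env.time_grid,
        seed=config.seed + (4 if task == sim.MI else 5),
        lesion_radius=config.lesion_radius, exclude_centers=eval_centers,
    )
    return eval_cases, train_cases


def train_solver(config: ExperimentConfig, env: Environment, train_cases,
                 solver: str):
    t0 = time.time()
    if solver == "p2an":
        res = train(train_cases, config.model_config(), env.H.entries,
                    scaler=env.scaler)
        model = P2ANModel(res, env.U_std)
    elif solver == "ista_net":
        model = bl.train_ista_net(train_cases, config.ista_config(),
                                  env.H.entries, env.scaler)
    elif solver == "ffnn":
        model = bl.train_ffnn(train_cases, config.ffnn_config(),
                              env.H.entries, env.scaler)
    else:
        raise ValueError(f"unknown solver {solver!r}; registered: {SOLVERS}")
    log.info("trained %s in %.1f s", solver, time.time() - t0)
    return model


def evaluate_solver(model, eval_cases, env: Environment,
                    config: ExperimentConfig) -> pd.DataFrame:
    """Per-case metrics at every noise level (inf = clean).

    All (case, noise-level) BSP records are reconstructed in one batched
    call; the metrics are then computed per record.
    """
    conditions = []
    for j, case in enumerate(eval_cases):
        for snr in (None, *sorted(case.bsp_noisy, reverse=True)):
            conditions.append((j, case, snr))
    stack = np.stack([case.bsp(snr) for _, case, snr in conditions])
    U_hats = np.asarray(model.reconstruct(stack))
    rows = []
    for (j, case, snr), U_hat in zip(conditions, U_hats):
        le, _ = mt.localize(
            U_hat, case, env.mesh, env.time_grid,
            threshold_frac=config.threshold_frac,
            threshold_delay=config.threshold_delay,
        )
        rows.append({
            "case_id": f"{case.lesion.kind}-{j:02d}",
            "task": case.lesion.kind,
            "solver": model.name,
            "snr_db": np.inf if snr is None else snr,
            "RE": mt.relative_error(U_hat, case.U_true),
            "CC": mt.correlation_coeff(U_hat, case.U_true),
            "LE_mm": le,
        })
    return pd.DataFrame(rows)


def summary_table(metrics: pd.DataFrame, clean_only=True) -> pd.DataFrame:
    """'mean (SD)' table: rows RE/CC/LE (mm), columns one per solver."""
    df = metrics[np.isinf(metrics["snr_db"])] if clean_only else metrics
    out = {}
    for solver, g in df.groupby("solver", sort=False):
        out[solver] = {
            name: f"{g[col].mean():.3f} ({g[col].std(ddof=1):.3f})"
            for name, col in (("RE", "RE"), ("CC", "CC"), ("LE (mm)", "LE_mm"))
        }
    cols = [s for s in ("P2AN", "ISTA", "FFNN") if s in out]
    return pd.DataFrame(out)[cols]


def noise_stats(metrics: pd.DataFrame) -> dict:
    """Paired comparisons of P2AN vs each baseline on RE and LE, noisy cases
    pooled over all SNR levels."""
    noisy = metrics[~np.isinf(metrics["snr_db"])]
    pivots = {}
    for col in ("RE", "LE_mm"):
        p = noisy.pivot_table(index=["case_id", "snr_db"], columns="solver",
                              values=col)
        pivots[col] = mt.compare_methods(
            {s: p[s].to_numpy() for s in p.columns},
            metric_name=col,
        )
    return {k: v.to_dict() for k, v in pivots.items()}


def run_task(config: ExperimentConfig, env: Environment, task: str) -> dict:
    """Full per-task pipeline: simulate, train all solvers, evaluate."""
    eval_cases, train_cases = simulate_task(config, env, task)
    models = {
        s: train_solver(config, env, train_cases, s) for s in config.solvers
    }
    metrics = pd.concat(
        [evaluate_solver(m, eval_cases, env, config) for m in models.values()],
        ignore_index=True,
    )
    return {
        "task": task,
        "eval_cases": eval_cases,
        "train_cases": train_cases,
        "models": models,
        "metrics": metrics,
        "stats": noise_stats(metrics),
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Both tasks end to end; returns per-task results keyed by task name."""
    env = build_environment(config)
    results = {"env": env, "config": config}
    for task in config.tasks:
        log.info("running %s task", task)
        results[task] = run_task(config, env, task)
    return results


def experiment_targets(results: dict) -> dict:
    """Headline quantities of the study, computed from a finished run.

    Mean RE/CC/LE of the attention model on the clean ischemia set, mean
    RE/LE on the clean hypertrophy set, mean RE at the worst (15 dB) noise
    level, and the minimum |Cohen's d| over the paired noise-robustness
    comparisons against both baselines on RE and LE.
    """
    out = {}
    mi = results[sim.MI]["metrics"]
    p_clean = mi[(mi.solver == "P2AN") & np.isinf(mi.snr_db)]
    out["mi_re"] = float(p_clean["RE"].mean())
    out["mi_cc"] = float(p_clean["CC"].mean())
    out["mi_le_mm"] = float(p_clean["LE_mm"].mean())
    vh = results[sim.VH]["metrics"]
    v_clean = vh[(vh.solver == "P2AN") & np.isinf(vh.snr_db)]
    out["vh_re"] = float(v_clean["RE"].mean())
    out["vh_le_mm"] = float(v_clean["LE_mm"].mean())
    p15 = mi[(mi.solver == "P2AN") & (mi.snr_db == 15.0)]
    out["mi_re_15db"] = float(p15["RE"].mean())
    ds = []
    for task in (sim.MI, sim.VH):
        if task not in results:
            continue
        for col in ("RE", "LE_mm"):
            pairs = results[task]["stats"][col]["pairs"]
            for name, rec in pairs.items():
                if "P2AN" in name:
                    ds.append(abs(rec["cohens_d"]))
    out["min_abs_cohens_d"] = float(min(ds)) if ds else float("nan")
    out["n_eval_cases"] = int(len(p_clean))
    return out


# ---------------------------------------------------------------------------
# file I/O: meshes (OFF), transfer matrix (MatrixMarket), CSV, manifests
# ---------------------------------------------------------------------------

def save_mesh_off(mesh: TriMesh, path: str | Path) -> None:
    mesh.to_trimesh().export(str(path), file_type="off")

def load_mesh_off(path: str | Path) -> TriMesh:
    tm = _trimesh.load(str(path), file_type="off", process=False)
    return TriMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))

def save_matrix_mtx(H: TransferMatrix | np.ndarray, path: str | Path) -> None:
    m = H.entries if isinstance(H, TransferMatrix) else np.asarray(H)
    mmwrite(str(path), m)

def load_matrix_mtx(path: str | Path) -> np.ndarray:
    return np.asarray(mmread(str(path)))

def save_electrodes_csv(arr: ElectrodeArray, path: str | Path) -> None:
    df = pd.DataFrame(arr.positions, columns=["x", "y", "z"])
    df.index.name = "id"
    df.to_csv(path)

def load_electrodes_csv(path: str | Path) -> ElectrodeArray:
    df = pd.read_csv(path, index_col="id")
    return ElectrodeArray(positions=df[["x", "y", "z"]].to_numpy())


def file_manifest(directory: str | Path) -> dict:
    """Inventory of every file under ``directory`` with sha256 checksums."""
    d = Path(directory)
    files = {}
    for p in sorted(d.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(d))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return files


def write_manifest(directory: str | Path, config: ExperimentConfig,
                   stage: str) -> dict:
    d = Path(directory)
    cfg_yaml = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    manifest = {
        "stage": stage,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": file_manifest(d),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
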