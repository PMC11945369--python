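"""Simulation of standard and lesioned transmembrane potentials and BSP.

Action potentials are modelled as a smooth two-sigmoid template

    V(t) = resting + amplitude * sigma((t - t_dep)/w_up) * sigma((t_rep - t)/w_rec)

with a fast upstroke at the depolarization time ``t_dep`` and a slower
recovery ending at the repolarization time ``t_rep``.  A healthy "standard"
activation sequence is produced by pacing one node and propagating activation
along graph geodesics of the heart mesh at a fixed conduction velocity.

Two lesion families are simulated:

* myocardial ischemia (MI): the action-potential amplitude of all nodes
  within a Euclidean ball around a center node is reduced by a severity
  fraction (study range 25-80%);
* ventricular hypertrophy (VH): depolarization (and with it repolarization)
  of the nodes in the ball is delayed by 25-50 ms.

BSP is obtained through the EDL forward model; measurement noise is additive
Gaussian calibrated to a global (all-lead) signal-to-noise ratio in dB.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.special import expit

from .geometry import GeometryError, TransferMatrix, TriMesh, forward_bsp

MI = "MI"
VH = "VH"

#: severity / delay ranges used throughout the study
MI_SEVERITY_RANGE = (0.25, 0.80)
VH_DELAY_RANGE_MS = (25.0, 50.0)
NOISE_SNR_LEVELS_DB = (30.0, 25.0, 20.0, 15.0)


@dataclass(frozen=True)
class APParams:
    """Action-potential template parameters for one node."""

    t_dep: float            # ms
    t_rep: float            # ms
    amplitude: float = 100.0   # mV
    resting: float = -90.0     # mV
    upstroke_width: float = 2.0    # ms
    recovery_width: float = 12.0   # ms

    def validate(self) -> None:
        if not self.t_rep > self.t_dep:
            raise ValueError(f"t_rep ({self.t_rep}) must exceed t_dep ({self.t_dep})")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.upstroke_width <= 0 or self.recovery_width <= 0:
            raise ValueError("widths must be > 0")


@dataclass(frozen=True)
class LesionSpec:
    """Ground-truth lesion description."""

    kind: str                   # "MI" or "VH"
    center_node: int
    radius: float = 15.0        # mm, Euclidean ball
    severity: float | None = None   # MI: fractional amplitude drop
    delay: float | None = None      # VH: depolarization delay, ms

    def validate(self, n_nodes: int) -> None:
        if self.kind not in (MI, VH):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if not 0 <= self.center_node < n_nodes:
            raise ValueError(f"center_node {self.center_node} out of range")
        if self.kind == MI:
            if self.severity is None:
                raise ValueError("MI lesion requires a severity")
            lo, hi = MI_SEVERITY_RANGE
            if not (0.0 <= self.severity <= 1.0):
                raise ValueError("severity must be a fraction in [0, 1]")
        else:
            if self.delay is None:
                raise ValueError("VH lesion requires a delay")
            if self.delay < 0:
                raise ValueError("delay must be >= 0")


@dataclass
class SimCase:
    """One simulated record: ground truth, prior and measurements."""

    lesion: LesionSpec | None
    U_true: np.ndarray          # (M, L) mV
    U_std: np.ndarray           # (M, L) mV, healthy prior
    bsp_clean: np.ndarray       # (N, L) mV
    affected_nodes: np.ndarray  # lesion node indices (empty if no lesion)
    seed: int = 0
    bsp_noisy: dict[float, np.ndarray] = field(default_factory=dict)  # snr_db -> (N,L)

    def bsp(self, snr_db: float | None = None) -> np.ndarray:
        if snr_db is None or np.isinf(snr_db):
            return self.bsp_clean
        return self.bsp_noisy[snr_db]


def ap_waveform(time_grid: np.ndarray, p: APParams) -> np.ndarray:
    """Evaluate the two-sigmoid action-potential template on a time grid (mV)."""
    p.validate()
    t = np.asarray(time_grid, dtype=float)
    up = expit((t - p.t_dep) / p.upstroke_width)
    down = expit((p.t_rep - t) / p.recovery_width)
    return p.resting + p.amplitude * up * down


def tmp_from_params(params: list[APParams], time_grid: np.ndarray) -> np.ndarray:
    """Stack per-node templates into an (M, L) TMP matrix."""
    return np.vstack([ap_waveform(time_grid, p) for p in params])


def standard_tmp(
    mesh: TriMesh,
    pacing_node: int,
    conduction_velocity: float = 2.0,   # mm/ms
    apd: float = 250.0,                 # ms, action-potential duration
    base: APParams | None = None,
    time_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, list[APParams]]:
    """Healthy reference TMP: pacing-node activation spread at fixed velocity.

    Per node, t_dep = base.t_dep + geodesic(mesh graph) / velocity and
    t_rep = t_dep + apd; amplitudes are uniform.  Returns the (M, L) matrix
    and the per-node template parameters (used downstream for lesioning).
    """
    if conduction_velocity <= 0:
        raise ValueError("conduction_velocity must be > 0")
    if base is None:
        base = APParams(t_dep=20.0, t_rep=20.0 + apd)
    if time_grid is None:
        time_grid = default_time_grid()
    dist = dijkstra(mesh.edge_graph(), indices=pacing_node)
    if not np.all(np.isfinite(dist)):
        raise GeometryError("mesh graph is disconnected")
    params = [
        replace(
            base,
            t_dep=base.t_dep + d / conduction_velocity,
            t_rep=base.t_dep + d / conduction_velocity + apd,
        )
        for d in dist
    ]
    return tmp_from_params(params, time_grid), params


def default_time_grid(dt: float = 1.0, duration: float = 500.0) -> np.ndarray:
    """Uniform grid [0, duration) in ms; defaults to 1 ms over 500 ms."""
    return np.arange(0.0, duration, dt)


def apply_lesion(
    std_params: list[APParams], mesh: TriMesh, lesion: LesionSpec
) -> tuple[list[APParams], np.ndarray]:
    """Modify per-node templates inside the lesion ball; others untouched.

    Returns (new params, affected node indices).  If the radius captures no
    node beyond numerical reach, the center node alone is affected (with a
    warning).
    """
    lesion.validate(mesh.n_vertices)
    d = np.linalg.norm(
        mesh.vertices - mesh.vertices[lesion.center_node], axis=1
    )
    affected = np.nonzero(d <= lesion.radius)[0]
    if affected.size == 0:
        warnings.warn("lesion radius captured no node; using center node only")
        affected = np.array([lesion.center_node])
    out = list(std_params)
    for i in affected:
        p = out[i]
        if lesion.kind == MI:
            out[i] = replace(p, amplitude=p.amplitude * (1.0 - lesion.severity))
        else:
            out[i] = replace(
                p, t_dep=p.t_dep + lesion.delay, t_rep=p.t_rep + lesion.delay
            )
    return out, affected


def add_gaussian_noise(
    bsp: np.ndarray, snr_db: float, seed: int = 0
) -> np.ndarray:
    """Additive zero-mean Gaussian noise at a global SNR (dB).

    Noise variance is set from the mean signal power over all leads and
    samples so that 10*log10(P_signal / P_noise) = snr_db in expectation.
    ``snr_db = inf`` is the no-noise path.
    """
    bsp = np.asarray(bsp, dtype=float)
    if np.isinf(snr_db):
        return bsp.copy()
    p_signal = np.mean(bsp**2)
    p_noise = p_signal / (10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    return bsp + rng.normal(0.0, np.sqrt(p_noise), size=bsp.shape)


def measured_snr_db(noisy: np.ndarray, clean: np.ndarray) -> float:
    """Empirical SNR of (noisy - clean) against clean, in dB."""
    p_n = np.mean((np.asarray(noisy) - np.asarray(clean)) ** 2)
    return float(10.0 * np.log10(np.mean(np.asarray(clean) ** 2) / p_n))


# ---------------------------------------------------------------------------
# case and dataset construction
# ---------------------------------------------------------------------------

def make_case(
    mesh: TriMesh,
    H: TransferMatrix | np.ndarray,
    std_params: list[APParams],
    U_std: np.ndarray,
    time_grid: np.ndarray,
    lesion: LesionSpec | None,
    seed: int = 0,
    snr_levels_db: tuple[float, ...] = (),
) -> SimCase:
    """Simulate one record: lesioned TMP, clean BSP, optional noisy BSP."""
    if lesion is None:
        U_true = U_std.copy()
        affected = np.array([], dtype=np.int64)
    else:
        les_params, affected = apply_lesion(std_params, mesh, lesion)
        U_true = tmp_from_params(les_params, time_grid)
    bsp_clean = forward_bsp(H, U_true)
    case = SimCase(
        lesion=lesion,
        U_true=U_true,
        U_std=U_std,
        bsp_clean=bsp_clean,
        affected_nodes=affected,
        seed=seed,
    )
    for k, snr in enumerate(snr_levels_db):
        case.bsp_noisy[snr] = add_gaussian_noise(bsp_clean, snr, seed=seed + 7919 * (k + 1))
    return case


def _sample_lesion(kind: str, center: int, radius: float, rng) -> LesionSpec:
    if kind == MI:
        lo, hi = MI_SEVERITY_RANGE
        return LesionSpec(kind=MI, center_node=center, radius=radius,
                          severity=float(rng.uniform(lo, hi)))
    lo, hi = VH_DELAY_RANGE_MS
    return LesionSpec(kind=VH, center_node=center, radius=radius,
                      delay=float(rng.uniform(lo, hi)))


def build_dataset(
    kind: int,
    n_cases: int,
    mesh: TriMesh,
    H: TransferMatrix | np.ndarray,
    std_params: list[APParams],
    U_std: np.ndarray,
    time_grid: np.ndarray,
    seed: int = 0,
    lesion_radius: float = 15.0,
    snr_levels_db: tuple[float, ...] = NOISE_SNR_LEVELS_DB,
) -> list[SimCase]:
    """Build one of the four evaluation datasets.

    1: MI cases (centers sampled without replacement, severity U[0.25, 0.80]);
    2: VH cases (delay U[25, 50] ms);
    3/4: datasets 1/2 with noisy BSP at each SNR in ``snr_levels_db``.
    """
    if kind not in (1, 2, 3, 4):
        raise ValueError(f"dataset kind must be 1-4, got {kind}")
    if n_cases > mesh.n_vertices:
        raise ValueError(
            f"n_cases ({n_cases}) exceeds node count ({mesh.n_vertices})"
        )
    rng = np.random.default_rng(seed)
    centers = rng.choice(mesh.n_vertices, size=n_cases, replace=False)
    lesion_kind = MI if kind in (1, 3) else VH
    snrs = snr_levels_db if kind in (3, 4) else ()
    cases = []
    for j, c in enumerate(centers):
        lesion = _sample_lesion(lesion_kind, int(c), lesion_radius, rng)
        cases.append(
            make_case(mesh, H, std_params, U_std, time_grid, lesion,
                      seed=seed + 1000 + j, snr_levels_db=snrs)
        )
    return cases


def build_training_corpus(
    task: str,
    n_cases: int,
    mesh: TriMesh,
    H: TransferMatrix | np.ndarray,
    std_params: list[APParams],
    U_std: np.ndarray,
    time_grid: np.ndarray,
    seed: int = 0,
    lesion_radius: float = 15.0,
    exclude_centers: np.ndarray | None = None,
) -> list[SimCase]:
    """Training corpus disjoint from an evaluation set.

    Centers are drawn (with replacement; a corpus may exceed the node count)
    from nodes not in ``exclude_centers``; severities/delays are uniform in
    the study ranges.  Only clean BSP is stored -- noise augmentation is
    applied on the fly during training.
    """
    rng = np.random.default_rng(seed)
    pool = np.arange(mesh.n_vertices)
    if exclude_centers is not None and len(exclude_centers) > 0:
        pool = np.setdiff1d(pool, np.asarray(exclude_centers))
    if pool.size == 0:
        raise ValueError("no candidate lesion centers left after exclusion")
    cases = []
    for j in range(n_cases):
        c = int(rng.choice(pool))
        lesion = _sample_lesion(task, c, lesion_radius, rng)
        cases.append(
            make_case(mesh, H, std_params, U_std, time_grid, lesion,
                      seed=seed + 5000 + j)
        )
    return cases


# ---------------------------------------------------------------------------
# serialization (one directory per case)
# ---------------------------------------------------------------------------

def save_case(case: SimCase, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "U_true.csv", case.U_true, delimiter=",")
    np.savetxt(d / "U_std.csv", case.U_std, delimiter=",")
    np.savetxt(d / "bsp_clean.csv", case.bsp_clean, delimiter=",")
    for snr, b in case.bsp_noisy.items():
        np.savetxt(d / f"bsp_{snr:g}dB.csv", b, delimiter=",")
    lesion = None
    if case.lesion is not None:
        lesion = {
            "kind": case.lesion.kind,
            "center_node": case.lesion.center_node,
            "radius": case.lesion.radius,
            "severity": case.lesion.severity,
            "delay": case.lesion.delay,
        }
    meta = {
        "lesion": lesion,
        "affected_nodes": case.affected_nodes.tolist(),
        "seed": case.seed,
        "snr_levels_db": sorted(case.bsp_noisy),
    }
    (d / "lesion.json").write_text(json.dumps(meta, indent=1))


def load_case(directory: str | Path) -> SimCase:
    d = Path(directory)
    meta = json.loads((d / "lesion.json").read_text())
    lesion = None
    if meta["lesion"] is not None:
        m = meta["lesion"]
        lesion = LesionSpec(kind=m["kind"], center_node=m["center_node"],
                            radius=m["radius"], severity=m["severity"],
                            delay=m["delay"])
    case = SimCase(
        lesion=lesion,
        U_true=np.loadtxt(d / "U_true.csv", delimiter=",", ndmin=2),
        U_std=np.loadtxt(d / "U_std.csv", delimiter=",", ndmin=2),
        bsp_clean=np.loadtxt(d / "bsp_clean.csv", delimiter=",", ndmin=2),
        affected_nodes=np.array(meta["affected_nodes"], dtype=np.int64),
        seed=meta["seed"],
    )
    for snr in meta["snr_levels_db"]:
        case.bsp_noisy[snr] = np.loadtxt(
            d / f"bsp_{snr:g}dB.csv", delimiter=",", ndmin=2
        )
    return case
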