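"""Comparison solvers for the inverse problem.

* Tikhonov: classical zeroth-order regularized least squares, the standard
  reference solution for linear ill-posed bioelectric problems.
* ISTA: iterative shrinkage-thresholding, alternating a gradient step on the
  data term with a proximal (soft-threshold) step; available both in its
  classical form (identity transform) and as an unrolled, trainable network
  in which the sparsifying transform is a learned pair of convolutions
  F(u) = B ReLU(A u).
* FFNN: a per-time-sample fully connected map from the N-vector of BSP to
  the M-vector of TMP.

The trainable baselines are optimized with the same composite
physics + prior loss and the same simulated corpus as the attention model,
so the architecture is the only manipulated variable in comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten

from .model import Scaler, adam_step, leaky_relu, loss_total


# ---------------------------------------------------------------------------
# Tikhonov
# ---------------------------------------------------------------------------

def tikhonov_solve(H, bsp, reg: float) -> np.ndarray:
    """U = (H^T H + reg I)^-1 H^T Omega, columnwise over time."""
    if reg <= 0:
        raise ValueError("reg must be > 0")
    Hm = np.asarray(H.entries if hasattr(H, "entries") else H, float)
    A = Hm.T @ Hm + reg * np.eye(Hm.shape[1])
    return np.linalg.solve(A, Hm.T @ np.asarray(bsp, float))


def tikhonov_prior_solve(H, bsp, U_std, reg: float) -> np.ndarray:
    """Generalized Tikhonov shrinking toward the standard TMP.

    U = U_std + (H^T H + reg I)^-1 H^T (Omega - H U_std); the closed-form
    minimizer of ||H U - Omega||^2 + reg ||U - U_std||^2, used as an
    independent classical cross-check of the learned reconstructions.
    """
    Hm = np.asarray(H.entries if hasattr(H, "entries") else H, float)
    dU = tikhonov_solve(Hm, np.asarray(bsp, float) - Hm @ U_std, reg)
    return np.asarray(U_std, float) + dU


# ---------------------------------------------------------------------------
# ISTA
# ---------------------------------------------------------------------------

@dataclass
class ISTAConfig:
    rho: float = 1.0            # gradient step size
    lambda_s: float = 1e-3      # soft-threshold level
    iterations: int = 6
    n_filters: int = 8          # channels of the learned transform
    kernel_size: int = 3
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 60
    batch_size: int = 20
    lambda_weight: float = 0.01
    noise_levels_db: tuple[float, ...] = (np.inf, 30.0, 25.0, 20.0, 15.0)

    def validate(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


def ista_gradient_step(u_prev, Phi, omega, rho):
    """r = u - rho * Phi^T (Phi u - omega)."""
    if Phi.shape[-1] != u_prev.shape[-2]:
        raise ValueError("shape mismatch between Phi and u")
    resid = anp.matmul(Phi, u_prev) - omega
    return u_prev - rho * anp.matmul(anp.swapaxes(Phi, -1, -2), resid)


def soft_threshold(r, lam):
    """Elementwise soft(r, lam) = sign(r) max(|r| - lam, 0)."""
    return anp.sign(r) * anp.maximum(anp.abs(r) - lam, 0.0)


def _conv_time(u, kernels, bias):
    """Multi-channel 1-D convolution along time.

    ``u``: (..., C_in, L); ``kernels``: (C_out, C_in, k); returns
    (..., C_out, L) with zero padding.
    """
    c_out, c_in, k = kernels.shape
    half = k // 2
    zeros = u[..., :, :half] * 0.0
    up = anp.concatenate([zeros, u, zeros], axis=-1)
    L = u.shape[-1]
    out = 0.0
    for j in range(k):
        out = out + anp.matmul(kernels[:, :, j], up[..., j:j + L])
    return out + bias[..., :, None]


def ista_proximal(r, lambda_s, A=None, B=None):
    """Proximal step of one ISTA iteration.

    Classical mode (A and B None): elementwise soft-threshold.
    Learned mode: u = B(soft(ReLU(A(r)), lambda_s)) with A, B convolutional
    transforms along time (the unrolled-network replacement of the L1
    regularizer).
    """
    if A is None and B is None:
        return soft_threshold(r, lambda_s)
    # node axis acts as batch; the transform works on a 1-channel time series
    z = r[..., :, None, :]                     # (..., M, 1, L)
    z = _conv_time(z, A["k"], A["b"])          # (..., M, F, L)
    z = soft_threshold(leaky_relu(z), lambda_s)
    z = _conv_time(z, B["k"], B["b"])          # (..., M, 1, L)
    return z[..., :, 0, :]


def ista_run(bsp, Phi, config: ISTAConfig, params=None, u0=None):
    """K unrolled iterations alternating gradient and proximal steps."""
    config.validate()
    if u0 is None:
        u0 = 0.0 * anp.matmul(anp.swapaxes(Phi, -1, -2), bsp)
    u = u0
    for k in range(config.iterations):
        if params is not None:
            rho = params["rho"][k]
            lam = anp.abs(params["lam"][k])
            A, B = params["A"][k], params["B"][k]
        else:
            rho, lam, A, B = config.rho, config.lambda_s, None, None
        r = ista_gradient_step(u, Phi, bsp, rho)
        u = ista_proximal(r, lam, A, B)
    return u


def ista_objective(u, Phi, omega, lambda_s):
    """0.5 ||Phi u - omega||_F^2 + lambda_s ||u||_1 (classical objective)."""
    resid = Phi @ u - omega
    return 0.5 * np.sum(resid**2) + lambda_s * np.sum(np.abs(u))


def _init_ista_params(config: ISTAConfig, rho0: float, rng) -> dict:
    F, k = config.n_filters, config.kernel_size
    A, B, rho, lam = [], [], [], []
    for _ in range(config.iterations):
        A.append({"k": rng.normal(0, 0.1, size=(F, 1, k)), "b": np.zeros(F)})
        kb = rng.normal(0, 0.1, size=(1, F, k))
        B.append({"k": kb, "b": np.zeros(1)})
        rho.append(np.array(rho0))
        lam.append(np.array(config.lambda_s))
    return {"A": A, "B": B, "rho": rho, "lam": lam}


@dataclass
class ISTANetModel:
    """Unrolled ISTA solver (trained or classical/identity mode)."""

    name = "ISTA"
    H: np.ndarray
    config: ISTAConfig
    scaler: Scaler
    params: dict | None = None
    loss_history: list[float] = field(default_factory=list)

    def reconstruct(self, bsp: np.ndarray) -> np.ndarray:
        Hs = self.scaler.scale_H(self.H)
        u = ista_run(
            self.scaler.bsp_to_net(np.asarray(bsp, float)),
            Hs, self.config, params=self.params,
        )
        return self.scaler.tmp_from_net(np.asarray(u))


def train_ista_net(train_cases, config: ISTAConfig, H, scaler: Scaler) -> ISTANetModel:
    """Fit the unrolled transforms with the shared physics + prior loss."""
    Hm = np.asarray(H.entries if hasattr(H, "entries") else H, float)
    Hs = scaler.scale_H(Hm)
    sigma_max = np.linalg.svd(Hs, compute_uv=False)[0]
    rho0 = 1.0 / sigma_max**2
    U_std = train_cases[0].U_std
    c_net = scaler.tmp_to_net(U_std)
    bsp_clean = np.stack([c.bsp_clean for c in train_cases])
    clean_power = np.mean(bsp_clean**2, axis=(1, 2))
    rng = np.random.default_rng(config.seed)
    params = _init_ista_params(config, rho0, rng)
    flat, unflatten = flatten(params)
    state = (np.zeros_like(flat), np.zeros_like(flat), 0)

    def batch_loss(p, b, b_clean):
        u = ista_run(b, Hs, config, params=p)
        total, _, _ = loss_total(u, b_clean, c_net, Hs, config.lambda_weight)
        return total

    vag = value_and_grad(
        lambda f, b, bc: batch_loss(unflatten(f), b, bc)
    )
    history = []
    n = len(train_cases)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, bs):
            idx = order[s:s + bs]
            b = bsp_clean[idx].copy()
            if config.noise_levels_db:
                snrs = rng.choice(config.noise_levels_db, size=len(idx))
                fin = np.isfinite(snrs)
                sd = np.zeros(len(idx))
                sd[fin] = np.sqrt(clean_power[idx][fin] / 10 ** (snrs[fin] / 10))
                b += sd[:, None, None] * rng.standard_normal(b.shape)
            val, g = vag(flat, scaler.bsp_to_net(b),
                         scaler.bsp_to_net(bsp_clean[idx]))
            if not np.isfinite(val):
                raise RuntimeError(f"non-finite ISTA-net loss at epoch {epoch}")
            flat, state = adam_step(flat, g, state, config.learning_rate)
            losses.append(float(val))
        history.append(float(np.mean(losses)))
    return ISTANetModel(H=Hm, config=config, scaler=scaler,
                        params=unflatten(flat), loss_history=history)


# ---------------------------------------------------------------------------
# FFNN
# ---------------------------------------------------------------------------

@dataclass
class FFNNConfig:
    hidden_sizes: tuple[int, ...] = (256, 256)
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 60
    batch_size: int = 20
    lambda_weight: float = 0.01
    noise_levels_db: tuple[float, ...] = (np.inf, 30.0, 25.0, 20.0, 15.0)

    def validate(self) -> None:
        if len(self.hidden_sizes) < 1:
            raise ValueError("need at least one hidden layer")


def ffnn_forward(bsp, params):
    """Per-time-sample MLP: (..., N, L) -> (..., M, L)."""
    z = anp.swapaxes(bsp, -1, -2)          # (..., L, N)
    for W, b in params[:-1]:
        z = leaky_relu(anp.matmul(z, W) + b)
    W, b = params[-1]
    z = anp.matmul(z, W) + b
    return anp.swapaxes(z, -1, -2)


def _init_ffnn(config: FFNNConfig, n_in: int, n_out: int, rng) -> list:
    sizes = (n_in, *config.hidden_sizes, n_out)
    return [
        (rng.normal(0, np.sqrt(2.0 / (a + b)), size=(a, b)), np.zeros(b))
        for a, b in zip(sizes[:-1], sizes[1:])
    ]


@dataclass
class FFNNModel:
    name = "FFNN"
    config: FFNNConfig
    scaler: Scaler
    params: list
    loss_history: list[float] = field(default_factory=list)

    def reconstruct(self, bsp: np.ndarray) -> np.ndarray:
        u = ffnn_forward(self.scaler.bsp_to_net(np.asarray(bsp, float)),
                         self.params)
        return self.scaler.tmp_from_net(np.asarray(u))


def train_ffnn(train_cases, config: FFNNConfig, H, scaler: Scaler) -> FFNNModel:
    """Train the per-sample MLP with the shared physics + prior loss."""
    config.validate()
    Hm = np.asarray(H.entries if hasattr(H, "entries") else H, float)
    Hs = scaler.scale_H(Hm)
    U_std = train_cases[0].U_std
    c_net = scaler.tmp_to_net(U_std)
    N = train_cases[0].bsp_clean.shape[0]
    M = U_std.shape[0]
    bsp_clean = np.stack([c.bsp_clean for c in train_cases])
    clean_power = np.mean(bsp_clean**2, axis=(1, 2))
    rng = np.random.default_rng(config.seed)
    params = _init_ffnn(config, N, M, rng)
    flat, unflatten = flatten(params)
    state = (np.zeros_like(flat), np.zeros_like(flat), 0)

    def batch_loss(p, b, b_clean):
        u = ffnn_forward(b, p)
        total, _, _ = loss_total(u, b_clean, c_net, Hs, config.lambda_weight)
        return total

    vag = value_and_grad(
        lambda f, b, bc: batch_loss(unflatten(f), b, bc)
    )
    history = []
    n = len(train_cases)
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, bs):
            idx = order[s:s + bs]
            b = bsp_clean[idx].copy()
            if config.noise_levels_db:
                snrs = rng.choice(config.noise_levels_db, size=len(idx))
                fin = np.isfinite(snrs)
                sd = np.zeros(len(idx))
                sd[fin] = np.sqrt(clean_power[idx][fin] / 10 ** (snrs[fin] / 10))
                b += sd[:, None, None] * rng.standard_normal(b.shape)
            val, g = vag(flat, scaler.bsp_to_net(b),
                         scaler.bsp_to_net(bsp_clean[idx]))
            if not np.isfinite(val):
                raise RuntimeError(f"non-finite FFNN loss at epoch {epoch}")
            flat, state = adam_step(flat, g, state, config.learning_rate)
            losses.append(float(val))
        history.append(float(np.mean(losses)))
    return FFNNModel(config=config, scaler=scaler, params=unflatten(flat),
                     loss_history=history)
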