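"""Causal sequential variational autoencoder for fluorescence population activity.

The network follows the LFADS lineage adapted to continuous calcium traces:

* a strictly causal (forward-only) GRU **encoder** reads the observed
  fluorescence one bin at a time;
* the encoder state at the first bin parameterizes a diagonal-Gaussian
  posterior over the generator's **initial condition** g0;
* at every bin a small **controller** MLP maps the encoder state to a
  diagonal-Gaussian posterior over a low-dimensional **inferred input** u(t)
  (dimension 1 by default) — the model's estimate of unobserved upstream drive;
* a GRU **generator** evolves autonomously from g0, perturbed only by u(t);
  its state is read out linearly to **factors** and then to per-neuron means;
* emission is Gaussian with a learned, time-independent variance per neuron.

Because the encoder is forward-only and the controller sees only the current
encoder state, every inferred quantity at bin t is a function of observations
at bins <= t. Training maximizes the evidence lower bound

    ELBO = E_q[log p(x | g0, u)] - KL(q(g0) || N(0,I)) - sum_t KL(q(u_t) || N(0,I))

with reparameterized sampling, an L2 penalty on the recurrent weight matrices,
dropout on encoder inputs and generator outputs, KL warm-up, gradient clipping,
and early stopping on the validation ELBO. All gradients are analytic
(backpropagation through time written out by hand) and are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .synth import SessionData

_LOGVAR_MIN, _LOGVAR_MAX = -12.0, 8.0


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters of the network and its training loop.

    Defaults are the full-scale settings used on real recordings (256-unit
    RNNs, 32 factors, 200 ms bins, inferred-input dimension 1);
    :meth:`test_scale` returns the small configuration used for synthetic
    parameter-recovery experiments.
    """

    n_generator_units: int = 256
    n_factors: int = 32
    n_input_dims: int = 1
    n_encoder_units: int = 256
    n_controller_units: int = 256
    bin_size: float = 0.2
    l2_penalty: float = 1e-9
    dropout_keep_rate: float = 0.98
    kl_ic_weight: float = 1.0
    kl_u_weight: float = 1.0
    # AR(1) prior on the inferred input u(t): correlation time in seconds.
    # A short timescale penalizes persistent inferred drive, forcing the
    # generator dynamics (not the input channel) to store slow structure.
    input_prior_tau: float = 0.2
    learning_rate: float = 5e-3
    lr_decay: float = 0.997
    lr_min: float = 2e-4
    gen_update_bias: float = 0.0
    kl_warmup_epochs: int = 50
    max_epochs: int = 500
    patience: int = 100
    clip_norm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_generator_units",
            "n_factors",
            "n_input_dims",
            "n_encoder_units",
            "n_controller_units",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.dropout_keep_rate <= 1:
            raise ValueError("dropout_keep_rate must be in (0, 1]")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be nonnegative")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @classmethod
    def test_scale(cls, **overrides) -> "ModelConfig":
        """Small configuration (64/8/1/64/64) for synthetic-data experiments."""
        base = dict(
            n_generator_units=64,
            n_factors=8,
            n_input_dims=1,
            n_encoder_units=64,
            n_controller_units=64,
        )
        base.update(overrides)
        return cls(**base)


# --------------------------------------------------------------------------
# Closed-form building blocks
# --------------------------------------------------------------------------

def gaussian_log_likelihood(observed, mean, variance) -> float:
    """Sum over elements of log N(observed | mean, variance)."""
    observed = np.asarray(observed, dtype=float)
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if observed.shape != mean.shape:
        raise ValueError("observed and mean shapes differ")
    if np.any(variance <= 0):
        raise ValueError("variance must be strictly positive")
    return float(
        -0.5 * np.sum(np.log(2 * np.pi * variance) + (observed - mean) ** 2 / variance)
    )


def kl_diag_gaussians(mean_q, var_q, mean_p, var_p) -> float:
    """KL(q || p) between diagonal Gaussians, summed over dimensions."""
    mean_q, var_q = np.asarray(mean_q, float), np.asarray(var_q, float)
    mean_p, var_p = np.asarray(mean_p, float), np.asarray(var_p, float)
    if np.any(var_q <= 0) or np.any(var_p <= 0):
        raise ValueError("variances must be strictly positive")
    return float(
        0.5
        * np.sum(
            np.log(var_p / var_q) + (var_q + (mean_q - mean_p) ** 2) / var_p - 1.0
        )
    )


def ar1_sequence_kl(mean: np.ndarray, var: np.ndarray, phi: float):
    """KL of a factorized Gaussian posterior from a stationary AR(1) prior.

    The prior over a sequence u_0..u_{T-1} (per trial and input dimension) is
    u_t = phi u_{t-1} + eps, eps ~ N(0, 1 - phi^2), stationary variance 1.
    ``mean``/``var`` have shape (B, T, U). Returns (kl, dkl/dmean, dkl/dvar);
    phi = 0 reduces to the i.i.d. standard-normal KL.
    """
    if not 0 <= phi < 1:
        raise ValueError("phi must lie in [0, 1)")
    if np.any(var <= 0):
        raise ValueError("variances must be strictly positive")
    m, v = mean, var
    s_e = 1.0 - phi**2
    e = m[:, 1:] - phi * m[:, :-1]  # innovations
    kl0 = 0.5 * np.sum(v[:, 0] + m[:, 0] ** 2 - 1.0 - np.log(v[:, 0]))
    klt = 0.5 * np.sum(
        (v[:, 1:] + phi**2 * v[:, :-1] + e**2) / s_e
        - 1.0
        - np.log(v[:, 1:])
        + np.log(s_e)
    )
    dm = np.zeros_like(m)
    dm[:, 0] = m[:, 0]
    dm[:, 1:] += e / s_e
    dm[:, :-1] -= phi * e / s_e
    dv = np.empty_like(v)
    dv[:, 0] = 0.5
    dv[:, 1:] = 0.5 / s_e
    dv[:, :-1] += 0.5 * phi**2 / s_e
    dv -= 0.5 / v
    return float(kl0 + klt), dm, dv


def split_train_valid(data: SessionData) -> tuple[SessionData, SessionData]:
    """Split trials into training (odd 1-based index) and validation (even)."""
    if data.n_trials < 2:
        raise ValueError("need at least 2 trials to split")
    idx = np.arange(data.n_trials)
    odd = idx % 2 == 0  # 1-based odd == 0-based even index
    def subset(mask):
        return SessionData(
            fluorescence=data.fluorescence[mask],
            trial_type=data.trial_type[mask],
            cue_bin=data.cue_bin,
            bin_size=data.bin_size,
            neuron_ids=data.neuron_ids,
            session_id=data.session_id,
        )
    return subset(odd), subset(~odd)


# --------------------------------------------------------------------------
# GRU primitives (batched, hand-written backprop)
# --------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gru_forward_core(xx, h0, Wh):
    B, T, H3 = xx.shape
    H = H3 // 3
    states = np.empty((B, T, H))
    HPREV = np.empty((B, T, H))
    R = np.empty((B, T, H))
    Z = np.empty((B, T, H))
    N = np.empty((B, T, H))
    HHN = np.empty((B, T, H))
    h = h0
    for t in range(T):
        hh = h @ Wh
        rz = _sigmoid(xx[:, t, : 2 * H] + hh[:, : 2 * H])
        r, z = rz[:, :H], rz[:, H:]
        hh_n = hh[:, 2 * H :]
        n = np.tanh(xx[:, t, 2 * H :] + r * hh_n)
        HPREV[:, t] = h
        R[:, t] = r
        Z[:, t] = z
        N[:, t] = n
        HHN[:, t] = hh_n
        h = (1.0 - z) * n + z * h
        states[:, t] = h
    return states, HPREV, R, Z, N, HHN


def _gru_backward_core(WhT, dstates, HPREV, R, Z, N, HHN):
    B, T, H = dstates.shape
    DXX = np.empty((B, T, 3 * H))
    DHH = np.empty((B, T, 3 * H))
    carry = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dstates[:, t] + carry
        h_prev = HPREV[:, t]
        r = R[:, t]
        z = Z[:, t]
        n = N[:, t]
        dpre_z = dh * (h_prev - n) * z * (1.0 - z)
        dpre_n = dh * (1.0 - z) * (1.0 - n * n)
        dpre_r = dpre_n * HHN[:, t] * r * (1.0 - r)
        DXX[:, t, :H] = dpre_r
        DXX[:, t, H : 2 * H] = dpre_z
        DXX[:, t, 2 * H :] = dpre_n
        DHH[:, t, :H] = dpre_r
        DHH[:, t, H : 2 * H] = dpre_z
        DHH[:, t, 2 * H :] = dpre_n * r
        carry = dh * z + DHH[:, t] @ WhT
    return DXX, DHH, carry


def _gru_forward(xx: np.ndarray, h0: np.ndarray, Wh: np.ndarray):
    """Run a GRU over time.

    ``xx`` is the precomputed input-side preactivation (B, T, 3H) with gate
    order [reset, update, candidate] and biases already added; ``h0`` (B, H).
    Returns the state sequence (B, T, H) and a cache for backprop.
    """
    states, *cache = _gru_forward_core(
        np.ascontiguousarray(xx), np.ascontiguousarray(h0), Wh
    )
    return states, tuple(cache)


def _gru_backward(cache, Wh: np.ndarray, dstates: np.ndarray):
    """Backprop through :func:`_gru_forward`.

    ``dstates`` (B, T, H) holds the gradients arriving at each state from
    downstream consumers. Returns (dxx, dh0, dWh).
    """
    HPREV = cache[0]
    DXX, DHH, dh0 = _gru_backward_core(
        np.ascontiguousarray(Wh.T), np.ascontiguousarray(dstates), *cache
    )
    B, T, H = dstates.shape
    dWh = HPREV.reshape(B * T, H).T @ DHH.reshape(B * T, 3 * H)
    return DXX, dh0, dWh


def _gru_step(x_pre: np.ndarray, h: np.ndarray, Wh: np.ndarray) -> np.ndarray:
    """Single GRU step; ``x_pre`` (B, 3H) is the input-side preactivation."""
    H = h.shape[-1]
    hh = h @ Wh
    r = _sigmoid(x_pre[..., :H] + hh[..., :H])
    z = _sigmoid(x_pre[..., H : 2 * H] + hh[..., H : 2 * H])
    n = np.tanh(x_pre[..., 2 * H :] + r * hh[..., 2 * H :])
    return (1.0 - z) * n + z * h


def _gru_jacobian(x_pre: np.ndarray, h: np.ndarray, Wh: np.ndarray) -> np.ndarray:
    """Exact Jacobian d h' / d h of a GRU step, batched: (M, H, H)."""
    h = np.atleast_2d(h)
    x_pre = np.broadcast_to(np.atleast_2d(x_pre), (h.shape[0], Wh.shape[1]))
    M, H = h.shape
    hh = h @ Wh
    r = _sigmoid(x_pre[:, :H] + hh[:, :H])
    z = _sigmoid(x_pre[:, H : 2 * H] + hh[:, H : 2 * H])
    hh_n = hh[:, 2 * H :]
    n = np.tanh(x_pre[:, 2 * H :] + r * hh_n)
    WhrT = Wh[:, :H].T
    WhzT = Wh[:, H : 2 * H].T
    WhnT = Wh[:, 2 * H :].T
    a = (h - n) * z * (1.0 - z)
    b = (1.0 - z) * (1.0 - n * n)
    J = np.eye(H)[None] * z[:, :, None]
    J = J + a[:, :, None] * WhzT[None]
    J = J + (b * r)[:, :, None] * WhnT[None]
    J = J + (b * hh_n * r * (1.0 - r))[:, :, None] * WhrT[None]
    return J


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

def _init_params(cfg: ModelConfig, n_neurons: int, rng: np.random.Generator) -> dict:
    E, C, G, F, U = (
        cfg.n_encoder_units,
        cfg.n_controller_units,
        cfg.n_generator_units,
        cfg.n_factors,
        cfg.n_input_dims,
    )
    N = n_neurons

    def mat(n_in, n_out, scale=None):
        s = scale if scale is not None else 1.0 / np.sqrt(n_in)
        return rng.normal(scale=s, size=(n_in, n_out))

    p = {
        "enc_Wx": mat(N, 3 * E),
        "enc_Wh": mat(E, 3 * E),
        "enc_b": np.zeros(3 * E),
        "enc_h0": np.zeros(E),
        "ic_Wm": mat(E, G),
        "ic_bm": np.zeros(G),
        "ic_Wv": mat(E, G, scale=0.01),
        "ic_bv": np.full(G, -2.0),
        "con_W1": mat(E, C),
        "con_b1": np.zeros(C),
        "con_Wm": mat(C, U, scale=0.1),
        "con_bm": np.zeros(U),
        "con_Wv": mat(C, U, scale=0.01),
        "con_bv": np.full(U, -2.0),
        "gen_Wx": mat(U, 3 * G),
        "gen_Wh": mat(G, 3 * G),
        "gen_b": np.zeros(3 * G),
        "fac_W": mat(G, F),
        "out_W": mat(F, N),
        "out_b": np.zeros(N),
        "out_logvar": np.zeros(N),
    }
    # Optional update-gate bias: positive values bias the generator toward
    # memory at init but leave spurious slow directions; default 0 so that
    # only data-driven slow modes survive training.
    p["gen_b"][G : 2 * G] = cfg.gen_update_bias
    return p


@dataclass
class TrainedModel:
    """Trained network parameters plus configuration and training history."""

    params: dict
    config: ModelConfig
    n_neurons: int
    data_mean: np.ndarray  # per-neuron standardization of encoder inputs
    data_std: np.ndarray
    training_curve: dict = field(default_factory=dict)
    best_epoch: int = -1

    # -- generator as a standalone dynamical system -------------------------
    def generator_step(self, h: np.ndarray, u: np.ndarray) -> np.ndarray:
        """One step of the generator map F(h, u); batched over leading axis."""
        h = np.asarray(h, float)
        u = np.asarray(u, float)
        if h.shape[-1] != self.config.n_generator_units:
            raise ValueError("state dimension mismatch")
        x_pre = u @ self.params["gen_Wx"] + self.params["gen_b"]
        return _gru_step(x_pre, h, self.params["gen_Wh"])

    def generator_vjp(self, h: np.ndarray, u: np.ndarray, delta: np.ndarray) -> np.ndarray:
        """Vector-Jacobian product (dF/dh)^T delta without forming the Jacobian."""
        h = np.atleast_2d(np.asarray(h, float))
        delta = np.atleast_2d(np.asarray(delta, float))
        Wh = self.params["gen_Wh"]
        H = h.shape[1]
        x_pre = np.atleast_2d(u) @ self.params["gen_Wx"] + self.params["gen_b"]
        x_pre = np.broadcast_to(x_pre, (h.shape[0], 3 * H))
        hh = h @ Wh
        r = _sigmoid(x_pre[:, :H] + hh[:, :H])
        z = _sigmoid(x_pre[:, H : 2 * H] + hh[:, H : 2 * H])
        hh_n = hh[:, 2 * H :]
        n = np.tanh(x_pre[:, 2 * H :] + r * hh_n)
        dpre_z = delta * (h - n) * z * (1.0 - z)
        dpre_n = delta * (1.0 - z) * (1.0 - n * n)
        dpre_r = dpre_n * hh_n * r * (1.0 - r)
        dhh = np.concatenate([dpre_r, dpre_z, dpre_n * r], axis=1)
        return delta * z + dhh @ Wh.T

    def generator_jacobian(self, h: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Exact Jacobian dF/dh at (h, u); (H, H) or batched (M, H, H)."""
        single = np.asarray(h).ndim == 1
        x_pre = np.atleast_2d(u) @ self.params["gen_Wx"] + self.params["gen_b"]
        J = _gru_jacobian(x_pre, np.atleast_2d(h), self.params["gen_Wh"])
        return J[0] if single else J

    def rates_from_generator(self, states: np.ndarray) -> np.ndarray:
        """Map generator states to per-neuron emission means (rate space)."""
        states = np.asarray(states, float)
        f = states @ self.params["fac_W"]
        return f @ self.params["out_W"] + self.params["out_b"]

    def factors_from_generator(self, states: np.ndarray) -> np.ndarray:
        return np.asarray(states, float) @ self.params["fac_W"]


@dataclass
class PosteriorOutputs:
    """Per-trial posterior quantities and ELBO decomposition."""

    ic_mean: np.ndarray  # (trials, G)
    ic_var: np.ndarray  # (trials, G)
    inferred_inputs: np.ndarray  # (trials, bins, U)
    input_mean: np.ndarray  # (trials, bins, U) posterior mean of u(t)
    input_var: np.ndarray  # (trials, bins, U)
    factors: np.ndarray  # (trials, bins, F)
    denoised_means: np.ndarray  # (trials, bins, neurons)
    recon: float
    kl_g0: float
    kl_u: float

    @property
    def elbo(self) -> float:
        return self.recon - self.kl_g0 - self.kl_u


# --------------------------------------------------------------------------
# Forward pass and analytic gradients
# --------------------------------------------------------------------------

def _forward(params, X_std, X_raw, cfg, *, eps_ic=None, eps_u=None,
             mask_x=None, mask_g=None):
    """Run the full network; deterministic given the supplied noise tensors.

    ``eps_ic`` (B, G) and ``eps_u`` (B, T, U) are reparameterization draws
    (``None`` = posterior means). ``mask_x``/``mask_g`` are dropout keep masks
    already divided by the keep rate (``None`` = no dropout). Returns outputs
    and a cache sufficient for :func:`_backward`.
    """
    E = cfg.n_encoder_units
    G = cfg.n_generator_units
    B, T, N = X_std.shape

    x_in = X_std if mask_x is None else X_std * mask_x
    xx_e = x_in @ params["enc_Wx"] + params["enc_b"]
    h0 = np.broadcast_to(params["enc_h0"], (B, E))
    e, enc_cache = _gru_forward(xx_e, h0, params["enc_Wh"])

    # Initial-condition posterior from the encoder state after the first bin.
    e0 = e[:, 0]
    ic_mean = e0 @ params["ic_Wm"] + params["ic_bm"]
    ic_lv_raw = e0 @ params["ic_Wv"] + params["ic_bv"]
    ic_lv = np.clip(ic_lv_raw, _LOGVAR_MIN, _LOGVAR_MAX)
    ic_sd = np.exp(0.5 * ic_lv)
    g0 = ic_mean if eps_ic is None else ic_mean + ic_sd * eps_ic

    # Controller: per-bin inferred-input posterior from the causal encoder state.
    c_hid = np.tanh(e @ params["con_W1"] + params["con_b1"])
    u_mean = c_hid @ params["con_Wm"] + params["con_bm"]
    u_lv_raw = c_hid @ params["con_Wv"] + params["con_bv"]
    u_lv = np.clip(u_lv_raw, _LOGVAR_MIN, _LOGVAR_MAX)
    u_sd = np.exp(0.5 * u_lv)
    u = u_mean if eps_u is None else u_mean + u_sd * eps_u

    xx_g = u @ params["gen_Wx"] + params["gen_b"]
    g, gen_cache = _gru_forward(xx_g, g0, params["gen_Wh"])
    g_out = g if mask_g is None else g * mask_g

    factors = g_out @ params["fac_W"]
    means = factors @ params["out_W"] + params["out_b"]

    em_var = np.exp(params["out_logvar"])
    resid = X_raw - means
    recon = -0.5 * np.sum(
        np.log(2 * np.pi) + params["out_logvar"] + resid**2 / em_var
    )
    kl_ic = 0.5 * np.sum(ic_mean**2 + np.exp(ic_lv) - 1.0 - ic_lv)
    phi = np.exp(-cfg.bin_size / cfg.input_prior_tau) if cfg.input_prior_tau > 0 else 0.0
    kl_u, dklu_dm, dklu_dv = ar1_sequence_kl(u_mean, np.exp(u_lv), phi)

    out = dict(
        ic_mean=ic_mean, ic_var=np.exp(ic_lv), u_mean=u_mean,
        u_var=np.exp(u_lv), u=u,
        factors=factors, means=means, recon=float(recon),
        kl_ic=float(kl_ic), kl_u=float(kl_u),
    )
    cache = dict(
        x_in=x_in, e=e, enc_cache=enc_cache, e0=e0,
        ic_mean=ic_mean, ic_lv=ic_lv, ic_lv_raw=ic_lv_raw, ic_sd=ic_sd,
        eps_ic=eps_ic, c_hid=c_hid, u_mean=u_mean, u_lv=u_lv,
        u_lv_raw=u_lv_raw, u_sd=u_sd, eps_u=eps_u, u=u,
        gen_cache=gen_cache, g=g, g_out=g_out, mask_g=mask_g,
        factors=factors, means=means, resid=resid, em_var=em_var,
        dklu_dm=dklu_dm, dklu_dv=dklu_dv,
    )
    return out, cache


def _loss_from_forward(out, params, cfg, kl_scale, denom):
    neg_elbo = -(
        out["recon"]
        - cfg.kl_ic_weight * kl_scale * out["kl_ic"]
        - cfg.kl_u_weight * kl_scale * out["kl_u"]
    ) / denom
    l2 = cfg.l2_penalty * (
        np.sum(params["enc_Wh"] ** 2) + np.sum(params["gen_Wh"] ** 2)
    )
    return neg_elbo + l2


def _backward(params, cfg, cache, kl_scale, denom):
    """Gradients of the scaled training loss for every parameter."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    c = 1.0 / denom
    wi = cfg.kl_ic_weight * kl_scale
    wu = cfg.kl_u_weight * kl_scale

    resid = cache["resid"]
    em_var = cache["em_var"]
    # d(-recon/denom)/d mean and /d logvar
    dmeans = c * (-resid) / em_var
    grads["out_logvar"] = c * np.sum(0.5 - 0.5 * resid**2 / em_var, axis=(0, 1))

    factors = cache["factors"]
    F_ = factors.shape[-1]
    grads["out_W"] = factors.reshape(-1, F_).T @ dmeans.reshape(-1, dmeans.shape[-1])
    grads["out_b"] = dmeans.sum(axis=(0, 1))
    dfac = dmeans @ params["out_W"].T
    g_out = cache["g_out"]
    grads["fac_W"] = g_out.reshape(-1, g_out.shape[-1]).T @ dfac.reshape(-1, F_)
    dg_out = dfac @ params["fac_W"].T
    if cache["mask_g"] is not None:
        dg_out = dg_out * cache["mask_g"]

    dxx_g, dg0, dWh_g = _gru_backward(cache["gen_cache"], params["gen_Wh"], dg_out)
    grads["gen_Wh"] = dWh_g
    u = cache["u"]
    grads["gen_Wx"] = u.reshape(-1, u.shape[-1]).T @ dxx_g.reshape(-1, dxx_g.shape[-1])
    grads["gen_b"] = dxx_g.sum(axis=(0, 1))
    du = dxx_g @ params["gen_Wx"].T

    # inferred-input posterior: reparameterization + KL
    u_mean, u_lv, u_sd, eps_u = (
        cache["u_mean"], cache["u_lv"], cache["u_sd"], cache["eps_u"],
    )
    du_mean = du + c * wu * cache["dklu_dm"]
    du_lv = c * wu * cache["dklu_dv"] * np.exp(u_lv)
    if eps_u is not None:
        du_lv = du_lv + du * u_sd * eps_u * 0.5
    du_lv = du_lv * ((cache["u_lv_raw"] > _LOGVAR_MIN) & (cache["u_lv_raw"] < _LOGVAR_MAX))

    c_hid = cache["c_hid"]
    C_ = c_hid.shape[-1]
    c_flat = c_hid.reshape(-1, C_)
    grads["con_Wm"] = c_flat.T @ du_mean.reshape(-1, du_mean.shape[-1])
    grads["con_bm"] = du_mean.sum(axis=(0, 1))
    grads["con_Wv"] = c_flat.T @ du_lv.reshape(-1, du_lv.shape[-1])
    grads["con_bv"] = du_lv.sum(axis=(0, 1))
    dc = du_mean @ params["con_Wm"].T + du_lv @ params["con_Wv"].T
    dpre1 = dc * (1.0 - c_hid**2)
    e = cache["e"]
    grads["con_W1"] = e.reshape(-1, e.shape[-1]).T @ dpre1.reshape(-1, C_)
    grads["con_b1"] = dpre1.sum(axis=(0, 1))
    de = dpre1 @ params["con_W1"].T  # (B, T, E)

    # initial-condition posterior
    ic_mean, ic_lv, ic_sd, eps_ic = (
        cache["ic_mean"], cache["ic_lv"], cache["ic_sd"], cache["eps_ic"],
    )
    dic_mean = dg0 + c * wi * ic_mean
    dic_lv = c * wi * 0.5 * (np.exp(ic_lv) - 1.0)
    if eps_ic is not None:
        dic_lv = dic_lv + dg0 * ic_sd * eps_ic * 0.5
    dic_lv = dic_lv * ((cache["ic_lv_raw"] > _LOGVAR_MIN) & (cache["ic_lv_raw"] < _LOGVAR_MAX))
    e0 = cache["e0"]
    grads["ic_Wm"] = e0.T @ dic_mean
    grads["ic_bm"] = dic_mean.sum(axis=0)
    grads["ic_Wv"] = e0.T @ dic_lv
    grads["ic_bv"] = dic_lv.sum(axis=0)
    de = de.copy()
    de[:, 0] += dic_mean @ params["ic_Wm"].T + dic_lv @ params["ic_Wv"].T

    dxx_e, dh0, dWh_e = _gru_backward(cache["enc_cache"], params["enc_Wh"], de)
    grads["enc_Wh"] = dWh_e
    x_in = cache["x_in"]
    grads["enc_Wx"] = x_in.reshape(-1, x_in.shape[-1]).T @ dxx_e.reshape(-1, dxx_e.shape[-1])
    grads["enc_b"] = dxx_e.sum(axis=(0, 1))
    grads["enc_h0"] = dh0.sum(axis=0)

    grads["enc_Wh"] = grads["enc_Wh"] + 2.0 * cfg.l2_penalty * params["enc_Wh"]
    grads["gen_Wh"] = grads["gen_Wh"] + 2.0 * cfg.l2_penalty * params["gen_Wh"]
    return grads


def loss_and_grads(params, X_std, X_raw, cfg, kl_scale, *, eps_ic=None,
                   eps_u=None, mask_x=None, mask_g=None):
    """Scaled negative-ELBO loss and its analytic gradients (testing hook)."""
    denom = float(np.prod(X_raw.shape))
    out, cache = _forward(
        params, X_std, X_raw, cfg,
        eps_ic=eps_ic, eps_u=eps_u, mask_x=mask_x, mask_g=mask_g,
    )
    loss = _loss_from_forward(out, params, cfg, kl_scale, denom)
    grads = _backward(params, cfg, cache, kl_scale, denom)
    return loss, grads, out


# --------------------------------------------------------------------------
# Inference API
# --------------------------------------------------------------------------

def forward_causal(
    model: TrainedModel,
    data: SessionData,
    mode: str = "mean",
    seed: int | None = 0,
) -> PosteriorOutputs:
    """Run posterior inference; all outputs at bin t depend only on bins <= t.

    ``mode='mean'`` uses posterior means throughout (deterministic);
    ``mode='sample'`` draws one reparameterized sample per trial with ``seed``.
    """
    if mode not in ("mean", "sample"):
        raise ValueError("mode must be 'mean' or 'sample'")
    X = np.asarray(data.fluorescence, float)
    if X.shape[2] != model.n_neurons:
        raise ValueError("neuron count mismatch between data and model")
    X_std = (X - model.data_mean) / model.data_std
    cfg = model.config
    eps_ic = eps_u = None
    if mode == "sample":
        rng = np.random.default_rng(seed)
        eps_ic = rng.standard_normal((X.shape[0], cfg.n_generator_units))
        eps_u = rng.standard_normal((X.shape[0], X.shape[1], cfg.n_input_dims))
    out, _ = _forward(model.params, X_std, X, cfg, eps_ic=eps_ic, eps_u=eps_u)
    return PosteriorOutputs(
        ic_mean=out["ic_mean"],
        ic_var=out["ic_var"],
        inferred_inputs=out["u"],
        input_mean=out["u_mean"],
        input_var=out["u_var"],
        factors=out["factors"],
        denoised_means=out["means"],
        recon=out["recon"],
        kl_g0=out["kl_ic"],
        kl_u=out["kl_u"],
    )


def posterior_average(
    model: TrainedModel, data: SessionData, n_samples: int, seed: int = 0
) -> PosteriorOutputs:
    """Average denoised means, inputs, and factors over posterior samples."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_samples):
        po = forward_causal(model, data, mode="sample", seed=int(rng.integers(2**31)))
        if acc is None:
            acc = po
        else:
            acc = PosteriorOutputs(
                ic_mean=acc.ic_mean,
                ic_var=acc.ic_var,
                inferred_inputs=acc.inferred_inputs + po.inferred_inputs,
                input_mean=acc.input_mean,
                input_var=acc.input_var,
                factors=acc.factors + po.factors,
                denoised_means=acc.denoised_means + po.denoised_means,
                recon=acc.recon + po.recon,
                kl_g0=acc.kl_g0 + po.kl_g0,
                kl_u=acc.kl_u + po.kl_u,
            )
    k = float(n_samples)
    return PosteriorOutputs(
        ic_mean=acc.ic_mean,
        ic_var=acc.ic_var,
        inferred_inputs=acc.inferred_inputs / k,
        input_mean=acc.input_mean,
        input_var=acc.input_var,
        factors=acc.factors / k,
        denoised_means=acc.denoised_means / k,
        recon=acc.recon / k,
        kl_g0=acc.kl_g0 / k,
        kl_u=acc.kl_u / k,
    )


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

def _clip_by_global_norm(grads: dict, max_norm: float) -> dict:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        return {k: g * scale for k, g in grads.items()}
    return grads


def train(data: SessionData, config: ModelConfig) -> TrainedModel:
    """Fit the network on odd trials, early-stopping on even-trial ELBO.

    Adam with exponentially decaying learning rate, linear KL warm-up over
    ``kl_warmup_epochs``, dropout, recurrent L2, and gradient clipping by
    global norm. Deterministic given ``config.seed``.
    """
    per_var = np.var(data.fluorescence, axis=(0, 1))
    if np.any(per_var <= 0):
        raise ValueError("every neuron needs nonzero variance")
    train_set, valid_set = split_train_valid(data)
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    X_tr = np.asarray(train_set.fluorescence, float)
    X_va = np.asarray(valid_set.fluorescence, float)
    data_mean = X_tr.mean(axis=(0, 1))
    data_std = X_tr.std(axis=(0, 1))
    data_std = np.where(data_std > 1e-8, data_std, 1.0)
    Xs_tr = (X_tr - data_mean) / data_std
    Xs_va = (X_va - data_mean) / data_std

    params = _init_params(cfg, data.n_neurons, rng)
    params["out_logvar"] = np.log(np.maximum(per_var, 1e-6))
    params["out_b"] = data_mean.copy()

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    denom = float(np.prod(X_tr.shape))
    denom_va = float(np.prod(X_va.shape))
    keep = cfg.dropout_keep_rate

    curve = {"train_elbo": [], "valid_elbo": []}
    best_valid = -np.inf
    best_params = copy.deepcopy(params)
    best_epoch = 0
    step = 0
    B, T, N = X_tr.shape
    G, U = cfg.n_generator_units, cfg.n_input_dims

    for epoch in range(cfg.max_epochs):
        kl_scale = min(1.0, (epoch + 1) / max(1, cfg.kl_warmup_epochs))
        lr = max(cfg.learning_rate * cfg.lr_decay**epoch, cfg.lr_min)

        eps_ic = rng.standard_normal((B, G))
        eps_u = rng.standard_normal((B, T, U))
        mask_x = mask_g = None
        if keep < 1.0:
            mask_x = (rng.random((B, T, N)) < keep) / keep
            mask_g = (rng.random((B, T, G)) < keep) / keep

        out, cache = _forward(
            params, Xs_tr, X_tr, cfg,
            eps_ic=eps_ic, eps_u=eps_u, mask_x=mask_x, mask_g=mask_g,
        )
        loss = _loss_from_forward(out, params, cfg, kl_scale, denom)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        grads = _backward(params, cfg, cache, kl_scale, denom)
        grads = _clip_by_global_norm(grads, cfg.clip_norm)

        step += 1
        for k in params:
            m[k] = b1 * m[k] + (1 - b1) * grads[k]
            v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
            mhat = m[k] / (1 - b1**step)
            vhat = v[k] / (1 - b2**step)
            params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + adam_eps)

        elbo_tr = out["recon"] - out["kl_ic"] - out["kl_u"]
        curve["train_elbo"].append(elbo_tr / denom)

        # validation ELBO every few epochs (always at full KL weight, so
        # warm-up and post-warm-up epochs are comparable)
        if epoch % 5 == 0 or epoch == cfg.max_epochs - 1:
            out_va, _ = _forward(params, Xs_va, X_va, cfg)
            elbo_va = out_va["recon"] - out_va["kl_ic"] - out_va["kl_u"]
            curve["valid_elbo"].append(elbo_va / denom_va)
            if elbo_va > best_valid:
                best_valid = elbo_va
                best_params = copy.deepcopy(params)
                best_epoch = epoch
        if kl_scale >= 1.0 and epoch - best_epoch > cfg.patience:
            break

    return TrainedModel(
        params=best_params,
        config=cfg,
        n_neurons=data.n_neurons,
        data_mean=data_mean,
        data_std=data_std,
        training_curve=curve,
        best_epoch=best_epoch,
    )
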