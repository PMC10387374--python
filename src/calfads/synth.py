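"""Synthetic trial-structured fluorescence sessions from ground-truth attractor systems.

The simulator produces population recordings driven by a discrete-time linear
latent system that is either a *line attractor* (exactly one eigenvalue of the
update matrix equals 1; pulses aligned to that eigenvector are summed and stored
indefinitely) or a *point attractor* (spectral radius strictly below 1; every
perturbation decays back to the origin). Latents are read out linearly to
per-neuron rates, convolved with a single-exponential calcium kernel, and
corrupted with i.i.d. Gaussian noise — the emission model the inference network
assumes.

Trials follow a head-fixed reward task: a pre-cue baseline, a cue pulse, and on
rewarded trials a reward pulse whose latent direction has a large projection on
the integrating eigenvector. The latent state carries over between trials
(no reset by default), so reward history accumulates across a session and
baseline activity ramps — the behavioural signature the downstream analyses
are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

# Stability margin: non-integrating eigenvalues keep modulus <= 1 - SPECTRAL_MARGIN.
SPECTRAL_MARGIN = 0.1

TRIAL_TYPES = ("rewarded", "unrewarded", "perturbation")


@dataclass
class PulseSchedule:
    """A latent-space input pulse: direction, and per-bin amplitudes relative to cue.

    ``offsets`` are bin indices relative to ``cue_bin``; the pulse injects
    ``amplitude[i] * direction`` into the latent state at ``cue_bin + offsets[i]``.
    """

    direction: np.ndarray
    offsets: np.ndarray
    amplitudes: np.ndarray

    def dense(self, cue_bin: int, n_bins: int) -> np.ndarray:
        """(n_bins, n_latent) array of injected input per bin of one trial."""
        out = np.zeros((n_bins, self.direction.size))
        for off, amp in zip(self.offsets, self.amplitudes):
            b = cue_bin + int(off)
            if 0 <= b < n_bins:
                out[b] += amp * self.direction
        return out


@dataclass
class GroundTruthSystem:
    """Latent linear dynamical system with linear readout and calcium emission."""

    kind: str  # "line" or "point"
    n_latent: int
    update_matrix: np.ndarray  # (L, L) discrete-time update A
    integration_mode: np.ndarray  # unit vector; eigenvector for eigenvalue 1 if line
    input_rewarded: PulseSchedule
    input_unrewarded: PulseSchedule
    input_cue: PulseSchedule
    readout: np.ndarray  # (N, L) latent -> rate
    rate_offset: np.ndarray  # (N,) baseline rate, arbitrary fluorescence units
    calcium_tau_decay: float  # seconds
    noise_sd: float
    bin_size: float  # seconds

    @property
    def n_neurons(self) -> int:
        return self.readout.shape[0]

    def validate(self) -> None:
        if self.kind not in ("line", "point"):
            raise ValueError(f"kind must be 'line' or 'point', got {self.kind!r}")
        if self.calcium_tau_decay <= 0:
            raise ValueError("calcium_tau_decay must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        eig = np.linalg.eigvals(self.update_matrix)
        mod = np.abs(eig)
        if self.kind == "line":
            n_unit = int(np.sum(np.abs(eig - 1.0) < 1e-10))
            if n_unit != 1:
                raise ValueError("line system must have exactly one eigenvalue 1")
            rest = np.sort(mod)[:-1]
            if rest.size and rest.max() > 1 - SPECTRAL_MARGIN + 1e-9:
                raise ValueError("non-integrating eigenvalues exceed stability margin")
            v = self.update_matrix @ self.integration_mode
            if not np.allclose(v, self.integration_mode, atol=1e-8):
                raise ValueError("integration_mode is not an eigenvalue-1 eigenvector")
        else:
            if mod.max() > 1 - SPECTRAL_MARGIN + 1e-9:
                raise ValueError("point system spectral radius exceeds margin")
        if not np.isclose(np.linalg.norm(self.integration_mode), 1.0, atol=1e-8):
            raise ValueError("integration_mode must have unit norm")


@dataclass
class SessionData:
    """Trial-structured population fluorescence with metadata.

    ``fluorescence`` has shape (trials, bins, neurons); all trials share
    ``cue_bin`` and bin count. ``trial_type`` entries are in
    {"rewarded", "unrewarded", "perturbation"}.
    """

    fluorescence: np.ndarray
    trial_type: np.ndarray
    cue_bin: int
    bin_size: float = 0.2
    neuron_ids: np.ndarray | None = None
    session_id: str = "session-0"

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 3:
            raise ValueError("fluorescence must be (trials, bins, neurons)")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence contains non-finite values")
        self.trial_type = np.asarray(self.trial_type, dtype=object)
        if self.trial_type.shape[0] != self.fluorescence.shape[0]:
            raise ValueError("trial_type length mismatch")
        bad = set(self.trial_type) - set(TRIAL_TYPES)
        if bad:
            raise ValueError(f"unknown trial types: {bad}")
        if not (0 <= self.cue_bin < self.fluorescence.shape[1]):
            raise ValueError("cue_bin outside trial")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.array(
                [f"n{i}" for i in range(self.fluorescence.shape[2])], dtype=object
            )

    @property
    def n_trials(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_bins(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.fluorescence.shape[2]

    @property
    def trial_duration(self) -> float:
        return self.n_bins * self.bin_size


@dataclass
class GroundTruthLatents:
    """Noiseless quantities saved alongside a simulated session."""

    latents: np.ndarray  # (trials, bins, n_latent)
    rates: np.ndarray  # (trials, bins, neurons) noiseless convolved rates
    integrated: np.ndarray  # (trials, bins) projection of latents on integration_mode


def _random_orthonormal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


def make_system(
    kind: str,
    n_latent: int,
    n_neurons: int,
    seed: int,
    *,
    bin_size: float = 0.2,
    cue_amplitude: float = 0.03,
    reward_amplitude: float = 0.05,
    unrewarded_amplitude: float = 0.05,
    reward_alignment: float = 0.9,
    calcium_tau_decay: float = 0.6,
    noise_sd: float = 0.2,
) -> GroundTruthSystem:
    """Construct a line- or point-attractor ground-truth system.

    The rewarded-input direction has cosine ``reward_alignment`` with the
    integrating eigenvector; the unrewarded input is orthogonal to it, so only
    rewards accumulate. Decaying eigenvalues are drawn in [0.2, 1 - margin].
    """
    if kind not in ("line", "point"):
        raise ValueError(f"kind must be 'line' or 'point', got {kind!r}")
    if n_latent < 2:
        raise ValueError("n_latent must be >= 2")
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    rng = np.random.default_rng(seed)
    basis = _random_orthonormal(rng, n_latent)
    mode = basis[:, 0]
    rest = basis[:, 1:]
    decay = rng.uniform(0.2, 1 - SPECTRAL_MARGIN, size=n_latent - 1)
    if kind == "line":
        lead = 1.0
    else:
        lead = rng.uniform(0.4, 1 - SPECTRAL_MARGIN)
    update = lead * np.outer(mode, mode) + rest @ np.diag(decay) @ rest.T

    ortho = rest[:, 0]
    a = reward_alignment
    reward_dir = a * mode + np.sqrt(1 - a * a) * ortho
    unrew_dir = rest[:, 1] if n_latent > 2 else ortho
    cue_dir = rest[:, -1]

    # Cue pulse spans the 1 s cue period; outcome pulse arrives 1 s after cue
    # onset (reward consumption) and is spread over 2 bins.
    cue_bins_1s = max(1, int(round(1.0 / bin_size)))
    cue = PulseSchedule(
        cue_dir,
        np.arange(cue_bins_1s),
        np.full(cue_bins_1s, cue_amplitude / cue_bins_1s),
    )
    outcome_off = np.array([cue_bins_1s, cue_bins_1s + 1])
    rewarded = PulseSchedule(
        reward_dir, outcome_off, np.full(2, reward_amplitude / 2)
    )
    unrewarded = PulseSchedule(
        unrew_dir, outcome_off, np.full(2, unrewarded_amplitude / 2)
    )

    # Readout with a positive loading on the integration mode for every neuron,
    # so accumulated evidence raises total population activity (photometry-like).
    pos = rng.uniform(0.5, 1.5, size=n_neurons)
    mix = rng.normal(scale=0.3, size=(n_neurons, n_latent))
    mix -= np.outer(mix @ mode, mode)  # keep the mode loading purely positive
    readout = np.outer(pos, mode) + mix
    rate_offset = rng.uniform(0.5, 1.5, size=n_neurons)

    system = GroundTruthSystem(
        kind=kind,
        n_latent=n_latent,
        update_matrix=update,
        integration_mode=mode,
        input_rewarded=rewarded,
        input_unrewarded=unrewarded,
        input_cue=cue,
        readout=readout,
        rate_offset=rate_offset,
        calcium_tau_decay=calcium_tau_decay,
        noise_sd=noise_sd,
        bin_size=bin_size,
    )
    system.validate()
    return system


def calcium_convolve(
    rates: np.ndarray,
    tau_decay: float,
    bin_size: float,
    initial_value: np.ndarray | float | None = None,
) -> np.ndarray:
    """Causal exponential calcium filter with unit DC gain.

    Impulse response ``(1 - alpha) * alpha**k`` with ``alpha = exp(-bin/tau)``:
    an impulse decays geometrically with ratio ``alpha`` and a constant input
    passes through unchanged (unit DC gain). Filtering is along axis 0.
    ``initial_value`` sets the filter's pre-history equilibrium (the indicator
    level before the first sample); default 0 (filter at rest).
    """
    if tau_decay <= 0:
        raise ValueError("tau_decay must be positive")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rates = np.asarray(rates, dtype=float)
    alpha = np.exp(-bin_size / tau_decay)
    if initial_value is None:
        return lfilter([1 - alpha], [1.0, -alpha], rates, axis=0)
    # recursion y_t = (1-a) x_t + a y_{t-1} with y_{-1} = initial_value
    init = np.broadcast_to(np.asarray(initial_value, float), rates.shape[1:])
    zi = alpha * init[None] if rates.ndim > 1 else np.array([alpha * float(initial_value)])
    y, _ = lfilter([1 - alpha], [1.0, -alpha], rates, axis=0, zi=zi)
    return y


def simulate_session(
    system: GroundTruthSystem,
    n_trials: int,
    p_reward: float,
    bins_per_trial: int,
    seed: int,
    *,
    cue_bin: int = 10,
    reset_between_trials: bool = False,
    session_id: str | None = None,
) -> tuple[SessionData, GroundTruthLatents]:
    """Simulate one session of ``n_trials`` trials.

    Trial types are drawn i.i.d. Bernoulli(``p_reward``); the latent state
    evolves as ``x_{t+1} = A x_t + pulse_t`` and, unless
    ``reset_between_trials``, trial k+1 continues from trial k's final state
    so reward history carries across trials. Calcium convolution is applied to
    the concatenated session so indicator decay also spans trial boundaries.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= p_reward <= 1.0:
        raise ValueError("p_reward must be in [0, 1]")
    if not 0 <= cue_bin < bins_per_trial:
        raise ValueError("cue_bin must lie inside the trial")
    rng = np.random.default_rng(seed)
    rewarded = rng.random(n_trials) < p_reward
    trial_type = np.where(rewarded, "rewarded", "unrewarded").astype(object)

    L = system.n_latent
    cue_dense = system.input_cue.dense(cue_bin, bins_per_trial)
    rew_dense = cue_dense + system.input_rewarded.dense(cue_bin, bins_per_trial)
    unr_dense = cue_dense + system.input_unrewarded.dense(cue_bin, bins_per_trial)

    latents = np.zeros((n_trials, bins_per_trial, L))
    x = np.zeros(L)
    A = system.update_matrix
    for k in range(n_trials):
        pulses = rew_dense if rewarded[k] else unr_dense
        if reset_between_trials:
            x = np.zeros(L)
        for t in range(bins_per_trial):
            x = A @ x + pulses[t]
            latents[k, t] = x

    rates = latents @ system.readout.T + system.rate_offset  # (K, T, N)
    flat = rates.reshape(-1, system.n_neurons)
    # indicator starts at equilibrium with the pre-session baseline rate
    conv = calcium_convolve(
        flat, system.calcium_tau_decay, system.bin_size,
        initial_value=system.rate_offset,
    )
    conv = conv.reshape(rates.shape)
    noise = rng.normal(scale=system.noise_sd, size=conv.shape) if system.noise_sd > 0 else 0.0
    fluo = conv + noise

    data = SessionData(
        fluorescence=fluo,
        trial_type=trial_type,
        cue_bin=cue_bin,
        bin_size=system.bin_size,
        session_id=session_id or f"sim-{system.kind}-{seed}",
    )
    truth = GroundTruthLatents(
        latents=latents,
        rates=conv,
        integrated=latents @ system.integration_mode,
    )
    return data, truth
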