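"""In-silico experiments: run the trained generator as a standalone system.

The generator is rolled forward with condition-averaged inferred inputs
(the trial-averaged inferred input of rewarded or unrewarded trials over the
window from 1 s before to 3 s after cue onset), with trial types drawn
Bernoulli(p_reward) and 1 s of zero input between trials for relaxation.
Sessions stop after 10 rewarded trials (or at a configurable trial cap).
The rate-space trajectory projected onto the total-activity mode serves as a
photometry proxy; titrating p_reward yields accumulation slopes across
rewarded trials — the model's prediction for how steeply bulk activity ramps
with reward rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TrainedModel, PosteriorOutputs
from .synth import SessionData
from .geometry import total_activity_mode
from .fixed_points import FixedPointSet


@dataclass
class InputLibrary:
    """Condition-averaged inferred inputs for generator rollouts."""

    rewarded_input: np.ndarray  # (bins, n_input_dims)
    unrewarded_input: np.ndarray
    relaxation_bins: int  # zero-input bins between trials (default 1 s)
    bin_size: float
    cue_offset_bins: int  # bins from window start to cue onset (1 s)

    def __post_init__(self) -> None:
        if self.rewarded_input.shape != self.unrewarded_input.shape:
            raise ValueError("rewarded and unrewarded inputs must share shape")


@dataclass
class SessionRollout:
    """One simulated session of generator dynamics."""

    states: np.ndarray  # (total_bins, G)
    photometry_proxy: np.ndarray  # (total_bins,)
    trial_types: np.ndarray  # per simulated trial
    trial_slices: list  # slice into the time axis per trial
    hit_trial_cap: bool = False


def condition_averaged_inputs(
    posterior: PosteriorOutputs,
    data: SessionData,
    pre_s: float = 1.0,
    post_s: float = 3.0,
    relaxation_s: float = 1.0,
) -> InputLibrary:
    """Trial-type-averaged inferred inputs in a -1 s ... +3 s window around cue."""
    bs = data.bin_size
    pre = int(round(pre_s / bs))
    post = int(round(post_s / bs))
    lo, hi = data.cue_bin - pre, data.cue_bin + post
    if lo < 0 or hi > data.n_bins:
        raise ValueError("input window does not fit within the trial")
    out = {}
    for label in ("rewarded", "unrewarded"):
        mask = data.trial_type == label
        if not np.any(mask):
            raise ValueError(f"no {label} trials in session")
        out[label] = posterior.inferred_inputs[mask, lo:hi].mean(axis=0)
    return InputLibrary(
        rewarded_input=out["rewarded"],
        unrewarded_input=out["unrewarded"],
        relaxation_bins=int(round(relaxation_s / bs)),
        bin_size=bs,
        cue_offset_bins=pre,
    )


def run_session(
    model: TrainedModel,
    lib: InputLibrary,
    p_reward: float,
    init_state: np.ndarray,
    seed: int = 0,
    max_rewarded: int = 10,
    trial_cap: int = 40,
    photometry_mode: np.ndarray | None = None,
) -> SessionRollout:
    """Roll the generator through Bernoulli-sampled trials until the stop rule.

    Each trial plays the 4 s condition-averaged input then ``relaxation_bins``
    of exactly zero input; the session ends after the relaxation of the
    ``max_rewarded``-th rewarded trial, or at ``trial_cap`` trials.
    """
    if not 0.0 <= p_reward <= 1.0:
        raise ValueError("p_reward must be in [0, 1]")
    rng = np.random.default_rng(seed)
    G = model.config.n_generator_units
    h = np.asarray(init_state, float).reshape(G)
    mode = (
        total_activity_mode(model.n_neurons)
        if photometry_mode is None
        else np.asarray(photometry_mode, float)
    )
    zeros_u = np.zeros(lib.rewarded_input.shape[1])

    states = []
    trial_types = []
    trial_slices = []
    n_rewarded = 0
    n_trials = 0
    t_cursor = 0
    while n_rewarded < max_rewarded and n_trials < trial_cap:
        rewarded = rng.random() < p_reward
        inp = lib.rewarded_input if rewarded else lib.unrewarded_input
        start = t_cursor
        for t in range(inp.shape[0]):
            h = model.generator_step(h, inp[t])
            states.append(h)
            t_cursor += 1
        for _ in range(lib.relaxation_bins):
            h = model.generator_step(h, zeros_u)
            states.append(h)
            t_cursor += 1
        trial_slices.append(slice(start, t_cursor))
        trial_types.append("rewarded" if rewarded else "unrewarded")
        n_rewarded += int(rewarded)
        n_trials += 1

    states = np.array(states)
    rates = model.rates_from_generator(states)
    proxy = rates @ mode
    return SessionRollout(
        states=states,
        photometry_proxy=proxy,
        trial_types=np.array(trial_types, dtype=object),
        trial_slices=trial_slices,
        hit_trial_cap=(n_rewarded < max_rewarded),
    )


def _rewarded_trial_values(rollout: SessionRollout, lib: InputLibrary) -> np.ndarray:
    """Mean photometry proxy during the 1 s reward period of each rewarded trial."""
    bs = lib.bin_size
    r0 = lib.cue_offset_bins + int(round(1.0 / bs))  # reward starts 1 s after cue
    w = int(round(1.0 / bs))
    vals = []
    for sl, tt in zip(rollout.trial_slices, rollout.trial_types):
        if tt == "rewarded":
            seg = rollout.photometry_proxy[sl][r0 : r0 + w]
            vals.append(seg.mean())
    return np.array(vals)


def sample_line_attractor_states(
    fps: FixedPointSet, n: int, rng: np.random.Generator, extent: float = 1.0
) -> np.ndarray:
    """Uniform initial conditions along the segment spanned by the slow points.

    Points are ordered by projection on their first principal component; the
    segment between the extreme projections (scaled by ``extent``) is sampled
    uniformly and mapped back through the centroid.
    """
    if fps.n_points < 2:
        raise ValueError(
            "need >= 2 fixed points to sample on the line attractor; "
            "pass explicit initial states instead"
        )
    pts = fps.points
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    lo, hi = proj.min() * extent, proj.max() * extent
    t = rng.uniform(lo, hi, size=n)
    return centroid + t[:, None] * axis


@dataclass
class TitrationResult:
    """Per-probability accumulation curves and slopes."""

    probs: np.ndarray
    mean_curves: dict  # p -> (max_rewarded,) mean proxy by n-th rewarded trial
    slopes: dict  # p -> least-squares slope of the mean curve
    n_sessions: int


def titrate(
    model: TrainedModel,
    lib: InputLibrary,
    probs,
    n_sessions: int = 1000,
    seed: int = 0,
    fps: FixedPointSet | None = None,
    init_states: np.ndarray | None = None,
    max_rewarded: int = 10,
    trial_cap: int = 40,
) -> TitrationResult:
    """Average generator rollouts over sessions for each reward probability.

    Initial conditions are sampled uniformly along the identified line
    attractor (``fps``), or taken from ``init_states``. The accumulation curve
    indexes the mean photometry proxy by n-th rewarded trial; its slope is the
    ordinary least-squares slope over that index.
    """
    rng = np.random.default_rng(seed)
    if init_states is None:
        if fps is None:
            raise ValueError("provide fps (line attractor) or explicit init_states")
        init_states = sample_line_attractor_states(fps, n_sessions, rng)
    init_states = np.atleast_2d(init_states)

    mean_curves = {}
    slopes = {}
    for p in probs:
        curves = np.full((n_sessions, max_rewarded), np.nan)
        for s in range(n_sessions):
            init = init_states[s % len(init_states)]
            roll = run_session(
                model, lib, p, init,
                seed=int(rng.integers(2**31)),
                max_rewarded=max_rewarded,
                trial_cap=trial_cap,
            )
            vals = _rewarded_trial_values(roll, lib)
            curves[s, : len(vals)] = vals[:max_rewarded]
        curve = np.nanmean(curves, axis=0)
        ok = np.isfinite(curve)
        x = np.arange(max_rewarded)[ok]
        y = curve[ok]
        slope = float(np.polyfit(x, y, 1)[0]) if len(x) >= 2 else np.nan
        mean_curves[float(p)] = curve
        slopes[float(p)] = slope
    return TitrationResult(
        probs=np.asarray(list(probs), float),
        mean_curves=mean_curves,
        slopes=slopes,
        n_sessions=n_sessions,
    )
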