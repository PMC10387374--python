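"""Targeted dimensionality reduction onto hypothesis-driven modes.

Trajectories are projected onto an ordered orthonormal basis of three
directions defined in per-neuron rate space:

1. the **total-activity mode** — the all-ones direction, whose projection
   proxies bulk (photometry-like) population activity;
2. the **condition-independent mode** — per-neuron mean activity during the
   1 s reward period minus the 1 s pre-cue period;
3. the **line-attractor mode** — the first principal component of the slow
   points (mapped to rate space).

The three vectors are orthonormalized with classical Gram-Schmidt in that
order before projection. Generator states and fixed points are mapped to rate
space through the model's linear factor and emission readouts so that all
three modes live in one space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TrainedModel
from .synth import SessionData

_ORTHO_TOL = 1e-10
_INDEP_TOL = 1e-8


@dataclass
class ModeBasis:
    """Ordered orthonormal mode basis in the analysis space."""

    modes: np.ndarray  # (n_modes, n_dims), rows orthonormal
    mode_names: tuple
    space_tag: str = "rate_space"

    def __post_init__(self) -> None:
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(len(self.modes)), atol=1e-8):
            raise ValueError("modes are not orthonormal")

    @property
    def n_modes(self) -> int:
        return len(self.modes)


def total_activity_mode(n_dims: int) -> np.ndarray:
    """The normalized all-ones direction (1, ..., 1)/sqrt(n)."""
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    return np.ones(n_dims) / np.sqrt(n_dims)


def condition_independent_mode(
    activity: np.ndarray,
    cue_bin: int,
    bin_size: float,
    reward_start_s: float = 1.0,
    window_s: float = 1.0,
) -> np.ndarray:
    """Per-neuron mean over the reward window minus the pre-cue window.

    ``activity`` is (trials, bins, neurons); the reward window starts
    ``reward_start_s`` after cue onset and the pre-cue window is the
    ``window_s`` seconds immediately before the cue. Returned un-normalized
    (normalization happens in Gram-Schmidt).
    """
    activity = np.asarray(activity, float)
    w = int(round(window_s / bin_size))
    r0 = cue_bin + int(round(reward_start_s / bin_size))
    pre0 = cue_bin - w
    if w < 1 or pre0 < 0 or r0 + w > activity.shape[1]:
        raise ValueError("windows do not fit within the trial")
    reward_mean = activity[:, r0 : r0 + w].mean(axis=(0, 1))
    precue_mean = activity[:, pre0:cue_bin].mean(axis=(0, 1))
    return reward_mean - precue_mean


def condition_independent_mode_from_session(
    data: SessionData, **kwargs
) -> np.ndarray:
    return condition_independent_mode(
        data.fluorescence, data.cue_bin, data.bin_size, **kwargs
    )


def gram_schmidt(
    vectors,
    mode_names: tuple | None = None,
    space_tag: str = "rate_space",
    sign_align: bool = True,
) -> ModeBasis:
    """Classical Gram-Schmidt orthonormalization in the given order.

    Raises if a vector is linearly dependent on its predecessors (residual
    norm below tolerance relative to the input norm), naming the offender.
    With ``sign_align``, each output after the first is flipped if needed so
    it correlates positively with its pre-orthogonalization original.
    """
    vecs = [np.asarray(v, float) for v in vectors]
    out = []
    for i, v in enumerate(vecs):
        r = v.copy()
        for q in out:
            r = r - (q @ r) * q
        nrm = np.linalg.norm(r)
        if nrm <= _INDEP_TOL * max(np.linalg.norm(v), 1.0):
            raise ValueError(
                f"vector {i} is linearly dependent on its predecessors"
            )
        q = r / nrm
        if sign_align and i > 0 and q @ v < 0:
            q = -q
        out.append(q)
    names = mode_names or tuple(f"mode_{i}" for i in range(len(out)))
    return ModeBasis(modes=np.array(out), mode_names=names, space_tag=space_tag)


def build_mode_basis(
    model: TrainedModel,
    activity: np.ndarray,
    cue_bin: int,
    bin_size: float,
    fixed_points_rate_space: np.ndarray | None = None,
    **ci_kwargs,
) -> ModeBasis:
    """Assemble the (total-activity, condition-independent, line-attractor) basis.

    All vectors are in rate space; the line-attractor mode is included only
    when at least two fixed points are supplied.
    """
    from .fixed_points import line_attractor_mode

    n = activity.shape[2]
    vecs = [total_activity_mode(n)]
    names = ["total_activity", "condition_independent"]
    vecs.append(condition_independent_mode(activity, cue_bin, bin_size, **ci_kwargs))
    if fixed_points_rate_space is not None and len(fixed_points_rate_space) >= 2:
        vecs.append(
            line_attractor_mode(fixed_points_rate_space, sign_reference=np.ones(n))
        )
        names.append("line_attractor")
    return gram_schmidt(vecs, mode_names=tuple(names))


def project(trajectories: np.ndarray, basis: ModeBasis) -> np.ndarray:
    """Inner products with each mode; preserves all leading axes."""
    trajectories = np.asarray(trajectories, float)
    if trajectories.shape[-1] != basis.modes.shape[1]:
        raise ValueError("trajectory dimension does not match basis")
    return trajectories @ basis.modes.T


def map_generator_to_rate_space(model: TrainedModel, states: np.ndarray) -> np.ndarray:
    """Map generator states to per-neuron rates via the model's linear readouts."""
    states = np.asarray(states, float)
    if states.shape[-1] != model.config.n_generator_units:
        raise ValueError("states are not in generator space")
    return model.rates_from_generator(states)
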