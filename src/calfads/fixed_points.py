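"""Fixed/slow-point analysis of the trained generator dynamics.

The generator is a discrete-time map ``h' = F(h, u)``. Under a constant
reference input u* (by convention the trial-averaged pre-cue inferred input,
which is close to zero), candidate fixed points are found by gradient-based
minimization of the squared one-step speed

    q(h) = || F(h, u*) - h ||^2         (no 1/2 factor),

initialized from states visited by the posterior trajectories plus jittered
copies. Candidates above the squared-speed threshold are discarded and
survivors merged within a tolerance. Each retained point is linearized
(exact Jacobian dF/dh) and the point cloud is classified:

* **line**: many slow points whose first principal component captures most of
  their variance and whose median linearization has exactly one eigenvalue
  near modulus 1 — a one-dimensional continuum of marginally stable states
  that integrates aligned inputs;
* **point**: all survivors collapse to a single cluster with no near-unit
  eigenvalue — an isolated stable state to which perturbations decay;
* **other**: anything else, including an empty survivor set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import TrainedModel, PosteriorOutputs

# Frozen classification thresholds: minimum number of slow points, PC1
# explained-variance ratio, and the eigenvalue band |lambda - 1| <= EPS_UNIT
# counting as "near unit modulus".
K_MIN_LINE = 5
RHO_PC1 = 0.90
EPS_UNIT = 0.05


@dataclass
class FixedPointSet:
    """Slow/fixed points of the generator under a reference input."""

    points: np.ndarray  # (M, G)
    squared_speeds: np.ndarray  # (M,)
    jacobian_eigenvalues: np.ndarray  # (M, G) complex
    reference_input: np.ndarray
    speed_threshold: float
    classification: str = "other"
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)


def squared_speed(model: TrainedModel, state: np.ndarray, inp: np.ndarray) -> np.ndarray:
    """Squared one-step speed ``||F(h, u) - h||^2``; batched over leading axis."""
    state = np.asarray(state, float)
    if state.shape[-1] != model.config.n_generator_units:
        raise ValueError("state dimension mismatch")
    nxt = model.generator_step(state, inp)
    return np.sum((nxt - state) ** 2, axis=-1)


def posterior_generator_states(
    posterior: PosteriorOutputs, model: TrainedModel
) -> np.ndarray:
    """Generator state trajectories (trials, bins, G) re-rolled from the
    posterior-mean initial conditions and inferred inputs."""
    B, T, _ = posterior.inferred_inputs.shape
    G = model.config.n_generator_units
    states = np.empty((B, T, G))
    h = posterior.ic_mean
    for t in range(T):
        h = model.generator_step(h, posterior.inferred_inputs[:, t])
        states[:, t] = h
    return states


def default_initial_states(
    posterior: PosteriorOutputs,
    model: TrainedModel,
    n_init: int = 512,
    jitter: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Subsample generator states visited by posterior trajectories, jittered.

    Jitter SD is ``jitter`` times the per-dimension std of visited states.
    """
    rng = np.random.default_rng(seed)
    flat = posterior_generator_states(posterior, model).reshape(
        -1, model.config.n_generator_units
    )
    idx = rng.integers(0, len(flat), size=n_init)
    base = flat[idx]
    sd = flat.std(axis=0)
    return base + rng.normal(scale=jitter, size=base.shape) * sd


def _speed_gradient(model: TrainedModel, h: np.ndarray, inp: np.ndarray) -> np.ndarray:
    """Exact gradient of q(h) = ||F(h,u)-h||^2: 2 (J - I)^T (F(h)-h)."""
    delta = model.generator_step(h, inp) - h
    return 2.0 * (model.generator_vjp(h, inp, delta) - delta)


def find_fixed_points(
    model: TrainedModel,
    reference_input: np.ndarray,
    init_states: np.ndarray,
    speed_threshold: float = 3e-4,
    merge_tol: float | None = None,
    max_iters: int = 2000,
    learning_rate: float = 0.05,
    reference_states: np.ndarray | None = None,
    proximity_factor: float = 0.5,
) -> FixedPointSet:
    """Minimize squared speed from every initialization; filter and merge.

    Adam descent runs on all initializations in parallel with exact gradients.
    ``merge_tol=None`` resolves to 0.01 times the RMS norm of the
    initializations (a scale-free default). Survivors are merged greedily,
    keeping the lowest-speed representative of each cluster.

    ``reference_states`` (optionally) restricts the retained set to the
    *relevant* slow points: candidates whose nearest-neighbour distance to
    the visited trajectory states exceeds ``proximity_factor`` times the mean
    per-dimension spread of those states are discarded. Slow regions far from
    any data tell us nothing about the dynamics the network actually uses.
    """
    inits = np.atleast_2d(np.asarray(init_states, float))
    if inits.size == 0:
        raise ValueError("init_states must be nonempty")
    u = np.asarray(reference_input, float).reshape(-1)
    if merge_tol is None:
        scale = float(np.sqrt(np.mean(np.sum(inits**2, axis=1))))
        merge_tol = 0.01 * max(scale, 1.0)

    h = inits.copy()
    m = np.zeros_like(h)
    v = np.zeros_like(h)
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = learning_rate
    for it in range(1, max_iters + 1):
        gr = _speed_gradient(model, h, u)
        m = b1 * m + (1 - b1) * gr
        v = b2 * v + (1 - b2) * gr**2
        mhat = m / (1 - b1**it)
        vhat = v / (1 - b2**it)
        h = h - lr * mhat / (np.sqrt(vhat) + eps)
        if it % 500 == 0:
            lr *= 0.5

    speeds = squared_speed(model, h, u)
    keep = speeds <= speed_threshold
    if reference_states is not None and np.any(keep):
        from scipy.spatial import cKDTree

        ref = np.asarray(reference_states, float).reshape(-1, h.shape[1])
        radius = proximity_factor * float(ref.std(axis=0).mean())
        dist, _ = cKDTree(ref[:: max(1, len(ref) // 2000)]).query(h[keep])
        prox = np.zeros_like(keep)
        prox[np.flatnonzero(keep)[dist <= radius]] = True
        if np.any(prox):  # never let the proximity filter empty the set
            keep = prox
    if not np.any(keep):
        return FixedPointSet(
            points=np.empty((0, h.shape[1])),
            squared_speeds=np.empty(0),
            jacobian_eigenvalues=np.empty((0, h.shape[1]), complex),
            reference_input=u,
            speed_threshold=float(speed_threshold),
            classification="other",
            converged=False,
            diagnostics={"status": "no candidate below threshold"},
        )
    cand = h[keep]
    cand_speed = speeds[keep]

    # greedy merge: lowest-speed representative absorbs neighbours within tol
    order = np.argsort(cand_speed)
    reps: list[int] = []
    for i in order:
        if all(np.linalg.norm(cand[i] - cand[j]) >= merge_tol for j in reps):
            reps.append(i)
    points = cand[reps]
    point_speeds = cand_speed[reps]

    eig = np.array(
        [np.linalg.eigvals(model.generator_jacobian(p, u)) for p in points]
    )
    fps = FixedPointSet(
        points=points,
        squared_speeds=point_speeds,
        jacobian_eigenvalues=eig,
        reference_input=u,
        speed_threshold=float(speed_threshold),
        diagnostics={"merge_tol": merge_tol, "n_candidates": int(keep.sum())},
    )
    fps.classification = classify_attractor(fps)[0]
    return fps


def linearize(
    model: TrainedModel, point: np.ndarray, reference_input: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the exact Jacobian dF/dh at (point, u*)."""
    J = model.generator_jacobian(np.asarray(point, float), np.asarray(reference_input, float))
    return np.linalg.eig(J)


def _pc1_ratio(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    total = np.sum(sv**2)
    return float(sv[0] ** 2 / total) if total > 0 else 0.0


def classify_attractor(fps: FixedPointSet) -> tuple[str, dict]:
    """Apply the frozen line/point decision rule; returns (label, diagnostics)."""
    M = fps.n_points
    diag: dict = {"n_points": M}
    if M == 0:
        return "other", diag
    near_unit = np.abs(np.abs(fps.jacobian_eigenvalues) - 1.0) <= EPS_UNIT
    unit_counts = near_unit.sum(axis=1)
    diag["median_unit_count"] = float(np.median(unit_counts))
    if M >= 2:
        diag["pc1_ratio"] = _pc1_ratio(fps.points)
    merge_tol = fps.diagnostics.get("merge_tol", 0.01)

    if (
        M >= K_MIN_LINE
        and diag.get("pc1_ratio", 0.0) >= RHO_PC1
        and np.median(unit_counts) == 1
    ):
        return "line", diag
    centroid = fps.points.mean(axis=0)
    radius = float(np.max(np.linalg.norm(fps.points - centroid, axis=1))) if M else 0.0
    diag["cluster_radius"] = radius
    if radius <= merge_tol and np.all(unit_counts == 0):
        return "point", diag
    return "other", diag


def line_attractor_mode(
    points: np.ndarray, sign_reference: np.ndarray | None = None
) -> np.ndarray:
    """Unit-norm first principal component of a slow-point cloud.

    Sign convention: positive projection onto ``sign_reference`` (default:
    the all-ones direction of the space the points live in).
    """
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) < 2:
        raise ValueError("need at least 2 points for a line-attractor mode")
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    mode = vt[0]
    ref = (
        np.ones(points.shape[1]) if sign_reference is None
        else np.asarray(sign_reference, float)
    )
    if mode @ ref < 0:
        mode = -mode
    return mode / np.linalg.norm(mode)
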