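"""End-to-end pipeline: simulate -> train -> posterior -> fixed points ->
mode basis -> in-silico titration -> session statistics, with provenance.

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn``, so any stage can be rerun independently
yet reproducibly. Every run writes a :class:`RunManifest` recording the
configuration snapshot, per-stage seeds, and SHA-256 digests of stage
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fixed_points as fp
from . import geometry, insilico, io, model, stats, synth

STAGES = (
    "simulate",
    "train",
    "posterior",
    "fixed_points",
    "geometry",
    "insilico",
    "stats",
)


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    kind: str = "line"
    n_latent: int = 4
    n_neurons: int = 30
    n_trials: int = 120
    p_reward: float = 0.85
    bins_per_trial: int = 40
    cue_bin: int = 10
    master_seed: int = 0
    model: model.ModelConfig = field(default_factory=model.ModelConfig.test_scale)
    speed_threshold: float = 3e-4
    titration_probs: tuple = (0.5, 0.8, 1.0)
    titration_sessions: int = 100
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        if self.kind not in ("line", "point"):
            raise ValueError("kind must be 'line' or 'point'")
        if not 0 <= self.p_reward <= 1:
            raise ValueError("p_reward must be in [0, 1]")
        for p in self.titration_probs:
            if not 0 <= p <= 1:
                raise ValueError(f"titration probability {p} outside [0, 1]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    outputs: dict  # stage -> {path, sha256}
    package_version: str = "0.1.0"

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def stage_seeds(master_seed: int) -> dict:
    """Per-stage integer seeds derived from the master seed (all < 2**31)."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(STAGES, children)
    }


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the requested stages in dependency order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.master_seed)
    outputs: dict = {}

    def record(stage, path):
        outputs[stage] = {"path": str(path), "sha256": io.file_digest(path)}

    stages = set(config.stages)

    session_path = out / "session.h5"
    if "simulate" in stages:
        system = synth.make_system(
            config.kind, config.n_latent, config.n_neurons, seeds["simulate"]
        )
        data, truth = synth.simulate_session(
            system,
            config.n_trials,
            config.p_reward,
            config.bins_per_trial,
            seeds["simulate"],
            cue_bin=config.cue_bin,
        )
        io.write_session(session_path, data, latents=truth.latents)
        record("simulate", session_path)
    else:
        data = io.read_session(session_path)

    model_path = out / "model.h5"
    if "train" in stages:
        data = io.read_session(session_path)
        cfg = dataclasses.replace(config.model, seed=seeds["train"])
        trained = model.train(data, cfg)
        io.save_model(model_path, trained)
        record("train", model_path)
    else:
        trained = io.load_model(model_path)

    posterior = None
    if stages & {"posterior", "fixed_points", "geometry", "insilico"}:
        posterior = model.forward_causal(trained, data, mode="mean")
        outputs["posterior"] = {"elbo": posterior.elbo}

    fps = None
    if stages & {"fixed_points", "geometry", "insilico"}:
        u_star = posterior.inferred_inputs[:, : data.cue_bin].mean(axis=(0, 1))
        inits = fp.default_initial_states(
            posterior, trained, seed=seeds["fixed_points"]
        )
        ref = fp.posterior_generator_states(posterior, trained)
        fps = fp.find_fixed_points(
            trained, u_star, inits,
            speed_threshold=config.speed_threshold,
            reference_states=ref,
        )
        fps_path = out / "fixed_points.h5"
        io.save_fixed_points(fps_path, fps)
        record("fixed_points", fps_path)

    basis = None
    if "geometry" in stages:
        fps_rate = geometry.map_generator_to_rate_space(trained, fps.points) \
            if fps.n_points >= 2 else None
        basis = geometry.build_mode_basis(
            trained,
            posterior.denoised_means,
            data.cue_bin,
            data.bin_size,
            fixed_points_rate_space=fps_rate,
        )
        outputs["geometry"] = {"modes": list(basis.mode_names)}

    titration = None
    if "insilico" in stages and fps is not None and fps.n_points >= 2:
        lib = insilico.condition_averaged_inputs(posterior, data)
        titration = insilico.titrate(
            trained,
            lib,
            config.titration_probs,
            n_sessions=config.titration_sessions,
            seed=seeds["insilico"],
            fps=fps,
        )
        outputs["insilico"] = {
            "slopes": {str(p): s for p, s in titration.slopes.items()}
        }

    if "stats" in stages:
        precue = data.fluorescence[:, max(0, data.cue_bin - 10) : data.cue_bin].mean(
            axis=(1, 2)
        )
        label, slope, pval = stats.classify_ramping(precue)
        outputs["stats"] = {"ramping": label, "slope": slope, "p": pval}

    manifest = RunManifest(
        config={
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "model"
            },
            "model": dataclasses.asdict(config.model),
        },
        seeds=seeds,
        outputs=outputs,
    )
    manifest.save(out / "manifest.json")
    return manifest
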