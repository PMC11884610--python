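"""Stage orchestration: simulate -> train -> denoise -> snr with provenance."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis import compute_snr_db, detect_particles, frame_average
from .config import RunConfig, save_config, stage_seed
from .nn.training import denoise, save_model, train
from .optics import ParticleState
from .simulate import (
    EventSchedule,
    ParticleScene,
    generate_training_pairs,
    simulate_sequence,
)
from .stackio import write_stack

logger = logging.getLogger("deepsm")

__all__ = ["build_scene", "run_pipeline"]


def build_scene(scene_cfg: dict) -> ParticleScene:
    """ParticleScene from a config block: {particles: [{x, y, ..., event: {...}}]}."""
    scene = ParticleScene()
    for entry in scene_cfg.get("particles", []):
        entry = dict(entry)
        event = entry.pop("event", None)
        state = ParticleState(**entry)
        schedule = EventSchedule(**event) if event else EventSchedule()
        scene.add(state, schedule)
    return scene


def run_pipeline(cfg: RunConfig, stages=("simulate", "train", "denoise", "snr")):
    """Execute the requested stages in order; outputs land in ``cfg.out_dir``.

    Each run writes its resolved config next to the outputs; identical
    config + seed gives identical artifacts.  A stage failure aborts with
    the stage name and cause.
    """
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise KeyError(f"unknown pipeline stage(s): {unknown}")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out_dir / "resolved_config.yaml")
    logger.info("run %s (deepsm %s, seed %d)", cfg.digest(), __version__, cfg.seed)

    artifacts: dict = {}
    for stage in stages:
        try:
            _STAGES[stage](cfg, out_dir, artifacts)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts


def _stage_simulate(cfg, out_dir, artifacts):
    optical = cfg.optical_model()
    noise = cfg.noise_model()
    scene = build_scene(cfg.scene)
    n_frames = cfg.scene.get("n_frames", 8)
    shape = tuple(cfg.scene.get("shape", (64, 64)))
    noisy, gt = simulate_sequence(
        scene, optical, noise, n_frames, shape, stage_seed(cfg.seed, "simulate")
    )
    write_stack(noisy, out_dir / "stack.tif")
    gt.to_csv(out_dir / "ground_truth.csv")
    artifacts.update(noisy=noisy, ground_truth=gt, optical=optical, noise=noise)


def _stage_train(cfg, out_dir, artifacts):
    spec = cfg.denoiser_spec()
    train_cfg = cfg.train_config()
    pairs_cfg = cfg.training.get("data", {})
    pairs = generate_training_pairs(
        n_pairs=pairs_cfg.get("n_pairs", 24),
        n_frames=pairs_cfg.get("n_frames", spec.in_frames),
        shape=tuple(pairs_cfg.get("shape", (32, 32))),
        optical=artifacts.get("optical", cfg.optical_model()),
        noise=artifacts.get("noise", cfg.noise_model()),
        seed=stage_seed(cfg.seed, "train-data"),
    )
    model, history = train(pairs, spec, train_cfg)
    history.to_csv(out_dir / "history.csv", index=False)
    save_model(out_dir / "model.npz", model, train_cfg)
    artifacts.update(model=model, history=history)


def _stage_denoise(cfg, out_dir, artifacts):
    if "model" not in artifacts:
        raise ValueError("denoise stage requires a trained model")
    noisy = artifacts["noisy"]
    denoised = denoise(noisy, artifacts["model"])
    write_stack(denoised, out_dir / "denoised.tif")
    artifacts["denoised"] = denoised


def _stage_snr(cfg, out_dir, artifacts):
    optical = artifacts.get("optical", cfg.optical_model())
    bg = optical.background_level
    rows = []
    for label in ("noisy", "denoised"):
        seq = artifacts.get(label)
        if seq is None:
            continue
        diff = seq.frames - bg
        image = diff[len(diff) // 2]
        for pid, (x, y) in enumerate(detect_particles(image, optical)):
            rec = compute_snr_db(image, (x, y), particle_id=pid)
            rows.append({
                "source": label, "particle_id": pid, "x_px": x, "y_px": y,
                "snr_db": rec.snr_db, "detected": rec.detected,
            })
    if "noisy" in artifacts and len(artifacts["noisy"]) >= 4:
        fa = frame_average(artifacts["noisy"].frames - bg, 4)
        for pid, (x, y) in enumerate(detect_particles(fa[0], optical)):
            rec = compute_snr_db(fa[0], (x, y), particle_id=pid)
            rows.append({
                "source": "frame_average_4", "particle_id": pid, "x_px": x,
                "y_px": y, "snr_db": rec.snr_db, "detected": rec.detected,
            })
    table = pd.DataFrame(rows, columns=["source", "particle_id", "x_px", "y_px",
                                        "snr_db", "detected"])
    table.to_csv(out_dir / "snr.csv", index=False)
    artifacts["snr_table"] = table


_STAGES = {
    "simulate": _stage_simulate,
    "train": _stage_train,
    "denoise": _stage_denoise,
    "snr": _stage_snr,
}
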