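"""Configuration-driven orchestration of the full synthetic study.

``run_pipeline`` executes the requested stages in order — simulate →
select-stimuli → rdm → rsa → unique-variance → decode → searchlight — on
synthetic data with a single global seed, writing every intermediate
artifact plus a JSON manifest (parameters, seeds, content hashes) so a run
is exactly re-derivable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from . import decoding, ga, inference, io, rdm, spatial, synth, variance

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGES = ("simulate", "select-stimuli", "rdm", "rsa", "unique-variance", "decode", "searchlight")

# stage -> stages it needs upstream
_DEPS = {
    "simulate": (),
    "select-stimuli": ("simulate",),
    "rdm": ("simulate",),
    "rsa": ("rdm",),
    "unique-variance": ("rdm",),
    "decode": ("simulate",),
    "searchlight": ("rdm",),
}


class SimBlock(BaseModel):
    n_stimuli: int = 300
    n_dims: int = 5
    n_participants: int = 26
    n_subjects: int = 19
    noise_sd: float = 2.72
    rdm_noise_sd: float = 1.0
    target_corr_offdiag: float = 0.0  # uniform planted inter-dimension correlation
    # epochs (condition count kept apart from the rating pool)
    n_conditions: int = 8
    trials_per_condition: int = 30
    n_channels: int = 64
    time_start_ms: float = -100.0
    time_stop_ms: float = 600.0
    time_step_ms: float = 20.0
    effect_window_ms: tuple[float, float] = (50.0, 400.0)
    effect_size: float = 1.0
    epoch_noise_sd: float = 1.0
    # volume
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    roi_corner: tuple[int, int, int] = (2, 2, 2)
    roi_size: tuple[int, int, int] = (4, 4, 4)


class GABlock(BaseModel):
    subset_size: int = 128
    n_generations: int = 1000
    population_size: int = 200
    n_random_baseline: int = 1000
    penalty_weight: float = 10.0
    max_per_category: int = 2


class DecodeBlock(BaseModel):
    k: int = 5
    n_iterations: int = 100


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown fields are rejected."""

    model_config = {"extra": "forbid"}

    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    seed: int = 0
    outdir: str = "pipeline_out"
    fdr_q: float = 0.05
    searchlight_radius: float = 2.0
    n_top_voxels: int = 100
    sim: SimBlock = Field(default_factory=SimBlock)
    ga: GABlock = Field(default_factory=GABlock)
    decode: DecodeBlock = Field(default_factory=DecodeBlock)

    def check(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0,1)")
        seen: set[str] = set()
        for s in self.stages:
            missing = [d for d in _DEPS[s] if d not in seen]
            if missing:
                raise ValueError(f"stage {s!r} requires upstream stage(s) {missing}")
            seen.add(s)


def load_config(path: str | Path) -> PipelineConfig:
    try:
        cfg = PipelineConfig.model_validate_json(Path(path).read_text())
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ValueError(f"config {path}: invalid field '{loc}': {first['msg']}") from err
    cfg.check()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    config.check()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    seeds = {s: int(root.integers(2**31)) for s in STAGES}
    manifest: dict = {"seed": config.seed, "stages": {}, "parameters": json.loads(config.model_dump_json())}

    ctx: dict = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        files = _run_stage(stage, config, seeds[stage], outdir, ctx)
        manifest["stages"][stage] = {
            "seed": seeds[stage],
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        }
        logger.info("stage %s done in %.2fs", stage, manifest["stages"][stage]["wall_time_s"])

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(stage: str, config: PipelineConfig, seed: int, outdir: Path, ctx: dict) -> list[Path]:
    sim = config.sim
    if stage == "simulate":
        corr = np.full((sim.n_dims, sim.n_dims), sim.target_corr_offdiag)
        np.fill_diagonal(corr, 1.0)
        spec = synth.SimSpec(
            seed=seed, n_stimuli=sim.n_stimuli, n_dims=sim.n_dims,
            n_participants=sim.n_participants, target_corr=corr, noise_sd=sim.noise_sd,
        )
        catalog = synth.gen_rating_catalog(spec)
        ctx["catalog"] = catalog
        path = outdir / "catalog.csv"
        io.catalog_to_csv(catalog, path)
        return [path]

    if stage == "select-stimuli":
        g = config.ga
        cfg = ga.GAConfig(
            subset_size=g.subset_size, n_generations=g.n_generations,
            population_size=g.population_size, n_random_baseline=g.n_random_baseline,
            penalty_weight=g.penalty_weight, max_per_category=g.max_per_category, seed=seed,
        )
        result = ga.run_ga(ctx["catalog"], cfg)
        baseline = ga.random_baseline(ctx["catalog"], cfg)
        ctx["subset"] = result.best_subset
        path = outdir / "selection.json"
        path.write_text(json.dumps({
            "best_subset": result.best_subset,
            "best_fitness": result.best_fitness,
            "fitness_trace": result.fitness_trace.tolist(),
            "baseline": {"min": float(baseline.min()), "median": float(np.median(baseline))},
            "covered_cells": result.covered_cells,
            "corr_matrix": result.corr_matrix.tolist(),
        }, indent=2))
        return [path]

    if stage == "rdm":
        catalog: synth.RatingCatalog = ctx["catalog"]
        subset = ctx.get("subset", catalog.stimulus_ids)
        idx = [catalog.stimulus_ids.index(s) for s in subset]
        sub_catalog = synth.RatingCatalog(
            stimulus_ids=[catalog.stimulus_ids[i] for i in idx],
            category_labels=[catalog.category_labels[i] for i in idx],
            dimension_names=catalog.dimension_names,
            ratings=catalog.ratings[:, idx, :],
        )
        models = rdm.ModelRDMSet(rdms={
            d: rdm.model_rdm_from_dimension(sub_catalog, d) for d in sub_catalog.dimension_names
        })
        ctx["models"] = models
        # subject RDMs: equal-weight mixture of the first two dimensions + noise
        weights = np.zeros(len(models.rdms))
        weights[: min(2, weights.size)] = 1.0
        stack = synth.gen_subject_rdm_stack(
            [m.values for m in models.rdms.values()], weights,
            noise_sd=sim.rdm_noise_sd * np.mean([m.values.std() for m in models.rdms.values()]),
            n_subjects=sim.n_subjects, seed=seed, stimulus_ids=list(sub_catalog.stimulus_ids),
        )
        ctx["stack"] = stack
        files = []
        for name, m in models.rdms.items():
            p = outdir / f"model_{name.replace(' ', '_')}.csv"
            io.rdm_to_csv(m, p)
            files.append(p)
        io.stack_to_dir(stack, outdir / "subject_rdms")
        files.append(outdir / "subject_rdms" / "manifest.json")
        return files

    if stage == "rsa":
        result = rdm.rsa(ctx["models"], ctx["stack"])
        rows = ["subject,model,rho"]
        for s, sid in enumerate(result.subject_ids):
            for m, name in enumerate(result.model_names):
                rows.append(f"{sid},{name},{result.rho[s, m]:.6f}")
        csv_path = outdir / "rsa.csv"
        csv_path.write_text("\n".join(rows) + "\n")
        p_mat, rej = inference.pairwise_model_comparison(result.rho, result.model_names, config.fdr_q)
        json_path = outdir / "rsa_summary.json"
        json_path.write_text(json.dumps({
            "model_names": result.model_names,
            "group_mean_rho": result.group_mean().tolist(),
            "noise_ceiling": result.noise_ceiling,
            "pairwise_p": p_mat.tolist(),
            "pairwise_rejected": rej.tolist(),
        }, indent=2))
        return [csv_path, json_path]

    if stage == "unique-variance":
        parts = variance.partition_per_subject(ctx["models"], ctx["stack"])
        names = ctx["models"].names
        rows = ["subject,model,unique_variance,r2_full"]
        for sid, part in zip(ctx["stack"].subject_ids, parts):
            for name in names:
                rows.append(f"{sid},{name},{part.unique[name]:.6f},{part.r2_full:.6f}")
        path = outdir / "unique_variance.csv"
        path.write_text("\n".join(rows) + "\n")
        return [path]

    if stage == "decode":
        spec = synth.SimSpec(
            seed=seed, n_conditions=sim.n_conditions,
            trials_per_condition=sim.trials_per_condition, n_channels=sim.n_channels,
            timepoints=np.arange(sim.time_start_ms, sim.time_stop_ms + 1e-9, sim.time_step_ms),
            effect_window_ms=sim.effect_window_ms, effect_size=sim.effect_size,
            noise_sd=sim.epoch_noise_sd,
        )
        epochs = synth.gen_epochs(spec)
        cfg = decoding.DecodingConfig(k=config.decode.k, n_iterations=config.decode.n_iterations,
                                      seed=seed)
        tc = decoding.decode_all_pairs(epochs, cfg)
        mean = tc.mean_curve()
        rows = ["time_ms,mean_accuracy"]
        rows += [f"{t:g},{a:.4f}" for t, a in zip(tc.timepoints, mean)]
        path = outdir / "decoding_mean_curve.csv"
        path.write_text("\n".join(rows) + "\n")
        sig = inference.timecourse_significance(tc.accuracies.T, tc.timepoints,
                                                null_value=50.0, q=config.fdr_q)
        jpath = outdir / "decoding_latency.json"
        jpath.write_text(json.dumps({
            "onset_ms": sig.onset_ms, "peak_ms": sig.peak_ms,
            "peak_accuracy": float(mean.max()),
        }, indent=2))
        return [path, jpath]

    if stage == "searchlight":
        models: rdm.ModelRDMSet = ctx["models"]
        first = models.rdms[models.names[0]]
        n_cond = min(first.n_stimuli, 12)
        model_small = rdm.RDM(stimulus_ids=first.stimulus_ids[:n_cond],
                              values=first.values[:n_cond, :n_cond])
        roi = np.zeros(sim.grid_shape, dtype=bool)
        z0, y0, x0 = sim.roi_corner
        dz, dy, dx = sim.roi_size
        roi[z0:z0 + dz, y0:y0 + dy, x0:x0 + dx] = True
        spec = synth.SimSpec(seed=seed, n_conditions=n_cond, grid_shape=sim.grid_shape,
                             noise_sd=sim.epoch_noise_sd)
        vol = synth.gen_voxel_volume(spec, roi.ravel(), model_small.values)
        sl = spatial.searchlight_rsa(vol, model_small, radius=config.searchlight_radius)
        roi_def = spatial.select_roi_top_voxels(vol.activation_map, vol.mask, config.n_top_voxels)
        path = outdir / "searchlight.json"
        finite = np.isfinite(sl.rho)
        path.write_text(json.dumps({
            "radius": sl.radius,
            "n_centers": int(finite.sum()),
            "mean_rho_in_roi": float(np.nanmean(sl.rho[roi.ravel()])),
            "mean_rho_outside": float(np.nanmean(sl.rho[~roi.ravel() & finite])),
            "roi_n_voxels": int(roi_def.voxel_indices.size),
        }, indent=2))
        return [path]

    raise ValueError(f"unknown stage {stage!r}")
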