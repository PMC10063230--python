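"""Effect-size reporting and pipeline orchestration.

Group comparisons use Cohen's d only (no p-values: significance could be
inflated at will by simulating more realizations).  d > 0.8 is flagged as a
large and d > 1.3 as a very large effect.  ``run_pipeline`` chains the
stages synth -> fit -> vae -> perturb -> report on a config file, recording
seeds and artifact hashes in a JSON manifest; completed stages are skipped
on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fc import FCMatrix, compute_fc, simulated_bold
from .fitting import FitResult, GAConfig, derive_seed, fit_group
from .hopf import HopfParams, SimulationConfig, integrate_hopf
from .io import (
    save_connectome,
    save_fc,
    save_fit_ensemble,
    save_region_table,
)
from .perturbation import StimulationProtocol, compute_landscape, target_centroid
from .priors import build_membership_prior, combine_delta
from .synthetic import SyntheticSpec, generate_connectome, generate_group_fc, generate_region_metadata
from .vae import LatentPoint, VAEConfig, encode_batch, train_vae, vectorize_fc

logger = logging.getLogger(__name__)

__all__ = [
    "LARGE_EFFECT",
    "VERY_LARGE_EFFECT",
    "EffectSize",
    "EffectSizeReport",
    "cohens_d",
    "compare_parameter_ensembles",
    "split_by_median",
    "latent_distance_distributions",
    "run_pipeline",
]

LARGE_EFFECT = 0.8
VERY_LARGE_EFFECT = 1.3


def cohens_d(sample_a, sample_b, hedges: bool = False) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    The pooled SD uses (n-1)-weighted variances (Cohen's original form);
    ``hedges=True`` applies the small-sample bias correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(d)


@dataclass
class EffectSize:
    """One comparison: signed d, magnitude flags and the direction of shift."""

    d: float
    large: bool
    very_large: bool
    direction: str  # "toward_fixed_point" | "toward_oscillation" | "none"

    @classmethod
    def from_samples(cls, patient, control) -> "EffectSize":
        d = cohens_d(patient, control)
        mag = abs(d)
        if mag > LARGE_EFFECT:
            direction = "toward_fixed_point" if d < 0 else "toward_oscillation"
        else:
            direction = "none"
        return cls(d=d, large=mag > LARGE_EFFECT, very_large=mag > VERY_LARGE_EFFECT, direction=direction)


@dataclass
class EffectSizeReport:
    """Coefficient-level and region-level effect sizes of one group contrast."""

    delta_level: dict[str, EffectSize]
    region_level: dict[str, EffectSize]

    @property
    def flagged_regions(self) -> list[str]:
        return [r for r, e in self.region_level.items() if e.large]


def _delta_matrix(results: list[FitResult]) -> np.ndarray:
    return np.vstack([r.best_delta for r in results])


def compare_parameter_ensembles(
    ensembles: dict[str, list[FitResult]],
    M,
    control: str = "CNT",
) -> dict[str, EffectSizeReport]:
    """Effect sizes of each patient-analogue ensemble against the control.

    Per group coefficient, Cohen's d between the patient and control
    distributions across runs; per region, d on the combined bifurcation
    parameters a = M @ delta.  Regions with |d| > 0.8 are flagged together
    with the direction of the shift.
    """
    if control not in ensembles:
        raise KeyError(f"control group {control!r} missing from ensembles")
    n_groups = M.n_groups
    for name, runs in ensembles.items():
        if len(runs) < 2:
            raise ValueError(f"ensemble {name!r} needs >= 2 runs")
        if any(r.best_delta.shape[0] != n_groups for r in runs):
            raise ValueError(f"ensemble {name!r} does not match the prior's group count")

    ctrl_delta = _delta_matrix(ensembles[control])
    ctrl_a = np.vstack([combine_delta(M, d) for d in ctrl_delta])
    region_labels = [f"R{i:03d}" for i in range(M.n_regions)]

    reports = {}
    for name, runs in ensembles.items():
        if name == control:
            continue
        pat_delta = _delta_matrix(runs)
        pat_a = np.vstack([combine_delta(M, d) for d in pat_delta])
        delta_level = {
            M.group_labels[j]: EffectSize.from_samples(pat_delta[:, j], ctrl_delta[:, j])
            for j in range(n_groups)
        }
        region_level = {
            region_labels[i]: EffectSize.from_samples(pat_a[:, i], ctrl_a[:, i])
            for i in range(M.n_regions)
        }
        reports[name] = EffectSizeReport(delta_level=delta_level, region_level=region_level)
    return reports


def split_by_median(scores, labels=None) -> tuple[list, list]:
    """Median split of subjects by a severity scalar; ties go to the high group."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two subjects")
    if np.all(s == s[0]):
        raise ValueError("all scores equal: median split undefined")
    labels = list(labels) if labels is not None else list(range(s.size))
    if len(labels) != s.size:
        raise ValueError("labels and scores length mismatch")
    med = float(np.median(s))
    low = [lab for lab, v in zip(labels, s) if v < med]
    high = [lab for lab, v in zip(labels, s) if v >= med]
    return low, high


def latent_distance_distributions(
    points_per_group: dict[str, list[LatentPoint]],
    target_group: str,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Distances of each run's latent point to the target group's centroid.

    Returns the per-group distance samples and, for every non-target group,
    Cohen's d of its distances against the target group's own distances.
    """
    if target_group not in points_per_group:
        raise KeyError(f"target group {target_group!r} missing")
    for name, pts in points_per_group.items():
        if not pts:
            raise ValueError(f"group {name!r} is empty")
    centroid = target_centroid(points_per_group[target_group])
    c = centroid.as_array()
    distances = {
        name: np.array([np.linalg.norm(p.as_array() - c) for p in pts])
        for name, pts in points_per_group.items()
    }
    effects = {
        name: cohens_d(d, distances[target_group])
        for name, d in distances.items()
        if name != target_group
    }
    return distances, effects


# ---------------------------------------------------------------------------
# pipeline orchestration


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        return yaml.safe_load(text)
    return dict(config)


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _finish_stage(out: Path, manifest: dict, stage: str, outputs: list[Path]) -> None:
    manifest["stages"][stage] = {
        "status": "done",
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    _write_manifest(out, manifest)


def _stage_done(out: Path, manifest: dict, stage: str) -> bool:
    entry = manifest["stages"].get(stage)
    if not entry or entry.get("status") != "done":
        return False
    return all((out / name).exists() for name in entry["outputs"])


def run_pipeline(config, out_dir: str | Path) -> dict:
    """Run synth -> fit -> vae -> perturb -> report on a config mapping/file.

    Artifacts and a manifest with per-stage status, seeds and SHA-256 hashes
    are written to ``out_dir``.  Stages already marked done in an existing
    manifest are skipped (resumability); a stage failure marks the stage
    failed and skips everything downstream.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text())
        if manifest_path.exists()
        else {"seed": seed, "stages": {}}
    )

    state: dict = {}
    stages = [
        ("synth", _stage_synth),
        ("fit", _stage_fit),
        ("vae", _stage_vae),
        ("perturb", _stage_perturb),
        ("report", _stage_report),
    ]
    failed = False
    for name, fn in stages:
        if failed:
            manifest["stages"][name] = {"status": "skipped", "outputs": {}}
            continue
        try:
            outputs = fn(cfg, seed, out, state, resume=_stage_done(out, manifest, name))
            _finish_stage(out, manifest, name, outputs)
        except Exception as exc:  # noqa: BLE001 - pipeline-level isolation
            logger.error("stage %s failed: %s", name, exc)
            manifest["stages"][name] = {"status": "failed", "error": str(exc), "outputs": {}}
            failed = True
    _write_manifest(out, manifest)
    return manifest


def _make_spec(cfg: dict, seed: int) -> SyntheticSpec:
    synth_cfg = dict(cfg.get("synthetic", {}))
    synth_cfg.setdefault("seed", derive_seed(seed, 1))
    return SyntheticSpec(**synth_cfg)


def _prepare_state(cfg: dict, seed: int, state: dict) -> None:
    """Deterministic in-memory inputs shared by the stages (cheap to rebuild)."""
    if "spec" in state:
        return
    spec = _make_spec(cfg, seed)
    state["spec"] = spec
    state["connectome"] = generate_connectome(spec)
    state["meta"] = generate_region_metadata(spec)
    state["M"] = build_membership_prior(state["meta"].labels)
    state["omega"] = 2.0 * np.pi * state["meta"].natural_frequencies
    state["groups"] = list(spec.group_deltas)
    state["group_fc"] = {}
    state["truth"] = {}
    for g in state["groups"]:
        _, avg, truth = generate_group_fc(
            spec, g, state["connectome"], state["M"], state["omega"]
        )
        state["group_fc"][g] = avg
        state["truth"][g] = truth


def _stage_synth(cfg, seed, out, state, resume) -> list[Path]:
    _prepare_state(cfg, seed, state)
    spec, meta, conn = state["spec"], state["meta"], state["connectome"]
    outputs = [out / "connectome.tsv", out / "atrophy.tsv", out / "labels.tsv",
               out / "ground_truth.json"]
    outputs += [out / f"fc_{g.replace('+', 'plus').replace('-', 'minus')}.tsv" for g in state["groups"]]
    if resume:
        return outputs
    save_connectome(out / "connectome.tsv", conn)
    save_region_table(out / "atrophy.tsv", conn.region_labels, list(meta.atrophy))
    save_region_table(out / "labels.tsv", conn.region_labels, meta.labels)
    truth_blob = {
        g: {
            "delta_star": state["truth"][g].delta_star.tolist(),
            "a_star": state["truth"][g].a_star.tolist(),
        }
        for g in state["groups"]
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_blob, indent=1, sort_keys=True))
    for g in state["groups"]:
        safe = g.replace("+", "plus").replace("-", "minus")
        save_fc(out / f"fc_{safe}.tsv", state["group_fc"][g])
    return outputs


def _stage_fit(cfg, seed, out, state, resume) -> list[Path]:
    _prepare_state(cfg, seed, state)
    fit_cfg = dict(cfg.get("fit", {}))
    groups = fit_cfg.get("groups") or state["groups"]
    n_runs = int(fit_cfg.get("n_runs", 3))
    ga_kwargs = dict(fit_cfg.get("ga", {}))
    sim_cfg = SimulationConfig(
        dt=state["spec"].dt,
        duration=float(fit_cfg.get("duration", state["spec"].duration)),
        transient=state["spec"].transient,
    )
    outputs = []
    state["fits"] = {}
    for g in groups:
        safe = g.replace("+", "plus").replace("-", "minus")
        path = out / f"fits_{safe}.tsv"
        outputs.append(path)
        ga = GAConfig(**ga_kwargs)
        results = fit_group(
            state["M"],
            state["connectome"],
            state["omega"],
            state["group_fc"][g],
            n_runs=n_runs,
            base_seed=derive_seed(seed, 2, sum(ord(c) for c in g)),
            ga_config=ga,
            G=state["spec"].G,
            sim_config=sim_cfg,
            beta=state["spec"].beta,
        )
        state["fits"][g] = results
        save_fit_ensemble(path, results, state["M"].group_labels)
    return outputs


def _best_delta(results: list[FitResult]) -> np.ndarray:
    return min(results, key=lambda r: r.best_gof).best_delta


def _simulate_samples(state, delta, n_samples, duration, base_seed) -> list[FCMatrix]:
    spec = state["spec"]
    a = combine_delta(state["M"], delta)
    params = HopfParams(a=a, omega=state["omega"], G=spec.G, beta=spec.beta)
    samples = []
    for s in range(n_samples):
        cfg = SimulationConfig(
            dt=spec.dt, duration=duration, transient=spec.transient, seed=derive_seed(base_seed, s)
        )
        signals = integrate_hopf(params, state["connectome"], cfg)
        samples.append(compute_fc(simulated_bold(signals), state["connectome"].region_labels))
    return samples


def _stage_vae(cfg, seed, out, state, resume) -> list[Path]:
    _prepare_state(cfg, seed, state)
    if "fits" not in state:
        raise RuntimeError("fit stage did not run in this session; delete the manifest to rerun")
    vae_cfg = dict(cfg.get("vae", {}))
    n_per_group = int(vae_cfg.get("samples_per_group", 50))
    duration = float(vae_cfg.get("duration", state["spec"].duration))
    groups = list(state["fits"])
    sample_sets = {}
    for gi, g in enumerate(groups):
        sample_sets[g] = _simulate_samples(
            state, _best_delta(state["fits"][g]), n_per_group, duration, derive_seed(seed, 3, gi)
        )
    all_samples = [m for g in groups for m in sample_sets[g]]
    input_dim = vectorize_fc(all_samples[0]).shape[0]
    config = VAEConfig(
        input_dim=input_dim,
        encoder_widths=tuple(vae_cfg.get("encoder_widths", (512, 64))),
        batch_size=int(vae_cfg.get("batch_size", 128)),
        epochs=int(vae_cfg.get("epochs", 50)),
        learning_rate=float(vae_cfg.get("learning_rate", 1e-3)),
        kl_weight=float(vae_cfg.get("kl_weight", 1.0)),
        seed=derive_seed(seed, 4),
    )
    model = train_vae(all_samples, config)
    state["vae"] = model
    state["latent"] = {
        g: [LatentPoint(float(z[0]), float(z[1])) for z in encode_batch(model, sample_sets[g])]
        for g in groups
    }
    rows = [
        {"group": g, "run_id": i, "z1": p.z1, "z2": p.z2}
        for g in groups
        for i, p in enumerate(state["latent"][g])
    ]
    latent_path = out / "latent_points.tsv"
    pd.DataFrame(rows).to_csv(latent_path, sep="\t", index=False, float_format="%.12g")
    model_path = out / "vae_model.json"
    model.save(model_path)
    return [latent_path, model_path]


def _stage_perturb(cfg, seed, out, state, resume) -> list[Path]:
    if "vae" not in state:
        raise RuntimeError("vae stage did not run in this session; delete the manifest to rerun")
    pert_cfg = dict(cfg.get("perturb", {}))
    group = pert_cfg.get("group") or [g for g in state["fits"] if g != "CNT"][0]
    target_group = pert_cfg.get("target_group", "CNT")
    kind = pert_cfg.get("kind", "sync")
    step = float(pert_cfg.get("grid_step", 0.5))
    stop = float(pert_cfg.get("grid_stop", 2.0))
    if kind == "noise":
        step, stop = -abs(step), -abs(stop)
    grid = np.round(np.arange(0.0, stop + step / 2, step), 10)
    protocol = StimulationProtocol(
        kind=kind, intensity_grid=grid, runs_per_point=int(pert_cfg.get("runs_per_point", 5))
    )
    pairs = state["connectome"].homotopic_pairs
    n_pairs = pert_cfg.get("n_pairs")
    if n_pairs:
        pairs = pairs[: int(n_pairs)]
    spec = state["spec"]
    a = combine_delta(state["M"], _best_delta(state["fits"][group]))
    params = HopfParams(a=a, omega=state["omega"], G=spec.G, beta=spec.beta)
    target = target_centroid(state["latent"][target_group])
    sim_cfg = SimulationConfig(
        dt=spec.dt,
        duration=float(pert_cfg.get("duration", spec.duration)),
        transient=spec.transient,
    )
    landscape = compute_landscape(
        params,
        state["connectome"],
        protocol,
        state["vae"],
        target,
        pairs=pairs,
        seed=derive_seed(seed, 5),
        sim_config=sim_cfg,
    )
    state["landscape"] = landscape
    rows = []
    for traj in landscape.trajectories:
        for intensity, p in zip(traj.intensities, traj.points):
            rows.append(
                {
                    "kind": traj.kind,
                    "pair": f"{traj.pair[0]}-{traj.pair[1]}",
                    "intensity": intensity,
                    "z1": p.z1,
                    "z2": p.z2,
                    "min_distance": landscape.min_distance_to_target[traj.pair],
                }
            )
    traj_path = out / "trajectories.tsv"
    pd.DataFrame(rows).to_csv(traj_path, sep="\t", index=False, float_format="%.12g")
    rank_path = out / "ranking.tsv"
    pd.DataFrame(
        {
            "pair": [f"{i}-{j}" for i, j in landscape.ranking],
            "min_distance": [landscape.min_distance_to_target[p] for p in landscape.ranking],
            "top_decile": [p in landscape.top_decile for p in landscape.ranking],
        }
    ).to_csv(rank_path, sep="\t", index=False, float_format="%.12g")
    return [traj_path, rank_path]


def _stage_report(cfg, seed, out, state, resume) -> list[Path]:
    if "fits" not in state or "latent" not in state:
        raise RuntimeError("upstream stages did not run in this session")
    control = dict(cfg.get("report", {})).get("control", "CNT")
    usable = {g: r for g, r in state["fits"].items() if len(r) >= 2}
    blob: dict = {"control": control}
    if control in usable and len(usable) > 1:
        reports = compare_parameter_ensembles(usable, state["M"], control=control)
        blob["effect_sizes"] = {
            g: {
                "delta_level": {k: asdict(v) for k, v in rep.delta_level.items()},
                "flagged_regions": rep.flagged_regions,
            }
            for g, rep in reports.items()
        }
    distances, effects = latent_distance_distributions(state["latent"], control)
    blob["latent_distance"] = {
        "mean_distance_to_control": {g: float(d.mean()) for g, d in distances.items()},
        "cohens_d_vs_control": effects,
    }
    if "landscape" in state:
        blob["top_decile_pairs"] = [list(p) for p in state["landscape"].top_decile]
    report_path = out / "report.json"
    report_path.write_text(json.dumps(blob, indent=1, sort_keys=True))
    return [report_path]
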