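"""In-silico stimulation protocols and perturbational landscapes.

Three protocols act on one homotopic region pair at a time: Wave adds
periodic forcing F0*cos(omega0*t) at each member's own natural frequency;
Sync shifts the pair's bifurcation parameters up (delta-a > 0, toward
synchronized oscillation); Noise shifts them down (delta-a < 0, toward
noisy fixed-point dynamics).  Sweeping the intensity and encoding the
resulting FC matrices with the trained VAE yields one latent trajectory per
pair; pairs are ranked by the minimum latent distance of their trajectory
to a target (e.g. healthy-group) point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fc import FCMatrix, compute_fc, group_average_fc, simulated_bold
from .fitting import derive_seed
from .hopf import Connectome, Forcing, HopfParams, SimulationConfig, integrate_hopf
from .vae import LatentPoint, TrainedVAE, encode, latent_distance

__all__ = [
    "StimulationProtocol",
    "Trajectory",
    "LandscapeResult",
    "apply_stimulation",
    "perturbed_fc",
    "compute_landscape",
    "target_centroid",
]

logger = logging.getLogger(__name__)

PROTOCOL_KINDS = ("wave", "sync", "noise")


@dataclass
class StimulationProtocol:
    """A stimulation kind plus its intensity sweep.

    Wave and Sync sweep 0 to 2 in steps of 0.1; Noise sweeps 0 to -2 in
    steps of -0.1.  Each grid point is averaged over ``runs_per_point``
    independent simulations.
    """

    kind: str
    intensity_grid: np.ndarray | None = None
    runs_per_point: int = 100

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown stimulation kind {self.kind!r}")
        if self.intensity_grid is None:
            step = -0.1 if self.kind == "noise" else 0.1
            stop = -2.0 if self.kind == "noise" else 2.0
            self.intensity_grid = np.round(np.arange(0.0, stop + step / 2, step), 10)
        grid = np.asarray(self.intensity_grid, dtype=float)
        if grid.size < 1 or grid[0] != 0.0:
            raise ValueError("intensity grid must start at 0")
        diffs = np.diff(grid)
        if self.kind == "noise":
            if np.any(diffs >= 0) or np.any(grid > 0):
                raise ValueError("noise intensities must decrease from 0")
        else:
            if np.any(diffs <= 0) or np.any(grid < 0):
                raise ValueError(f"{self.kind} intensities must increase from 0")
        if self.runs_per_point < 1:
            raise ValueError("runs_per_point must be >= 1")
        self.intensity_grid = grid


@dataclass
class Trajectory:
    """Latent points of one pair's intensity sweep (first point: intensity 0)."""

    pair: tuple[int, int]
    kind: str
    intensities: np.ndarray
    points: list[LatentPoint]
    fc_per_intensity: list[FCMatrix] | None = None

    def distances_to(self, target: LatentPoint) -> np.ndarray:
        return np.array([latent_distance(p, target) for p in self.points])


@dataclass
class LandscapeResult:
    """Trajectories for every pair plus the min-distance ranking."""

    trajectories: list[Trajectory]
    min_distance_to_target: dict[tuple[int, int], float]
    ranking: list[tuple[int, int]]
    top_decile: list[tuple[int, int]]
    failed_pairs: list[tuple[int, int]] = field(default_factory=list)


def apply_stimulation(
    params: HopfParams,
    kind: str,
    pair: tuple[int, int],
    intensity: float,
) -> tuple[HopfParams, Forcing | None]:
    """Perturbed parameters and forcing for one protocol at one homotopic pair.

    Sync/Noise shift the bifurcation parameter of both pair members by the
    (signed) intensity; Wave leaves parameters untouched and adds in-phase
    periodic forcing of amplitude ``intensity`` at each member's own natural
    frequency.  Intensity 0 returns the baseline for every kind.
    """
    if kind not in PROTOCOL_KINDS:
        raise ValueError(f"unknown stimulation kind {kind!r}")
    i, j = pair
    n = params.n_regions
    if not (0 <= i < n and 0 <= j < n and i != j):
        raise ValueError(f"invalid region pair {pair} for {n} regions")
    if kind == "sync" and intensity < 0:
        raise ValueError("sync intensity must be >= 0")
    if kind == "noise" and intensity > 0:
        raise ValueError("noise intensity must be <= 0")
    if kind == "wave" and intensity < 0:
        raise ValueError("wave amplitude must be >= 0")

    if kind == "wave":
        if intensity == 0:
            return params, None
        amplitude = np.zeros(n)
        amplitude[[i, j]] = intensity
        return params, Forcing(amplitude=amplitude, omega0=params.omega.copy())

    a = params.a.copy()
    a[[i, j]] += intensity
    return params.with_a(a), None


def perturbed_fc(
    params: HopfParams,
    connectome: Connectome,
    kind: str,
    pair: tuple[int, int],
    intensity: float,
    runs: int = 100,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
) -> FCMatrix:
    """Fisher-z average FC over independent simulations under one stimulation."""
    sim_config = sim_config or SimulationConfig()
    stim_params, forcing = apply_stimulation(params, kind, pair, intensity)
    matrices = []
    for run in range(runs):
        cfg = SimulationConfig(
            dt=sim_config.dt,
            duration=sim_config.duration,
            transient=sim_config.transient,
            seed=derive_seed(seed, run),
            initial_state=sim_config.initial_state,
        )
        signals = integrate_hopf(stim_params, connectome, cfg, forcing)
        matrices.append(compute_fc(simulated_bold(signals), connectome.region_labels))
    return group_average_fc(matrices)


def target_centroid(points: list[LatentPoint]) -> LatentPoint:
    """Coordinate-wise mean of a group's encoded latent points."""
    if not points:
        raise ValueError("need at least one latent point")
    arr = np.array([[p.z1, p.z2] for p in points])
    return LatentPoint(float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def compute_landscape(
    params: HopfParams,
    connectome: Connectome,
    protocol: StimulationProtocol,
    vae: TrainedVAE,
    target_point: LatentPoint,
    pairs: list[tuple[int, int]] | None = None,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    keep_fc: bool = False,
) -> LandscapeResult:
    """Sweep the protocol over homotopic pairs and rank them by proximity to target.

    For each pair and each intensity on the grid, the stimulated model's
    average FC is encoded with the VAE, producing one latent trajectory per
    pair.  Pairs are ranked in ascending order of the minimum latent
    distance of their trajectory to ``target_point``; the top decile
    (ceil(n_pairs / 10)) is reported as candidate stimulation targets.
    Failed pairs are logged and excluded.
    """
    pairs = list(pairs) if pairs is not None else list(connectome.homotopic_pairs)
    if not pairs:
        raise ValueError("no homotopic pairs to stimulate")
    trajectories: list[Trajectory] = []
    failed: list[tuple[int, int]] = []
    min_dist: dict[tuple[int, int], float] = {}

    for p_idx, pair in enumerate(pairs):
        try:
            pts, fcs = [], []
            for k_idx, intensity in enumerate(protocol.intensity_grid):
                fc = perturbed_fc(
                    params,
                    connectome,
                    protocol.kind,
                    pair,
                    float(intensity),
                    runs=protocol.runs_per_point,
                    seed=derive_seed(seed, p_idx, k_idx),
                    sim_config=sim_config,
                )
                pts.append(encode(vae, fc))
                if keep_fc:
                    fcs.append(fc)
            traj = Trajectory(
                pair=tuple(pair),
                kind=protocol.kind,
                intensities=protocol.intensity_grid.copy(),
                points=pts,
                fc_per_intensity=fcs if keep_fc else None,
            )
            trajectories.append(traj)
            min_dist[tuple(pair)] = float(traj.distances_to(target_point).min())
        except Exception as exc:  # noqa: BLE001 - pair-level isolation
            logger.warning("pair %s failed: %s", pair, exc)
            failed.append(tuple(pair))
    if not trajectories:
        raise RuntimeError("every pair failed")
    if failed:
        logger.warning("%d of %d pairs failed and were excluded", len(failed), len(pairs))

    ranking = sorted(min_dist, key=lambda pr: (min_dist[pr], pr))
    n_top = int(np.ceil(len(ranking) / 10))
    return LandscapeResult(
        trajectories=trajectories,
        min_distance_to_target=min_dist,
        ranking=ranking,
        top_decile=ranking[:n_top],
        failed_pairs=failed,
    )
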