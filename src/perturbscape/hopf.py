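"""Coupled stochastic Hopf (Stuart-Landau) oscillators on a connectome.

Each brain region j is a nonlinear oscillator at the normal form of a Hopf
bifurcation with local bifurcation parameter ``a_j`` and natural angular
frequency ``omega_j``.  For ``a_j < 0`` the node decays to a stable fixed
point at the origin; for ``a_j > 0`` it settles on a limit cycle of radius
``sqrt(a_j)`` and frequency ``omega_j / 2*pi``.  Nodes are diffusively
coupled through the structural connectivity matrix ``K`` scaled by a global
coupling factor ``G``, and driven by additive Gaussian noise of amplitude
``beta``.  The system is integrated with the Euler-Maruyama scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Connectome",
    "HopfParams",
    "SimulationConfig",
    "Forcing",
    "SimulatedSignals",
    "integrate_hopf",
    "estimate_natural_frequencies",
    "DimensionMismatchError",
    "SimulationDivergedError",
]

#: maximum structural coupling weight after rescaling ("weak coupling")
SC_MAX_WEIGHT = 0.2


class DimensionMismatchError(ValueError):
    """Shapes of parameters, connectome and/or forcing disagree."""


class SimulationDivergedError(RuntimeError):
    """The integrated state became non-finite."""


@dataclass
class Connectome:
    """Structural connectivity: symmetric nonnegative coupling weights.

    Parameters
    ----------
    weights : ndarray, shape (n, n)
        Symmetric, nonnegative, zero-diagonal coupling matrix with maximum
        entry at most ``SC_MAX_WEIGHT`` (0.2).  Use :meth:`from_weights` to
        rescale an arbitrary raw matrix.
    region_labels : list of str
        Ordered region names.
    homotopic_pairs : list of (int, int)
        Left/right instances of the same anatomical region.  When derived
        automatically, consecutive (even, odd) indices are paired, matching
        the AAL left/right interleaving convention.
    """

    weights: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    homotopic_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionMismatchError(f"connectome must be square, got {w.shape}")
        if not np.allclose(w, w.T, atol=1e-10, rtol=0.0):
            raise ValueError("connectome weights must be symmetric (tol 1e-10)")
        if np.any(w < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("connectome diagonal must be zero")
        if w.max(initial=0.0) > SC_MAX_WEIGHT + 1e-12:
            raise ValueError(
                f"max weight {w.max():.4g} exceeds {SC_MAX_WEIGHT}; "
                "use Connectome.from_weights to rescale"
            )
        self.weights = w
        n = w.shape[0]
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(n)]
        if len(self.region_labels) != n:
            raise DimensionMismatchError("region_labels length != matrix size")
        if not self.homotopic_pairs:
            if n % 2:
                raise ValueError(
                    "auto-derived homotopic pairing requires an even region count"
                )
            self.homotopic_pairs = [(i, i + 1) for i in range(0, n, 2)]
        for i, j in self.homotopic_pairs:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"invalid homotopic pair ({i}, {j})")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_weights(
        cls,
        raw: np.ndarray,
        region_labels: list[str] | None = None,
        homotopic_pairs: list[tuple[int, int]] | None = None,
    ) -> "Connectome":
        """Build a connectome from a raw weight matrix.

        Symmetry is enforced by averaging with the transpose, the diagonal
        is zeroed (self-coupling cancels in the diffusive coupling anyway),
        and weights are rescaled so the maximum entry equals 0.2.
        """
        w = np.asarray(raw, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionMismatchError(f"connectome must be square, got {w.shape}")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        peak = w.max(initial=0.0)
        if peak <= 0:
            raise ValueError("connectome has no positive weights; cannot rescale")
        w = w * (SC_MAX_WEIGHT / peak)
        return cls(w, region_labels or [], homotopic_pairs or [])


@dataclass
class HopfParams:
    """Per-region Hopf model parameters.

    ``a`` is the bifurcation parameter (dimensionless), ``omega`` the natural
    angular frequency in rad/s, ``G`` the global coupling scalar and ``beta``
    the additive-noise amplitude (default 0.04).
    """

    a: np.ndarray
    omega: np.ndarray
    G: float = 0.5
    beta: float = 0.04

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.a.shape != self.omega.shape:
            raise DimensionMismatchError(
                f"a has shape {self.a.shape} but omega has shape {self.omega.shape}"
            )
        if np.any(self.omega <= 0):
            raise ValueError("omega must be strictly positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.a.shape[0]

    def with_a(self, a: np.ndarray) -> "HopfParams":
        return HopfParams(a=np.asarray(a, float), omega=self.omega, G=self.G, beta=self.beta)


@dataclass
class SimulationConfig:
    """Euler-Maruyama integration settings.

    ``dt`` is the integration step in seconds (0.1 s by default), ``duration``
    the total simulated time, and ``transient`` the initial stretch discarded
    from the output.  ``initial_state`` is either ``"small-random"`` (seeded
    uniform components in [-0.1, 0.1]) or an explicit per-region complex array.
    """

    dt: float = 0.1
    duration: float = 480.0
    transient: float = 20.0
    seed: int = 0
    initial_state: str | np.ndarray = "small-random"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.duration > self.transient >= 0):
            raise ValueError("require duration > transient >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_keep(self) -> int:
        return int(np.floor((self.duration - self.transient) / self.dt))


@dataclass
class Forcing:
    """Additive periodic forcing F0 * cos(omega0 * t + phase).

    By default the forcing enters only the drift of the real component x
    (``force_y=False``).  Zero amplitude leaves the dynamics untouched.
    """

    amplitude: np.ndarray
    omega0: np.ndarray
    phase: float = 0.0
    force_y: bool = False

    def __post_init__(self) -> None:
        self.amplitude = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        self.omega0 = np.atleast_1d(np.asarray(self.omega0, dtype=float))
        if self.amplitude.shape != self.omega0.shape:
            raise DimensionMismatchError("forcing amplitude/omega0 shape mismatch")
        if np.any(self.amplitude < 0):
            raise ValueError("forcing amplitude must be nonnegative")

    @property
    def is_active(self) -> bool:
        return bool(np.any(self.amplitude > 0))


@dataclass
class SimulatedSignals:
    """Real (x) and imaginary (y) components of the simulated state."""

    x: np.ndarray
    y: np.ndarray
    sampling_interval: float

    @property
    def n_regions(self) -> int:
        return self.x.shape[0]

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]


_FINITE_CHECK_EVERY = 50


def integrate_hopf(
    params: HopfParams,
    connectome: Connectome,
    config: SimulationConfig,
    forcing: Forcing | None = None,
) -> SimulatedSignals:
    """Integrate the coupled stochastic Hopf system by Euler-Maruyama.

    Per step, the deterministic drift

    ``dx_j = (a_j - x_j^2 - y_j^2) x_j - omega_j y_j + G sum_i K_ij (x_i - x_j)``
    ``dy_j = (a_j - x_j^2 - y_j^2) y_j + omega_j x_j + G sum_i K_ij (y_i - y_j)``

    is advanced by ``dt`` and independent Gaussian increments
    ``beta * sqrt(dt) * N(0, 1)`` are added to each component of each region.
    Optional forcing adds ``F0 cos(omega0 t + phase)`` to the x drift of the
    forced regions.  Identical seeds give identical outputs.
    """
    n = connectome.n_regions
    if params.n_regions != n:
        raise DimensionMismatchError(
            f"params describe {params.n_regions} regions, connectome has {n}"
        )
    if forcing is not None and forcing.amplitude.shape[0] != n:
        raise DimensionMismatchError(
            f"forcing describes {forcing.amplitude.shape[0]} regions, connectome has {n}"
        )

    rng = np.random.default_rng(config.seed)
    if isinstance(config.initial_state, str):
        if config.initial_state != "small-random":
            raise ValueError(f"unknown initial_state {config.initial_state!r}")
        x = rng.uniform(-0.1, 0.1, size=n)
        y = rng.uniform(-0.1, 0.1, size=n)
    else:
        z0 = np.asarray(config.initial_state, dtype=complex)
        if z0.shape != (n,):
            raise DimensionMismatchError("initial_state must have one value per region")
        x = z0.real.copy()
        y = z0.imag.copy()

    a, omega, G, beta = params.a, params.omega, params.G, params.beta
    K = connectome.weights
    ksum = K.sum(axis=1)
    dt = config.dt
    noise_scale = beta * np.sqrt(dt)
    n_steps, n_keep = config.n_steps, config.n_keep
    n_trans = n_steps - n_keep

    apply_forcing = forcing is not None and forcing.is_active
    if apply_forcing:
        F0, w0, phase = forcing.amplitude, forcing.omega0, forcing.phase
        force_y = forcing.force_y

    out_x = np.empty((n, n_keep))
    out_y = np.empty((n, n_keep))

    # noise pre-drawn in chunks: same stream as per-step draws, less overhead
    chunk_size = 512
    noise_chunk = None
    # overflow during a diverging trajectory is reported via the explicit
    # finiteness check below, not as a numpy warning
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(n_steps):
            r2 = x * x + y * y
            dx = (a - r2) * x - omega * y + G * (K @ x - ksum * x)
            dy = (a - r2) * y + omega * x + G * (K @ y - ksum * y)
            if apply_forcing:
                drive = F0 * np.cos(w0 * (step * dt) + phase)
                dx = dx + drive
                if force_y:
                    dy = dy + drive
            if beta > 0:
                k = step % chunk_size
                if k == 0:
                    noise_chunk = rng.standard_normal((min(chunk_size, n_steps - step), 2, n))
                incr = noise_chunk[k]
                x = x + dt * dx + noise_scale * incr[0]
                y = y + dt * dy + noise_scale * incr[1]
            else:
                x = x + dt * dx
                y = y + dt * dy
            if step % _FINITE_CHECK_EVERY == 0 or step == n_steps - 1:
                bad = ~(np.isfinite(x) & np.isfinite(y))
                if bad.any():
                    region = int(np.flatnonzero(bad)[0])
                    raise SimulationDivergedError(
                        f"non-finite state at step {step} "
                        f"(t={step * dt:.1f} s), region {region} "
                        f"({connectome.region_labels[region]})"
                    )
            if step >= n_trans:
                k = step - n_trans
                out_x[:, k] = x
                out_y[:, k] = y

    return SimulatedSignals(x=out_x, y=out_y, sampling_interval=dt)


def estimate_natural_frequencies(
    series: np.ndarray | list[np.ndarray],
    sampling_interval: float,
    band: tuple[float, float] = (0.04, 0.07),
) -> np.ndarray:
    """Estimate per-region natural angular frequencies from signals.

    For each region the peak of the periodogram of the band-passed signal,
    restricted to ``band`` Hz, is taken as the natural frequency; with a list
    of per-subject arrays the peak frequencies are averaged across subjects.
    Returns ``omega = 2 * pi * f`` in rad/s.
    """
    subjects = series if isinstance(series, list) else [series]
    low, high = band
    nyquist = 0.5 / sampling_interval
    if not (0 < low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyquist:.4g})"
        )
    fs = 1.0 / sampling_interval

    peak_freqs = []
    for s_idx, arr in enumerate(subjects):
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[1] < 64:
            raise ValueError(f"series {s_idx}: need >= 64 samples, got {arr.shape[1]}")
        if np.any(arr.std(axis=1) == 0):
            region = int(np.flatnonzero(arr.std(axis=1) == 0)[0])
            raise ValueError(f"series {s_idx}: region {region} is flat (no spectral peak)")
        b, a_coef = sps.butter(2, [low, high], btype="bandpass", fs=fs)
        filtered = sps.filtfilt(b, a_coef, arr - arr.mean(axis=1, keepdims=True), axis=1)
        freqs, power = sps.periodogram(filtered, fs=fs, axis=1)
        in_band = (freqs >= low) & (freqs <= high)
        if not in_band.any():
            raise ValueError("requested band contains no frequency bins; series too short")
        band_power = power[:, in_band]
        if np.any(band_power.max(axis=1) <= 0):
            region = int(np.flatnonzero(band_power.max(axis=1) <= 0)[0])
            raise ValueError(f"series {s_idx}: region {region} has no power in band")
        peak_freqs.append(freqs[in_band][np.argmax(band_power, axis=1)])

    shapes = {p.shape for p in peak_freqs}
    if len(shapes) != 1:
        raise DimensionMismatchError("subject series disagree on region count")
    return 2.0 * np.pi * np.mean(peak_freqs, axis=0)
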