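"""Functional connectivity: preprocessing, Pearson FC, group averaging, SSIM.

Signals are detrended, demeaned, band-pass filtered in the 0.04-0.07 Hz band
(zero-phase 2nd-order Butterworth) and z-scored before Pearson correlation.
Group averaging applies Fisher's r-to-z transform before the mean.  Model fit
is scored with the structural similarity index (SSIM) between FC matrices
treated as images over a fixed dynamic range of 2 (entries span [-1, 1]); the
fitting objective is the distance 1 - SSIM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter

from .hopf import DimensionMismatchError, SimulatedSignals

__all__ = [
    "FCMatrix",
    "BandpassSpec",
    "preprocess_series",
    "simulated_bold",
    "compute_fc",
    "group_average_fc",
    "ssim_similarity",
    "goodness_of_fit",
]


@dataclass
class FCMatrix:
    """Pearson correlation matrix of band-passed signals."""

    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionMismatchError(f"FC matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-8, rtol=0.0):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("FC matrix must have unit diagonal")
        if v.min() < -1 - 1e-8 or v.max() > 1 + 1e-8:
            raise ValueError("FC entries must lie in [-1, 1]")
        self.values = v
        if not self.region_labels:
            self.region_labels = [f"R{i:03d}" for i in range(v.shape[0])]
        elif len(self.region_labels) != v.shape[0]:
            raise DimensionMismatchError("region_labels length != matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class BandpassSpec:
    """Band-pass settings: low/high cutoffs in Hz and the sampling interval in s."""

    low: float = 0.04
    high: float = 0.07
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        nyquist = 0.5 / self.sampling_interval
        if not (0 < self.low < self.high < nyquist):
            raise ValueError(
                f"require 0 < low < high < Nyquist; got ({self.low}, {self.high}) "
                f"with Nyquist {nyquist:.4g} Hz"
            )

    @property
    def fs(self) -> float:
        return 1.0 / self.sampling_interval


def preprocess_series(series: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Detrend, demean, zero-phase band-pass and z-score a region x time array."""
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    if arr.shape[1] < 64:
        raise ValueError(f"need >= 64 time points, got {arr.shape[1]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    flat = arr.std(axis=1) == 0
    if flat.any():
        region = int(np.flatnonzero(flat)[0])
        raise ValueError(f"region {region} has zero variance")

    detrended = sps.detrend(arr, axis=1, type="linear")
    b, a = sps.butter(2, [spec.low, spec.high], btype="bandpass", fs=spec.fs)
    filtered = sps.filtfilt(b, a, detrended, axis=1)
    sd = filtered.std(axis=1)
    dead = sd < 1e-12
    if dead.any():
        region = int(np.flatnonzero(dead)[0])
        raise ValueError(f"region {region} has zero variance after filtering")
    return (filtered - filtered.mean(axis=1, keepdims=True)) / sd[:, None]


def simulated_bold(
    signals: SimulatedSignals,
    spec: BandpassSpec | None = None,
    resample_interval: float = 2.0,
) -> np.ndarray:
    """Resample the simulated x component to BOLD-like sampling and preprocess.

    The x component is decimated to one sample per ``resample_interval``
    seconds (simple stride decimation; the band-pass that follows removes any
    out-of-band content) and then passed through :func:`preprocess_series`.
    """
    step_f = resample_interval / signals.sampling_interval
    step = int(round(step_f))
    if step < 1 or abs(step_f - step) > 1e-9:
        raise ValueError(
            f"sampling interval {signals.sampling_interval} s does not divide "
            f"resample interval {resample_interval} s"
        )
    if spec is None:
        spec = BandpassSpec(sampling_interval=resample_interval)
    elif abs(spec.sampling_interval - resample_interval) > 1e-12:
        spec = BandpassSpec(low=spec.low, high=spec.high, sampling_interval=resample_interval)
    return preprocess_series(signals.x[:, ::step], spec)


def compute_fc(series: np.ndarray, region_labels: list[str] | None = None) -> FCMatrix:
    """Pearson correlation across regions of a preprocessed region x time array."""
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains NaN or infinite values")
    r = np.corrcoef(arr)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, region_labels or [])


def group_average_fc(matrices: list[FCMatrix]) -> FCMatrix:
    """Fisher-z average of FC matrices: tanh(mean(atanh(r))) with unit diagonal."""
    if not matrices:
        raise ValueError("need at least one FC matrix")
    shape = matrices[0].values.shape
    stack = []
    for m in matrices:
        v = m.values
        if v.shape != shape:
            raise DimensionMismatchError("FC matrices have mismatched shapes")
        off = ~np.eye(shape[0], dtype=bool)
        if np.any(np.abs(v[off]) >= 1.0):
            raise ValueError("off-diagonal |r| >= 1: Fisher transform diverges")
        z = v.copy()
        z[off] = np.arctanh(v[off])
        stack.append(z)
    mean_z = np.mean(stack, axis=0)
    out = np.tanh(mean_z)
    np.fill_diagonal(out, 1.0)
    return FCMatrix(out, matrices[0].region_labels)


def _ssim_global(a: np.ndarray, b: np.ndarray, data_range: float, k1: float, k2: float) -> float:
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def _ssim_windowed(
    a: np.ndarray, b: np.ndarray, data_range: float, k1: float, k2: float, sigma: float
) -> float:
    # Gaussian-weighted local statistics (Wang et al. algorithm): population
    # covariance, reflect boundary, window radius int(truncate*sigma + 0.5).
    truncate = 3.5
    radius = int(truncate * sigma + 0.5)
    win = 2 * radius + 1
    if min(a.shape) < win:
        raise ValueError(f"matrix smaller than the {win}x{win} SSIM window")
    filt = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ua = gaussian_filter(a, **filt)
    ub = gaussian_filter(b, **filt)
    uaa = gaussian_filter(a * a, **filt)
    ubb = gaussian_filter(b * b, **filt)
    uab = gaussian_filter(a * b, **filt)
    va = uaa - ua * ua
    vb = ubb - ub * ub
    vab = uab - ua * ub
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua**2 + ub**2 + c1) * (va + vb + c2))
    pad = (win - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean(dtype=np.float64))


def ssim_similarity(
    fc_a: FCMatrix | np.ndarray,
    fc_b: FCMatrix | np.ndarray,
    mode: str = "global",
    data_range: float = 2.0,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = 1.5,
) -> float:
    """Structural similarity between two FC matrices.

    ``mode="global"`` (default) computes a single SSIM statistic from the
    means, variances and covariance of the full matrices; ``mode="windowed"``
    computes the canonical mean of local Gaussian-weighted SSIM values
    (sigma 1.5).  The dynamic range is fixed at 2 so scores are comparable
    across matrices.  Symmetric in its arguments; 1 means identical.
    """
    a = fc_a.values if isinstance(fc_a, FCMatrix) else np.asarray(fc_a, dtype=float)
    b = fc_b.values if isinstance(fc_b, FCMatrix) else np.asarray(fc_b, dtype=float)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mode == "global":
        return _ssim_global(a, b, data_range, k1, k2)
    if mode == "windowed":
        return _ssim_windowed(a, b, data_range, k1, k2, sigma)
    raise ValueError(f"unknown SSIM mode {mode!r}")


def goodness_of_fit(fc_sim: FCMatrix | np.ndarray, fc_emp: FCMatrix | np.ndarray, **kwargs) -> float:
    """Fit distance 1 - SSIM in [0, 2]; 0 is a perfect fit.  Minimized by the fitter."""
    return 1.0 - ssim_similarity(fc_sim, fc_emp, **kwargs)
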