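"""Variational autoencoder embedding FC matrices in a 2-D latent space.

A dense encoder (two ReLU hidden layers) maps the vectorized upper triangle
of an FC matrix to a diagonal-Gaussian posterior over two latent units
(z1, z2); a mirrored decoder maps latent points back to FC space.  Training
minimizes mean squared reconstruction error plus the KL divergence of the
posterior from a standard normal, by mini-batch Adam.  The implementation
is self-contained numpy (forward, backward and optimizer written out), which
keeps runs bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fc import FCMatrix
from .hopf import DimensionMismatchError

__all__ = [
    "VAEConfig",
    "LatentPoint",
    "TrainedVAE",
    "vectorize_fc",
    "devectorize_fc",
    "train_vae",
    "encode",
    "encode_batch",
    "decode",
    "latent_distance",
]


def vectorize_fc(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (diagonal excluded) flattening of an FC matrix."""
    v = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise DimensionMismatchError(f"expected a square matrix, got {v.shape}")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu].copy()


def devectorize_fc(vec: np.ndarray, region_labels: list[str] | None = None) -> FCMatrix:
    """Rebuild a symmetric unit-diagonal FC matrix from an upper-triangle vector."""
    vec = np.asarray(vec, dtype=float).ravel()
    length = vec.shape[0]
    n = int((1 + np.sqrt(1 + 8 * length)) / 2)
    if n * (n - 1) // 2 != length:
        raise ValueError(f"vector length {length} is not a triangular number")
    out = np.eye(n)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return FCMatrix(np.clip(out, -1.0, 1.0), region_labels or [])


@dataclass
class VAEConfig:
    """Architecture and training settings.

    ``encoder_widths`` are the two hidden-layer sizes (decoder mirrored);
    the latent space is fixed at two dimensions.  Defaults follow standard
    practice for this scale: batches of 128, 50 epochs, Adam at 1e-3, unit
    KL weight, seeded 80/20 train/validation split.
    """

    input_dim: int
    encoder_widths: tuple[int, int] = (512, 64)
    latent_dim: int = 2
    batch_size: int = 128
    epochs: int = 50
    learning_rate: float = 1e-3
    kl_weight: float = 1.0
    seed: int = 0
    split_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.latent_dim != 2:
            raise ValueError("the latent space is two-dimensional by construction")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if min(self.encoder_widths) < self.latent_dim:
            raise ValueError("hidden widths must be at least the latent dimension")
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")


@dataclass
class LatentPoint:
    z1: float
    z2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.z1) and np.isfinite(self.z2)):
            raise ValueError("latent coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.z1, self.z2])


@dataclass
class TrainedVAE:
    """Trained weights plus the loss curves of both objective components."""

    params: dict[str, np.ndarray]
    config: VAEConfig
    train_recon: np.ndarray = field(default_factory=lambda: np.array([]))
    train_kl: np.ndarray = field(default_factory=lambda: np.array([]))
    val_recon: np.ndarray = field(default_factory=lambda: np.array([]))
    val_kl: np.ndarray = field(default_factory=lambda: np.array([]))

    def save(self, path: str) -> None:
        blob = {
            "config": {
                "input_dim": self.config.input_dim,
                "encoder_widths": list(self.config.encoder_widths),
                "latent_dim": self.config.latent_dim,
                "batch_size": self.config.batch_size,
                "epochs": self.config.epochs,
                "learning_rate": self.config.learning_rate,
                "kl_weight": self.config.kl_weight,
                "seed": self.config.seed,
                "split_fraction": self.config.split_fraction,
            },
            "params": {k: v.tolist() for k, v in self.params.items()},
            "train_recon": self.train_recon.tolist(),
            "train_kl": self.train_kl.tolist(),
            "val_recon": self.val_recon.tolist(),
            "val_kl": self.val_kl.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path: str) -> "TrainedVAE":
        with open(path) as fh:
            blob = json.load(fh)
        cfg = blob["config"]
        cfg["encoder_widths"] = tuple(cfg["encoder_widths"])
        return cls(
            params={k: np.asarray(v) for k, v in blob["params"].items()},
            config=VAEConfig(**cfg),
            train_recon=np.asarray(blob["train_recon"]),
            train_kl=np.asarray(blob["train_kl"]),
            val_recon=np.asarray(blob["val_recon"]),
            val_kl=np.asarray(blob["val_kl"]),
        )


def _init_params(config: VAEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    d, (h1, h2), k = config.input_dim, config.encoder_widths, config.latent_dim

    def he(n_in: int, n_out: int) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

    return {
        "W1": he(d, h1), "b1": np.zeros(h1),
        "W2": he(h1, h2), "b2": np.zeros(h2),
        "Wm": he(h2, k), "bm": np.zeros(k),
        "Wv": he(h2, k), "bv": np.zeros(k),
        "U1": he(k, h2), "c1": np.zeros(h2),
        "U2": he(h2, h1), "c2": np.zeros(h1),
        "U3": he(h1, d), "c3": np.zeros(d),
    }


def _encode_forward(p: dict[str, np.ndarray], x: np.ndarray):
    h1 = np.maximum(x @ p["W1"] + p["b1"], 0.0)
    h2 = np.maximum(h1 @ p["W2"] + p["b2"], 0.0)
    mu = h2 @ p["Wm"] + p["bm"]
    lv = np.clip(h2 @ p["Wv"] + p["bv"], -15.0, 15.0)
    return h1, h2, mu, lv


def _decode_forward(p: dict[str, np.ndarray], z: np.ndarray):
    g1 = np.maximum(z @ p["U1"] + p["c1"], 0.0)
    g2 = np.maximum(g1 @ p["U2"] + p["c2"], 0.0)
    xh = g2 @ p["U3"] + p["c3"]
    return g1, g2, xh


def _losses(x: np.ndarray, xh: np.ndarray, mu: np.ndarray, lv: np.ndarray):
    recon = float(np.mean(np.sum((xh - x) ** 2, axis=1)))
    kl = float(np.mean(-0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv), axis=1)))
    return recon, kl


def _batch_step(
    p: dict[str, np.ndarray],
    x: np.ndarray,
    eps: np.ndarray,
    kl_weight: float,
) -> tuple[dict[str, np.ndarray], float, float]:
    """One forward/backward pass; returns gradients and the two loss terms."""
    B = x.shape[0]
    h1, h2, mu, lv = _encode_forward(p, x)
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    g1, g2, xh = _decode_forward(p, z)
    recon, kl = _losses(x, xh, mu, lv)

    g: dict[str, np.ndarray] = {}
    dxh = 2.0 * (xh - x) / B
    g["U3"] = g2.T @ dxh
    g["c3"] = dxh.sum(axis=0)
    dg2 = (dxh @ p["U3"].T) * (g2 > 0)
    g["U2"] = g1.T @ dg2
    g["c2"] = dg2.sum(axis=0)
    dg1 = (dg2 @ p["U2"].T) * (g1 > 0)
    g["U1"] = z.T @ dg1
    g["c1"] = dg1.sum(axis=0)
    dz = dg1 @ p["U1"].T

    dmu = dz + kl_weight * mu / B
    dlv = dz * eps * 0.5 * std + kl_weight * 0.5 * (np.exp(lv) - 1.0) / B
    g["Wm"] = h2.T @ dmu
    g["bm"] = dmu.sum(axis=0)
    g["Wv"] = h2.T @ dlv
    g["bv"] = dlv.sum(axis=0)
    dh2 = (dmu @ p["Wm"].T + dlv @ p["Wv"].T) * (h2 > 0)
    g["W2"] = h1.T @ dh2
    g["b2"] = dh2.sum(axis=0)
    dh1 = (dh2 @ p["W2"].T) * (h1 > 0)
    g["W1"] = x.T @ dh1
    g["b1"] = dh1.sum(axis=0)
    return g, recon, kl


def _as_matrix(dataset) -> np.ndarray:
    rows = [vectorize_fc(m) if isinstance(m, (FCMatrix, np.ndarray)) else m for m in dataset]
    rows = [np.asarray(r, float).ravel() for r in rows]
    return np.vstack(rows)


def train_vae(dataset, config: VAEConfig | None = None) -> TrainedVAE:
    """Train the VAE on a list of FC matrices (or pre-vectorized rows).

    An 80/20 seeded split separates training and validation data; the loss
    (per-sample summed squared reconstruction error plus kl_weight times the
    KL divergence from the standard normal) is minimized with Adam.  Returns
    per-epoch training and validation curves for both components.
    """
    X = _as_matrix(dataset)
    if config is None:
        config = VAEConfig(input_dim=X.shape[1])
    if X.shape[1] != config.input_dim:
        raise DimensionMismatchError(
            f"dataset vectors have length {X.shape[1]}, config expects {config.input_dim}"
        )
    if X.shape[0] < config.batch_size:
        raise ValueError(
            f"dataset size {X.shape[0]} smaller than batch size {config.batch_size}"
        )

    rng = np.random.default_rng(config.seed)
    n_train = int(round(config.split_fraction * X.shape[0]))
    perm = rng.permutation(X.shape[0])
    train, val = X[perm[:n_train]], X[perm[n_train:]]

    p = _init_params(config, rng)
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(val_) for k, val_ in p.items()}
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    t = 0

    tr_recon, tr_kl, va_recon, va_kl = [], [], [], []
    for epoch in range(config.epochs):
        order = rng.permutation(train.shape[0])
        ep_recon, ep_kl, n_batches = 0.0, 0.0, 0
        for start in range(0, train.shape[0] - config.batch_size + 1, config.batch_size):
            xb = train[order[start : start + config.batch_size]]
            eps = rng.standard_normal((xb.shape[0], config.latent_dim))
            grads, recon, kl = _batch_step(p, xb, eps, config.kl_weight)
            if not (np.isfinite(recon) and np.isfinite(kl)):
                raise RuntimeError(f"NaN loss at epoch {epoch}")
            t += 1
            for key in p:
                m[key] = b1 * m[key] + (1 - b1) * grads[key]
                v[key] = b2 * v[key] + (1 - b2) * grads[key] ** 2
                mhat = m[key] / (1 - b1**t)
                vhat = v[key] / (1 - b2**t)
                p[key] = p[key] - lr * mhat / (np.sqrt(vhat) + eps_adam)
            ep_recon += recon
            ep_kl += kl
            n_batches += 1
        tr_recon.append(ep_recon / max(n_batches, 1))
        tr_kl.append(ep_kl / max(n_batches, 1))
        if val.shape[0]:
            _, _, mu, lv = _encode_forward(p, val)
            _, _, xh = _decode_forward(p, mu)
            r, k = _losses(val, xh, mu, lv)
        else:
            r, k = np.nan, np.nan
        va_recon.append(r)
        va_kl.append(k)

    return TrainedVAE(
        params=p,
        config=config,
        train_recon=np.asarray(tr_recon),
        train_kl=np.asarray(tr_kl),
        val_recon=np.asarray(va_recon),
        val_kl=np.asarray(va_kl),
    )


def encode(model: TrainedVAE, fc: FCMatrix | np.ndarray) -> LatentPoint:
    """Posterior-mean latent coordinates of one FC matrix (deterministic)."""
    vec = vectorize_fc(fc) if not (isinstance(fc, np.ndarray) and fc.ndim == 1) else fc
    if vec.shape[0] != model.config.input_dim:
        raise DimensionMismatchError(
            f"input has length {vec.shape[0]}, model expects {model.config.input_dim}"
        )
    _, _, mu, _ = _encode_forward(model.params, vec[None, :])
    return LatentPoint(float(mu[0, 0]), float(mu[0, 1]))


def encode_batch(model: TrainedVAE, dataset) -> np.ndarray:
    """Posterior means for a list of FC matrices, as an (n, 2) array."""
    X = _as_matrix(dataset)
    _, _, mu, _ = _encode_forward(model.params, X)
    return mu


def decode(model: TrainedVAE, point: LatentPoint, region_labels: list[str] | None = None) -> FCMatrix:
    """Decode a latent point to a valid FC matrix (symmetric, clipped, unit diagonal)."""
    z = point.as_array()[None, :]
    _, _, xh = _decode_forward(model.params, z)
    return devectorize_fc(np.clip(xh[0], -1.0, 1.0), region_labels)


def latent_distance(p: LatentPoint, q: LatentPoint) -> float:
    """Euclidean distance between two latent points."""
    return float(np.hypot(p.z1 - q.z1, p.z2 - q.z2))
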