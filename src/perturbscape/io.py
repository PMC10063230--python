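"""Delimited-text I/O for the pipeline's artifacts.

Everything is plain TSV (matrices with a header row of region labels,
two-column region metadata) or JSON (sidecar metadata, manifests), so runs
are diffable and portable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import FCMatrix
from .fitting import FitResult
from .hopf import Connectome, SimulatedSignals

logger = logging.getLogger(__name__)

__all__ = [
    "save_matrix",
    "load_matrix",
    "load_connectome",
    "save_connectome",
    "save_fc",
    "load_fc",
    "save_signals",
    "load_signals",
    "load_region_table",
    "save_region_table",
    "save_fit_ensemble",
    "load_fit_ensemble",
]


def save_matrix(path: str | Path, values: np.ndarray, labels: list[str] | None = None) -> None:
    n = values.shape[0]
    labels = labels or [f"R{i:03d}" for i in range(n)]
    pd.DataFrame(values, columns=labels).to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def load_connectome(path: str | Path, homotopic_pairs: list[tuple[int, int]] | None = None) -> Connectome:
    """Load a square weight matrix and rescale it to a maximum of 0.2."""
    raw, labels = load_matrix(path)
    peak = raw.max(initial=0.0)
    conn = Connectome.from_weights(raw, labels, homotopic_pairs or [])
    logger.info("connectome %s: raw max weight %.4g rescaled to 0.2", path, peak)
    return conn


def save_connectome(path: str | Path, connectome: Connectome) -> None:
    save_matrix(path, connectome.weights, connectome.region_labels)


def save_fc(path: str | Path, fc: FCMatrix) -> None:
    save_matrix(path, fc.values, fc.region_labels)


def load_fc(path: str | Path) -> FCMatrix:
    values, labels = load_matrix(path)
    return FCMatrix(values, labels)


def save_signals(path: str | Path, signals: SimulatedSignals, meta: dict | None = None) -> None:
    """Region x time TSV plus a JSON sidecar with sampling metadata."""
    path = Path(path)
    pd.DataFrame(signals.x).to_csv(path, sep="\t", index=False, header=False, float_format="%.12g")
    sidecar = {"sampling_interval": signals.sampling_interval}
    sidecar.update(meta or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_signals(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    x = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return x, sidecar


def load_region_table(path: str | Path) -> tuple[list[str], list]:
    """Two-column (region_label, value-or-label) delimited text."""
    df = pd.read_csv(path, sep="\t", header=None, names=["region", "value"])
    return [str(r) for r in df["region"]], list(df["value"])


def save_region_table(path: str | Path, regions: list[str], values: list) -> None:
    pd.DataFrame({"region": regions, "value": values}).to_csv(
        path, sep="\t", index=False, header=False
    )


def save_fit_ensemble(path: str | Path, results: list[FitResult], group_labels: list[str]) -> None:
    """One row per GA run: seed, coefficients, fit distance, halting reason."""
    rows = []
    for r in results:
        row = {"seed": r.seed}
        row.update({f"delta_{lab}": v for lab, v in zip(group_labels, r.best_delta)})
        row["gof"] = r.best_gof
        row["halting_reason"] = r.halting_reason
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_fit_ensemble(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
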