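"""Spatial heterogeneity priors: grouping matrices and group coefficients.

Per-region bifurcation parameters are reduced to a few group coefficients
through a binary grouping matrix M (region x group, overlap allowed):
``a_i = sum_j delta_j * M[i, j]``.  Four prior families are provided:
resting-state-network membership, atrophy-quantile bins, random assignment,
and anatomical-proximity blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hopf import DimensionMismatchError

__all__ = [
    "GroupingMatrix",
    "combine_delta",
    "build_atrophy_prior",
    "build_random_prior",
    "build_proximity_prior",
    "build_membership_prior",
    "build_identity_prior",
]

logger = logging.getLogger(__name__)

PRIOR_KINDS = {"rsn", "atrophy_quantile", "random", "proximity_equal", "identity"}


@dataclass
class GroupingMatrix:
    """Binary region x group membership matrix; groups may overlap."""

    M: np.ndarray
    group_labels: list[str] = field(default_factory=list)
    prior_kind: str = "rsn"

    def __post_init__(self) -> None:
        m = np.asarray(self.M)
        if m.ndim != 2:
            raise DimensionMismatchError("grouping matrix must be 2-D (region x group)")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("grouping matrix entries must be 0 or 1")
        if m.shape[1] < 1:
            raise ValueError("need at least one group")
        empty = m.sum(axis=0) == 0
        if empty.any():
            raise ValueError(f"empty group at column {int(np.flatnonzero(empty)[0])}")
        if self.prior_kind not in PRIOR_KINDS:
            raise ValueError(f"unknown prior kind {self.prior_kind!r}")
        self.M = m.astype(int)
        if not self.group_labels:
            self.group_labels = [f"G{j}" for j in range(m.shape[1])]
        elif len(self.group_labels) != m.shape[1]:
            raise DimensionMismatchError("group_labels length != group count")

    @property
    def n_regions(self) -> int:
        return self.M.shape[0]

    @property
    def n_groups(self) -> int:
        return self.M.shape[1]


def combine_delta(M: GroupingMatrix, delta: np.ndarray) -> np.ndarray:
    """Per-region bifurcation parameters a_i = sum_j delta_j M[i, j].

    Regions belonging to no group get a_i = 0 (and are logged).
    """
    d = np.asarray(delta, dtype=float)
    if d.ndim != 1 or d.shape[0] != M.n_groups:
        raise DimensionMismatchError(
            f"delta has length {d.shape[0] if d.ndim == 1 else d.shape}, "
            f"grouping matrix has {M.n_groups} groups"
        )
    if not np.all(np.isfinite(d)):
        raise ValueError("delta coefficients must be finite")
    orphans = M.M.sum(axis=1) == 0
    if orphans.any():
        logger.warning(
            "%d region(s) belong to no group; their a_i defaults to 0", int(orphans.sum())
        )
    return M.M @ d


def _chunk_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if j < extra else 0) for j in range(k)]


def build_atrophy_prior(atrophy_map: np.ndarray, n_groups: int = 6) -> GroupingMatrix:
    """Quantile-bin a per-region atrophy scalar into equal-sized disjoint groups.

    Regions are ranked by atrophy value (ties broken by region index via a
    stable sort) and cut into ``n_groups`` contiguous rank ranges whose sizes
    differ by at most one.
    """
    vals = np.asarray(atrophy_map, dtype=float)
    if vals.ndim != 1:
        raise DimensionMismatchError("atrophy map must be one value per region")
    if not np.all(np.isfinite(vals)):
        raise ValueError("atrophy map contains non-finite values")
    n = vals.shape[0]
    if n_groups > n:
        raise ValueError("more groups than regions")
    order = np.argsort(vals, kind="stable")
    M = np.zeros((n, n_groups), dtype=int)
    start = 0
    for j, size in enumerate(_chunk_sizes(n, n_groups)):
        M[order[start : start + size], j] = 1
        start += size
    labels = [f"atrophy_q{j + 1}" for j in range(n_groups)]
    return GroupingMatrix(M, labels, prior_kind="atrophy_quantile")


def build_random_prior(n_regions: int, n_groups: int = 6, seed: int = 0) -> GroupingMatrix:
    """Seeded uniform random assignment of regions to groups; no group empty."""
    if n_groups > n_regions:
        raise ValueError("more groups than regions")
    rng = np.random.default_rng(seed)
    while True:
        assign = rng.integers(0, n_groups, size=n_regions)
        if len(np.unique(assign)) == n_groups:
            break
    M = np.zeros((n_regions, n_groups), dtype=int)
    M[np.arange(n_regions), assign] = 1
    return GroupingMatrix(M, [f"rand_{j}" for j in range(n_groups)], prior_kind="random")


def build_proximity_prior(centroids: np.ndarray, n_groups: int = 6) -> GroupingMatrix:
    """Balanced spatial partition along the first principal axis of the centroids.

    Regions are projected on the leading principal component of the centroid
    cloud, sorted, and cut into ``n_groups`` contiguous equal-size blocks.
    Group membership depends only on centroid geometry, not on input order.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DimensionMismatchError("centroids must be an (n_regions, 3) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("centroids contain non-finite values")
    n = pts.shape[0]
    if n_groups > n:
        raise ValueError("more groups than regions")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # fix the sign deterministically so the projection is order-invariant
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    proj = centered @ axis
    order = np.argsort(proj, kind="stable")
    M = np.zeros((n, n_groups), dtype=int)
    start = 0
    for j, size in enumerate(_chunk_sizes(n, n_groups)):
        M[order[start : start + size], j] = 1
        start += size
    return GroupingMatrix(M, [f"block_{j}" for j in range(n_groups)], prior_kind="proximity_equal")


def build_membership_prior(labels: list[str | list[str]]) -> GroupingMatrix:
    """Grouping matrix from per-region network labels (multi-label allowed).

    Each region may carry one label or a list of labels; one column is built
    per distinct label (sorted).  A region with no label belongs to no group
    and a warning is logged.
    """
    per_region: list[list[str]] = []
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            entry = [lab] if lab else []
        else:
            entry = [s for s in lab if s]
        if not entry:
            logger.warning("region %d has no network label; assigned to no group", i)
        per_region.append(entry)
    distinct = sorted({l for entry in per_region for l in entry})
    if not distinct:
        raise ValueError("no labels given")
    col = {l: j for j, l in enumerate(distinct)}
    M = np.zeros((len(per_region), len(distinct)), dtype=int)
    for i, entry in enumerate(per_region):
        for l in entry:
            M[i, col[l]] = 1
    return GroupingMatrix(M, distinct, prior_kind="rsn")


def build_identity_prior(n_regions: int) -> GroupingMatrix:
    """One group per region: combine_delta becomes the identity map on delta."""
    return GroupingMatrix(
        np.eye(n_regions, dtype=int),
        [f"region_{i}" for i in range(n_regions)],
        prior_kind="identity",
    )
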