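"""Functional connectivity: task-block correlation, Fisher z, binarization.

For each subject, Pearson correlations between all channel pairs are computed
from the oxy-Hb time course restricted to the task block, variance-stabilized
with Fisher's z = atanh(r), and binarized by *proportional thresholding*: the
strongest fraction (default 15%) of available channel pairs become edges of an
undirected, unweighted graph.  Density is defined over pairs of valid
channels only, so subjects with different channel exclusions remain
comparable.

Edges are ranked by signed z by default — a strong negative correlation is
never selected as an edge; pass ``absolute=True`` to rank by |z| instead.
The edge-count quota is round-half-up of ``density * n_pairs``, and ties at
the cutoff are broken deterministically by ascending (i, j) channel index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import HbTimeSeries, as_sample_range

__all__ = [
    "ConnectivityMatrix",
    "AdjacencyMatrix",
    "fisher_z",
    "task_block_correlation",
    "proportional_threshold",
    "density_of",
]

#: Correlations are clipped to +/- (1 - Z_CLIP_EPS) before atanh so that
#: degenerate r = +/-1 pairs stay finite and maximally ranked.
Z_CLIP_EPS = 1e-12


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's variance-stabilizing transform z = atanh(r).

    Odd and strictly increasing; values at exactly +/-1 are clipped to keep
    the result finite.
    """
    r = np.clip(r, -1.0 + Z_CLIP_EPS, 1.0 - Z_CLIP_EPS)
    return np.arctanh(r)


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity over channel pairs.

    ``values[i, j]`` is z for channels i+1, j+1 (0-based storage of 1-based
    channels); NaN marks missing entries (invalid channel or zero-variance
    trace) and the diagonal.
    """

    values: np.ndarray
    valid_channels: np.ndarray
    block_used: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_channels = np.asarray(self.valid_channels, dtype=bool)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity values must be square")
        if self.valid_channels.shape != (n,):
            raise ValueError("valid_channels length must match matrix size")
        vals = self.values[~np.isnan(self.values)]
        sym = self.values.copy()
        if not np.allclose(np.nan_to_num(sym), np.nan_to_num(sym.T)):
            raise ValueError("connectivity matrix must be symmetric")
        del vals

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def available_pairs(self) -> np.ndarray:
        """(n_pairs, 2) array of 0-based upper-triangle index pairs with data."""
        n = self.n_channels
        iu, ju = np.triu_indices(n, k=1)
        ok = (
            self.valid_channels[iu]
            & self.valid_channels[ju]
            & ~np.isnan(self.values[iu, ju])
        )
        return np.column_stack([iu[ok], ju[ok]])


@dataclass
class AdjacencyMatrix:
    """Binary undirected graph over channels.

    ``a`` is symmetric with zero diagonal; rows/columns of invalid channels
    are all zero.  ``edge_count`` counts upper-triangle ones.
    """

    a: np.ndarray
    valid_channels: np.ndarray
    target_density: float | None = None
    subject_id: str | None = None
    edge_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        self.valid_channels = np.asarray(self.valid_channels, dtype=bool)
        n = self.a.shape[0]
        if self.a.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.a, self.a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(self.a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        invalid = ~self.valid_channels
        if np.any(self.a[invalid, :]) or np.any(self.a[:, invalid]):
            raise ValueError("edges touching invalid channels must be absent")
        self.a = self.a.astype(np.int8)
        self.edge_count = int(np.triu(self.a, k=1).sum())

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid_channels.sum())


def task_block_correlation(
    series: HbTimeSeries, block: str = "task"
) -> ConnectivityMatrix:
    """Fisher-z correlation matrix of oxy-Hb within one block.

    Pearson r is computed pairwise over the block's samples for every pair of
    valid channels, then transformed with :func:`fisher_z`.  Entries touching
    an invalid channel, or a zero-variance trace, are NaN.  Requires at least
    3 samples in the block.
    """
    ann = series.block(block)  # raises KeyError if absent
    if ann.n_samples < 3:
        raise ValueError(
            f"block {block!r} has {ann.n_samples} samples; need at least 3 "
            "for a correlation estimate"
        )
    data = series.oxy[:, as_sample_range(ann)]
    n = series.n_channels
    valid = series.valid_channels.copy()

    sd = data.std(axis=1)
    # relative tolerance: a constant trace's sd is ~1e-16 * |level|, not 0
    sd_floor = 1e-10 * np.maximum(1.0, np.abs(data).mean(axis=1))
    sd = np.where(sd <= sd_floor, 0.0, sd)
    degenerate = valid & (sd == 0)
    if degenerate.any():
        warnings.warn(
            f"zero-variance oxy trace in block {block!r} on channels "
            f"{list(np.flatnonzero(degenerate) + 1)}; entries marked missing",
            stacklevel=2,
        )

    usable = valid & (sd > 0)
    z = np.full((n, n), np.nan)
    idx = np.flatnonzero(usable)
    if idx.size >= 2:
        r = np.corrcoef(data[idx])
        np.fill_diagonal(r, np.nan)
        zsub = fisher_z(r)
        z[np.ix_(idx, idx)] = zsub
        np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(
        values=z, valid_channels=valid, block_used=block, subject_id=series.subject_id
    )


def proportional_threshold(
    conn: ConnectivityMatrix, density: float = 0.15, absolute: bool = False
) -> AdjacencyMatrix:
    """Binarize a connectivity matrix at a target edge density.

    Keeps the ``round_half_up(density * M)`` pairs with the largest z (or
    |z| with ``absolute=True``) among the M available valid pairs.  Ties at
    the cutoff are resolved by ascending (i, j) index.
    """
    if not 0 < density < 1:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    pairs = conn.available_pairs()
    m = len(pairs)
    n_keep = int(np.floor(density * m + 0.5))
    if n_keep < 1:
        raise ValueError(
            f"density {density} keeps zero of {m} available pairs; "
            "increase the density or the number of valid channels"
        )
    z = conn.values[pairs[:, 0], pairs[:, 1]]
    score = np.abs(z) if absolute else z
    # sort by descending score, then ascending (i, j) for deterministic ties
    order = np.lexsort((pairs[:, 1], pairs[:, 0], -score))
    keep = pairs[order[:n_keep]]

    a = np.zeros((conn.n_channels, conn.n_channels), dtype=np.int8)
    a[keep[:, 0], keep[:, 1]] = 1
    a[keep[:, 1], keep[:, 0]] = 1
    return AdjacencyMatrix(
        a=a,
        valid_channels=conn.valid_channels,
        target_density=density,
        subject_id=conn.subject_id,
    )


def density_of(adj: AdjacencyMatrix) -> float:
    """Achieved edge density: edges / possible pairs among valid channels."""
    nv = adj.n_valid
    if nv < 2:
        raise ValueError("density undefined with fewer than 2 valid channels")
    return adj.edge_count / (nv * (nv - 1) / 2)
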