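"""Degree centrality, hub extraction, and group-consensus connections.

Degree k_i = sum_j a_ij is the only centrality used: in a binarized
functional network it counts how many channels a node is functionally
connected to.  *Hubs* are the nodes in the top fraction (default 10%) of the
degree distribution; the hub-set size is ceil(fraction * n_valid), with ties
at the cutoff resolved toward lower channel indices.  A *consensus edge* is
a connection present in at least a stated fraction (default 60%) of the
subjects in a group, counting only subjects where both channels are valid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import AdjacencyMatrix
from .geometry import ChannelMap

__all__ = [
    "DegreeVector",
    "HubSet",
    "degree",
    "top_degree_hubs",
    "consensus_edges",
    "roi_degree",
]


@dataclass
class DegreeVector:
    """Per-channel degree counts; NaN marks invalid channels.

    Satisfies the handshake lemma: nansum(k) == 2 * edge_count of the source
    adjacency (checked at construction).
    """

    k: np.ndarray
    valid_channels: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.valid_channels = np.asarray(self.valid_channels, dtype=bool)
        if self.k.shape != self.valid_channels.shape:
            raise ValueError("k and valid_channels must have equal length")
        if np.isnan(self.k[self.valid_channels]).any():
            raise ValueError("valid channels must have finite degrees")

    @property
    def n_valid(self) -> int:
        return int(self.valid_channels.sum())

    @property
    def n_channels(self) -> int:
        return self.k.size


@dataclass
class HubSet:
    """Channels in the top fraction of the degree distribution (1-based)."""

    channels: tuple[int, ...]
    fraction: float
    regions: tuple[str, ...] = ()

    def __contains__(self, channel: int) -> bool:
        return channel in self.channels


def degree(adj: AdjacencyMatrix) -> DegreeVector:
    """Degree k_i = sum_j a_ij per valid node; invalid nodes get NaN."""
    k = adj.a.sum(axis=1).astype(float)
    k[~adj.valid_channels] = np.nan
    dv = DegreeVector(k=k, valid_channels=adj.valid_channels, subject_id=adj.subject_id)
    # handshake lemma, asserted on every output
    total = np.nansum(dv.k)
    if int(total) != 2 * adj.edge_count:
        raise AssertionError(
            f"handshake lemma violated: sum(k)={total}, 2*edges={2 * adj.edge_count}"
        )
    return dv


def hub_set_size(n_valid: int, fraction: float) -> int:
    """Number of hubs: ceil(fraction * n_valid)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"hub fraction must lie in (0, 1], got {fraction}")
    return math.ceil(fraction * n_valid)


def top_degree_hubs(
    deg: DegreeVector,
    fraction: float = 0.10,
    channel_map: ChannelMap | None = None,
) -> HubSet:
    """Channels with the top-``fraction`` degrees.

    Selects ceil(fraction * n_valid) valid channels with highest degree; a
    tie at the cutoff is broken by ascending channel index (with a warning,
    since the selection is then not unique on degree alone).
    """
    n_hubs = hub_set_size(deg.n_valid, fraction)
    valid_idx = np.flatnonzero(deg.valid_channels)  # 0-based
    k = deg.k[valid_idx]
    order = np.lexsort((valid_idx, -k))
    chosen = valid_idx[order[:n_hubs]]
    if n_hubs < valid_idx.size and k[order[n_hubs - 1]] == k[order[n_hubs]]:
        warnings.warn(
            "degree tie at the hub cutoff; resolved toward lower channel indices",
            stacklevel=2,
        )
    channels = tuple(sorted(int(c) + 1 for c in chosen))
    regions: tuple[str, ...] = ()
    if channel_map is not None:
        regions = tuple(dict.fromkeys(channel_map.region_of(c) for c in channels))
    return HubSet(channels=channels, fraction=fraction, regions=regions)


def consensus_edges(
    adjs: list[AdjacencyMatrix], prevalence: float = 0.60
) -> pd.DataFrame:
    """Edges present in at least ``prevalence`` of the subjects (inclusive).

    For each channel pair the denominator counts only subjects where both
    channels are valid.  Returns a DataFrame with 1-based ``channel_i`` <
    ``channel_j``, ``prevalence``, and ``n_subjects`` (the denominator),
    sorted by descending prevalence then index.
    """
    if not adjs:
        raise ValueError("consensus requires at least one adjacency matrix")
    n = adjs[0].n_nodes
    if any(a.n_nodes != n for a in adjs):
        raise ValueError("all adjacency matrices must share the node indexing")
    present = np.zeros((n, n), dtype=int)
    countable = np.zeros((n, n), dtype=int)
    for adj in adjs:
        both_valid = np.outer(adj.valid_channels, adj.valid_channels)
        countable += both_valid
        present += adj.a
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(countable > 0, present / np.maximum(countable, 1), np.nan)
    iu, ju = np.triu_indices(n, k=1)
    ok = (countable[iu, ju] > 0) & (prev[iu, ju] >= prevalence)
    df = pd.DataFrame(
        {
            "channel_i": iu[ok] + 1,
            "channel_j": ju[ok] + 1,
            "prevalence": prev[iu, ju][ok],
            "n_subjects": countable[iu, ju][ok],
        }
    )
    return df.sort_values(
        ["prevalence", "channel_i", "channel_j"], ascending=[False, True, True]
    ).reset_index(drop=True)


def roi_degree(
    deg: DegreeVector, region: str | list[str], channel_map: ChannelMap
) -> float:
    """Mean degree over a region's valid channels for one subject.

    Returns NaN (with a warning) if every channel of the region is invalid
    for this subject.
    """
    channels = sorted(channel_map.channels_of_region(region))
    idx = np.array(channels) - 1
    usable = deg.valid_channels[idx]
    if not usable.any():
        warnings.warn(
            f"region {region!r} has no valid channels for subject "
            f"{deg.subject_id!r}; ROI degree is missing",
            stacklevel=2,
        )
        return float("nan")
    return float(np.nanmean(deg.k[idx[usable]]))
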