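"""Probe-grid geometry and the channel -> brain-region lookup.

An fNIRS probe set is a rectangular grid of optodes in which emitters and
detectors alternate in a checkerboard pattern with a fixed 30 mm spacing.
A measurement channel sits at the midpoint of every orthogonally adjacent
emitter-detector pair, so an ``rows x cols`` grid yields
``rows*(cols-1) + (rows-1)*cols`` channels.  The standard whole-head montage
used throughout this package is two 3 x 10 sets (forehead, occiput; 47
channels each) plus one 3 x 5 set on the vertex (22 channels), 116 channels
in total.

Channels are mapped to anatomical labels through a fixed packaged lookup
table (``data/channel_regions.tsv``) instead of per-subject probabilistic
registration to MNI space; :func:`load_channel_map` accepts a path so a
user-supplied table can be substituted.  Channel indices are 1-based
everywhere, matching the lookup table and all file headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ProbeGrid",
    "ChannelMap",
    "STANDARD_MONTAGE",
    "channel_count",
    "montage_total",
    "load_channel_map",
]

INTER_PROBE_DISTANCE_MM = 30.0
N_STANDARD_CHANNELS = 116


@dataclass(frozen=True)
class ProbeGrid:
    """A rectangular optode grid with alternating emitters and detectors.

    Parameters
    ----------
    rows, cols
        Grid dimensions in optodes (both >= 1).
    inter_probe_distance
        Optode spacing in mm (fixed at 30 mm for the supported hardware).
    """

    rows: int
    cols: int
    inter_probe_distance: float = INTER_PROBE_DISTANCE_MM

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid must be at least 1 x 1, got {self.rows} x {self.cols}")
        if self.inter_probe_distance <= 0:
            raise ValueError("inter_probe_distance must be positive")

    @property
    def n_optodes(self) -> int:
        return self.rows * self.cols

    @property
    def n_emitters(self) -> int:
        # checkerboard starting with an emitter in the corner
        return (self.n_optodes + 1) // 2

    @property
    def n_detectors(self) -> int:
        return self.n_optodes // 2


#: Two 3 x 10 sets (forehead, occiput) and one 3 x 5 set (vertex): 116 channels.
STANDARD_MONTAGE: tuple[ProbeGrid, ...] = (
    ProbeGrid(3, 10),
    ProbeGrid(3, 10),
    ProbeGrid(3, 5),
)


def channel_count(grid: ProbeGrid) -> int:
    """Number of measurement channels formed by ``grid``.

    Every orthogonally adjacent optode pair in the alternating grid is an
    emitter-detector pair and hence a channel:
    ``rows*(cols-1)`` horizontal plus ``(rows-1)*cols`` vertical pairs.
    """
    return grid.rows * (grid.cols - 1) + (grid.rows - 1) * grid.cols


def montage_total(grids: Iterable[ProbeGrid]) -> int:
    """Total channel count over a montage of probe grids (non-empty)."""
    grids = list(grids)
    if not grids:
        raise ValueError("montage must contain at least one probe grid")
    return sum(channel_count(g) for g in grids)


@dataclass
class ChannelMap:
    """Lookup from 1-based channel index to anatomical region and hemisphere.

    Wraps a table with columns ``channel`` (1..n, unique, contiguous),
    ``region`` and ``hemisphere`` (``left``/``right``/``midline``).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"channel", "region", "hemisphere"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"channel map missing columns: {sorted(missing)}")
        ch = self.table["channel"].to_numpy()
        n = len(ch)
        if n == 0 or sorted(ch.tolist()) != list(range(1, n + 1)):
            raise ValueError("channel indices must be unique and contiguous from 1")
        self.table = self.table.sort_values("channel").reset_index(drop=True)
        self._by_channel = dict(zip(self.table["channel"], self.table["region"]))

    @property
    def n_channels(self) -> int:
        return len(self.table)

    @property
    def regions(self) -> list[str]:
        """Distinct region labels, in first-appearance (channel) order."""
        return list(dict.fromkeys(self.table["region"]))

    def region_of(self, channel: int) -> str:
        """Anatomical label of a 1-based channel index."""
        try:
            return self._by_channel[int(channel)]
        except KeyError:
            raise KeyError(
                f"channel {channel} out of range 1..{self.n_channels}"
            ) from None

    def hemisphere_of(self, channel: int) -> str:
        self.region_of(channel)  # range check
        return self.table.loc[int(channel) - 1, "hemisphere"]

    def channels_of_region(self, region: str | Sequence[str]) -> set[int]:
        """All channels whose label matches ``region`` (or any of a set of labels)."""
        labels = [region] if isinstance(region, str) else list(region)
        known = set(self.table["region"])
        unknown = [lab for lab in labels if lab not in known]
        if unknown:
            raise KeyError(
                f"unknown region label(s) {unknown}; known labels: {sorted(known)}"
            )
        mask = self.table["region"].isin(labels)
        return set(self.table.loc[mask, "channel"].tolist())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def load_channel_map(path: str | Path | None = None) -> ChannelMap:
    """Load a channel map from a TSV file, or the packaged 116-channel table."""
    if path is None:
        ref = resources.files("fnirsnet.data").joinpath("channel_regions.tsv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return ChannelMap(table)
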