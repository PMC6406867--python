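"""Core data containers shared across the pipeline.

Units and conventions used throughout:

* Hemoglobin concentration changes are in mM.mm (concentration x optical
  path length), sampled at ``sampling_rate`` Hz (10 Hz for the supported
  hardware).
* Channel axes always hold the full montage (116 slots by default); bad
  channels are masked via ``valid_channels`` rather than deleted, so that
  1-based channel indexing and the region lookup stay aligned everywhere.
* Block annotations use half-open sample ranges ``[start, end)`` and must
  tile the recording.
* Event times (stimuli, responses) are in seconds from recording onset;
  synchronization errors are in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BLOCK_LABELS",
    "BlockAnnotation",
    "HbTimeSeries",
    "StimulusSchedule",
    "BehavioralRecord",
]

#: Canonical block order of a single run.
BLOCK_LABELS = ("pre_scan", "control", "task", "post_control")


@dataclass(frozen=True)
class BlockAnnotation:
    """One experimental block: label and half-open sample range [start, end)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in BLOCK_LABELS:
            raise ValueError(f"unknown block label {self.label!r}; expected one of {BLOCK_LABELS}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid block range [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class HbTimeSeries:
    """Per-subject oxy-/deoxy-hemoglobin recording.

    Attributes
    ----------
    subject_id
        Identifier, e.g. ``"sub-03"``.
    sampling_rate
        Sampling frequency in Hz.
    oxy, deoxy
        ``(n_channels, n_samples)`` float arrays of concentration changes in
        mM.mm.  Shapes must match.
    blocks
        Contiguous, non-overlapping annotations covering all samples.
    valid_channels
        Boolean mask, ``False`` where a channel is excluded from analysis
        (e.g. motion-contaminated).  Data are retained but masked.
    """

    subject_id: str
    sampling_rate: float
    oxy: np.ndarray
    deoxy: np.ndarray
    blocks: tuple[BlockAnnotation, ...]
    valid_channels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.oxy = np.asarray(self.oxy, dtype=float)
        self.deoxy = np.asarray(self.deoxy, dtype=float)
        if self.oxy.ndim != 2:
            raise ValueError("oxy must be a 2-D (channels x samples) array")
        if self.oxy.shape != self.deoxy.shape:
            raise ValueError(
                f"oxy and deoxy shapes differ: {self.oxy.shape} vs {self.deoxy.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.blocks = tuple(self.blocks)
        self._check_blocks()
        if self.valid_channels is None:
            self.valid_channels = np.ones(self.n_channels, dtype=bool)
        self.valid_channels = np.asarray(self.valid_channels, dtype=bool)
        if self.valid_channels.shape != (self.n_channels,):
            raise ValueError("valid_channels length must equal the channel count")

    def _check_blocks(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block annotation is required")
        pos = 0
        for b in self.blocks:
            if b.start != pos:
                raise ValueError(
                    f"block annotations must be contiguous: block {b.label!r} "
                    f"starts at {b.start}, expected {pos}"
                )
            pos = b.end
        if pos != self.n_samples:
            raise ValueError(
                f"block annotations cover {pos} samples but recording has {self.n_samples}"
            )

    @property
    def n_channels(self) -> int:
        return self.oxy.shape[0]

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def block(self, label: str) -> BlockAnnotation:
        """The first block with the given label (raises ``KeyError`` if absent)."""
        for b in self.blocks:
            if b.label == label:
                return b
        raise KeyError(f"no block labelled {label!r}; have {[b.label for b in self.blocks]}")

    def with_data(self, oxy: np.ndarray, deoxy: np.ndarray) -> "HbTimeSeries":
        """Copy of this recording with replaced signal matrices."""
        return replace(self, oxy=np.array(oxy, dtype=float), deoxy=np.array(deoxy, dtype=float))

    def with_valid_channels(self, mask: np.ndarray) -> "HbTimeSeries":
        return replace(self, valid_channels=np.array(mask, dtype=bool))

    def copy(self) -> "HbTimeSeries":
        return replace(
            self,
            oxy=self.oxy.copy(),
            deoxy=self.deoxy.copy(),
            valid_channels=self.valid_channels.copy(),
        )


@dataclass(frozen=True)
class StimulusSchedule:
    """Auditory cue onsets for one block.

    ``onsets`` are strictly increasing times in seconds from recording onset.
    The cue itself is a 500 Hz sine lasting 0.1 s; frequency and duration are
    carried only as metadata.
    """

    onsets: tuple[float, ...]
    block: str
    tone_frequency: float = 500.0
    tone_duration: float = 0.1

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.onsets)
        object.__setattr__(self, "onsets", onsets)
        if any(b >= a for a, b in zip(onsets[1:], onsets[:-1])):
            raise ValueError("stimulus onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def intervals(self) -> np.ndarray:
        """Inter-stimulus intervals in seconds."""
        return np.diff(np.asarray(self.onsets))


@dataclass
class BehavioralRecord:
    """One subject's tapping responses to a stimulus schedule.

    ``responses`` are button-press times in seconds (sorted).  ``se`` holds
    the synchronization errors in milliseconds, response minus stimulus, with
    the first task stimulus excluded; it is filled in by the behavioral
    analysis (or by the generator's ground truth) and may contain NaN for
    unmatched stimuli.
    """

    subject_id: str
    stimuli: StimulusSchedule
    responses: tuple[float, ...]
    se: np.ndarray | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        self.responses = tuple(float(t) for t in self.responses)
        if list(self.responses) != sorted(self.responses):
            raise ValueError("responses must be sorted in time")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.size > max(len(self.stimuli) - 1, 0):
                raise ValueError(
                    "se cannot hold more values than task stimuli minus one "
                    f"({self.se.size} > {len(self.stimuli) - 1})"
                )


def as_sample_range(block: BlockAnnotation) -> slice:
    """Slice selecting a block's samples from a (channels x samples) array."""
    return slice(block.start, block.end)
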