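"""Data-driven subject grouping by brain-network similarity.

Each subject is described by their per-channel degree profile — degree is the
network measure the rest of the pipeline computes, so profiles of it are the
natural similarity space.  Subjects are clustered agglomeratively with Ward's
minimum-variance linkage on Euclidean distances, and the dendrogram is cut
where the distance between successive merges is largest ("largest gap"),
with the cluster count capped (default 2..5) so a single outlying subject
cannot dictate a trivial cut.

Channels invalid in *any* subject are dropped from the feature space, so all
subjects are compared over the same channels; the dropped set is recorded on
the feature table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .graph_metrics import DegreeVector

__all__ = [
    "SubjectClustering",
    "subject_features",
    "ward_cluster",
    "cut_largest_gap",
]


def subject_features(degs: list[DegreeVector]) -> pd.DataFrame:
    """Subjects x channels degree table over commonly valid channels.

    Columns are 1-based channel indices; the index holds subject ids.  The
    DataFrame's ``attrs['dropped_channels']`` records channels removed
    because they were invalid in at least one subject.
    """
    if len(degs) < 2:
        raise ValueError("need at least 2 subjects to build a feature matrix")
    n_channels = degs[0].n_channels
    if any(d.n_channels != n_channels for d in degs):
        raise ValueError("all subjects must share the channel indexing")
    common_valid = np.logical_and.reduce([d.valid_channels for d in degs])
    dropped = [int(c) + 1 for c in np.flatnonzero(~common_valid)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} channel(s) invalid in at least one "
            f"subject from the feature space: {dropped}",
            stacklevel=2,
        )
    cols = np.flatnonzero(common_valid)
    ids = [d.subject_id if d.subject_id is not None else f"subject-{i}" for i, d in enumerate(degs)]
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    mat = np.vstack([d.k[cols] for d in degs])
    df = pd.DataFrame(mat, index=pd.Index(ids, name="subject_id"), columns=cols + 1)
    df.attrs["dropped_channels"] = dropped
    return df


@dataclass
class SubjectClustering:
    """Ward merge tree over subjects, optionally with a flat cut applied.

    ``linkage`` is in scipy's standard form (one row per merge: left id,
    right id, height, size).  ``labels`` maps subject id -> 1-based cluster
    id once :func:`cut_largest_gap` has been applied.
    """

    linkage: np.ndarray
    subject_ids: tuple[str, ...]
    features: pd.DataFrame = field(repr=False)
    labels: dict[str, int] | None = None
    n_clusters: int | None = None
    gap_profile: dict[int, float] | None = None

    def __post_init__(self) -> None:
        heights = self.merge_heights
        if np.any(np.diff(heights) < -1e-9):
            raise AssertionError("Ward merge heights must be non-decreasing")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def merge_heights(self) -> np.ndarray:
        return np.asarray(self.linkage[:, 2], dtype=float)

    def cluster_members(self) -> dict[int, list[str]]:
        if self.labels is None:
            raise ValueError("no flat cut applied yet; call cut_largest_gap first")
        out: dict[int, list[str]] = {}
        for sid, lab in self.labels.items():
            out.setdefault(lab, []).append(sid)
        return {k: sorted(v) for k, v in sorted(out.items())}


def ward_cluster(features: pd.DataFrame) -> SubjectClustering:
    """Agglomerate subjects with Ward linkage on Euclidean distances."""
    if features.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if features.shape[1] < 1:
        raise ValueError("need at least 1 feature")
    z = hierarchy.linkage(features.to_numpy(dtype=float), method="ward")
    return SubjectClustering(
        linkage=z,
        subject_ids=tuple(str(s) for s in features.index),
        features=features,
    )


def cut_largest_gap(
    clustering: SubjectClustering, k_min: int = 2, k_max: int = 5
) -> SubjectClustering:
    """Cut the dendrogram at the largest gap between successive merge heights.

    For each candidate cluster count k, the gap is the height of the first
    merge *not* performed minus the height of the last merge performed; the
    k in [k_min, k_max] with the largest gap wins, smallest k on ties (with
    a warning).  Returns a copy with ``labels`` filled in.
    """
    n = clustering.n_subjects
    if not 1 <= k_min <= k_max:
        raise ValueError(f"need 1 <= k_min <= k_max, got ({k_min}, {k_max})")
    if k_max >= n:
        k_max = n - 1
        if k_min > k_max:
            raise ValueError(f"k_min={k_min} exceeds n_subjects-1={n - 1}")
    h = clustering.merge_heights  # length n-1, non-decreasing
    gaps: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        # k clusters <=> merges 0..n-k-1 performed, merge n-k withheld
        gaps[k] = float(h[n - k] - h[n - k - 1])
    best_gap = max(gaps.values())
    best_k = min(k for k, g in gaps.items() if g == best_gap)
    if sum(1 for g in gaps.values() if g == best_gap) > 1:
        warnings.warn(
            f"tied largest gap {best_gap:g} across cluster counts; "
            f"choosing the smallest k = {best_k}",
            stacklevel=2,
        )
    flat = _cut_after_merges(clustering.linkage, n - best_k)
    labels = {sid: int(lab) for sid, lab in zip(clustering.subject_ids, flat)}
    return replace(
        clustering,
        labels=labels,
        n_clusters=int(len(set(flat))),
        gap_profile=gaps,
    )


def _cut_after_merges(linkage: np.ndarray, n_merges: int) -> np.ndarray:
    """Flat labels after performing exactly the first ``n_merges`` merges.

    Unlike a height-threshold cut this is well defined under tied merge
    heights: cutting to k clusters always withholds exactly the top k - 1
    merges.  Cluster ids are 1-based in order of first member.
    """
    n = linkage.shape[0] + 1
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for row in range(n_merges):
        a, b = int(linkage[row, 0]), int(linkage[row, 1])
        members[n + row] = members.pop(a) + members.pop(b)
    labels = np.empty(n, dtype=int)
    clusters = sorted(members.values(), key=min)
    for lab, mem in enumerate(clusters, start=1):
        labels[mem] = lab
    return labels
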