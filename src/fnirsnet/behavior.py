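"""Sensorimotor synchronization error and between-cluster statistics.

The behavioral measure is the synchronization error
``SE(n) = Response(n) - Stimulus(n)`` in milliseconds: negative when the tap
anticipates the cue (predictive responding), positive when it follows it
(reactive responding).  The first task stimulus is excluded — it acts as a
start cue rather than a signal to synchronize with.  Responses are paired to
stimuli by proximity: each stimulus accepts the nearest unused response
within half its local inter-stimulus interval, ties going to the earlier
stimulus.

Cluster-level summaries aggregate within subject first (the per-subject mean
SE), then across the subjects of a cluster, avoiding pseudo-replication of
taps.  Group differences (SE or ROI degree) use an unpaired two-sample
t-test, Student by default with a Welch option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BehavioralRecord, StimulusSchedule

__all__ = [
    "GroupComparison",
    "match_responses",
    "synchronization_error",
    "subject_mean_se",
    "cluster_se_summary",
    "group_ttest",
]


@dataclass
class GroupComparison:
    """Result of an unpaired two-sample t-test between clusters."""

    statistic: float
    p_value: float
    group_means: dict[str, tuple[float, float]]  # label -> (mean, sd)
    measure: str = ""
    alpha: float = 0.05
    equal_var: bool = True
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _half_windows(onsets: np.ndarray) -> np.ndarray:
    """Half the local inter-stimulus interval per stimulus.

    Interior stimuli use the smaller of the two flanking intervals; edge
    stimuli use their single flanking interval.  A lone stimulus accepts any
    response (infinite window).
    """
    n = len(onsets)
    if n == 1:
        return np.array([np.inf])
    iv = np.diff(onsets)
    local = np.empty(n)
    local[0] = iv[0]
    local[-1] = iv[-1]
    if n > 2:
        local[1:-1] = np.minimum(iv[:-1], iv[1:])
    return local / 2.0


def match_responses(
    stimuli: StimulusSchedule, responses: tuple[float, ...] | np.ndarray
) -> list[tuple[float, float | None]]:
    """Pair each stimulus with at most one response by temporal proximity.

    Returns one ``(stimulus_time, response_time_or_None)`` per stimulus, in
    stimulus order.  A response may serve at most one stimulus; candidate
    pairs are taken greedily by increasing |response - stimulus|, restricted
    to half the local inter-stimulus interval, and an exactly equidistant
    response goes to the earlier stimulus (flagged with a warning).
    """
    onsets = np.asarray(stimuli.onsets, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if np.any(np.diff(resp) < 0):
        raise ValueError("responses must be sorted")
    windows = _half_windows(onsets)

    candidates: list[tuple[float, int, int]] = []
    for si, (t, w) in enumerate(zip(onsets, windows)):
        dt = np.abs(resp - t)
        for ri in np.flatnonzero(dt <= w):
            candidates.append((float(dt[ri]), si, int(ri)))
    candidates.sort()  # |dt| first, then earlier stimulus, then earlier response

    # flag exact equidistance between two admissible stimuli
    by_resp: dict[int, list[float]] = {}
    for d, si, ri in candidates:
        by_resp.setdefault(ri, []).append(d)
    for ri, ds in by_resp.items():
        if len(ds) > 1 and min(ds) in ds[1:]:
            warnings.warn(
                f"response at {resp[ri]:.3f} s is equidistant between two "
                "stimuli; assigned to the earlier one",
                stacklevel=2,
            )
            break

    matched_stim: dict[int, int] = {}
    used_resp: set[int] = set()
    for _, si, ri in candidates:
        if si in matched_stim or ri in used_resp:
            continue
        matched_stim[si] = ri
        used_resp.add(ri)

    pairs: list[tuple[float, float | None]] = []
    for si, t in enumerate(onsets):
        ri = matched_stim.get(si)
        pairs.append((float(t), float(resp[ri]) if ri is not None else None))
    if resp.size and not matched_stim:
        warnings.warn("no responses could be matched to any stimulus", stacklevel=2)
    return pairs


def synchronization_error(
    pairs: list[tuple[float, float | None]], drop_first: bool = True
) -> np.ndarray:
    """SE(n) = Response(n) - Stimulus(n) in milliseconds.

    The first stimulus of the block is dropped by default (it is a start
    signal, not a synchronization target).  Unmatched stimuli yield NaN.
    """
    if drop_first:
        pairs = pairs[1:]
    se = np.array(
        [(r - s) * 1000.0 if r is not None else np.nan for s, r in pairs], dtype=float
    )
    if se.size and np.isnan(se).all():
        warnings.warn("all synchronization errors are missing", stacklevel=2)
    return se


def analyze_record(record: BehavioralRecord, drop_first: bool = True) -> BehavioralRecord:
    """Fill in ``record.se`` from its stimuli and responses."""
    pairs = match_responses(record.stimuli, record.responses)
    record.se = synchronization_error(pairs, drop_first=drop_first)
    return record


def subject_mean_se(record: BehavioralRecord) -> float:
    """Mean SE (ms) over this subject's matched task stimuli."""
    if record.se is None:
        analyze_record(record)
    assert record.se is not None
    if np.isnan(record.se).all():
        return float("nan")
    return float(np.nanmean(record.se))


def cluster_se_summary(
    records: list[BehavioralRecord], labels: dict[str, int]
) -> pd.DataFrame:
    """Per-cluster mean and sd (ms) of the per-subject mean SE.

    Every record's subject must be labelled; empty clusters are an error.
    ``sd`` is the population-style sample standard deviation (ddof=1; 0 for
    a singleton cluster).
    """
    unlabeled = [r.subject_id for r in records if r.subject_id not in labels]
    if unlabeled:
        raise ValueError(f"subjects without a cluster label: {unlabeled}")
    per_subject = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "cluster": [labels[r.subject_id] for r in records],
            "mean_se_ms": [subject_mean_se(r) for r in records],
        }
    )
    for cluster in set(labels.values()):
        if cluster not in set(per_subject["cluster"]):
            raise ValueError(f"cluster {cluster} has no subjects with records")
    out = per_subject.groupby("cluster")["mean_se_ms"].agg(
        n="count",
        mean_ms="mean",
        sd_ms=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
    )
    return out.reset_index()


def group_ttest(
    values_a: np.ndarray,
    values_b: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
    measure: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Unpaired two-sample t-test (Student by default, Welch optional).

    Degenerate zero-variance input is handled explicitly: identical
    constant samples give t = 0, p = 1; constant samples with different
    means give p = 0 (flagged as degenerate).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 non-missing values")
    means = {
        labels[0]: (float(a.mean()), float(a.std(ddof=1))),
        labels[1]: (float(b.mean()), float(b.std(ddof=1))),
    }
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p, degenerate = 0.0, 1.0, True
        else:
            t_stat = float(np.inf if a.mean() > b.mean() else -np.inf)
            p, degenerate = 0.0, True
        warnings.warn(
            "both samples have zero variance; t-test is degenerate", stacklevel=2
        )
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p, degenerate = float(res.statistic), float(res.pvalue), False
    return GroupComparison(
        statistic=t_stat,
        p_value=p,
        group_means=means,
        measure=measure,
        alpha=alpha,
        equal_var=equal_var,
        degenerate=degenerate,
    )
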