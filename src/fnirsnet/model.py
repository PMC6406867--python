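"""End-to-end analysis as a model/results pair.

:class:`TappingNetworkAnalysis` bundles the per-subject recordings and
behavioral records and, on :meth:`~TappingNetworkAnalysis.fit`, runs the
whole pipeline:

1. artifact screening and zero-phase band-pass filtering;
2. task-block Pearson/Fisher-z connectivity and proportional thresholding;
3. degree centrality per subject;
4. Ward clustering of degree profiles with the largest-gap cut;
5. per-cluster hub sets (top-10% of the cluster-mean degree profile),
   consensus edges, ROI degree t-tests, and synchronization-error
   summaries with a between-cluster t-test.

The returned :class:`TappingNetworkResults` carries every intermediate
product plus a human-readable :meth:`~TappingNetworkResults.summary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import clustering as cl
from . import connectivity as cn
from . import graph_metrics as gm
from .preprocess import PreprocessConfig, preprocess as preprocess_series
from .core import BehavioralRecord, HbTimeSeries
from .geometry import ChannelMap, load_channel_map
from .synthetic import GeneratorConfig, GroundTruth, generate_dataset

__all__ = ["TappingNetworkAnalysis", "TappingNetworkResults"]


class TappingNetworkAnalysis:
    """Functional brain-network analysis of a multi-subject tapping study.

    Parameters
    ----------
    series_list
        One :class:`~fnirsnet.core.HbTimeSeries` per subject.
    records
        Behavioral records (task stimuli and responses); optional — without
        them the behavioral stage is skipped.
    channel_map
        Channel -> region lookup; defaults to the packaged 116-channel table
        when the montage size matches.
    preprocess_config
        Filtering/screening parameters (defaults: 0.010-0.33 Hz, 0.1 mM.mm).
    """

    def __init__(
        self,
        series_list: list[HbTimeSeries],
        records: list[BehavioralRecord] | None = None,
        channel_map: ChannelMap | None = None,
        preprocess_config: PreprocessConfig | None = None,
        ground_truth: GroundTruth | None = None,
    ):
        if not series_list:
            raise ValueError("at least one subject recording is required")
        self.series_list = series_list
        self.records = records or []
        n_ch = series_list[0].n_channels
        if channel_map is None and n_ch == 116:
            channel_map = load_channel_map()
        self.channel_map = channel_map
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.ground_truth = ground_truth

    @classmethod
    def from_directory(cls, path: str | Path, **kwargs) -> "TappingNetworkAnalysis":
        """Load a text dataset directory written by :mod:`fnirsnet.io`."""
        from . import io as fio

        series_list, records = fio.read_dataset(path)
        truth_path = Path(path) / "ground_truth.json"
        truth = fio.read_ground_truth(truth_path) if truth_path.exists() else None
        return cls(series_list, records, ground_truth=truth, **kwargs)

    @classmethod
    def from_synthetic(
        cls, config: GeneratorConfig | None = None, **kwargs
    ) -> "TappingNetworkAnalysis":
        """Generate a synthetic dataset and wrap it for analysis."""
        series_list, records, truth = generate_dataset(config)
        return cls(series_list, records, ground_truth=truth, **kwargs)

    def fit(
        self,
        density: float = 0.15,
        hub_fraction: float = 0.10,
        consensus_prevalence: float = 0.60,
        k_min: int = 2,
        k_max: int = 5,
        block: str = "task",
        equal_var: bool = True,
        skip_behavior: bool = False,
    ) -> "TappingNetworkResults":
        """Run the pipeline and return the results object."""
        processed = [preprocess_series(s, self.preprocess_config) for s in self.series_list]
        conns = [cn.task_block_correlation(s, block) for s in processed]
        adjs = [cn.proportional_threshold(c, density) for c in conns]
        degrees = [gm.degree(a) for a in adjs]
        subject_hubs = {
            d.subject_id: gm.top_degree_hubs(d, hub_fraction, self.channel_map)
            for d in degrees
        }

        features = cl.subject_features(degrees)
        tree = cl.ward_cluster(features)
        clustering = cl.cut_largest_gap(tree, k_min=k_min, k_max=k_max)
        labels = clustering.labels or {}

        by_cluster: dict[int, list[int]] = {}
        for i, d in enumerate(degrees):
            by_cluster.setdefault(labels[d.subject_id], []).append(i)

        cluster_hubs: dict[int, gm.HubSet] = {}
        cluster_consensus: dict[int, pd.DataFrame] = {}
        for lab, idxs in sorted(by_cluster.items()):
            mean_k = np.nanmean(np.vstack([degrees[i].k for i in idxs]), axis=0)
            valid = np.logical_and.reduce([degrees[i].valid_channels for i in idxs])
            mean_deg = gm.DegreeVector(
                k=np.where(valid, mean_k, np.nan),
                valid_channels=valid,
                subject_id=f"cluster-{lab}",
            )
            cluster_hubs[lab] = gm.top_degree_hubs(mean_deg, hub_fraction, self.channel_map)
            cluster_consensus[lab] = gm.consensus_edges(
                [adjs[i] for i in idxs], consensus_prevalence
            )

        roi_tests: list[bh.GroupComparison] = []
        se_summary = None
        se_test = None
        if len(by_cluster) == 2:
            roi_tests = self._roi_tests(degrees, labels, cluster_hubs, equal_var)
            if self.records and not skip_behavior:
                se_summary, se_test = self._behavior_stats(labels, equal_var)

        return TappingNetworkResults(
            model=self,
            processed=processed,
            connectivity=conns,
            adjacency=adjs,
            degrees=degrees,
            degree_table=features,
            clustering=clustering,
            subject_hubs=subject_hubs,
            cluster_hubs=cluster_hubs,
            cluster_consensus=cluster_consensus,
            roi_tests=roi_tests,
            se_summary=se_summary,
            se_test=se_test,
            params={
                "density": density,
                "hub_fraction": hub_fraction,
                "consensus_prevalence": consensus_prevalence,
                "k_min": k_min,
                "k_max": k_max,
                "block": block,
                "equal_var": equal_var,
            },
        )

    def _roi_tests(self, degrees, labels, cluster_hubs, equal_var):
        """t-test each cluster's hub regions' mean degree between clusters."""
        if self.channel_map is None:
            return []
        out = []
        clusters = sorted(cluster_hubs)
        a_lab, b_lab = clusters[0], clusters[1]
        tested: set[str] = set()
        for lab in clusters:
            for region in cluster_hubs[lab].regions:
                if region in tested:
                    continue
                tested.add(region)
                vals = {a_lab: [], b_lab: []}
                for d in degrees:
                    vals[labels[d.subject_id]].append(
                        gm.roi_degree(d, region, self.channel_map)
                    )
                if min(len(v) for v in vals.values()) < 2:
                    continue
                out.append(
                    bh.group_ttest(
                        np.asarray(vals[a_lab]),
                        np.asarray(vals[b_lab]),
                        equal_var=equal_var,
                        measure=f"ROI degree: {region}",
                        labels=(str(a_lab), str(b_lab)),
                    )
                )
        return out

    def _behavior_stats(self, labels, equal_var):
        records = [r for r in self.records if r.subject_id in labels]
        for r in records:
            bh.analyze_record(r)
        summary = bh.cluster_se_summary(records, labels)
        by_cluster: dict[int, list[float]] = {}
        for r in records:
            by_cluster.setdefault(labels[r.subject_id], []).append(bh.subject_mean_se(r))
        clusters = sorted(by_cluster)
        test = None
        if len(clusters) == 2 and all(len(by_cluster[c]) >= 2 for c in clusters):
            test = bh.group_ttest(
                np.asarray(by_cluster[clusters[0]]),
                np.asarray(by_cluster[clusters[1]]),
                equal_var=equal_var,
                measure="mean synchronization error (ms)",
                labels=(str(clusters[0]), str(clusters[1])),
            )
        return summary, test


@dataclass
class TappingNetworkResults:
    """Everything the pipeline computed, with a printable summary."""

    model: TappingNetworkAnalysis
    processed: list[HbTimeSeries]
    connectivity: list[cn.ConnectivityMatrix]
    adjacency: list[cn.AdjacencyMatrix]
    degrees: list[gm.DegreeVector]
    degree_table: pd.DataFrame
    clustering: cl.SubjectClustering
    subject_hubs: dict[str, gm.HubSet]
    cluster_hubs: dict[int, gm.HubSet]
    cluster_consensus: dict[int, pd.DataFrame]
    roi_tests: list[bh.GroupComparison]
    se_summary: pd.DataFrame | None
    se_test: bh.GroupComparison | None
    params: dict = field(default_factory=dict)

    @property
    def labels(self) -> dict[str, int]:
        assert self.clustering.labels is not None
        return self.clustering.labels

    @property
    def n_clusters(self) -> int:
        return int(self.clustering.n_clusters or 0)

    def achieved_densities(self) -> list[float]:
        return [cn.density_of(a) for a in self.adjacency]

    def summary(self) -> str:
        lines = []
        p = self.params
        lines.append("Functional brain-network analysis (synchronized tapping)")
        lines.append("=" * 60)
        lines.append(
            f"subjects: {len(self.degrees)}   channels: {self.degrees[0].n_channels}   "
            f"edge density: {p.get('density'):.0%}   hub fraction: {p.get('hub_fraction'):.0%}"
        )
        dens = self.achieved_densities()
        lines.append(
            f"achieved density: {np.mean(dens):.4f} "
            f"(min {min(dens):.4f}, max {max(dens):.4f})"
        )
        lines.append(f"clusters (largest-gap Ward cut): k = {self.n_clusters}")
        for lab, members in self.clustering.cluster_members().items():
            lines.append(f"  cluster {lab}: n = {len(members)}  [{', '.join(members)}]")
        for lab, hubs in self.cluster_hubs.items():
            lines.append(f"  cluster {lab} hub channels (top {hubs.fraction:.0%} degree): "
                         f"{list(hubs.channels)}")
            if hubs.regions:
                lines.append(f"    regions: {'; '.join(hubs.regions)}")
        for lab, edges in self.cluster_consensus.items():
            lines.append(
                f"  cluster {lab} consensus edges (prevalence >= "
                f"{p.get('consensus_prevalence'):.0%}): {len(edges)}"
            )
        if self.roi_tests:
            lines.append("ROI degree t-tests (cluster vs cluster):")
            for t in self.roi_tests:
                flag = "*" if t.significant else " "
                lines.append(
                    f"  {t.measure}: t = {t.statistic:+.2f}, p = {t.p_value:.4f}{flag}"
                )
        if self.se_summary is not None:
            lines.append("Synchronization error by cluster (ms):")
            for _, row in self.se_summary.iterrows():
                lines.append(
                    f"  cluster {int(row['cluster'])}: "
                    f"{row['mean_ms']:+.1f} ± {row['sd_ms']:.1f} (n = {int(row['n'])})"
                )
        if self.se_test is not None:
            flag = "*" if self.se_test.significant else " "
            lines.append(
                f"SE cluster difference: t = {self.se_test.statistic:+.2f}, "
                f"p = {self.se_test.p_value:.4f}{flag}"
            )
        return "\n".join(lines)

    def plot_dendrogram(self, path: str | Path | None = None):
        """Dendrogram of the subject clustering (written to ``path`` if given)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy

        fig, ax = plt.subplots(figsize=(8, 4))
        hierarchy.dendrogram(
            self.clustering.linkage,
            labels=list(self.clustering.subject_ids),
            ax=ax,
            color_threshold=None,
        )
        ax.set_ylabel("Ward merge distance")
        ax.set_xlabel("subject")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
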