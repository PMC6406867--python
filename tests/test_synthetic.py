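"""The synthetic-data generator: determinism, planted structure, behavior."""

import dataclasses

import numpy as np
import pytest

from fnirsnet.core import BlockAnnotation, StimulusSchedule
from fnirsnet.preprocess import detect_motion_channels
from fnirsnet.synthetic import (
    ArtifactSpec,
    ConfigurationError,
    GeneratorConfig,
    default_partner_set,
    generate_behavior,
    generate_dataset,
    generate_network_signal,
    inject_motion_step,
    make_control_schedule,
    make_task_schedule,
)


class TestGeneratorConfig:
    def test_defaults_valid(self):
        GeneratorConfig().validate()

    @pytest.mark.parametrize(
        "override, field",
        [
            ({"n_subjects": 0}, "n_subjects"),
            ({"sampling_rate": -1.0}, "sampling_rate"),
            ({"coupling_strength": 1.5}, "coupling_strength"),
            ({"block_durations": (20.0, 30.0, -21.0, 30.0)}, "block_durations"),
            ({"group_assignment": ("A",) * 3}, "group_assignment"),
            ({"hub_channels_per_group": {"A": (7,), "B": (200,)}}, "hub_channels_per_group"),
            ({"artifacts": ArtifactSpec(channels=(0,))}, "artifacts"),
        ],
    )
    def test_invalid_field_named_in_error(self, override, field):
        cfg = dataclasses.replace(GeneratorConfig(), **override)
        with pytest.raises(ConfigurationError, match=field):
            cfg.validate()

    def test_default_blocks_cover_101_seconds(self):
        cfg = GeneratorConfig()
        blocks = cfg.block_annotations()
        assert [b.label for b in blocks] == ["pre_scan", "control", "task", "post_control"]
        assert blocks[-1].end == 1010
        assert cfg.n_samples == 1010


class TestGenerateDataset:
    def test_shapes_and_counts(self, default_dataset):
        _, series_list, records, truth = default_dataset
        assert len(series_list) == 20
        assert len(records) == 20
        for s in series_list:
            assert s.oxy.shape == (116, 1010)
            assert s.deoxy.shape == (116, 1010)
        assert sorted(truth.groups.values()).count("A") == 10

    def test_identical_seed_bit_identical(self):
        cfg = GeneratorConfig(seed=5, n_subjects=4, group_assignment=("A", "A", "B", "B"))
        s1, r1, t1 = generate_dataset(cfg)
        s2, r2, t2 = generate_dataset(cfg)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.oxy, b.oxy)
            np.testing.assert_array_equal(a.deoxy, b.deoxy)
        for a, b in zip(r1, r2):
            assert a.responses == b.responses
        assert t1.to_dict() == t2.to_dict()

    def test_subject_count_extension_preserves_prefix(self):
        small = GeneratorConfig(seed=3, n_subjects=4, group_assignment=("A", "A", "B", "B"))
        large = GeneratorConfig(seed=3, n_subjects=6, group_assignment=("A", "A", "B", "B", "A", "B"))
        s_small, _, _ = generate_dataset(small)
        s_large, _, _ = generate_dataset(large)
        for a, b in zip(s_small, s_large):
            np.testing.assert_array_equal(a.oxy, b.oxy)

    def test_artifact_channels_fail_motion_screen(self, default_dataset):
        _, series_list, _, truth = default_dataset
        for s in series_list:
            mask = detect_motion_channels(s)
            for ch in truth.artifact_channels:
                assert not mask[ch - 1]

    def test_ground_truth_pools_partition_channels(self, default_dataset):
        _, _, _, truth = default_dataset
        for g in ("A", "B"):
            hubs = set(truth.hub_channels[g])
            partners = set(truth.partner_channels[g])
            anti = set(truth.anti_channels[g])
            assert hubs | partners | anti == set(range(1, 117))
            assert not (hubs & partners) and not (hubs & anti) and not (partners & anti)


class TestNetworkSignal:
    def test_zero_coupling_gives_independent_channels(self):
        x = generate_network_signal(4, hub_set=(1, 2), coupling_strength=0.0,
                                    n_samples=10_000, seed=0)
        r = np.corrcoef(x)
        off = r[np.triu_indices(4, 1)]
        assert np.max(np.abs(off)) < 0.1

    def test_full_coupling_two_hubs_identical(self):
        x = generate_network_signal(2, hub_set=(1, 2), coupling_strength=1.0,
                                    n_samples=2_000, seed=1)
        r = np.corrcoef(x)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_connected_exceed_unconnected_at_moderate_coupling(self):
        hub_set = (1, 2, 3)
        x = generate_network_signal(20, hub_set=hub_set, coupling_strength=0.7,
                                    n_samples=10_000, seed=2)
        r = np.corrcoef(x)
        hubs = np.array(hub_set) - 1
        partners, anti = default_partner_set(20, hub_set)
        conn = [r[i, j] for i in hubs for j in np.array(partners) - 1]
        conn += [r[i, j] for a, i in enumerate(hubs) for j in hubs[a + 1:]]
        unconn = [r[i, j] for i in np.array(anti) - 1 for j in hubs]
        assert np.mean(conn) > np.mean(unconn) + 0.2

    def test_connected_correlation_monotone_in_coupling(self):
        hub_set = (1, 2, 3, 4)
        means = []
        for c in (0.0, 0.3, 0.6, 0.9):
            x = generate_network_signal(10, hub_set=hub_set, coupling_strength=c,
                                        n_samples=8_000, seed=3)
            r = np.corrcoef(x)
            hubs = np.array(hub_set) - 1
            means.append(np.mean([r[i, j] for a, i in enumerate(hubs) for j in hubs[a + 1:]]))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_empty_hub_set_rejected(self):
        with pytest.raises(ValueError, match="hub_set"):
            generate_network_signal(10, hub_set=(), coupling_strength=0.5,
                                    n_samples=1000, seed=0)


class TestSchedules:
    def test_control_schedule_half_second_cadence(self):
        block = BlockAnnotation("control", 200, 500)
        sched = make_control_schedule(block, sampling_rate=10.0)
        assert sched.onsets[0] == 20.0
        assert np.allclose(sched.intervals, 0.5)
        assert len(sched) == 60

    def test_task_schedule_seven_increasing_intervals(self):
        block = BlockAnnotation("task", 500, 710)
        rng = np.random.default_rng(0)
        sched = make_task_schedule(block, 10.0, rng)
        assert len(sched) == 7
        assert sched.onsets[0] == 50.0
        iv = sched.intervals
        assert np.all(np.diff(iv) > 0)  # intervals increase
        assert np.allclose(np.diff(iv), 0.6, atol=0.15)  # by ~0.6 s each
        assert sched.onsets[-1] < 71.0  # fits inside the 21 s block


class TestGenerateBehavior:
    def _schedule(self, n=7):
        return StimulusSchedule(onsets=tuple(50.0 + 1.1 * i for i in range(n)), block="task")

    def test_degenerate_sd_gives_exact_offset(self):
        rec = generate_behavior(self._schedule(), se_mean=100.0, se_sd=0.0, seed=0)
        offsets = np.array(rec.responses) - np.array(rec.stimuli.onsets)
        assert np.allclose(offsets, 0.1)

    def test_sample_mean_converges_to_planted(self):
        sched = StimulusSchedule(onsets=tuple(np.arange(10_000) * 2.0), block="task")
        rec = generate_behavior(sched, se_mean=90.0, se_sd=154.9, seed=1)
        se_ms = (np.array(rec.responses) - np.sort(rec.stimuli.onsets)) * 1000.0
        assert abs(se_ms.mean() - 90.0) < 5.0
        assert abs(se_ms.std(ddof=1) - 154.9) < 5.0

    def test_negative_planted_mean_recovered_negative(self):
        sched = StimulusSchedule(onsets=tuple(np.arange(10_000) * 2.0), block="task")
        rec = generate_behavior(sched, se_mean=-8.9, se_sd=261.5, seed=2)
        se_ms = (np.array(rec.responses) - np.sort(rec.stimuli.onsets)) * 1000.0
        assert se_ms.mean() < 0

    def test_clipping_flagged(self):
        sched = StimulusSchedule(onsets=(0.05,), block="task")
        rec = generate_behavior(sched, se_mean=-500.0, se_sd=0.0, seed=0,
                                recording_window=(0.0, 101.0))
        assert rec.clipped
        assert rec.responses[0] == 0.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="se_sd"):
            generate_behavior(self._schedule(), 0.0, -1.0, seed=0)


class TestInjectMotionStep:
    def _series(self, quiet: bool = False):
        if quiet:
            from fnirsnet.core import BlockAnnotation, HbTimeSeries

            zeros = np.zeros((8, 500))
            return HbTimeSeries(subject_id="q", sampling_rate=10.0, oxy=zeros,
                                deoxy=zeros.copy(),
                                blocks=(BlockAnnotation("pre_scan", 0, 500),))
        cfg = GeneratorConfig(seed=11, n_subjects=1, group_assignment=("A",),
                              artifacts=ArtifactSpec(channels=()))
        return generate_dataset(cfg)[0][0]

    def test_step_appears_in_first_difference(self):
        s = inject_motion_step(self._series(), channel=5, sample=100, amplitude=0.12)
        diff = np.diff(s.oxy[4])
        base = np.diff(self._series().oxy[4])
        assert diff[99] - base[99] == pytest.approx(0.12)

    def test_zero_amplitude_is_identity(self):
        base = self._series()
        s = inject_motion_step(base, channel=5, sample=100, amplitude=0.0)
        np.testing.assert_array_equal(s.oxy, base.oxy)

    def test_step_above_threshold_flags_channel(self):
        s = inject_motion_step(self._series(quiet=True), channel=5, sample=100,
                               amplitude=0.12)
        mask = detect_motion_channels(s)
        assert not mask[4]
        assert mask.sum() == 7  # only the stepped channel is flagged

    def test_step_below_threshold_not_flagged(self):
        s = inject_motion_step(self._series(quiet=True), channel=5, sample=100,
                               amplitude=0.05)
        assert detect_motion_channels(s).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            inject_motion_step(self._series(), channel=117, sample=0, amplitude=0.1)
        with pytest.raises(IndexError):
            inject_motion_step(self._series(), channel=1, sample=10_000, amplitude=0.1)
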