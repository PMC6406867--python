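"""Synthetic multi-subject fNIRS datasets with planted network structure.

The generator emulates the study design the analysis pipeline expects:
20 subjects in two groups of 10, a 116-channel whole-head montage sampled at
10 Hz, one run of pre-scan (20 s), control (30 s), task (21 s) and
post-control (30 s) blocks, auditory cues every 0.5 s in the control block
and seven cues with arithmetically increasing intervals in the task block,
and button-press responses whose synchronization error is drawn from a
planted per-group normal distribution.

Planted connectivity uses a single-factor model per subject.  A latent
band-limited "network" signal is shared by three channel pools: the group's
*hub* channels load strongly (``sqrt(c)`` with c the coupling strength, so a
hub pair correlates at c), a *partner* pool loads moderately
(``sqrt(0.6 c)``), and an *anticorrelated* pool loads weakly negatively
(``-sqrt(0.05 c)``) — the task-positive/task-negative opposition familiar
from hemodynamic networks.  Because edges are selected by signed
correlation, hubs collect edges to every partner, partners add a moderate
number of mutual edges, and anticorrelated channels are shut out of the
graph entirely (their correlations with the hub system are negative and
their mutual correlations are tiny).  Hubs therefore surface as the
top-degree nodes.  The two groups swap the partner/anticorrelated role of
almost every non-hub channel, so degree profiles are strongly
group-specific and the clustering stage can recover the planted partition.
The latent and residuals are standardized within the task block, making the
planted coupling a well-defined within-block quantity rather than a long-run
average.

Hemoglobin signals are expressed in mM.mm.  On top of the network signal the
generator layers standard fNIRS confounds: cardiac (1.2 Hz), respiratory
(0.25 Hz) and Mayer-wave (0.1 Hz) sinusoids with independent random phase
per channel, a linear drift, and white measurement noise — exercising the
band-pass stage without introducing spurious between-channel coupling.
Deoxy-Hb mirrors the oxy network signal with reversed sign and reduced
amplitude, as typically observed.

Reproducibility: one global seed is expanded into per-subject substreams
with ``numpy.random.SeedSequence.spawn``, so changing the subject count
never reshuffles earlier subjects, and equal seeds give bit-identical
datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sp_signal

from .core import BehavioralRecord, BlockAnnotation, HbTimeSeries, StimulusSchedule

__all__ = [
    "ConfigurationError",
    "NoiseSpec",
    "ArtifactSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_network_signal",
    "generate_behavior",
    "inject_motion_step",
    "default_partner_set",
    "DEFAULT_HUB_CHANNELS",
    "make_task_schedule",
    "make_control_schedule",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


#: Default planted hub channels per group, chosen from the montage's region
#: lookup.  Group A: left middle frontal gyrus (7, 17) and the left
#: triangular part of the inferior frontal gyrus (27, 37).  Group B: left
#: middle occipital gyrus (59), left postcentral gyrus (19), left
#: supramarginal gyrus (48), right middle temporal gyrus (65).  Four hubs
#: per group leaves slack inside the 12-slot top-10% hub set of a
#: 116-channel graph, which a short correlation window needs: with ~21 s of
#: band-limited signal the spurious-correlation tail is wide, and a few
#: partner channels will reach hub-level degrees.
DEFAULT_HUB_CHANNELS: dict[str, tuple[int, ...]] = {
    "A": (7, 17, 27, 37),
    "B": (19, 48, 59, 65),
}

#: Fraction of the latent-signal variance carried by partner channels,
#: relative to the hub coupling.
PARTNER_COUPLING_SCALE = 0.6

#: Variance fraction (relative to the hub coupling) of the *anticorrelated*
#: pool's negative loading.  Kept small: the negative sign keeps these
#: channels out of the signed edge ranking against hubs and partners, while
#: the small magnitude keeps their mutual (positive) correlation far below
#: the selection threshold, so they stay near-isolated in the graph.
ANTI_COUPLING_SCALE = 0.05

#: Spectral band of the shared latent signal (Hz).  Narrower than the
#: analysis passband at the low end so the latent cannot be near-constant
#: within a single 21 s task block.
LATENT_BAND = (0.04, 0.3)

N_CHANNELS_DEFAULT = 116


@dataclass(frozen=True)
class NoiseSpec:
    """Additive confounds layered on the network signal (amplitudes in mM.mm).

    ``sinusoids`` holds (frequency Hz, amplitude) pairs with an independent
    uniform random phase per channel; defaults are cardiac 1.2 Hz,
    respiratory 0.25 Hz and Mayer-wave 0.1 Hz components.  ``white_sd`` is
    the standard deviation of white measurement noise and
    ``drift_amplitude`` the total linear drift over the recording (random
    sign and magnitude per channel).
    """

    sinusoids: tuple[tuple[float, float], ...] = ((1.2, 0.02), (0.25, 0.004), (0.1, 0.004))
    white_sd: float = 0.008
    drift_amplitude: float = 0.02


@dataclass(frozen=True)
class ArtifactSpec:
    """Motion-artifact steps: 1-based channels and step amplitude in mM.mm.

    Each listed channel receives one persistent baseline step per subject at
    a random time in the middle of the recording.  The default amplitude
    (0.15 mM.mm) exceeds the screening threshold (0.1), so these channels
    are rejected downstream.
    """

    channels: tuple[int, ...] = (103, 110)
    amplitude: float = 0.15


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level parameters of the synthetic dataset."""

    n_subjects: int = 20
    group_assignment: tuple[str, ...] | None = None  # default: 10 x "A" + 10 x "B"
    sampling_rate: float = 10.0
    block_durations: tuple[float, float, float, float] = (20.0, 30.0, 21.0, 30.0)
    hub_channels_per_group: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_HUB_CHANNELS)
    )
    coupling_strength: float = 0.85
    signal_amplitude: float = 0.05  # rms of the network signal, mM.mm
    noise: NoiseSpec = NoiseSpec()
    artifacts: ArtifactSpec = ArtifactSpec()
    se_params_per_group: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (90.0, 154.9), "B": (-8.9, 261.5)}
    )
    n_channels: int = N_CHANNELS_DEFAULT
    n_task_stimuli: int = 7
    task_interval_start: float = 0.5  # s, carried over from the control rhythm
    task_interval_increment: float = 0.6  # s, mean per-stimulus increase
    task_interval_jitter: float = 0.03  # s, sd of the increment
    seed: int = 0

    def resolved_groups(self) -> tuple[str, ...]:
        if self.group_assignment is not None:
            return tuple(self.group_assignment)
        half = self.n_subjects // 2
        return tuple(["A"] * half + ["B"] * (self.n_subjects - half))

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        groups = self.resolved_groups()
        if len(groups) != self.n_subjects:
            raise ConfigurationError(
                f"group_assignment has {len(groups)} labels for "
                f"n_subjects={self.n_subjects}"
            )
        if self.sampling_rate <= 0:
            raise ConfigurationError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if len(self.block_durations) != 4 or any(d <= 0 for d in self.block_durations):
            raise ConfigurationError(
                f"block_durations must be four positive durations, got {self.block_durations}"
            )
        if not 0 <= self.coupling_strength <= 1:
            raise ConfigurationError(
                f"coupling_strength must lie in [0, 1], got {self.coupling_strength}"
            )
        for g in set(groups):
            if g not in self.hub_channels_per_group:
                raise ConfigurationError(f"hub_channels_per_group missing group {g!r}")
            hubs = self.hub_channels_per_group[g]
            if not hubs:
                raise ConfigurationError(f"hub_channels_per_group[{g!r}] is empty")
            bad = [c for c in hubs if not 1 <= c <= self.n_channels]
            if bad:
                raise ConfigurationError(
                    f"hub_channels_per_group[{g!r}] indices out of [1, {self.n_channels}]: {bad}"
                )
            if g not in self.se_params_per_group:
                raise ConfigurationError(f"se_params_per_group missing group {g!r}")
            if self.se_params_per_group[g][1] < 0:
                raise ConfigurationError(f"se_params_per_group[{g!r}] sd must be >= 0")
        for c in self.artifacts.channels:
            if not 1 <= c <= self.n_channels:
                raise ConfigurationError(
                    f"artifacts.channels index {c} out of [1, {self.n_channels}]"
                )
        if self.signal_amplitude < 0:
            raise ConfigurationError("signal_amplitude must be >= 0")
        if self.n_task_stimuli < 1:
            raise ConfigurationError("n_task_stimuli must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(sum(self.block_durations) * self.sampling_rate))

    def block_annotations(self) -> tuple[BlockAnnotation, ...]:
        labels = ("pre_scan", "control", "task", "post_control")
        out, pos = [], 0
        for lab, dur in zip(labels, self.block_durations):
            n = int(round(dur * self.sampling_rate))
            out.append(BlockAnnotation(lab, pos, pos + n))
            pos += n
        return tuple(out)


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset, stored alongside the data."""

    seed: int
    groups: dict[str, str]  # subject_id -> group label
    hub_channels: dict[str, tuple[int, ...]]  # group -> 1-based hubs
    partner_channels: dict[str, tuple[int, ...]]  # group -> 1-based partners
    anti_channels: dict[str, tuple[int, ...]]  # group -> anticorrelated channels
    planted_edges: dict[str, list[tuple[int, int]]]  # group -> 1-based (i, j)
    se_params: dict[str, tuple[float, float]]  # group -> (mean ms, sd ms)
    artifact_channels: tuple[int, ...]
    coupling_strength: float

    def to_dict(self) -> dict:
        return asdict(self)


def _bandlimited_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sampling_rate: float,
    band: tuple[float, float] = (0.01, 0.3),
    norm_slice: slice | None = None,
) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (Hz), per row.

    Standardized over ``norm_slice`` if given (else the whole length), so a
    planted coupling expressed as a variance share holds exactly within that
    window rather than only on long-run average.
    """
    n = shape[-1]
    if n < 60:
        raise ValueError(f"need at least 60 samples for band-limited noise, got {n}")
    sos = sp_signal.butter(4, band, btype="bandpass", fs=sampling_rate, output="sos")
    # generate with settle margins and trim them: the slow low-frequency
    # corner otherwise leaves pad-edge transients whose common shape (with
    # random per-row amplitude) would correlate nominally independent rows
    settle = int(round(3.0 * sampling_rate / band[0]))
    padded = shape[:-1] + (n + 2 * settle,)
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(padded), axis=-1)[..., settle:-settle]
    ref = x[..., norm_slice] if norm_slice is not None else x
    sd = ref.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - ref.mean(axis=-1, keepdims=True)) / sd


def default_partner_set(
    n_channels: int, hub_set: Sequence[int], phase: int = 0
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Default (partners, anticorrelated) split of the non-hub channels.

    Non-hub channels alternate between the positively coupled partner pool
    and the anticorrelated pool, so both spread evenly over the montage.
    ``phase`` (0 or 1) flips which pool starts; giving the two groups
    opposite phases makes almost every channel's coupling sign
    group-specific, which is what lets degree profiles separate the groups.
    """
    hubs = set(int(c) for c in hub_set)
    non_hubs = [c for c in range(1, n_channels + 1) if c not in hubs]
    return tuple(non_hubs[phase % 2 :: 2]), tuple(non_hubs[(phase + 1) % 2 :: 2])


def planted_edges(hub_set: Sequence[int], partner_set: Sequence[int]) -> list[tuple[int, int]]:
    """Planted supra-noise correlation pairs: hub-hub and hub-partner (1-based)."""
    hubs = sorted(set(int(c) for c in hub_set))
    partners = sorted(set(int(c) for c in partner_set))
    edges = [(a, b) for i, a in enumerate(hubs) for b in hubs[i + 1 :]]
    edges += [tuple(sorted((h, p))) for h in hubs for p in partners]
    return sorted(set(edges))


def generate_network_signal(
    n_channels: int,
    hub_set: Sequence[int],
    coupling_strength: float,
    n_samples: int,
    seed: int | np.random.SeedSequence,
    sampling_rate: float = 10.0,
    partner_set: Sequence[int] | None = None,
    anti_set: Sequence[int] | None = None,
    partner_coupling: float | None = None,
    norm_slice: slice | None = None,
) -> np.ndarray:
    """Unit-variance channels x samples matrix with a planted hub structure.

    Hub channels load ``sqrt(c)`` on a shared latent band-limited signal, so
    the expected correlation of a hub pair equals the coupling strength c
    (1 when c = 1, independent when c = 0).  Partner channels load
    moderately (``sqrt(0.6 c)``) and the anticorrelated pool weakly
    negatively (``-sqrt(0.05 c)``); by default the non-hub channels are
    split alternately between those two pools.  All residual variation is
    independent band-limited noise per channel.  The expected correlation of
    every connected (hub-hub or hub-partner) pair increases strictly with c.

    ``norm_slice`` standardizes the latent and residuals over that sample
    window (e.g. the task block) instead of the full length.
    """
    hub_set = sorted(set(int(c) for c in hub_set))
    if not hub_set:
        raise ValueError("hub_set must not be empty")
    if any(not 1 <= c <= n_channels for c in hub_set):
        raise ValueError(f"hub channels out of range 1..{n_channels}: {hub_set}")
    if not 0 <= coupling_strength <= 1:
        raise ValueError(f"coupling_strength must lie in [0, 1], got {coupling_strength}")
    if partner_set is None and anti_set is None:
        partner_set, anti_set = default_partner_set(n_channels, hub_set)
    partner_set = sorted(set(int(c) for c in (partner_set or ())) - set(hub_set))
    anti_set = sorted(set(int(c) for c in (anti_set or ())) - set(hub_set) - set(partner_set))
    if partner_coupling is None:
        partner_coupling = PARTNER_COUPLING_SCALE * coupling_strength
    if not 0 <= partner_coupling <= 1:
        raise ValueError("partner_coupling must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    latent = _bandlimited_noise(rng, (n_samples,), sampling_rate, band=LATENT_BAND,
                                norm_slice=norm_slice)
    resid = _bandlimited_noise(rng, (n_channels, n_samples), sampling_rate,
                               norm_slice=norm_slice)

    loading = np.zeros(n_channels)
    loading[np.asarray(hub_set) - 1] = np.sqrt(coupling_strength)
    if partner_set:
        loading[np.asarray(partner_set) - 1] = np.sqrt(partner_coupling)
    if anti_set:
        loading[np.asarray(anti_set) - 1] = -np.sqrt(ANTI_COUPLING_SCALE * coupling_strength)
    x = loading[:, None] * latent[None, :] + np.sqrt(1.0 - loading**2)[:, None] * resid
    return x


def make_control_schedule(
    block: BlockAnnotation, sampling_rate: float, interval: float = 0.5
) -> StimulusSchedule:
    """Isochronous control cues, one every ``interval`` seconds."""
    start = block.start / sampling_rate
    duration = block.n_samples / sampling_rate
    n = int(np.floor((duration - 1e-9) / interval)) + 1
    onsets = start + interval * np.arange(n)
    return StimulusSchedule(onsets=tuple(onsets), block="control")


def make_task_schedule(
    block: BlockAnnotation,
    sampling_rate: float,
    rng: np.random.Generator,
    n_stimuli: int = 7,
    interval_start: float = 0.5,
    increment_mean: float = 0.6,
    increment_sd: float = 0.03,
) -> StimulusSchedule:
    """Task cues with arithmetically increasing inter-stimulus intervals.

    The first cue falls at the block onset; successive intervals grow by
    ~``increment_mean`` seconds each (jittered), starting from the control
    rhythm's interval, so seven cues span roughly 16 s of a 21 s block.
    """
    start = block.start / sampling_rate
    onsets = [start]
    interval = interval_start
    for _ in range(n_stimuli - 1):
        interval += increment_mean + (increment_sd and rng.normal(0.0, increment_sd))
        onsets.append(onsets[-1] + interval)
    block_end = block.end / sampling_rate
    if onsets[-1] >= block_end:
        warnings.warn(
            f"task schedule overruns its block ({onsets[-1]:.2f} s >= {block_end:.2f} s)",
            stacklevel=2,
        )
    return StimulusSchedule(onsets=tuple(onsets), block="task")


def generate_behavior(
    schedule: StimulusSchedule,
    se_mean: float,
    se_sd: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
    subject_id: str = "subject",
    recording_window: tuple[float, float] | None = None,
) -> BehavioralRecord:
    """Responses as stimulus onsets plus Normal(se_mean, se_sd) offsets (ms).

    One independent draw per stimulus.  Responses falling outside
    ``recording_window`` (seconds) are clipped to it and the record is
    flagged as clipped.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must contain at least one stimulus")
    if se_sd < 0:
        raise ValueError(f"se_sd must be >= 0, got {se_sd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets_ms = rng.normal(se_mean, se_sd, size=len(schedule))
    responses = np.asarray(schedule.onsets) + offsets_ms / 1000.0
    clipped = False
    if recording_window is not None:
        lo, hi = recording_window
        clipped = bool((responses < lo).any() or (responses > hi).any())
        responses = np.clip(responses, lo, hi)
    return BehavioralRecord(
        subject_id=subject_id,
        stimuli=schedule,
        responses=tuple(np.sort(responses)),
        clipped=clipped,
    )


def inject_motion_step(
    series: HbTimeSeries, channel: int, sample: int, amplitude: float
) -> HbTimeSeries:
    """Add a persistent baseline step to one channel from ``sample`` onward.

    ``channel`` is 1-based.  The step is applied to both chromophores
    (motion shifts the optical coupling as a whole); the artifact screen
    reads only the oxy trace.
    """
    if not 1 <= channel <= series.n_channels:
        raise IndexError(f"channel {channel} out of range 1..{series.n_channels}")
    if not 0 <= sample < series.n_samples:
        raise IndexError(f"sample {sample} out of range 0..{series.n_samples - 1}")
    out = series.copy()
    out.oxy[channel - 1, sample:] += amplitude
    out.deoxy[channel - 1, sample:] += amplitude
    return out


def _subject_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, sampling_rate: float, spec: NoiseSpec
) -> np.ndarray:
    """Physiological sinusoids (random phase per channel), drift, white noise."""
    t = np.arange(n_samples) / sampling_rate
    noise = np.zeros((n_channels, n_samples))
    for freq, amp in spec.sinusoids:
        phases = rng.uniform(0.0, 2 * np.pi, size=n_channels)
        noise += amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    slopes = rng.uniform(-1.0, 1.0, size=n_channels) * spec.drift_amplitude
    noise += slopes[:, None] * (t[None, :] / t[-1])
    noise += rng.normal(0.0, spec.white_sd, size=(n_channels, n_samples))
    return noise


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[list[HbTimeSeries], list[BehavioralRecord], GroundTruth]:
    """Generate one Hb recording and one behavioral record per subject.

    Returns the recordings, the behavioral records (responses to the task
    cues; ``se`` left for the analysis to compute), and the planted ground
    truth.  Identical configs (including seed) give bit-identical output.
    """
    config = config or GeneratorConfig()
    config.validate()
    groups = config.resolved_groups()
    blocks = config.block_annotations()
    task_block = next(b for b in blocks if b.label == "task")
    n_samples = config.n_samples
    fs = config.sampling_rate

    split_per_group = {
        g: default_partner_set(config.n_channels, config.hub_channels_per_group[g], phase=i)
        for i, g in enumerate(sorted(set(groups)))
    }

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_subjects)

    series_list: list[HbTimeSeries] = []
    records: list[BehavioralRecord] = []
    subject_groups: dict[str, str] = {}
    for i, (group, child) in enumerate(zip(groups, children)):
        sid = f"sub-{i + 1:02d}"
        subject_groups[sid] = group
        streams = child.spawn(4)  # network, noise, schedule/behavior, artifacts
        network = generate_network_signal(
            config.n_channels,
            config.hub_channels_per_group[group],
            config.coupling_strength,
            n_samples,
            streams[0],
            sampling_rate=fs,
            partner_set=split_per_group[group][0],
            anti_set=split_per_group[group][1],
            norm_slice=slice(task_block.start, task_block.end),
        )
        noise_rng = np.random.default_rng(streams[1])
        oxy = config.signal_amplitude * network + _subject_noise(
            noise_rng, config.n_channels, n_samples, fs, config.noise
        )
        deoxy_noise = NoiseSpec(
            sinusoids=tuple((f, a * 0.5) for f, a in config.noise.sinusoids),
            white_sd=config.noise.white_sd * 0.5,
            drift_amplitude=config.noise.drift_amplitude * 0.5,
        )
        deoxy = -0.4 * config.signal_amplitude * network + _subject_noise(
            noise_rng, config.n_channels, n_samples, fs, deoxy_noise
        )
        series = HbTimeSeries(
            subject_id=sid, sampling_rate=fs, oxy=oxy, deoxy=deoxy, blocks=blocks
        )

        behav_rng = np.random.default_rng(streams[2])
        schedule = make_task_schedule(
            task_block,
            fs,
            behav_rng,
            n_stimuli=config.n_task_stimuli,
            interval_start=config.task_interval_start,
            increment_mean=config.task_interval_increment,
            increment_sd=config.task_interval_jitter,
        )
        se_mean, se_sd = config.se_params_per_group[group]
        record = generate_behavior(
            schedule,
            se_mean,
            se_sd,
            behav_rng,
            subject_id=sid,
            recording_window=(0.0, n_samples / fs),
        )

        artifact_rng = np.random.default_rng(streams[3])
        for ch in config.artifacts.channels:
            sample = int(artifact_rng.integers(n_samples // 10, 9 * n_samples // 10))
            series = inject_motion_step(series, ch, sample, config.artifacts.amplitude)

        series_list.append(series)
        records.append(record)

    truth = GroundTruth(
        seed=config.seed,
        groups=subject_groups,
        hub_channels={g: tuple(sorted(config.hub_channels_per_group[g])) for g in set(groups)},
        partner_channels={g: split_per_group[g][0] for g in set(groups)},
        anti_channels={g: split_per_group[g][1] for g in set(groups)},
        planted_edges={
            g: planted_edges(config.hub_channels_per_group[g], split_per_group[g][0])
            for g in set(groups)
        },
        se_params={g: tuple(config.se_params_per_group[g]) for g in set(groups)},
        artifact_channels=tuple(config.artifacts.channels),
        coupling_strength=config.coupling_strength,
    )
    return series_list, records, truth
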