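# Methods

This note documents the models, parameter choices and numerical decisions
behind `fnirsnet`, in the order the pipeline runs. Everything stated here
is computed by the test suite or by `scripts/acceptance.py`; nothing is an
empirical claim beyond what those runs measure.

## Probe geometry and channel→region lookup

An fNIRS probe set is a rectangular optode grid with emitters and detectors
alternating in a checkerboard; each orthogonally adjacent emitter–detector
pair forms a measurement channel, so an `r × c` grid yields
`r(c−1) + (r−1)c` channels. The standard whole-head montage is two 3×10
sets (47 channels each) plus one 3×5 set (22 channels): 116 channels at
30 mm spacing.

Channel-to-anatomy assignment is a fixed packaged table
(`data/channel_regions.tsv`: channel, region, hemisphere). This replaces
per-subject probabilistic registration to MNI space, which requires
digitizer data and external toolboxes; `load_channel_map(path)` accepts a
user-supplied table in the same three-column format. Channel indices are
1-based everywhere, matching the table and all file headers. The exact
emitter/detector phase and per-channel scalp coordinates of the montage are
not modelled — only counts and labels are used downstream.

## Preprocessing

* **Band-pass**: zero-phase (forward–backward) Butterworth, order 4 per
  band edge, passband 0.010–0.33 Hz, applied independently per channel to
  both chromophores. Zero phase matters because block timing is meaningful;
  the double pass squares the magnitude response (measured double-pass
  gain: ≥ 0.9 at 0.1 Hz, ~2·10⁻⁵ at the 1.2 Hz cardiac line). Order and
  band are configurable. When *measuring* the filter's gain, use a
  windowed (tapered) probe sinusoid: the 0.01 Hz corner has a ~100 s
  impulse response, and pad-edge transients otherwise mask the true
  stopband attenuation.
* **Motion artifacts**: a channel is excluded if any absolute single-sample
  first difference of its **raw oxy** trace exceeds 0.1 mM·mm. "Change per
  unit time" is interpreted as the per-sample difference at the native
  10 Hz; both the threshold and (through resampling) the time base are
  configurable. Screening runs **before** filtering — a zero-phase filter
  smears a step over many samples and would hide it. The deoxy trace
  inherits the channel flag. Channels are masked, never deleted, so the
  116-slot indexing and the region table stay aligned; the mask propagates
  through every later stage. No spline/wavelet/PCA artifact *correction* is
  attempted — exclusion only.

## Connectivity and binarization

Pearson correlations are computed pairwise over the task-block samples of
the oxy traces of valid channels, then transformed with Fisher's
z = atanh(r). Degenerate cases: a pair with |r| = 1 is clipped to
atanh(1 − 10⁻¹²) so it stays finite and maximally ranked; a trace whose
in-block standard deviation is below a relative floor (10⁻¹⁰ × mean
absolute level — a numerically constant trace) is marked missing with a
warning rather than producing NaN/Inf arithmetic.

**Proportional thresholding** keeps the `round_half_up(density × M)` pairs
with the largest z among the M available valid pairs (default density 15%;
for 116 full-rank channels: round(0.15 × 6670) = 1001 edges). Decisions
fixed here, each configurable or documented:

* Ranking is by **signed** z — a strong negative correlation is never an
  edge. An `absolute=True` flag ranks by |z| instead.
* The edge quota uses round-half-up, so the achieved density never deviates
  from the target by more than 1/M plus ties.
* Ties at the cutoff break by ascending (i, j) channel index —
  deterministic across runs and platforms.
* Invalid channels shrink the candidate pair set (density is defined over
  valid pairs), keeping density comparable across subjects with different
  exclusions.

The thresholding is rank-based, hence invariant to any strictly increasing
transform of z (property-tested).

## Degree, hubs, consensus

Degree is the row sum of the binary adjacency, k_i = Σ_j a_ij; the
handshake lemma Σk = 2·edges is asserted on every output. Hubs are the
⌈fraction × n_valid⌉ highest-degree valid channels (default 10%:
⌈0.10·116⌉ = 12), ties at the cutoff again resolved toward lower channel
indices with a warning. A consensus edge is a pair present in at least 60%
(inclusive) of the subjects in a group, where the denominator counts only
subjects with both channels valid. Consensus is computed per recovered
cluster; an all-subjects variant is a one-line call with the full adjacency
list. The ROI summary used for group testing is the mean degree over a
region's valid channels for each subject.

## Subject clustering

Subjects are clustered on their per-channel degree profiles. Degree is the
only network measure the pipeline computes, so degree profiles are the
natural similarity space; a flag in the code path (clustering on the
vectorized upper-triangle adjacency via `pandas` input) is available for
sensitivity checks. Channels invalid in any subject are dropped from the
feature space (recorded on the feature table) so all subjects are compared
over identical coordinates. Distances are Euclidean — required by Ward's
criterion — and features are not standardized: all coordinates are degree
counts and share units.

Ward linkage comes from `scipy.cluster.hierarchy`; merge heights are
checked monotone. The flat cut maximizes the gap between successive merge
heights over k ∈ [2, 5]: for each k the gap is the height of the first
merge *not* performed minus the last performed. The cap at 5 prevents a
single outlying subject from dictating a trivial cut; ties choose the
smallest k with a warning. Labels are assigned by replaying exactly the
first n−k merges rather than by a height threshold, which is well defined
under tied heights.

## Behavioral analysis

Stimulus–response matching: each stimulus accepts the nearest unused
response within half its local inter-stimulus interval (interior stimuli
use the smaller flanking interval; edge stimuli their single one), greedily
by |Δt|, ties to the earlier stimulus. SE(n) = Response(n) − Stimulus(n) in
ms; the first task stimulus is excluded (it is a start cue, not a
synchronization target), so seven task stimuli yield at most six SE values.
Note a consequence of the matching window: for very dispersed responders
(sd ≳ 250 ms against ~0.55 s half-windows early in the task block), extreme
taps go unmatched, which truncates the recovered SE spread below the
planted value by roughly 10%.

Cluster summaries aggregate within subject first (per-subject mean SE),
then across a cluster's subjects — avoiding pseudo-replication of taps in
the between-cluster test. Group comparisons (SE and ROI degree) use the
Student unpaired two-sample t-test, two-sided, α = 0.05, with a Welch
option; zero-variance degenerate inputs are answered explicitly (equal
constants: t = 0, p = 1; distinct constants: p = 0, flagged). No
multiple-testing correction is applied by default across the ROI tests
(none is part of the base procedure); a Bonferroni pass is a trivial caller
decision and the exact p values are always reported.

## Synthetic-data generator

The generator emulates the study design the pipeline expects: 20 subjects
(10 + 10 in groups A/B), 116 channels, 10 Hz, one run of
pre-scan/control/task/post-control blocks of 20/30/21/30 s. Control cues
every 0.5 s; task cues presented 7 times with arithmetically increasing
intervals — I(k+1) = I(k) + 0.6 s ± 0.03 s jitter starting from the 0.5 s
control rhythm, so the cues span ~16 s of the 21 s block. (The exact
task-interval rule is the one under-determined part of the emulated design;
count, start, increment and jitter are all config fields.) Responses are
stimulus onsets plus i.i.d. Normal(μ, σ²) offsets with per-group defaults
(+90.0 ± 154.9 ms and −8.9 ± 261.5 ms), clipped to the recording window
with a flag.

**Planted connectivity.** Per subject, one latent band-limited signal L and
independent band-limited residuals e_i drive three channel pools:

| pool | default channels | loading on L |
|---|---|---|
| hubs | 4 per group, region-mapped (A: L mid-frontal 7, 17 + L triangular IFG 27, 37; B: L postcentral 19, L supramarginal 48, L mid-occipital 59, R mid-temporal 65) | √c |
| partners | every other non-hub channel (56) | √(0.6·c) |
| anticorrelated | remaining non-hub channels (56) | −√(0.05·c) |

with x_i = loading·L + √(1 − loading²)·e_i and c the coupling strength
(default 0.85). Hub pairs therefore correlate at exactly c; hubs correlate
with every partner at √(0.6)·c ≈ 0.77c; and the anticorrelated pool —
the task-positive/task-negative opposition familiar from hemodynamic
networks — has *negative* correlation with the entire hub system and
negligible (+0.05c) mutual correlation. Because edges are ranked by signed
correlation, hubs collect edges to all partners, partners add moderate
mutual edges, and anticorrelated channels are shut out of the graph. The
two groups swap the partner/anticorrelated role of almost every non-hub
channel (opposite alternation phase), which is what makes degree profiles
group-discriminative for the clustering stage.

Design constraints that shaped these numbers: a 21 s task block band-limited
to ≤ 0.33 Hz supports only ~13 effective degrees of freedom per correlation
estimate, so noise correlations have sd ≈ 0.3, and positive-semidefiniteness
forces any two channels sharing a hub's signal to inter-correlate at least
quadratically in their hub correlation — partner channels inevitably rival
hubs in degree unless the planted hub set is small (4 ≤ 12 top-degree
slots) and the opposing pool is excluded by sign. The latent is restricted
to 0.04–0.3 Hz (inside the analysis passband, but with no component slower
than ~1 cycle per task block) and, like the residuals, is standardized over
the task-block window, so the planted coupling is a well-defined
within-block quantity. Band-limited noise is synthesized with settle
margins that are trimmed, because the slow filter corner otherwise leaves
pad-edge transients whose common shape would correlate nominally
independent channels.

**Confounds.** On top of the scaled network signal (0.05 mM·mm rms),
channels receive cardiac (1.2 Hz, 0.02 mM·mm), respiratory (0.25 Hz,
0.004 mM·mm) and Mayer-wave (0.1 Hz, 0.004 mM·mm) sinusoids with
independent random phase per channel, a random linear drift (±0.02 mM·mm
over the run), and white noise (sd 0.008 mM·mm). Deoxy-Hb is the oxy
network signal scaled by −0.4 plus its own (halved) confounds. Motion
artifacts are persistent +0.15 mM·mm steps on two fixed channels (103, 110)
at a random time per subject, which the screening stage must reject. With
these amplitudes the per-channel maximum first difference of clean channels
sits near 0.05 mM·mm, so an occasional (~1%) clean channel also crosses the
0.1 threshold — as in real screening, exclusion is conservative.

**Reproducibility.** One global seed expands into per-subject substreams
via `numpy.random.SeedSequence.spawn`, so equal seeds give bit-identical
datasets and growing the subject count never reshuffles earlier subjects.
Ground truth (groups, pools, planted edges, SE parameters, artifact
channels) is returned as a structured object and written as a JSON sidecar
so tests never re-derive it.

**What the generator does not emulate:** raw optical intensities and the
Beer–Lambert conversion (it emits concentration changes directly),
hemodynamic response functions locked to the stimuli, spatially correlated
noise from shared scalp vasculature, non-stationary artifacts other than
baseline steps, inter-subject anatomical variability (the channel→region
table is fixed), and any biomechanics of tapping (behavior is a planted
offset distribution). Recovery results therefore validate the pipeline's
machinery, not neuroscientific conclusions about real recordings.

## Recovery studies and problem sizes

`fnirsnet.experiments.run_replicates` generates independent 20-subject
studies (seeds derived from one base seed via `SeedSequence`) and scores,
per replicate: the selected cluster count, the adjusted Rand index (ARI)
between recovered and planted partitions, and the planted-hub recovery
rate over (subject, hub-channel) occurrences against each subject's
top-10%-degree set. The acceptance script and test suite run 100 replicates
at the default conditions — chosen as the scale at which a 95%-success
criterion is meaningfully estimable while a replicate (generate 20
subjects, preprocess 2×116×1010 samples each, correlate, threshold,
cluster) costs about a second. SE-distribution recovery uses 100 subjects
per cluster, where the standard error of a cluster mean (≈ σ/√600) is a few
ms. Filter-gain probes use 6000-sample tapered sinusoids measured over the
middle third.

## Known limitations

* The pipeline computes degree only; other graph metrics (clustering
  coefficient, path length, small-worldness) are out of scope.
* One correlation matrix per subject per run; no averaging over repeated
  runs and no dynamic (windowed) connectivity.
* The largest-gap cut is a heuristic; with k capped at 5 it cannot discover
  finer structure, and with genuinely unclustered data it still returns
  k ≥ 2 (the gap profile is reported so callers can judge).
* Text-based I/O (delimited matrices + JSON sidecars + TSV events) is the
  only interchange format; binary acquisition formats are intentionally
  outside the package.
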