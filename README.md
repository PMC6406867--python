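# fnirsnet

Functional brain-network analysis of fNIRS recordings from a synchronized
tapping experiment: from channel-wise oxy-/deoxy-hemoglobin time series and
button-press responses to binarized connectivity graphs, degree-based hubs,
data-driven subject clusters, and synchronization-error statistics.

The package is written for researchers analyzing multi-channel fNIRS
(functional near-infrared spectroscopy) studies of sensorimotor
synchronization — or, more generally, anyone who wants a tested, end-to-end
reference implementation of the classic correlation → Fisher-z →
proportional-threshold → degree → Ward-clustering pipeline. Because raw
recordings from such studies are rarely shared, a synthetic-data generator
with planted network structure is a first-class part of the package: every
stage can be exercised, and its recovery behavior quantified, without any
download.

## The pipeline

For each subject with channels *i* = 1…116 (two 3×10 probe grids on the
forehead and occiput plus one 3×5 grid at the vertex, 30 mm spacing,
sampled at 10 Hz):

1. **Preprocess** — zero-phase Butterworth band-pass, 0.010–0.33 Hz.
   A channel whose raw oxy-Hb trace jumps more than 0.1 mM·mm between
   consecutive samples is excluded as motion-contaminated (masked, never
   deleted, so channel indexing stays aligned with the region lookup).
2. **Connectivity** — Pearson correlation *r*ᵢⱼ of oxy-Hb over the task
   block, variance-stabilized as *z*ᵢⱼ = atanh(*r*ᵢⱼ).
3. **Binarize** — proportional thresholding: keep the strongest 15% of
   channel pairs as edges of an undirected graph with adjacency *a*ᵢⱼ.
4. **Degree** — *k*ᵢ = Σⱼ *a*ᵢⱼ; *hubs* are the top 10% of channels by
   degree (⌈0.10·*n*⌉ channels), mapped to anatomical labels through a
   packaged channel→region table.
5. **Cluster subjects** — Ward's minimum-variance hierarchical clustering
   of the subjects' degree profiles; the dendrogram is cut at the largest
   gap between successive merge distances (k capped at 2–5).
6. **Behavior** — synchronization error per tap,
   SE(*n*) = Response(*n*) − Stimulus(*n*) in ms (negative = predictive,
   positive = reactive; the first task stimulus is excluded), summarized
   per cluster and compared with an unpaired two-sample *t*-test, as are
   per-cluster hub-region degrees.

## Worked example

```python
from fnirsnet import TappingNetworkAnalysis, GeneratorConfig

model = TappingNetworkAnalysis.from_synthetic(GeneratorConfig(seed=42))
results = model.fit(density=0.15, hub_fraction=0.10)
print(results.summary())
```

prints (abridged):

```
Functional brain-network analysis (synchronized tapping)
============================================================
subjects: 20   channels: 116   edge density: 15%   hub fraction: 10%
achieved density: 0.1500 (min 0.1500, max 0.1500)
clusters (largest-gap Ward cut): k = 2
  cluster 1: n = 10  [sub-01, sub-02, ..., sub-10]
  cluster 2: n = 10  [sub-11, sub-12, ..., sub-20]
  cluster 1 hub channels (top 10% degree): [7, 17, 27, 34, 37, 53, 59, 69, 83, 85, 101, 113]
    regions: left middle frontal gyrus; left triangular part of inferior frontal gyrus; ...
  cluster 2 hub channels (top 10% degree): [4, 19, 37, 47, 48, 50, 54, 59, 65, 72, 102, 116]
    regions: right superior frontal gyrus; left postcentral gyrus; ...
ROI degree t-tests (cluster vs cluster):
  ROI degree: left middle frontal gyrus: t = +8.97, p = 0.0000*
  ROI degree: left supramarginal gyrus: t = -43.68, p = 0.0000*
  ...
Synchronization error by cluster (ms):
  cluster 1: +80.7 ± 62.0 (n = 10)
  cluster 2: -13.1 ± 133.6 (n = 10)
SE cluster difference: t = +2.01, p = 0.0593
```

Reading the output: the generator planted two 10-subject groups whose
strongly coupled "hub" channels sit in frontal regions (group A: left
middle frontal gyrus, left triangular inferior frontal gyrus) versus
occipito-parieto-temporal regions (group B: left middle occipital, left
postcentral, left supramarginal, right middle temporal gyri), with tapping
offsets drawn from Normal(+90, 154.9²) ms and Normal(−8.9, 261.5²) ms
respectively. The fit recovers the partition exactly (k = 2, clusters =
planted groups), every planted hub channel appears in its cluster's
top-degree set, the planted hub regions separate significantly in ROI
degree, and cluster 1 responds reactively (positive mean SE) while
cluster 2 is near-predictive, with no significant SE difference at this
sample size — the behavioral signature the network clusters are meant to
capture.

The same pipeline runs from the shell on a dataset directory of plain-text
matrices, JSON sidecars and event tables:

```bash
fnirsnet generate --out data/ --seed 42
fnirsnet analyze --data data/ --out results/ --density 0.15 --hub-fraction 0.10
```

(`fnirsnet preprocess` and `fnirsnet connect` expose the intermediate
stages; `TappingNetworkAnalysis.from_directory` loads the same layout in
Python.)

## What the synthetic tests do and do not show

Recovery rates measured on the generator validate the *pipeline machinery*
under the generator's assumptions (a shared band-limited latent signal,
stationary physiological confounds, step-like motion artifacts). They do
not validate neuroscientific claims about real tapping data; see
`docs/methods.md` for the generator's design, its known departures from
real fNIRS recordings, and every numerical decision the pipeline makes.
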