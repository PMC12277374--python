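# Methods

`meaburst` re-implements, as a tested pipeline, the analysis chain that
turns raw high-density microelectrode-array (HD-MEA) recordings of
co-cultured dorsal-root-ganglion (DRG) and spinal neurons into spike
trains, waveform clusters, network bursts, burst-initiation maps and
stimulation-induced activity-change statistics. Because no raw recordings
are publicly deposited, a synthetic session generator with full ground
truth stands in for laboratory data; every downstream stage is scored
against that truth.

## Spike detection

Each electrode trace (20 kHz) is bandpass filtered at 100–3000 Hz with a
4th-order Butterworth applied forward–backward (`sosfiltfilt`). The band
is part of the published protocol; the zero-phase realization is our
choice, because burst-initiator attribution downstream depends on spike
*timing* and a causal filter would delay every spike by a
frequency-dependent amount.

The per-electrode noise level is estimated robustly as
`SD = median(|x − median(x)|) / 0.6745` (the MAD with the Gaussian
consistency constant), and the detection threshold is the mean plus five
estimated SDs, applied to negative deflections: a sample crosses when
`x < mean − 5·SD`. Spike times are the local minima of sub-threshold
samples; when several detections fall within 2 ms, only the first is
kept (greedy rule, window restarting at each kept spike), emulating the
neuronal refractory period. Spikes inside any closed window from 1 ms
before a stimulation pulse's onset to 1 ms after its end are discarded.

Numerical details that the rules above leave open, fixed here:

- *Local minimum* means `x[i] ≤ x[i−1]` and `x[i] < x[i+1]` (the last
  sample of a flat minimum plateau); the detector is verified exactly
  against an exhaustive scan using this definition.
- *Degenerate MAD* (constant or clipped traces): the threshold collapses
  to the mean and would fire on every sample, so the electrode is
  flagged and skipped.
- The threshold is estimated on the full session trace of each
  electrode; a windowed estimate changes results only under
  nonstationary noise, which the generator does not produce.
- Artifact windows are closed intervals: boundary spikes are excluded
  (conservative).

## Waveform sorting

Within every 9-electrode recording unit, the electrode with the most
detections is the representative (ties → lowest electrode id). A
9 × 41-sample window (2 ms at 20 kHz) is cut around each representative
spike across all unit electrodes; windows overrunning the session edge
are dropped and counted. The flattened 369-dimensional waveforms are
embedded to 2-D with UMAP (20 neighbours, `min_dist` 0.2 — protocol
values) and clustered with DBSCAN (`min_samples` 5). Clusters with 50 or
fewer spikes are discarded. One retained cluster is treated as one
putative spinal neuron.

The DBSCAN radius is auto-selected at the knee of the ascending sorted
k-nearest-neighbour distance curve (k = `min_samples`), formalized as
the point of maximum discrete second difference and floored at the 90th
percentile of the curve. The floor matters: the knee statistic alone is
noisy when the curve contains a step (e.g. a tight artifact cluster next
to the main cloud) and can pick a radius that strands the periphery of a
genuine cluster, while between-cluster gaps in UMAP embeddings are an
order of magnitude wider than the 90th-percentile k-distance. A fixed
`eps` can be passed for exact reproducibility.

Units are embedded separately by default (the unit is the sorting
scope); a joint embedding across units can be had by pooling waveforms
before `embed_and_cluster`. Duplicate detection of one neuron by two
units is not removed. Identical-waveform inputs shortcut to a single
cluster: embedding exact duplicates is ill-posed for UMAP.

A behaviour worth knowing: a handful of mutually *dissimilar* outlier
waveforms (fewer than the neighbour count) is absorbed into the main
cloud by UMAP's local-connectivity normalization — each outlier's
nearest neighbours are genuine spikes, so no DBSCAN radius can separate
them. Mutually *similar* contamination (e.g. residual artifact snippets)
forms its own small cluster and is removed by the 50-spike rule. The
test suite pins down both behaviours.

## Network bursts and initiation points

Bursts are detected on the pooled spike raster of all retained clusters:
a burst exists wherever a 100 ms window holds strictly more than 50
spikes. The window slides spike-by-spike (event-driven — equivalent to,
and faster than, sample stepping for a count criterion); overlapping
qualifying windows merge, the burst onset is the merged region's first
spike and the offset its last. A literal per-cluster reading of the rule
(>50 spikes by a single cluster in 100 ms ≈ 500 Hz) is physiologically
implausible for low-rate spinal neurons and would make cross-cluster
initiation points meaningless; the pooled reading is the default and the
per-cluster variant is provided as an explicit alternate mode.

The burst initiator is the cluster owning the earliest spike at or after
the onset (ties → lowest cluster id); mapping it to its recording unit
gives the initiation point, and clusters initiating fewer than three
bursts are dropped from the initiator table. Participants are clusters
with at least one spike inside the burst; ordering participants by first
post-onset spike gives the propagation order, compared between bursts by
Spearman rank correlation over shared clusters.

Known sensitivity: with a Poisson background, a lone background spike up
to several tens of milliseconds before a burst can anchor a qualifying
window that reaches into the burst; after merging, that spike becomes
the onset and its cluster the attributed initiator. The effect grows
with the burst's propagation span and the pooled background rate. On
noise-free or in-burst-contaminated rasters attribution is exact; on
full default sessions (20 neurons, 3 ms delay, 0.2 Hz baseline) roughly
a quarter of bursts are attributed to a background cluster this way. We
report session-level leader agreement as measured rather than redefining
the onset, since the first-contained-spike onset is the method's stated
rule.

## Activity metrics

- **Rates**: spikes per period divided by period duration (pre / during
  / post stimulation).
- **Normalized change** between a baseline rate `a` and a comparison
  rate `b`: `(b − a) / (b + a)`. The published figures require newly
  active clusters to score 1 and unchanged clusters 0 while staying
  bounded; this form (unlike `b/a` or `(b−a)/a`) satisfies all three.
  Both rates zero is undefined and excluded from histograms.
- **Presence patterns**: a cluster is present in a period if it has at
  least one spike there; fractions over the 7 nonempty patterns sum
  to 1.
- **Burst-frequency fold change**: per-period bursts/min divided by the
  pre-stimulation rate; a zero pre rate is reported as infinite with a
  flag rather than dropped (control sessions may genuinely lack baseline
  bursts).
- **Collective activity strength**: per burst, the percentage of
  retained clusters participating; averaged per period. The source
  protocol reports this quantity in percent without a formula — this
  definition is our formalization.
- **Pairwise synchrony**: per period, spike counts in 100 ms bins (the
  burst-window scale; configurable), Pearson correlation for every
  cluster pair with nonzero variance, averaged per period; the
  stimulation and post periods are expressed as percentages of the
  pre-stimulation mean.
- **Paired comparisons**: two-sided Wilcoxon signed-rank; zero
  differences discarded, exact permutation null below 20 nonzero pairs
  and the tie-corrected normal approximation above; Bonferroni
  correction multiplies p by the number of comparisons, capped at 1.
  The exact branch is verified against exhaustive sign-flip enumeration.
- Summary values are mean ± sample standard deviation (ddof = 1).

## Colocalization

Culture separation is quantified on point sets (detected nuclei and
marker peaks, in µm): each marker point claims its nearest nucleus
within a 10 µm radius (distance ties → first nucleus by input order), a
nucleus claimed by several markers counts once, and the colocalized
fraction divides by the total nucleus count. This reproduces the
overlap de-duplication rule ("multiple nuclei near one marker count
once") and is verified against an all-pairs brute force.

## Synthetic sessions: what they emulate and what they do not

The generator builds a session from: a square grid of 3 × 3 electrode
patches (only unit membership and unit position matter downstream, so
the geometry is deliberately plain; 17.5 µm pitch); one neuron per unit
by default (making sorting recovery well-posed — multi-neuron units are
available for stress tests); biphasic negative-dominant templates with
an exponential amplitude footprint over the unit; Poisson baseline
firing; network bursts led by designated initiator neurons with members
recruited at a fixed propagation delay; optical-stimulation pulses (5 ms
at 0.2 Hz through the stimulation period) that evoke spikes
probabilistically and inject a common-mode artifact; white Gaussian
noise per electrode. Sessions default to 2/3/2 minutes — a
duration-scaled version of the 20/30/20-minute protocol; every rule in
the pipeline is duration-agnostic, and the scaled length keeps a full
analysis within minutes on one CPU.

Default parameters, with reasoning:

| parameter | default | why |
|---|---|---|
| baseline rate | 0.2 Hz | spinal neurons in culture fire sparsely; "normally inactive" populations |
| inactive fraction | 40 % | a large minority silent before stimulation, activated by it |
| burst rates pre/in/post | 2 / 6 / 4 per min | activity rises under stimulation and partially persists |
| burst membership | all neurons active in the period | a network burst recruits the population; configurable fraction for localization studies |
| within-burst spikes | 5 per member, 4 ms apart | with 40 % of neurons silent before stimulation, pre-period bursts must still exceed the >50-spikes/100 ms criterion (12 × 5 = 60) |
| propagation delay | 3 ms | above the 2 ms attribution resolution floor, below the burst window |
| spike amplitude | 100 µV peak | HD-MEA electrodes directly beneath somata routinely record ≥100 µV spikes; see template note below |
| trough width | σ = 2 samples (FWHM ≈ 0.23 ms) | fast extracellular spike; see template note below |
| amplitude jitter | 5 % per spike | natural spike-to-spike variability |
| noise SD | 5 µV | typical HD-MEA noise floor (≈2.7 µV after the bandpass) |
| artifact amplitude | 30 µV | see artifact note below |
| stimulation response | p = 0.5, 3 ms latency | reliable but not deterministic evoked response |

**Template note.** Detected spike times are quantized to samples, and
the local minimum of a noisy trough lands on a neighbouring sample with
a probability set by the trough's curvature relative to the filtered
noise SD. When that probability is appreciable, the extracted waveforms
split into discrete alignment classes that UMAP faithfully resolves into
separate clusters — misalignment by one sample moves the 369-d feature
vector by more than the noise scatter for sharp, large spikes. The
default template is therefore sharp *and* large enough that the minimum
is pinned to one sample (curvature ≈ 10 µV per sample² against ≈ 2.7 µV
filtered noise), which is exactly the regime in which sample-aligned
waveform extraction — the method's stated windowing rule — is
self-consistent. Real recordings with broader or smaller spikes would
need sub-sample alignment, which the pipeline deliberately does not add.

**Artifact note.** The stimulation artifact is modelled as a linear ramp
from +A at pulse onset to −A at offset (step discontinuities at both
edges) — the minimal shape consistent with a monotonically drifting
reference potential that jumps when stimulation switches. The bandpass
turns each step into a transient whose ringing extends ≈ 4 ms beyond the
pulse at up to ≈ 20 % of the step height, while the exclusion window
removes only ±1 ms. The default A = 30 µV keeps the residual ringing
(≈ 6 µV) below the detection threshold (≈ 13.5 µV): the generator
emulates data for which a ±1 ms exclusion window is a sufficient remedy,
which is the regime the protocol's rule presupposes. Larger artifacts
are configurable and will produce boundary false positives, as they
would in reality.

What the generator does **not** emulate: biophysical membrane dynamics,
template drift or electrode motion, correlated or non-Gaussian noise,
photoelectric artifact physics beyond the ramp, cross-unit signal
spread, and burst-size/shape variability beyond the membership fraction.
Passing recovery tests therefore demonstrate that the pipeline
implements its rules correctly and recovers truth under the stated
statistical structure — not that it would sort arbitrarily difficult
real recordings.

## Reproducibility and problem sizes

Every stochastic step (simulation, UMAP embedding) takes an explicit
seed; noise and amplitude-jitter streams are keyed by electrode/neuron
id so any subset of units renders bit-identically to a full session.
Rerunning a full pipeline configuration reproduces byte-identical
output files, and the manifest records parameters, seed and checksums.
Test and acceptance runs use 2/3/2-minute sessions with 20 recording
units (one neuron each) — the size at which every recovery statistic is
well-resolved — and raster-level constructions elsewhere; the unit count
and durations scale to the full protocol (110+ units, 20/30/20 min)
without code changes.
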