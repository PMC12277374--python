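# meaburst

Spike detection, waveform sorting and network-burst analysis for
high-density microelectrode-array (HD-MEA) recordings of co-cultured
sensory (dorsal-root-ganglion, DRG) and spinal neurons — the analysis
chain used to ask how optogenetic stimulation of sensory neurons changes
the firing and bursting of a downstream spinal network. It is written
for electrophysiologists and methods developers who need the full chain
— raw 20 kHz traces to stimulation-change statistics — as tested,
scriptable building blocks, together with a synthetic session generator
that provides ground truth for every stage.

## What it computes

Recording units of 9 electrodes are processed in a fixed order:

1. **Detection** — 100–3000 Hz zero-phase Butterworth bandpass; robust
   noise estimate `SD = median(|x − median(x)|)/0.6745`; spikes at local
   minima below `mean − 5·SD`; 2 ms greedy refractory rule; spikes
   within −1 ms/+1 ms of any optical-stimulation pulse excluded.
2. **Sorting** — per unit, the electrode with most detections is the
   representative; 9 × 41-sample waveforms around its spikes are
   embedded with UMAP (20 neighbours, min_dist 0.2) and clustered with
   DBSCAN (min_samples 5, radius at the knee of the k-distance curve);
   clusters with ≤ 50 spikes are discarded. Each retained *waveform
   cluster* is treated as one putative spinal neuron.
3. **Network bursts** — on the pooled raster, a burst is any merged run
   of 100 ms windows holding > 50 spikes; the cluster with the earliest
   spike after burst onset is the *initiation point* (mapped to its
   electrode unit); clusters initiating < 3 bursts are dropped from the
   initiator table.
4. **Metrics** — per-period firing rates; normalized rate change
   `(b − a)/(b + a)` (1 = newly active, 0 = unchanged); cluster presence
   patterns across pre/stim/post periods; burst-frequency fold changes;
   per-burst collective activity strength; binned pairwise Pearson
   synchrony; Wilcoxon signed-rank comparisons with Bonferroni
   correction.
5. **Colocalization** — fraction of neuron nuclei within 10 µm of a
   marker point (e.g. Peripherin+ peaks marking DRG neurons), with
   overlap de-duplication — the culture-separation quality metric.

Because raw recordings of this kind are not publicly deposited, the
`simulate` module generates complete sessions (traces + stimulation log
+ ground truth) with the statistical structure the analysis assumes:
low-baseline Poisson firing, designated burst leaders with a fixed
propagation delay, stimulation-locked responses and artifacts, and an
initially inactive subpopulation recruited by stimulation. See
`docs/methods.md` for the model, parameter defaults and their rationale,
and known limitations.

## Worked example

Simulate a 20-unit, 2/3/2-minute session (one neuron per unit, 40 % of
neurons silent before stimulation, burst rates 2/6/4 per minute across
the three periods) and analyse it end to end — about three minutes on
one CPU:

```python
from meaburst.simulate import make_session
from meaburst.pipeline import SimulatedTraceProvider, analyze_session

layout, templates, truth, stim, periods = make_session(n_units=20, seed=7)
provider = SimulatedTraceProvider(layout, templates, truth, stim,
                                  periods, seed=7)
result = analyze_session(provider, stim, seed=7)
m = result.metrics
```

Printing the headline metrics gives:

```text
retained waveform clusters    : 20
network bursts                : 22
not present before stim       : 30.0 %
present in all periods        : 70.0 %
burst rate (/min) pre/in/post : 0.5 / 5.0 / 3.0
burst-frequency fold in/post  : 10.00 / 6.00
initiation points pre/in/post : 1 / 6 / 2
```

Reading: all 20 simulated neurons were recovered as waveform clusters;
30 % of them fired no spike before stimulation (6 of the 8 programmed
silent neurons were recruited into detectable clusters at this seed);
burst frequency rose 10-fold during stimulation and stayed 6-fold above
baseline afterwards; and the number of distinct burst-initiation units
rose from 1 to 6 under stimulation — the signature of newly recruited
burst-leading neurons. `result.rates`, `result.changes`,
`result.bursts` and `result.initiation_map` carry the per-cluster and
per-burst tables behind these summaries.

The same pipeline runs from the shell on files:

```bash
meaburst simulate --config sim.json --out session/ --seed 7
meaburst run --config session.json          # detect → sort → bursts → metrics
meaburst coloc --nuclei nuc.csv --marker mrk.csv --radius 10
```

`run` writes per-stage CSV tables, a `metrics.json` summary and a
manifest with parameter values, seed and output checksums; rerunning an
identical configuration reproduces every file byte for byte.

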