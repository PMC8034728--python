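# stamp — spatiotemporal apoptosis mapping for tumor-on-chip videos

`stamp` analyzes two-channel time-lapse recordings of tumor-on-chip (ToC)
co-cultures — cancer cells pre-stained red, with a caspase-3/7 reporter
that turns green at apoptosis onset — and answers two questions:

1. **When do the cancer cells die?** Per-cell apoptosis onsets, the
   apoptosis rate *O*(*t*, *T*<sub>LAG</sub>) and the overall survival
   *OS*(*t*) of the tracked population.
2. **Do deaths promote nearby deaths?** A spatial statistic, the
   *potential of death induction* *P*<sub>death</sub>, that separates
   transmissible (chain-like) cell death from spatially random death.

It is aimed at groups running microfluidic cytotoxicity assays
(chemotherapy, CTL killing, stromal co-cultures) who record hourly
fluorescence videos and want kinetics and spatial death statistics
without hand annotation. A ground-truthed simulator generates synthetic
videos and death patterns, so the whole pipeline is testable without any
microscope data.

## Method

**Tracking.** Each red frame is Otsu-binarized and cells are localized by
a Circular Hough Transform over an imposed radius range; detections are
linked frame-to-frame by optimal assignment (Hungarian algorithm) on
squared displacement with distance gating, and short dropouts are
bridged by linear interpolation.

**Death calling.** For each track, a 31×31 px ROI is cut from the green
channel; with μ<sup>F</sup> the mean green intensity over the detected
cell disk and μ<sup>B</sup> the mean over the surrounding annulus, the
normalized caspase signal is

μ(t) = (μ<sup>F</sup>(t) − μ<sup>B</sup>(t)) / μ<sup>B</sup>(t) − min over the track of the same ratio,

so min μ = 0 for every track. One threshold *th* per video is estimated
by exact Otsu (between-class-variance maximization) over the pooled μ
samples of all tracks; a cell dies at the first frame with μ > *th*.

**Kinetics.** With *N*<sub>ap</sub> the death count in the trailing
window of *T*<sub>LAG</sub> frames and *N*<sub>avg</sub> the mean number
of living tracks over that window,
*O* = 100 · *N*<sub>ap</sub>/*N*<sub>avg</sub>; overall survival is the
3-frame-smoothed living count normalized to the start,
*OS*(*t*) = 100 · *N*<sub>avg2</sub>(*t*)/*N*<sub>avg2</sub>(start).

**Death maps and P<sub>death</sub>.** Each death seeds a binary disk in
an artificial video *MD*; a wake video *M* is built iteratively,
*M*(*t*) = ε<sub>B</sub>(*M*(*t*−1)) + *MD*(*t*), where ε<sub>B</sub> is
grayscale erosion with a disk of radius *r* (one third of the average
cell radius, so each wake survives ≥ 3 hourly frames). The cumulative
map *MC*(*t*) = Σ<sub>t′=t..t+T̃</sub> *M*(*t′*)² aggregates wakes over a
window T̃ (default 16 h, calibrated on chain-of-death durations); its
8-connected regions are the *death objects* *s<sub>i</sub>*, and

P<sub>death</sub> = 1/(2|S|) · Σ<sub>i&lt;j</sub> [mean MC(s<sub>i</sub>) + mean MC(s<sub>j</sub>)] / d̄(s<sub>i</sub>, s<sub>j</sub>),

with d̄ the Euclidean distance between boundary centroids normalized by
the evaluation-region side. The statistic is evaluated in sliding
283 μm × 283 μm windows covering the field. Many, intense, mutually
close death objects score high; isolated or scattered deaths score low.

## Worked example

Simulate a small culture (256×256 px, 24 hourly frames, 25 cells, 1 %/h
death hazard) and analyze it end to end:

```
$ stamp simulate -c sim.json -o demo_sim      # sim.json: {"dims": [256,256],
                                              #  "n_frames": 24, "n_cells": 25,
                                              #  "seed": 3, "hazard_per_frame": 0.01}
wrote red.tif, green.tif, true_events.csv, sim_config.json to demo_sim

$ stamp run -c run.json                       # points at demo_sim, pixel_size_um
tracks: 35  events: 8  threshold: 1.303       # 2.83, radius range 3..9 px,
artifacts in demo_run                         # T_LAG 10 h, T~ 8 h
```

The run directory then holds `tracks.csv`, `traces.csv`, `events.csv`,
`kinetics.csv`, `survival.csv`, `pdeath.csv`, `chains.csv` and a
checksummed `MANIFEST.json`. All 8 programmed deaths were called
(`events.csv`), the estimated pooled threshold was *th* = 1.303, and the
kinetics read:

```
 frame  hours  n_ap  n_track  o_percent
    11     11     6       20    24.4444
    23     23     2       20    10.5263
OS at 24 h: 76.0%
```

i.e. six of ~20 living tracks died in the 10 h window ending at 11 h
(*O* ≈ 24 %), killing slowed later, and three quarters of the starting
population survived the day. `stamp plot demo_run` renders the rate,
survival, P<sub>death</sub> and death-map figures;
`stamp pdeath --events deaths.csv ...` computes the induction potential
directly from an externally produced death table.

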