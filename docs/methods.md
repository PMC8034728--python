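# Methods

This note records the model underlying `stamp`, the conventions and
defaults it fixes, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Conventions

* Pixel arrays are indexed `(row y, col x, frame t)`; `x` is the column
  and `y` the row, both 0-based. Frames are 0-based internally and
  1-based in every CSV output, so a recording spans frames `1..T`.
* Intensities are converted to `float64` on read, with no per-frame
  rescaling; all normalization is local (per ROI, per track).
* Users state durations in hours and window sizes in micrometers; a
  `Calibration` (μm/px, h/frame, default 1 h/frame) converts to pixels
  and frames. Calibration is always explicit, never inferred from files.

## Detection and tracking

Cells are assumed near-circular and slow-moving at the hourly cadence of
ToC recordings. Each red frame is binarized with Otsu's threshold and the
mask boundary is fed to a Circular Hough Transform over an imposed radius
range (`radius_min_px..radius_max_px`); accumulator peaks below a
perimeter-support fraction of 0.4 are discarded and the rest are greedily
non-maximum-suppressed with minimum separation `radius_min_px`, which
prevents double detections of one cell. Running the CHT on the binarized
mask (rather than the grayscale image) makes detection insensitive to
absolute intensity.

Linking minimizes total squared displacement per frame pair (Hungarian
algorithm); pairs farther apart than the gating distance (default
3 × `radius_max_px` per frame — generous for cells that drift ~1 px/h)
are never matched. Unmatched detections open new tracks; a track
unmatched for more than `max_gap_frames` (default 2) terminates, and
shorter dropouts are bridged by linear interpolation of position and
radius so every track covers a contiguous frame interval. Tracks are
*not* truncated at the death call: the living-cell counts downstream are
computed by thresholding the caspase signal, not by ending tracks.

## Caspase signal and death calling

The 31×31 px ROI (≈20 μm at the intended magnification) bounds the
analysis to each cell's neighborhood. The foreground is the detected
cell disk (per-frame CHT radius); the background is the annulus between
that disk and a circle of radius `bg_radius_factor` (default 2.0) times
the experiment-average cell radius, clipped to the ROI. The annulus
reading keeps foreground and background disjoint. ROIs that cross the
frame edge are averaged over in-frame pixels only.

Frames whose background mean falls below an epsilon floor (default 10⁻⁶
of the channel maximum) would make the ratio (μF−μB)/μB explode; they
are excluded and linearly interpolated from valid neighbors instead.

The threshold *th* is one per video: all μ samples of all tracks are
pooled and the exact Otsu split (midpoint between consecutive sorted
values maximizing between-class variance, computed on the raw multiset
rather than a binned histogram) is taken. Death is the *first* crossing
μ > *th*; later dips below threshold (reporter bleaching) never retract
a call.

## Kinetics

`N_ap(t)` counts death events in the trailing window of `T_LAG` frames
ending at `t` (frames `t−T_LAG+1..t`), so a constant per-frame hazard
`h` gives `O ≈ 100·h·T_LAG`; `N_avg(t)` is the mean living-track count
over `[t−T_LAG, t]`. `O` is emitted from the first frame with a full
trailing window; earlier frames, and frames with `N_avg = 0`, are
missing values. `T_LAG` defaults: 10 h when benchmarking global
accuracy, 4 h when comparing kinetics. Overall survival smooths the
living count over three centered frames and normalizes to the mean of
the first three frames, so `OS` starts at 100 % by construction.

## Death maps and the induction potential

The structuring element is `B_r = {(x, y): x² + y² ≤ r²}` with `r` one
third of the experiment-average cell radius (rounded up), so each wake
survives at least three hourly frames: erosion shaves `r` off the object
radius per frame, `r_tc(t) = max(0, r_tc(t0) − r·(t−t0))`. Same-frame
overlapping seed disks are unioned (the seed video stays binary), but
the wake recursion is additive, so a death landing on a surviving wake
can exceed 1 — deliberate, as it encodes repeated death signaling at one
site. Grayscale erosion uses edge replication at the frame border, i.e.
the minimum is effectively over in-frame pixels.

The cumulative window is forward and inclusive:
`MC(t) = Σ_{t′=t}^{t+T̃} M(t′)²`, defined for `t ≤ T−T̃`. `T̃` defaults to
16 h, the value at which the distribution of chain-of-death durations
(see below) is essentially fully captured. Death objects are 8-connected
components of the non-zero support; each object's representative point
is its *boundary* centroid (mean coordinate of pixels with a background
8-neighbor), and pair distances are normalized by the largest dimension
of the evaluation region — the window side when evaluated in sliding
windows. Pairs with coincident centroids (possible for nested objects
after window clipping) are skipped with a logged count rather than
producing an infinite term.

The 283 μm sliding window is tiled with stride = one window side
(non-overlapping cover; the final row/column of windows anchors to the
frame edge), and the per-frame aggregate is the mean over windows
containing at least one object (`max` available as an option). A window
larger than the frame degrades to a single whole-frame evaluation.

Chains of death: every event seeds a chain; walking the remaining events
in death-time order, an event joins if it lies within 10× the seed's
death radius of the seed position and within `T_LAG` frames of the
latest member ("within" rather than "exactly at" the lag — the inclusive
reading). The chain's total duration is the seed's induction interval,
in hours. Because every event seeds a chain, members may belong to
several chains.

## Synthetic data

The video generator emulates: disk-shaped red cells (hard disks smoothed
by a σ=1 px Gaussian) with Brownian drift (default 0.5 px/frame) on a
dark background; scheduled or hazard-driven deaths; a green disk that
ramps up over `green_rise_frames` (default 2) at death and persists;
dead cells stop moving and keep their red stain; Gaussian read noise
(default σ=5 on a background of 20, cell peak 180 — peak ≥ 5× noise);
frames rounded to integer counts so a fixed seed reproduces stacks
bit-exactly. Defaults are 512×512 px, 48 hourly frames, ~100 cells with
radius 6 ± 1 px — dense enough for pairwise statistics, small enough for
minutes-scale runs. Not emulated: photobleaching, flat-field and
illumination drift, out-of-focus movement in the 3D gel, cell division,
unstained populations (T cells, fibroblasts), and partial-volume shape
changes during apoptosis. Tests passing on this generator therefore
validate the algorithmic chain, not robustness to those imaging
artifacts.

Abstract pattern generators produce event tables without rendering:
uniform-random or clustered (k Gaussian clusters) placements with
uniform or matched temporal profiles, and a contagion cohort — cells on
a jittered grid (a confluent culture), one initiating death forced near
the field center, every death raising the hazard of cells within a
capture radius (default 16 px) for a short lag (default 3 frames), so a
death wave expands for the rest of the video. The cluster spread
(22 px) and grid spacing (12 px) are chosen above the wake-merging
scale: death disks closer than a diameter fuse into one connected
object, which is physically the same death zone, not two inducing
neighbors.

## Numerical choices and problem sizes

* Exact Otsu on pooled signals (not 256-bin) because the pooled sample
  is small and a binned threshold need not maximize the true
  between-class variance; image binarization uses the standard binned
  Otsu.
* Assignment uses a large finite sentinel cost (10¹²) for gated pairs;
  sentinel matches are discarded after solving.
* The demonstration scenario fixes three deaths at hours 2, 9 and 11
  (radius 9 px, erosion radius 3, T̃ = 6 frames) at positions 24–31 px
  apart, chosen so the documented shape — zero potential with one
  object, a rise at the second and third deaths, a fall when the first
  wake leaves the window — is geometrically realized; assertions are on
  orderings, never on absolute values.
* Verification problem sizes: the closed-loop recovery runs one
  512×512×48 scene (~100 cells, ~40 deaths); hazard recovery uses 600
  idealized tracks over 60 frames; the spatial dichotomy uses 20
  replicates of 40-event patterns on 200×200 fields (contagion on
  300×300), with T̃ = 16 frames and a 100 px window. Slopes of
  P_death series are fitted after discarding the first 4 frames, the
  burn-in during which the map cannot yet contain full wake memory.
* Statistical criteria: clustered > random by one-sided sign test
  across replicates; flatness of the random-pattern slope within 2
  standard errors of the replicate mean; hazard recovery within 3
  binomial standard errors computed from the observed living
  cell-frames.

## Known limitations

* The tracker has no division or merge handling; a crossing pair at
  sub-radius separation can swap identities.
* Detection requires the imposed radius range to cover the true cell
  radii; radii at the range edge bias the Hough estimate inward.
* `P_death` depends on the window side and on T̃; values are comparable
  only between runs with identical calibration and windows.
* The per-window object clipping can split one object across tile
  boundaries; objects are not merged across windows.
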