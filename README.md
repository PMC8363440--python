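# bmptrack

Speckle tracking for echocardiographic image sequences by **pyramid-pruned
block matching**, with a ground-truth speckle phantom generator, a
search-strategy benchmark, and clinical efficacy grading for angina/ECG
treatment outcomes.

## The problem

Two-dimensional speckle-tracking echocardiography follows the granular
interference pattern (speckle) of ultrasound B-mode images across frames to
measure myocardial motion — for example the displacement of the left
ventricular wall in patients with coronary heart disease. The core
computational step is **block matching**: given a template block `x` of side
`2^M` centred on a marked spot, find within a search window the candidate
block `y` of the next frame that minimises the sum of absolute differences

```
SAD_m(x, y) = Σ_{i=1}^{2^m} Σ_{j=1}^{2^m} | x_m(i,j) − y_m(i,j) |
```

where `x_m` is layer `m` of a block *pyramid*: layer `M` is the original
block and each coarser layer is the exact 2×2 sum-pool of the finer one. By
the triangle inequality the layer SADs form a monotone chain,

```
SAD_0 ≤ SAD_1 ≤ … ≤ SAD_M ,
```

so any coarse-layer SAD is a lower bound on the full-resolution SAD. A
candidate can therefore be abandoned as soon as a coarse layer already
meets the best full SAD found so far — pruning that provably never changes
the optimum. `bmptrack` implements this pruned search alongside the
exhaustive (global) baseline and the classic 2-D logarithmic
(step-halving) search, lifts them to multi-frame spot tracking with
trajectories in pixels and millimetres and a motion-period estimate, and
ships a contracting-ring speckle phantom whose exact analytic ground truth
makes tracking accuracy measurable.

The package is for researchers and engineers evaluating block-matching
speckle trackers: it trades clinical image ingestion (DICOM, Doppler
overlays) for a fully reproducible, oracle-backed test bed.

## Worked example

Simulate a 250-frame phantom (contracting ring, period 50 frames,
amplitude 7.5 px, 16 marked spots) and track its spots with the
pyramid-pruned search:

```sh
bmptrack simulate --out demo --frames 250 --seed 7
bmptrack track demo/phantom.tif --seeds demo/seeds.csv \
    --out demo/traj.csv --method bmp --window 4
```

(the seeds CSV holds `spot_id,row,col` — here the rounded frame-0
ground-truth positions). The track command prints per-spot maxima and a
summary:

```
spot15: max displacement 7.62 px = 7.01 mm
maximum displacement 7.62 px = 7.01 mm (spot spot05)
estimated motion period: 50 frames
wrote demo/traj.csv
```

The maximum excursion of ~7.5 px matches the phantom's contraction
amplitude (each wall point moves inward by up to `A = 7.5` px, so
diametrically opposite wall points separate by up to 15 px — at the default
0.92 mm/px spacing, about 13.8 mm of wall-to-wall motion), and the period
estimate recovers the generator's 50-frame cycle from the displacement
autocorrelation. `demo/traj.csv` holds one row per spot per frame
(`frame_index, spot_id, row, col, dr, dc, displacement_px,
displacement_mm`).

Benchmark the search strategies against the phantom's exact ground truth:

```sh
bmptrack benchmark --out report.csv --plot report.png --seed 1
```

which reports, per (method, window radius), the fraction of (spot, frame)
pairs tracked to within 1 px and the mean number of candidate displacements
evaluated per match — the hardware-independent cost of each strategy.

Grade clinical outcomes from a CSV of per-patient scores:

```sh
bmptrack grade --angina angina.csv --out tally.csv
```

prints the total effective rate (percentage of patients graded obviously
effective — ≥60 % drop in total angina score — or effective — ≥30 % drop).

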