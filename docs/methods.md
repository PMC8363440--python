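# Methods

## Block matching and the pyramid bound

A template block of side `B = 2^M` (default 16, i.e. `M = 4`, five pyramid
layers) is compared with candidate blocks by the sum of absolute
differences (SAD) of raw intensities — no normalisation, no sub-pixel
interpolation; displacements are whole pixels, `(dr, dc) =` candidate
origin − window centre in 0-based (row, col) coordinates.

The pyramid of a block stacks the block itself (layer `M`) under its
successive exact 2×2 sum-pools down to a single cell (layer 0, the grand
sum). For sum-pooling, the triangle inequality gives
`|Σa − Σb| ≤ Σ|a − b|` cell-wise, so the SAD at layer `ℓ−1` never exceeds
the SAD at layer `ℓ`: coarse SAD is a true lower bound on full-resolution
SAD. The pyramid is built per block (template and candidate), not over the
whole frame, because the bound is needed between two blocks at arbitrary
integer offsets.

Three search strategies share one contract (window of radius `w`, border
candidates that would push the block out of frame are excluded rather than
padded, SAD ties broken by lexicographic `(dr, dc)`, smallest first):

* **global** — evaluates the finest-layer SAD of every candidate;
  the exact optimum and the accuracy reference.
* **bmp** — evaluates each candidate coarse-to-fine and abandons it at the
  first layer whose SAD meets the best finest-layer SAD so far. Because
  the bound is exact and the best is only replaced on a strict
  improvement, the result (displacement *and* SAD) is bit-identical to
  global search on every input; only the cost differs.
* **log** — 2-D logarithmic descent: step `s = max(1, ceil(w/2))`, score
  the centre and its four axial neighbours at distance `s`, recentre on
  the minimum, halve `s` when the centre wins, and at `s = 1` score the
  8-neighbourhood until the centre is a local minimum. Moves happen only
  on a strict decrease of the `(SAD, dr, dc)` tuple, which guarantees
  termination, makes ties deterministic, and at `w = 1` makes the search
  exhaustive. Scored positions are cached, so it never evaluates more
  candidates than global search; on multimodal SAD surfaces it may stop
  at a non-global local minimum — that is its accuracy/cost trade-off.

Cost is counted in candidates evaluated per match (for `bmp`, candidates
abandoned before the finest layer are additionally reported as pruned).
Candidate counts are the benchmark's cost measure; wall time is recorded
but informational, since it is hardware-dependent.

## Tracking

Seeds are explicit inputs (marked spots; CSV or API), the block being
centred on the seed. For each consecutive frame pair the template is
matched within a window centred at the current estimate and the estimate
advances by the recovered integer displacement. Trajectories report
per-frame positions, Euclidean displacement from the frame-0 position
(path length is also available), maxima in px and mm, and a period
estimate.

**Template update.** The template is by default the frame-0 block at the
seed (*anchored* matching). This is a deliberate choice forced by integer
displacements: cardiac wall motion at usual frame rates is well below one
pixel per frame, and a template re-cut every frame re-quantises the
position at every step, so each sub-pixel increment rounds to zero and the
motion is never seen (the tracker then only random-walks on noise). An
intermediate refresh-on-move rule fares no better: each refresh discards a
sub-pixel residual of consistent sign during a monotone contraction
phase, producing systematic drift. The anchored template accumulates
sub-pixel motion until it crosses the quantisation threshold and is
drift-free; its cost — slow decorrelation between the frame-0 texture and
the deformed current frame — is small over the displacement amplitudes
considered here. Sequential update (`template_update="previous"`) remains
available for data whose texture decorrelates quickly.

**Units.** Physical displacement is `pixels × pixel_spacing_mm`. The
default spacing is 0.92 mm/px (the value implied by a 15 px excursion
spanning 13.8 mm); sequence sidecar metadata overrides it.

**Period estimate.** The displacement series is demeaned and its biased
normalised autocorrelation computed; the estimate is the lag of the first
peak with autocorrelation ≥ 0.5 (lags up to half the series length). The
0.5 threshold rejects white-noise series at the 250-frame lengths used
here (noise autocorrelation is O(n^-1/2) ≈ 0.06) while a periodic
displacement sampled over ≥3 cycles scores ≈ 1 − lag/n ≥ 0.8. Constant
series return no estimate.

## The phantom

The phantom stands in for clinical cine loops: a bright ring
("myocardial wall", Gaussian radial profile, σ = 4 px) over a darker
background, multiplied by fully developed speckle — a low-pass-filtered
(grain 2 px) unit-variance Gaussian field at multiplicative strength 0.35,
giving an intensity coefficient of variation ≈ 0.3 in the band — plus
additive per-frame sensor noise (σ = 0.02 on a [0, 1] scale), clipped to
[0, 1].

Contraction is periodic radial translation of the wall: the band radius at
frame `t` is `R(t) = R − A·(1 − cos(2πt/P))/2` (defaults `R = 40` px,
`A = 7.5` px, `P = 50` frames, 250 frames per sequence — several cycles).
Material at reference radius `ρ` is displaced radially by
`(R(t) − R)·w(ρ)` with a Gaussian envelope `w` (σ = 20 px) equal to 1 on
the band and tapering to 0 at the image centre and far field. The wall and
its block-sized neighbourhood therefore move together — locally near-rigid,
as tissue does and as block matching assumes — while the map stays
invertible (checked at generation time) and the cavity centre stays put.
An early variant used a global radial zoom instead; it was replaced
because a zoom shears a 16-px block by ±20 % of the centre motion at peak
contraction, a deformation regime block matching is not meant for and
unlike wall-centred tissue motion.

Each frame resamples one fixed reference image under the inverse radial
map (cubic interpolation), so the speckle texture is advected with the
tissue — the property that makes speckle trackable in real ultrasound.
The 16 spots sit evenly on the band at `t = 0`, exactly where `w = 1`, and
are advected analytically: their radius is exactly `R(t)`, trajectories
are `P`-periodic in closed form, and the maximum true displacement equals
`A`. Ground truth is therefore exact, not itself tracked.

What the phantom does **not** model: point-spread-function convolution and
range-dependent resolution, log compression, attenuation and shadowing,
out-of-plane motion and speckle decorrelation beyond resampling, probe
sector geometry. Passing accuracy figures on the phantom show the
tracker's geometric and numerical behaviour under known motion with
realistic texture statistics; they do not certify accuracy on clinical
images.

A rigid-translation fixture (static textured canvas, integer shift per
frame, exact truth) covers the degenerate case where tracking must be
error-free.

## Benchmark

Accuracy is the fraction of (spot, frame) pairs whose tracked position
lies within 1 px (Euclidean) of the true position — the standard
endpoint-error criterion; 1 px is also the natural threshold for an
integer-valued tracker against real-valued truth (perfect integer tracking
errs by at most √0.5 ≈ 0.71 px). The default grid is global and
logarithmic search at window radii 2–8 on three seeded default phantoms
(128², 250 frames, 16 spots; 12 000 pairs per cell), pooled per cell.
These problem sizes keep a full grid run to well under a minute per method
while the accuracy estimates have sub-percent replicate noise. Because
`bmp` is bit-identical to `global`, benchmarking it adds cost information
only; the default grid therefore runs the two strategies that differ in
result.

## Efficacy grading

Angina: with fractional decrease `d = (pre − post)/pre` of the total
angina score (`pre > 0` required), grades are obviously effective
(`d ≥ 0.60`), effective (`0.30 ≤ d < 0.60`), ineffective (`0 < d < 0.30`)
and aggravated (`d ≤ 0`; "no decrease" is deterioration). Thresholds are
inclusive ("at least"). ECG: returned-to-normal → obviously effective;
else ST rise > 0.05 mV or T wave flat→upright → effective; else ST fall
> 0.05 mV, fully reversed T wave (upright↔inverted) or new ectopic rhythm
→ aggravated; else ineffective. Aggravation is checked before
"ineffective" so a frank deterioration is never classed as "no significant
change". The four predicates partition all valid records.

The total effective rate is `100 × (obviously effective + effective) / n`,
rounded to one decimal half away from zero — the only rounding rule
consistent with the conventional reporting of such rates. A generic 2×2
Pearson χ² helper is included for completeness; the package makes no
claim about any specific trial statistic.

## Numerical and interface choices

* Ties everywhere resolve to the lexicographically smallest `(dr, dc)`;
  repeated runs on identical inputs are bit-identical.
* A window with no in-frame candidate raises an error; during tracking a
  spot that can no longer be matched is clamped and its trajectory flagged
  truncated rather than discarded.
* All randomness flows through `numpy.random.default_rng(seed)`; the same
  config and seed reproduce phantom pixels byte-for-byte (the CLI
  `simulate` output is byte-identical across runs).
* Integer intensities are rescaled to [0, 1] on load; SAD operates on
  values as given.
* Output CSVs carry `#` header lines with the tool version, a
  configuration hash and the seed, so any artefact can be traced to the
  run that produced it.

## Limitations

Integer-pixel tracking bounds per-pair accuracy by the quantisation floor;
sub-pixel refinement is deliberately out of scope. Anchored templates
assume the tracked texture stays recognisable from frame 0 — long
sequences with strong decorrelation would need periodic re-anchoring.
The logarithmic search inherits the usual local-minimum risk on
low-contrast or repetitive texture. The efficacy module treats scores and
ECG features as given; it encodes grading rules, not clinical judgement.
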