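# Methods

This note records the models, conventions and numerical choices behind
`glottiseg`, in the order the pipeline applies them.

## Pre-processing

RGB frames are reduced to 8-bit grayscale with the BT.601 luma weights
(0.299, 0.587, 0.114), rounded half away from zero.  Motion is located
with the total-variation map, the per-pixel sum of absolute inter-frame
differences computed in int64: during phonation only the folds move, so
thresholding this map at a fraction of its maximum (default 0.25) and
keeping the largest 8-connected component isolates the glottal region.
The region's bounding box, expanded by a 10 px margin, is the ROI.  The
rotation that stands the glottal main axis upright is the principal-axis
angle of the thresholded component, from second-order central moments;
frames are rotated about the component centroid with bilinear
interpolation, out-of-frame pixels filled with the frame median.  An
isotropic component (no preferred axis) is left unrotated.  The
threshold fraction and margin are free choices — the upstream literature
only illustrates the map — and both are exposed in the configuration.

## Segmentation family

`mask = (med_α − I ≥ β)` with α odd in [1, 255] and β in [1, 255].  Even
window sizes have no centre pixel, so sweeps use odd α only; the nominal
parameter square 255 × 255 = 65,025 pairs is preserved as the "full"
grid's reference size.  Borders are handled by reflect padding, so edge
pixels see a mirrored neighbourhood rather than an implicit dark frame;
the median itself is an exact histogram-based rank filter, verified in
the tests against a per-pixel sorted-window oracle.  α = 1 makes the
difference identically zero and is allowed but logged.  The default
sweep is a 32 × 32 grid — 32 log-spaced odd α (small scales sampled
densely, where the behaviour changes fastest) × 32 linearly spaced β —
because the exhaustive square costs orders of magnitude more for
near-identical minima; `--grid full` restores the exhaustive sweep.

## Glottal geometry

Per frame, the glottal component is the largest 8-connected component
whose centroid falls in the central half of the ROI (spurious dark blobs
hug the ROI edges), with interior holes filled.  Hole filling and
labelling run on the whole stack at once with a frame-local 3-D
structuring element, which keeps the per-candidate cost flat.  The
glottovibrogram splits the sequence-wide occupied row range into L
contiguous bands (default L = 64, or one band per row when the extent is
smaller) and records the *mean per-row* foreground count per band, so
values are widths in pixels regardless of band height.  When L equals
the row count, the band widths sum exactly to the glottal area — a
conservation law the tests assert.  Level 0 is the top (anterior) row;
the mid level ⌊L/2⌋ is where quotients are read, following the clinical
focus on the middle glottis.

## Acoustic path and spectral matching

The voice recording is low-pass filtered with a 4th-order Butterworth at
1500 Hz applied forward–backward (zero phase, so audio and video stay
aligned), then decimated by keeping every 7th sample: 22,050 Hz → 3150 Hz,
the frame rate.  Both spectra use the bare 1/N-scaled DFT over a common
N = min(frames, ⌊samples/7⌋), moduli over bins 0‥N/2−1; no window is
applied by default.  The glottovibrogram spectrum sums the complex row
transforms *before* the modulus — equivalently, it is the DFT of the
level-summed width series — so in-phase rows reinforce.

The literal cost Σ| |F| − |S| | compares pixel widths with sound
pressure; its DC and overall scale would dominate the comparison.  The
default mode therefore drops bin 0 and normalizes both modulus vectors
to unit L1 mass before differencing ("unit-l1-nodc"); the literal
difference remains available as `normalization="none"`.  Under the
default the winner is invariant to the loudness of the recording, which
the tests assert.  Candidates that segment nothing in more than 90% of
frames, or whose spectrum has no mass after DC removal (truly static
content), are excluded from the argmin; ties break toward the smallest
(α, β).  The sweep computes each α's median stack once and streams the
β thresholds over it, discarding losing candidates immediately, so
memory does not grow with the grid.

## Cycles and quotients

Cycles run between consecutive minima of the moving-average-smoothed GAW
(window = ⌊period/8⌋ forced odd; minima at least half the dominant
period apart, the period taken from the GAW spectrum peak).  Within a
cycle, open frames are those whose mid-level gap width exceeds
`closure_eps` (default 0.5 px); the aperture maximum splits the open
span into opening and closing phases.  These phase conventions make
SQ = (OQ − CQ)/CQ hold per cycle exactly, and that identity doubles as a
consistency check on any reported index triple (under two-decimal
rounding of CQ and OQ the residual can legitimately reach ≈0.12).

Rasterized gap widths move in whole-pixel steps, so the aperture maximum
sits on a plateau and threshold crossings carry up to a frame of error —
large against a ~21-frame cycle.  By default the quotients therefore use
sub-frame phase boundaries: closure crossings linearly interpolated
between neighbouring samples, and the aperture maximum estimated as the
centre of mass of the above-threshold width excess (first-order
quantization error cancels; for strongly skewed pulses this estimator is
biased toward the pulse centre, which is the known trade-off).  Integer
whole-frame conventions remain available (`subframe=False`) and are what
the hand-worked fixture in the tests pins down.  Per-recording values
are the arithmetic mean over cycles (median by flag); cycles with zero
maximum area are skipped, and SQ averages only cycles with a non-empty
closing phase.

## Group statistics

The Mann–Whitney U test uses pooled midranks, U = R_x − n_x(n_x+1)/2,
and the plain normal approximation z = (U − n_x n_y/2) / √(n_x n_y (n+1)/12)
with **no** continuity and **no** tie correction — this exact variant is
required to reproduce the published p-values of the reference cohort
(complete separation on OQ gives U = 0 and p = 7.1 × 10⁻⁵ at n = 11+11);
an exact-permutation option exists for small samples.  Group medians use
the midpoint convention for even counts.  The packaged
`reference_cohort.csv` carries the published per-subject quotients of 11
normophonic and 11 dysphonic subjects and is the input to the
reproduction path.

## Synthetic recordings

The generator emulates what the instrument records, not fold mechanics:

* **Aperture**: w(l, t) = max(0, A(l)(sin(2πf0t/fv) − c)) + gap(l) with
  c = cos(π·OQ), so the open fraction equals the requested OQ exactly;
  A(l) encodes the closure-type profile (A flat, B hourglass, C/D
  wedges, E spindle) scaled to `amplitude_px` (default 9 px half-width),
  and gap(l) a never-closing residual that drives MRGA > 0.
* **Video**: one glottal level per image row on a 120 × 88 canvas
  (default; the glottis fills a fraction of the frame comparable to
  clinical recordings — the canvas is deliberately smaller than the
  clinical 480 × 400 so that full grid sweeps stay affordable, and every
  quantity is resolution-independent by construction).  Tissue is a
  bright textured background (low-frequency Gaussian field), radially
  vignetted, the gap is rendered dark, and Gaussian noise (σ = 3) is
  added after the ground-truth mask is taken.  The rasterization midline
  is offset a quarter pixel so widths do not move in even-only steps.
* **Audio**: length exactly 7 × frames.  Harmonic amplitudes and phases
  come from the Fourier series of the clipped-sine pulse itself — the
  voice is the vocal-tract-filtered glottal source, so its spectral
  envelope must track the pulse; a generic dB-per-harmonic rolloff
  (available as `source="rolloff"`) produces a spectrum closer to
  edge-artifact candidates than to the true aperture and defeats the
  matching principle.  Two unit-peak second-order resonators (280 Hz,
  2100 Hz — an /i:/-like formant pair) colour the spectrum, and white
  noise is added at 30 dB SNR.
* **Ground truth**: OQ = target (or 1 with a residual gap), CQ = OQ/2
  and SQ = 1 for the symmetric drive, MRGA from the analytic area ratio.
  All outputs are bit-reproducible given the model and seed.

What the generator does **not** emulate: mucosal waves, left–right
asymmetry, endoscope motion, specular highlights, lens distortion, or
aperiodic phonation.  Passing the recovery tests therefore shows the
method's internal consistency under its own assumptions, not clinical
performance.

## Problem sizes and defaults

The standard recovery experiment uses 512 frames at 3150 frames/s
(≈163 ms, 24 cycles at f0 = 150 Hz), 3584 audio samples, and the 32 × 32
coarse grid; the sweep takes a few minutes on one core, dominated by the
large-α median filters.  Tolerances asserted on synthetic data — Dice
≥ 0.80, OQ/CQ/MRGA within ±0.05, SQ within ±0.10, spectral peak within
one bin of f0 — reflect rasterization and cycle-quantization limits, not
the matching principle itself.

## Known limitations

* The cost compares one-dimensional spectra; two segmentations with
  identical level-summed width series are indistinguishable.
* Once a candidate segments the gap correctly, further parameter changes
  barely move its spectrum: correct candidates form a near-flat cost
  plateau, and the argmin within that plateau is decided by margins at
  the fourth decimal.  A very low β that admits sensor noise can sit just
  below the plateau on some noise realizations, so the overlap (Dice) of
  the selected masks varies with the realization while the recovered
  quotients stay stable — selection quality should be judged on the
  quotients, not on the identity of the winning (α, β).
* Audio/video synchronization is assumed exact (hardware-synchronized
  acquisition); a constant offset would not change amplitude spectra,
  but drift would.
* The aperture-maximum estimator biases SQ toward 1 for strongly skewed
  pulses (see above).
* AVI/MP4 input requires an imageio decoder plugin at runtime;
  multi-page TIFF is the self-contained interchange format.
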