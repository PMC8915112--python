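# glottiseg

Fully automatic segmentation of the glottal area in laryngeal high-speed
videoendoscopy (LHSV), guided by the synchronously recorded voice signal,
plus the vibratory indices and group statistics built on top of it.

## The problem

During sustained phonation the vocal folds open and close a few hundred
times per second; a high-speed camera (nominally 3150 frames/s) films the
dark gap between them — the glottis — while a microphone records the voice
at 22,050 Hz, exactly 7 samples per frame.  Clinical indices such as the
Open Quotient require an accurate per-frame segmentation of the glottal
area, but classic threshold segmentations need per-recording parameter
tuning, and expert ground truth is costly.

## The method

The segmentation family is a two-parameter median-difference threshold

```
mask(x, y) = 1   iff   med_α(x, y) − I(x, y) ≥ β
```

where `med_α` is an α×α median filter and β a darkness threshold.  For
every candidate (α, β) on a grid, the binary masks are reduced to a
*glottovibrogram* g(t, l) — gap width per frame t and glottal level l —
whose spectrum is

```
F(f) = (1/N) Σ_l Σ_t g(t, l) e^(−j2πtf/N)
```

The voice signal is low-pass filtered (4th-order Butterworth, 1500 Hz,
zero-phase), decimated by 7 to the frame rate, and transformed the same
way into |S(f)|.  Each candidate is scored by

```
d(α, β) = Σ_f | |F(f)| − |S(f)| |
```

(by default after dropping the DC bin and normalizing both modulus
vectors to unit L1 mass), and the minimizer (α*, β*) is selected.  The
physical rationale: a correct segmentation oscillates at the voice
fundamental frequency with the harmonic content of the glottal pulse, so
its spectrum matches the voice spectrum; segmentations that latch onto
static anatomy or noise do not.

From the winning masks the package derives the glottal area waveform
(GAW), the gap waveform at the mid glottis (GGW), per-cycle quotients

* **OQ** — open duration / cycle duration,
* **CQ** — closing duration (aperture max → closure) / cycle duration,
* **SQ** — opening duration / closing duration,
* **MRGA** — min area / max area within a cycle,

and two-sided Mann–Whitney U comparisons between normophonic and
dysphonic groups.

A synthetic recording generator (`glottiseg.synthetic_lhsv`) renders an
oscillating dark gap with the five standard glottal closure-type profiles
(A rectangle … E spindle) on textured, vignetted tissue, together with a
voice signal whose harmonics follow the glottal pulse — with analytic
ground-truth masks, waveforms and quotients, so the whole pipeline is
testable without clinical data.

## Worked example

```python
from glottiseg import (PhonationModel, simulate, optimize_segmentation,
                       coarse_grid, gaw, ggw)
from glottiseg.vibratory_indices import detect_cycles, compute_indices

rec = simulate(PhonationModel(seed=1))           # 512 frames, f0 = 150 Hz
res = optimize_segmentation(rec.video, rec.audio, coarse_grid())
print(res.best_params, round(res.best_cost, 4))

area, width = gaw(res.best_masks), ggw(res.best_gvg)
idx = compute_indices(detect_cycles(area, width), width, area)
print(idx.rounded())
print(rec.truth_indices)
```

prints

```
SegmentationParams(alpha=255, beta=17) 0.2386
GlottalIndices(CQ=0.37, OQ=0.71, SQ=0.93, MRGA=0.0, n_cycles=23)
GlottalIndices(CQ=0.35, OQ=0.7, SQ=1.0, MRGA=0.0, n_cycles=24)
```

i.e. the acoustically selected segmentation recovers the generator's
quotients to a few hundredths without ever seeing the ground truth.  The
full 32×32 sweep takes a few minutes on one core.

The same pipeline is available from the shell:

```
glottiseg simulate --frames 512 --seed 1 --out sim/
glottiseg full sim/video.tiff sim/audio.wav --out run/
glottiseg stats run/indices.csv --out report/
```

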