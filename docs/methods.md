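# Methods

## The assay this package models

Phototoxicity in live-cell microscopy is quantified here through its effect
on cell-cycle progression. A population of adherent cells is synchronised
at the G2/M boundary (CDK1 inhibition), exposed once to a controlled light
dose, released, and then imaged in low-irradiance brightfield every few
minutes for several hours. Because mitotic entry forces adherent cells into
a transient spherical morphology ("mitotic rounding"), the timing of the
population's division wave is observable without labels. Photodamage
manifests as a rightward shift of the rounding-time distribution, a delayed
appearance of daughter cells, an excess of cells that round but never
divide (cell-cycle arrest), reduced overall cellular activity, and, at high
doses, outright cell death.

The package computes five families of readouts:

1. **Rounding-time distribution C(t)** — per frame, the number of round-cell
   detections divided by the number of cells in the field of view, the
   latter counted once at frame 0. The peak time
   `t_p = argmax_t C(t)` marks the division wave. Ties break to the
   earliest time: photodamage shifts peaks rightward, so the earliest
   maximum is the conservative estimate. When `max C(t)` is below a
   configurable floor (default 0.01) the result is "no peak", which is the
   observed phenotype at very high doses rather than an error.
2. **Cell-size dynamics** — each detection's pixel area S maps to an
   equivalent-circle diameter via `S = πR²`, `D = 2R`, computed from the
   mask's own pixel calibration. Detections with `D > 18 µm` are mother
   cells (pre-division, ~20 µm), the rest daughters (~15 µm). Mother and
   daughter counts per frame expose the division transition; the fraction
   of tracked events that produce two daughters by a deadline (default
   50 min) is the transition fraction.
3. **Cellular activity** — `activity(t) = mean((eIm(t) − eIm(t−1))²)` over
   pixels of consecutive preprocessed frames, and its running sum. "mean of
   squared differences" (not a norm of the difference image) keeps the
   metric comparable across resolutions. The frame-0 term has no
   predecessor and is defined 0. Cumulative activity is conventionally
   reported at T = 420 min and, across conditions, divided by the
   replica's control mean so replicas of different raw scale become
   comparable fold-type values (max-scaling is a configurable alternative).
4. **Viability** — dye-positive nuclei in a fluorescence channel are
   segmented (Otsu threshold, distance-transform watershed, minimum-area
   filter) and divided by the same frame-0 cell count.
5. **Light-dose bookkeeping** — areal dose in J/cm² is
   `n_repeats · power · time / area`, with the full FOV as the area for
   widefield exposures and the single scan pixel (side² · 10⁻⁸ cm²) with
   the dwell time for point-scanning regimes. Powers are as measured at
   the sample; no optical-transmission modelling.

## Preprocessing chain

Activity is meaningless on raw frames because lamp drift and uneven
illumination dominate frame differences. The chain is, in order: per-frame
min–max normalisation to [0,1]; per-frame bleach/illumination correction by
subtracting a wide Gaussian low-pass of the frame; whole-video min–max
normalisation; per-frame CLAHE (25 px kernel, clip limit 0.01, 256 bins);
per-frame Gaussian smoothing with σ = 1 px. Design points:

* The bleach-correction σ defaults to `min(height, width)/4`: the low-pass
  must capture the illumination field, which is far larger than a ~20 µm
  cell (~36 px at 0.55 µm/px). For σ > 8 the filter runs at reduced
  resolution (downscale, filter, upscale), which is numerically equivalent
  for the smooth fields it estimates and far cheaper.
* Negative values after the subtraction are kept and rescaled by the
  subsequent whole-video min–max; clipping would destroy contrast. The
  whole-video scope (global min/max over all frames) is what keeps
  temporal differences comparable.
* The leading per-frame min–max makes the whole chain invariant to
  per-frame positive affine rescaling of the raw input; a ×1.5 linear
  brightness drift on static content changes post-chain frame means by
  < 0.001 % (tested).
* CLAHE's "kernel of size 25" is interpreted as a 25×25 px tile. Residual
  negatives after smoothing are clipped to 0.

Detection on real imagery conventionally runs on a grid resampled to
0.865 µm/px; the resampler picks the integer shape `round(extent/target)`
and recomputes the realized pixel size from it (within 1 % of the target).
Physical quantities always use the mask's own calibration, so video and
mask grids may differ.

## Detection: masks in, detections out

The package deliberately does **not** ship a learned detector. The
production contract is instance label masks from an external model (or
manual annotation) in, tabular detections out. The bundled classical
detector exists to close the loop on synthetic imagery: it thresholds the
bright halo ring (Otsu), fills the enclosed dark interior, splits touching
cells by a watershed seeded with h-maxima of the distance transform, and
keeps components whose circularity `4πA/P² ≥ 0.8` and equivalent diameter
lies in 10–25 µm. Seeding with h-maxima (depth ≈ 15 % of the minimum cell
radius) rather than raw local maxima matters: the distance-transform ridge
of an elongated blob has no deep saddle, so the blob stays one marker and
is then rejected by circularity, while two abutting discs are separated by
a genuinely deep saddle and split correctly. Border-touching instances are
kept. This detector is tuned to the generator's appearance model and makes
no claim about real microscope data.

The viability segmenter augments Otsu with a robust noise floor
(median + 6·1.4826·MAD): on a signal-free frame Otsu merely bisects the
sensor noise, and the floor keeps such frames empty. Watershed seeds need a
minimum separation of roughly half the expected nucleus diameter (default
5 px); components under 10 px are dropped as specks.

## Synthetic data generator

The generator produces the full study artefacts — brightfield stack,
per-frame round-cell instance masks, nuclei count, per-cell event table —
with one random stream per scenario (sub-streams for events, placement and
noise are derived from the scenario seed; identical seeds give bit-identical
output). Defaults describe the control condition: 126 cells per FOV,
512×512 px at 0.55 µm/px, frames every 4 min for 8 h, event-time law
Normal(mode 50 min, sd 10 min) truncated at 0 (a Gamma option covers
skewed, high-dose-like scenarios), 30 min from round-start to division,
mothers 20 µm dividing into two 15 µm daughters displaced by one daughter
radius, a ±10 % linear illumination gradient, optional temporal drift, and
Gaussian sensor noise (sd 0.01). Photodamage surrogates: `extra_delay`
(minutes added to every event time) and `arrest_prob` (cells that round and
never divide). The sd of the event-time law and the daughter respreading
window (12 min) are fixture choices — the source assay constrains the mode,
the division duration and the cell sizes, not the dispersion.

**Anchoring.** The configured mode is defined as the peak time of the
round-cell *occupancy* (what C(t) measures), not of the round-start law.
Since a cell is detectable over a window (30 min as a round mother, then
two daughters for 12 min), the occupancy peak lags round-starts by the
kernel offset; the generator computes that offset by numerically convolving
the event-law density with the visibility kernel (weight 1 during mother
rounding, 2 during the daughter window) and shifts sampled round-starts
accordingly. With the default phase structure the offset is ≈ 30 min, which
simultaneously places the median division time at the mode — i.e. about
half the cells have produced resolvable daughters by the nominal peak, as a
well-synchronised control population does.

Cells sit on a jittered square grid with pitch at least one mother diameter
plus margin; a field too small for the requested count raises instead of
silently overlapping cells. Daughters of neighbouring cells may touch — the
watershed handles that — but mothers never overlap. What the generator does
**not** emulate: optics (PSF, partial coherence, defocus), cell migration,
intensity texture of real cytoplasm, segmentation errors of a learned
detector, and biological variance structure between FOVs. Passing the
recovery suites therefore demonstrates that the analysis is correct and
well-calibrated on data satisfying its assumptions, not that any particular
detector performs on real imagery.

## Statistics

Condition comparisons use the two-sided two-sample Kolmogorov–Smirnov test
on pooled per-event times (the asymptotic p-value; event-level pooling is
the default, per-FOV summaries being the alternative unit), with the
conventional star thresholds 0.05/0.01/0.001/0.0001 and no
multiple-testing correction by default (a Bonferroni factor is available).
Per-FOV summaries get percentile-bootstrap 95 % confidence intervals of the
mean (1000 resamples). Calibration is verified by simulation: the KS
type-I error rate at α = 0.05 lies in [3.5 %, 6.5 %] over 1000 null trials
and bootstrap coverage in [92 %, 98 %] over 500 trials.

## Problem sizes and numerical choices

Event-time recovery runs at 200 cells per FOV, three FOVs per condition, on
a 704×704 px field (the default 512 px field cannot hold 200
non-overlapping mothers); per-FOV peaks are averaged per condition, which
is also how per-FOV peaks are aggregated in reporting. Recovered peaks land
within one frame interval (±4 min) of the configured modes 50/70/90 min and
order strictly. The full-scale end-to-end check uses 2 conditions × 10 FOVs
× 120 frames at 512×512 with activity computation enabled and completes in
a few minutes on one worker. Detector fidelity is scored by greedy centroid
matching within 5 px. C(t) may exceed 1 when daughters double-count against
the frame-0 denominator; this is logged as a warning, never an error. All
doses are kept exact internally and rounded only for display.

## Known limitations

* No cross-frame tracking: event tables come from ground truth or manual
  annotation, not from linking detections.
* The classical detector is a fixture device; real brightfield data needs
  an external instance-segmentation model.
* Per-pixel dose is the scanning-mode primary number; irradiance maps of a
  non-uniform field and photochemistry are out of scope.
* Pixel grids must be square; anisotropic calibrations are rejected.
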