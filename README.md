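# phototox

Quantitative phototoxicity assessment from label-free live-cell time-lapse
microscopy.

Intense excitation light damages living samples, and the damage is often
too subtle for viability stains to catch: cells survive but divide late,
arrest, or go quiet. `phototox` measures these effects by using the cell
cycle as a clock. From brightfield time-lapses of synchronised adherent
cell populations (real recordings with external segmentation masks, or the
built-in synthetic generator), it computes:

* **C(t)**, the fraction of cells in mitotic rounding at each time point,
  and its peak time `t_p : C(t_p) = max_t C(t)` — the division wave;
  photodamage shifts it rightward;
* **cell-size dynamics** via the equivalent-circle diameter
  (`S = πR²`, `D = 2R`) with mothers (> 18 µm) vs daughters, and the
  fraction of cells completing the mother→two-daughters transition by a
  deadline;
* **cellular activity**, `activity(t) = mean((eIm(t) − eIm(t−1))²)` on
  normalised, bleach-corrected, CLAHE-enhanced, smoothed frames, with its
  cumulative sum reported at 7 h and normalised per replica;
* **viability fractions** from a nuclear dye channel (Otsu + watershed);
* **light doses** in J/cm² for widefield exposures and confocal dwell-time
  regimes (`dose = n·P·t/A`), including inverse calculations and
  percent-of-maximum reporting;
* **condition comparisons**: two-sided Kolmogorov–Smirnov tests on event
  times with significance stars, and bootstrap 95 % CIs for per-FOV means.

It is intended for microscopists calibrating illumination protocols —
finding the dose at which a given wavelength starts to delay division — and
for method developers who need a fully synthetic, ground-truthed benchmark
for rounding-detection pipelines.

## Worked example

Simulate a control FOV and one exposed to a damaging dose (20 min delay,
30 % arrests), run the full pipeline, and compare:

```python
from phototox.pipeline import run_pipeline

config = {
    "seed": 1,
    "control": "control",
    "scenario": {"n_cells": 126, "field_shape": [512, 512], "duration": 476.0},
    "conditions": [
        {"label": "control", "dose_j_cm2": 0.0, "wavelength_nm": 385, "n_fovs": 3},
        {"label": "uv_60J", "dose_j_cm2": 60.0, "wavelength_nm": 385, "n_fovs": 3,
         "scenario": {"extra_delay": 20.0, "arrest_prob": 0.3}},
    ],
}
manifest = run_pipeline(config, "results/demo")
```

`results/demo/summary.csv` then holds one row per FOV with the rounding
peak and cumulative activity, `comparisons.csv` the KS test against the
control, and `transitions.csv` the divided-by-50-min fractions:

```
condition  peak_time_min   transition_fraction   ks p_value   stars
control    ~48–52          ~0.50
uv_60J     ~68–72          ~0.02                 < 1e-40      ****
```

The control population peaks at ~50 min (about half the cells have divided
by then); the exposed population's peak shifts by the configured 20 min,
its on-time divisions all but vanish, and the distribution shift is
overwhelmingly significant.

Dose arithmetic from the command line:

```bash
$ phototox dose --power-mw 84.9 --time-s 0.1 --area-cm2 0.014
{"dose_j_cm2": 0.6064285714285714}          # the classic 100 ms ≈ 0.6 J/cm²

$ phototox dose --mode scanning --power-mw 0.3 --dwell-us 3.528 \
    --pixel-um 0.42 --max-power-mw 3.4
{"dose_j_cm2": 0.6, "percent_of_max": 8.8}  # fast-scan regime, same dose
```

Other subcommands: `simulate`, `activity`, `detect`, `quantify`,
`viability`, `compare`, `run` (see `phototox --help`).

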