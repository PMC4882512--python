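# saltatrack

Analysis of saltatory organelle transport in time-lapse fluorescence movies,
built around the peroxisome-trafficking readout used to study
microtubule-dependent transport in axon-like processes (e.g. in hereditary
spastic paraplegia patient cells, where *SPAST* mutations reduce the number
of stable microtubules and with it the fraction of fast-moving peroxisomes).

The package covers the full chain:

1. **synthetic_data** — a generative model of three-class organelle motion
   (fast saltatory run-and-pause, slow Brownian-like, immobile) along a
   quasi-1-D process, plus movie rendering (Gaussian PSF, Poisson + read
   noise) and multi-channel cell fields for fluorescence quantification.
2. **detection** — maximum-intensity projection of z-stacks and
   Laplacian-of-Gaussian spot detection with subpixel centroids.
3. **tracking** — optimal per-frame-pair assignment linking (gated LAP) and
   the completeness filter (organelles not tracked for the entire
   observation period are discarded).
4. **motion_metrics** — per-track instantaneous/mean speeds, saltatory-event
   segmentation, fast-mover classification, direction, density windows.
5. **population_stats** — speed percentiles (check-loss/midpoint quantile
   convention), quantile-regression group contrasts with bootstrap CIs,
   pooled t tests from raw values or printed summaries, Pearson chi-square,
   and a two-factor mixed repeated-measures ANOVA.
6. **cell_fluorescence** — high-content-style per-cell cytoplasmic marker
   quantification (nucleus segmentation → seeded cytoplasm partition →
   per-cell marker means).

## The model in brief

Each organelle belongs to one of three classes with population fractions
(f_fast, f_slow, f_immobile). A fast organelle alternates processive runs
(duration ~ Exp(τ_run), speed ~ N(v, σ_v) truncated > 0) with pauses
(~ Exp(τ_pause)), moving anterogradely with per-organelle probability
p_antero; a slow organelle performs Brownian-like steps with per-organelle
mobility heterogeneity; an immobile organelle shows only localisation
noise. Per-track mean speed is the arithmetic mean of frame-to-frame speeds
v_i = ‖x_{i+1} − x_i‖ / Δt; a saltatory event is a maximal run of v_i > 0.1
μm/s; a fast mover has mean speed > 0.14 μm/s (the control population's
90th percentile). Condition presets: `control` (f_fast = 0.10,
p_antero = 0.609), `patient` (0.023, 0.861), and `patient_epoD`
(microtubule-stabilising rescue: control values restored).

## Worked example

```python
from saltatrack import (ImagingParams, make_condition_preset, simulate_tracks,
                        summarize_tracks, Thresholds, percent_fast, SpeedPopulation)

imaging = ImagingParams()            # 2 s frame interval, 4 min, 121 frames
params = make_condition_preset("control")
tracks = simulate_tracks(params, imaging, n_tracks=2000, seed=0)
summaries = summarize_tracks(tracks, Thresholds())
pop = SpeedPopulation("control", summaries["mean_speed_um_s"].to_numpy())
print(round(summaries["mean_speed_um_s"].mean(), 4))
print(percent_fast(pop)["overall_percent"])
```

prints

```
0.0556
9.55
```

i.e. a population mean speed of ≈0.06 μm/s with ≈10% fast movers, the
control regime. The same pipeline driven from the shell:

```bash
saltatrack simulate --preset control --n-tracks 50 --seed 7 --render --out run/
saltatrack detect run/movie.tif --out run/detections.csv
saltatrack track run/detections.csv --out run/tracks.csv
saltatrack motion run/tracks.csv --out run/summaries.csv
```

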