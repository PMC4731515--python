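# endodance

Quantitative analysis of early- and late-endosome dynamics in growing
*Arabidopsis* root hairs from spinning-disc time-lapse microscopy — with a
ground-truthed synthetic movie generator, so every stage of the analysis is
testable without microscope data.

Root hairs grow exclusively at their tip, fed by vesicular trafficking.
Early endosomes/TGN (markers RabA1d, VTI12) are small (~200 nm), fast
(6.5–8.7 µm/s) and move mostly in long, constant-speed runs; late
endosomes/MVBs (markers RabF2a, RabF2b, 2xFYVE) are larger (~340 nm,
ring-like under super-resolution), slower (5.5–5.7 µm/s), move
stop-and-go, and interact: pairs tether and move synchronously at close
range for tens of seconds ("dancing endosomes"), or merge into brighter
clustered/fused compartments. This package implements the measurement
chain for all of those quantities, and a simulator that generates movies
with exactly those statistics plus the full per-particle ground truth.

## What it computes

* **Spot detection** — Difference-of-Gaussians (diameter 1.5 px,
  threshold 2, optional 3×3 median filter) with sub-pixel localization by
  quadratic fit, plus a noise-adaptive threshold mode.
* **Tracking** — optimal frame-pair assignment (Hungarian) on squared
  displacement with gap closing; trajectories shorter than 5 µm are
  excluded.
* **Kymograph analysis** — intensity sampled along a 1-px line versus
  time; the maximum speed is the steepest straight ridge segment
  (automating the by-eye steepest-slope reading), and a trajectory is
  *continuous* when a straight constant-speed run spans ≥ 15 µm,
  *discontinuous* otherwise.
* **Interactions** — dancing events as windows of close range (≤ 2 µm,
  < 1 µm at closest approach) and synchronized displacement (rolling
  Pearson ≥ 0.5) lasting ≥ 5 s; clustering/fusion as track merges whose
  summed fluorescence persists > 20 s; per-zone event rates (apical =
  first 10 µm below the tip) and population composition
  (individual / dancing / clustered, counted in a 30 µm tip-ROI).
* **Sizing** — FWHM of normalized intensity profiles on SIM-like frames
  (first/last half-maximum crossing, so rings report their outer extent);
  watershed equivalent diameters on diffraction-limited frames.
* **Growth rate** — least-squares slope of tip position, µm/min.
* **Simulation** — root-hair-shaped domain (tube + hemispherical tip),
  continuous / stop-and-go / dancing-pair (Ornstein–Uhlenbeck tether) /
  cluster-fusion kinetics, Gaussian-PSF rendering with Poisson shot noise
  and read noise at 0.26 µm/px and 0.1–0.7 s/frame, or SIM-mode single
  frames (~100 nm PSF) with ring-shaped late endosomes.

## Worked example

```python
from endodance import (RootHairGeometry, simulate_population, render_movie,
                       OpticsConfig, detect_stack, link_spots, filter_tracks,
                       LinkingParams)
from endodance.pipeline import per_track_kymo_metrics, _default_detection

geometry = RootHairGeometry.for_stage("growing")
truth = simulate_population(geometry, "FYVE", n_particles=10, duration=20.0,
                            seed=7)
stack = render_movie(truth, OpticsConfig(seed=8))
spots = detect_stack(stack, _default_detection({}))
params = LinkingParams(max_displacement=0.96, max_gap=1, min_path_length=5.0)
tracks = filter_tracks(link_spots(spots, params), params)
metrics = per_track_kymo_metrics(stack, tracks, geometry)
```

prints, with the summary lines shown in the snippet's full version:

```
200 frames of (47, 203), 1817 spots, 21 tracks retained
mean max speed (kymograph): 5.48 um/s over 18 dynamic tracks
movement classes: {'discontinuous': 6, 'continuous': 1}
```

The simulated GFP-2xFYVE population moves at a go-phase speed of
5.5 µm/s; the kymograph steepest-slope estimate recovers 5.48 µm/s.
Classification sees mostly discontinuous movers, as expected for a late
endosome population whose continuous fraction is 40% (only fragments
observed for ≥ 4 s are classified, hence fewer classified than tracked).

The same chain is available from the shell:

```sh
endodance simulate --preset FYVE --n 10 --duration 20 --seed 7 --out run/
endodance detect run/movie.tif --threshold-mode noise --dog-threshold 4 \
    --no-median-filter --out run/spots.csv
endodance track run/spots.csv --max-displacement 0.96 --out run/tracks.csv
endodance interact run/tracks.csv --out run/events.csv
endodance run --seed 7 --out run/full      # full pipeline + JSON report
```

## Layout

| module | contents |
| --- | --- |
| `endodance.synthetic` | geometry, motion models, ground truth, rendering |
| `endodance.presets` | per-marker speed/size/interaction presets |
| `endodance.detection` | DoG spots, watershed diameters, area fractions |
| `endodance.tracking` | linking, 5 µm filter, speed profiles, stop/go |
| `endodance.kymograph` | kymographs, steepest slopes, movement classes |
| `endodance.interactions` | dancing + clustering/fusion detection, rates |
| `endodance.sizing` | FWHM profiles, size distributions |
| `endodance.regions` | axis frames, zone masks, growth rate |
| `endodance.pipeline` | orchestration, recovery experiments, reports |
| `endodance.cli` | `endodance` command-line interface |

Methodological details and the assumptions behind the simulator are in
`docs/methods.md`.
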