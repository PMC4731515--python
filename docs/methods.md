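# Methods

This note documents the models, estimators and numerical choices behind
`endodance`, in the order data flows through the package.

## The synthetic root hair

The hair is a 2D domain: a tube of radius *r* (default 5 µm) capped by a
hemisphere at the tip, embedded in a field of view with a 1 µm margin.
Developmental stages set the defaults — bulge (2 µm shank, no growth),
growing (50 µm shank, tip advancing at 1.941 µm/min, the rate measured
for the GFP-2xFYVE line), mature (50 µm, static). Coordinates are
image-physical micrometres with the axis along +x; arc-length distance
below the tip defines the apical zone (first 10 µm), the subapical zone
(the rest of the hair) and the 30 µm tip-ROI used for population counts.
Analysis is 2D + time throughout: single-plane acquisition is emulated
directly, and maximum projection of a z-stack is the caller's
responsibility.

## Motion repertoire

Each particle rides a fixed transverse "lane" (uniform within ±0.8 *r*,
its cytoplasmic strand) with Ornstein–Uhlenbeck (OU) positional jitter
(σ = 0.05 µm, relaxation 1 s), and moves axially by one of:

* **continuous** — constant speed *v* with reflection at the hair ends.
  Speeds per marker follow the published maxima (8.7, 6.5, 5.6, 5.7 and
  5.5 µm/s for RabA1d, VTI12, RabF2a, RabF2b and 2xFYVE).
* **stop-and-go** — immobile stop phases lasting U(0.75, 2.25) s
  alternate with go phases parameterized by run *length*, drawn
  U(4, 12) µm and executed at speed *v* with a fresh random heading.
  Parameterizing by length rather than duration is deliberate: the
  continuous/discontinuous dichotomy is defined by a straight-run length
  criterion (≥ 15 µm), so a discontinuous mover must have bounded run
  length at every speed. With duration-based draws, a fast discontinuous
  mover would produce ≥ 15 µm runs and contradict its own class.
* **dancing pair** — two particles share a centre-of-pair path (slow
  bidirectional shuttling at 0.5 µm/s plus a common OU jiggle,
  σ ≈ 0.18 µm) while their separation relaxes around the equilibrium
  `d_eq` (default 0.7 µm) as an OU process with relaxation time 2 s,
  for a window drawn U(10, 35) s — the reported duration range. Before
  and after the window the partners approach from / depart to > 3 µm at
  ~2.3 µm/s. The common jiggle is essential, not decorative: the
  synchrony statistic is a displacement correlation, and a tethered pair
  *without* common-mode motion is anti-correlated (the tether noise is
  equal and opposite on the two partners). How strongly the pair
  co-moves is not quantified in published data; the default is chosen so
  the displacement correlation of a dancing pair is ≈ 0.7–0.9.
* **cluster/fusion pair** — two particles converge over 3 s and merge;
  the product's pre-noise intensity is *exactly* the member sum, and its
  diameter follows volume conservation, d = (d₁³ + d₂³)^{1/3}. Negative
  controls can be scripted: transient pairs (an unsynchronized passer-by
  pausing < 1 µm away for 5 s) and occlusion pairs (a track blinking out
  next to a continuing one whose intensity does not change).

The mixture of continuous vs stop-and-go movers is assigned exactly
(`round(f·n)` particles), so mixture-recovery experiments have a sharp
ground truth. Per-particle intensities are lognormal (σ = 0.3, median
2.3 a.u. ⇒ SNR ≈ 10 at the default photon scale); the intensity
distribution of real endosomes is not published, so this is a modelling
choice. Apparent diameters are truncated-normal draws from the published
per-marker distributions (197 ± 20.7 nm early; 336.2 ± 72 / 339.7 ± 79 nm
late), truncated below at max(150 nm, µ − 2.5 σ) because sizes far below
the optical resolution are neither generated nor measurable.

## Optics and rendering

Spinning-disc mode renders each particle as a 2D Gaussian of FWHM
max(PSF, apparent diameter) at 0.26 µm/px and 0.1 s/frame (the published
acquisition settings; intervals up to 0.7 s are supported). The PSF FWHM
default is 0.25 µm — a diffraction-limit estimate for the high-NA
objectives used, not a printed value. The peak amplitude scales as
intensity × photon_scale × (σ_PSF/σ)², so the *integrated* photon count
follows ground-truth intensity and fusion conserves summed photons.
Poisson shot noise on (background + signal), then Gaussian read noise
(defaults 10 photons/px background, 50 photons per intensity unit at
peak, 2 photons RMS read noise ⇒ SNR ≈ 10 at the default intensity).
Positions are sampled at frame times with no motion blur.

"Apparent diameter" means *the FWHM a measurement would report*, PSF
folded in. Early endosomes render as Gaussians whose FWHM equals the
apparent diameter by construction. Late endosomes in SIM mode render as
thin circular shells convolved with the SIM PSF (FWHM 0.1 µm, 40 nm/px);
the shell radius is solved numerically (from the analytic shell ⊗
Gaussian profile, exp(−(ρ−R)²/2σ²)·i0e(ρR/σ²)) so that the *outer-extent
half-maximum width* of the rendered ring equals the drawn apparent
diameter. A shell drawn literally at the apparent diameter would measure
roughly d + PSF and could not reproduce the published ring sizes. Rings
whose apparent diameter is below ~1.2× the PSF are rendered but flagged
unresolvable.

## Detection

The detector is a two-scale Difference of Gaussians with
σ₁ = diameter/(1+√2)/2.355, σ₂ = √2 σ₁ (blob-radius convention),
non-maximum suppression within one diameter, and sub-pixel refinement by
a per-axis quadratic fit clamped to ±0.5 px. Spot intensity is the
background-subtracted sum in a 7×7 px window (background = window-border
median), matching the window used for fusion intensity measurements.

Two threshold conventions exist because an absolute threshold does not
transfer across noise levels. `absolute` (the default) min-max scales
the frame to 8-bit and thresholds the response in grey levels — the
published small-particle settings, "diameter 1.5 px, threshold 2".
`noise` computes the response on the raw frame and thresholds at k×
(1.4826·MAD) of the response; the pipeline uses k = 4, which on SNR-10
movies keeps per-frame recall of the dimmest (large, late-endosome)
spots at ≈ 96% with about one spurious maximum per frame. The pipeline
also disables the 3×3 median pre-filter: at 0.26 µm/px a
diffraction-limited particle occupies essentially one pixel and a median
filter erases it; the option remains for data with broader PSFs.

Watershed sizing thresholds the frame (Otsu unless given), floods from
the spot seeds and reports equivalent-circle diameters; seeds on
background keep NaN and are counted in a QC report. Area fraction is the
fraction of zone pixels at or above threshold in the maximum-intensity
projection; empty zones report NaN with a warning.

## Tracking

Frame-to-frame linking is an optimal bipartite assignment on squared
displacement (birth/death handled by cost-matrix augmentation), gated at
1.2 × v_max × Δt **plus 0.3 µm** — three sigma of the measured
localization error. Without the noise budget, a genuine link at
late-endosome speeds fails on noise about one frame in five and tracks
shatter. Gaps up to 1 frame are bridged by linear interpolation;
interpolated spots are flagged `inferred`, carry no intensity, and are
excluded from intensity- and ridge-based analyses (they are estimates,
not measurements). Trajectories with summed path length < 5 µm are
excluded (the standard short-trajectory rule; net-displacement filtering
is available as a switch — path length matches the notion of trajectory
length, so it is the default). Speed profiles are |displacement|/Δt over
retained spots; stop/go segmentation labels runs below 0.5 µm/s lasting
≥ 0.3 s as stop phases, partitioning the track's time span exactly.

## Kymographs, maximum speed, movement classes

A kymograph samples the movie along a polyline (nearest-pixel at the
default 1 px width, averaged across the width otherwise), one column per
frame. Ridges are either traced bottom-up (per-column peaks linked
across columns) or, inside the pipeline, refined around a linked track
projected onto the line (±2 px snap + parabolic sub-pixel); the
per-track line is drawn along the axis at the track's own transverse
position, starting 10 µm below the tip (the subapical placement used for
kymograph lines).

**Maximum speed** automates the by-eye steepest-slope reading, with an
acknowledged ±10% methodological tolerance. Sliding windows (0.7 s) are
fit with straight lines; a window is rejected if the RMS residual
exceeds 1 px or any single point deviates more than 1.5 px (which
rejects identity handoffs where a crossing neighbour captures the
refinement). Because the maximum over many overlapping noisy windows is
biased upward by the noise extreme, each window reports the lower
confidence bound |slope| − 1.5·SE; the maximum of those is nearly
unbiased for both long continuous runs and brief go-phases. If no
window shows movement above 0.5 µm/s, the ridge is re-scanned at 0.5 s
windows — short track fragments can contain go-phases briefer than the
primary window that would otherwise read as immobile. Speed-recovery
statistics include only *dynamic* tracks (kymograph maximum ≥ 1 µm/s),
mirroring the practice of measuring maximum speeds on highly dynamic
endosomes visible in the kymograph; an immobile fragment carries no
steepest-slope information.

**Movement class**: maximal piecewise-linear ridge segments are grown
greedily under a 1 px RMS tolerance, skipping isolated outlier points
(up to 2 consecutive, ≤ 15% of the run) so a single localization glitch
does not cut a genuine 20 µm run in half. A trajectory is *continuous*
if some straight run spans ≥ 15 µm (the permissive end of the published
15–20 µm range, configurable), else *discontinuous*. Classification
requires ≥ 40 ridge points (4 s at 0.1 s/frame): a shorter fragment
cannot possibly display a 15 µm run, so classifying it would measure
track fragmentation, not motility. Population fractions weight each
classified fragment by its duration so a particle split into several
fragments counts once.

## Interactions

**Dancing**: for every overlapping track pair, per-interval displacement
vectors are correlated in a centred rolling window (1.5 s, x and y
pooled); frames qualify when pair distance ≤ 2 µm *and* correlation
≥ 0.5. Dips shorter than 3 s (≈ twice the estimation window — the scale
over which the rolling estimate can drop on noise alone) are bridged
while the distance envelope holds. Maximal qualifying runs ≥ 5 s become
events — the 5 s minimum sits deliberately below the reported 10–35 s
range, so that range is a measured output rather than an imposed prior.
Two further requirements come from the phenomenon's definition: the pair
must actually approach within 1 µm at some point (events never closer
than that are parallel travel), and the window must be observed to begin
and end (distance beyond 2 µm on both sides) — two same-speed particles
travelling in parallel look perfectly synchronized to a pooled
displacement correlation but are not an interaction. A consequence:
dancing windows truncated by the start or end of the observation are not
reported.

**Clustering/fusion**: merge topology (two members ending within 1 µm of
a product track appearing at the next frames, or one member ending next
to a continuing track) plus an intensity budget — the post-merge
intensity must stay within ±30% of the summed pre-merge member
intensities for ≥ 20 s (≥ 90% of samples in the window). The reported
intensity ratio normalizes the product to the dimmer member, mirroring
normalization to one individual endosome. A candidate dancing window
whose intensity already sits at the member sum for ≥ 20 s is routed to
fusion (one object seen twice); fusion takes precedence over dancing in
population labels. Each member track is consumed by at most one fusion
event. Zone assignment uses the mean member position at event onset.

## Sizing

Profiles are sampled at pixel/4 steps by cubic-spline interpolation
(bilinear sampling broadens a σ = 2 px Gaussian by ~2%, which matters at
a 3% accuracy budget), background-subtracted (median of the three
outermost samples per side), normalized to a locally-fit quadratic peak
(robust to per-sample noise), and measured between the first and last
half-maximum crossings — so a two-peaked ring yields its outer extent,
with the peak-to-peak distance recorded as an auxiliary metric. The
default profile is horizontal through the given centre; orientation is a
parameter, and isotropy can be checked by comparing axes. Flat or
saturated profiles and profiles whose crossings leave the sampled
segment are rejected with diagnostics.

## Problem sizes and reproducibility

Recovery experiments use populations spread over several movies (speed:
4 movies × 5 particles; motility: 10 × 5) to stay in the ~0.01
spots/µm² regime where linking is reliable; sizing uses single SIM
frames of 76 (early) and 62 (late) particles; interaction experiments
script 50 dancing and 20 fusion events with distractors and negative
controls over 60 s movies. At these sizes the full acceptance
computation takes well under a minute on one CPU. Every random draw
flows through `numpy.random.default_rng` seeded from the experiment
seed; identical seeds give bit-identical ground truth, movies and
reports.

## What passing tests do and do not show

The generator emulates the motion, interaction and optical statistics
that the analysis assumes — not everything real movies contain. It has
no photobleaching, no motion blur, no cytoplasmic-streaming flow field,
no cytoskeleton, no z-dimension, no heterotypic (early↔late)
interactions, and its background is spatially flat. Recovery results
therefore validate the estimators under the stated noise and motion
models; on real data the same estimators additionally face focus drift,
background structure and out-of-plane loss, and detection/linking
parameters (threshold mode, gates) are exposed for exactly that reason.
Identity swaps during close particle crossings are fundamentally
ambiguous to any motion-model-free linker, ours included; the kymograph
estimators are built to be robust to the resulting track defects rather
than to pretend they do not happen.
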