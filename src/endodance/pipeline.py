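"""End-to-end orchestration: simulate -> render -> detect -> track ->
kymograph -> interactions -> sizing -> zones, plus the parameter-recovery
experiments that validate the whole chain against the generator's ground
truth.

Everything here is deterministic given the configured seed; all randomness
flows through ``numpy.random.default_rng`` seeded from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import DetectionParams, area_fraction, detect_stack, \
    measure_diameter_watershed
from .interactions import InteractionParams, classify_population, \
    detect_cluster_fusion, detect_dancing, event_rates, events_to_frame
from .io import ImageStack, write_stack
from .kymograph import CONTINUOUS_MIN_LENGTH_UM, build_kymograph, \
    classify_movement, max_speed_from_kymograph
from .presets import get_preset
from .regions import growth_rate, make_zone_mask
from .synthetic import MotionModel, OpticsConfig, RootHairGeometry, \
    draw_apparent_diameters, render_movie, render_sim_frame, simulate_population
from .tracking import LinkingParams, filter_tracks, iter_tracks, link_spots, \
    track_summary

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_CONFIG_KEYS = None  # filled after the dataclass definition


@dataclass
class PipelineConfig:
    """One configured, reproducible analysis run.

    Sub-parameter dictionaries are keyword overrides for the corresponding
    parameter dataclasses; every default traces to the acquisition
    settings, the published analysis rules, or a documented design choice.
    """

    preset: str = "FYVE"
    stage: str = "growing"
    n_particles: int = 20
    duration: float = 20.0          # s
    frame_interval: float = 0.1     # s
    seed: int = 0
    motion_kind: str | None = None  # force all single movers to one kind
    n_dancing_pairs: int | None = None
    n_fusion_pairs: int | None = None
    optics: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    linking: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    tip_offset_um: float = 10.0     # kymograph lines start this far below tip
    continuous_min_length: float = CONTINUOUS_MIN_LENGTH_UM
    out_dir: str | None = None
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema {self.schema_version}")
        get_preset(self.preset)  # validates the name
        if self.duration <= 0 or self.frame_interval <= 0:
            raise ValueError("duration and frame_interval must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_CONFIG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


#: localization error of a diffraction-limited spot at SNR ~10, um; the
#: linking gate budgets 3 sigma of it on top of the expected go-phase step,
#: otherwise genuine links fail on noise a fifth of the time
LOCALIZATION_SIGMA_UM = 0.1


def _default_linking(preset, frame_interval: float, overrides: dict) -> LinkingParams:
    """Pipeline linking gate: 1.2 x expected go-phase step + noise budget."""
    kw = dict(max_displacement=1.2 * preset.v_max * frame_interval
              + 3.0 * LOCALIZATION_SIGMA_UM,
              max_gap=1, min_path_length=5.0)
    kw.update(overrides)
    return LinkingParams(**kw)


#: Detector operating point for diffraction-limited movies: noise-adaptive
#: threshold (4 x robust response sigma keeps per-frame recall of the dim,
#: large late-endosome spots at ~96% so tracks do not fragment, at about
#: one spurious maximum per frame) and no median pre-filter, because a PSF
#: sampled at ~1 px would not survive a 3x3 median.
PIPELINE_DETECTION_DEFAULTS = dict(threshold_mode="noise", dog_threshold=4.0,
                                   use_median_filter=False)


def _default_detection(overrides: dict) -> DetectionParams:
    kw = dict(PIPELINE_DETECTION_DEFAULTS)
    kw.update(overrides)
    return DetectionParams(**kw)


# ---------------------------------------------------------------------------
# per-track kymograph metrics
# ---------------------------------------------------------------------------


def per_track_kymo_metrics(
    stack: ImageStack,
    tracks: pd.DataFrame,
    geometry: RootHairGeometry,
    tip_offset_um: float = 10.0,
    continuous_min_length: float = CONTINUOUS_MIN_LENGTH_UM,
    classify: bool = True,
    min_points: int = 8,
    classify_min_points: int = 40,
) -> pd.DataFrame:
    """Kymograph speed and movement class for every track.

    For each track a 1-px kymograph line is drawn along the hair axis
    direction at the track's own transverse position (its cytoplasmic
    strand), starting ``tip_offset_um`` below the tip; the track's own
    positions guide the ridge refinement. Tracks with too few points on
    the line report NaN. Movement classification additionally requires
    ``classify_min_points`` ridge points (default 4 s at 0.1 s/frame):
    a shorter fragment cannot possibly display a 15 um straight run, so
    calling it discontinuous would be an artifact of track fragmentation,
    not a property of the endosome.
    """
    x_start = geometry.tip_x(0.0) - tip_offset_um
    x_end = geometry.base_x + 0.2
    h = stack.frame_shape[0]
    y_max = (h - 1) * stack.pixel_size
    recs = []
    for tr in iter_tracks(tracks):
        lane = float(np.clip(np.median(tr.y), 0.0, y_max))
        line = [(x_start, lane), (x_end, lane)]
        kym = build_kymograph(stack, line, width=1)
        dist = x_start - tr.x
        # inferred (gap-interpolated) spots are synthetic positions, not
        # measurements; they must not guide the ridge
        sel = (dist >= 0) & (dist <= kym.distances[-1]) & ~tr.inferred
        rec = {"track_id": tr.track_id, "max_speed_kymo": np.nan,
               "movement_class": None, "qualifying_run_um": np.nan}
        if sel.sum() >= min_points:
            guide = pd.DataFrame({"frame": tr.frames[sel], "distance": dist[sel]})
            rec["max_speed_kymo"] = max_speed_from_kymograph(kym, guide=guide)
            if classify and sel.sum() >= classify_min_points:
                mc = classify_movement(kym, continuous_min_length, guide=guide)
                rec["movement_class"] = mc.label
                rec["qualifying_run_um"] = mc.qualifying_run_length
        recs.append(rec)
    return pd.DataFrame(recs,
                        columns=["track_id", "max_speed_kymo",
                                 "movement_class", "qualifying_run_um"])


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain on a simulated movie and return the report.

    All intermediates (movie, ground truth, spots, tracks, events, report)
    are persisted to ``config.out_dir`` when set. Reports are
    reproducible: identical config and seed give identical numbers.
    """
    preset = get_preset(config.preset)
    geometry = RootHairGeometry.for_stage(config.stage)
    motion = (MotionModel(kind=config.motion_kind, v=preset.v_max)
              if config.motion_kind else None)
    truth = simulate_population(
        geometry, preset, config.n_particles, config.duration,
        motion_overrides=motion, seed=config.seed,
        frame_interval=config.frame_interval,
        n_dancing_pairs=config.n_dancing_pairs,
        n_fusion_pairs=config.n_fusion_pairs)
    optics = OpticsConfig(frame_interval=config.frame_interval,
                          seed=config.seed + 1, **config.optics)
    stack = render_movie(truth, optics)
    logger.info("rendered %d frames of %s", stack.n_frames, stack.frame_shape)

    det_params = _default_detection(config.detection)
    spots = detect_stack(stack, det_params)
    logger.info("detected %d spots", len(spots))

    link_params = _default_linking(preset, config.frame_interval, config.linking)
    tracks_all = link_spots(spots, link_params)
    tracks = filter_tracks(tracks_all, link_params)
    n_removed = tracks_all["track_id"].nunique() - tracks["track_id"].nunique() \
        if len(tracks_all) else 0
    logger.info("linked %d tracks (%d removed by the %.0f um filter)",
                tracks["track_id"].nunique() if len(tracks) else 0,
                n_removed, link_params.min_path_length)

    axis = geometry.axis_frame(0.0)
    hair = geometry.hair_mask(stack.frame_shape, stack.pixel_size)
    mask = make_zone_mask(stack.frame_shape, axis, hair, stack.pixel_size)

    summary = track_summary(tracks) if len(tracks) else pd.DataFrame()
    kymo = (per_track_kymo_metrics(stack, tracks, geometry,
                                   config.tip_offset_um,
                                   config.continuous_min_length)
            if len(tracks) else pd.DataFrame())

    int_params = InteractionParams(**config.interaction)
    dancing = detect_dancing(tracks, int_params, mask) if len(tracks) else []
    fusions = detect_cluster_fusion(tracks, int_params, mask) if len(tracks) else []
    events = dancing + fusions
    population = classify_population(tracks, events, mask) if len(tracks) else \
        {"individual": 0, "dancing": 0, "clustered": 0,
         "population_first_frame": 0, "labels": {}}
    rates = event_rates(events, mask, config.duration)

    proj = stack.max_project()
    from skimage.filters import threshold_otsu
    af_thr = det_params.af_threshold or float(threshold_otsu(proj))
    fractions = area_fraction(stack, mask, af_thr)

    first = spots[spots["frame"] == 0] if len(spots) else spots
    sized, ws_report = measure_diameter_watershed(
        stack.frame(0), first, stack.pixel_size)

    classed = kymo.dropna(subset=["max_speed_kymo"]) if len(kymo) else kymo
    report = {
        "provenance": {
            "software": f"endodance {__version__}",
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "counts": {
            "particles_simulated": int(truth.particles["particle_id"].nunique())
            if len(truth.particles) else 0,
            "spots_detected": int(len(spots)),
            "tracks_linked": int(tracks_all["track_id"].nunique())
            if len(tracks_all) else 0,
            "tracks_retained": int(tracks["track_id"].nunique())
            if len(tracks) else 0,
            "tracks_removed_short": int(n_removed),
        },
        "speeds": {
            "mean_max_speed_kymo": float(classed["max_speed_kymo"].mean())
            if len(classed) else float("nan"),
            "mean_max_speed_track": float(summary["max_speed"].mean())
            if len(summary) else float("nan"),
            "mean_speed_track": float(summary["mean_speed"].mean())
            if len(summary) else float("nan"),
        },
        "movement": _movement_fraction(kymo),
        "population": {k: v for k, v in population.items() if k != "labels"},
        "event_rates_per_s": rates,
        "area_fraction": fractions,
        "sizing": {
            "watershed_mean_diameter_um":
                float(sized["diameter_um"].mean()) if len(sized) else float("nan"),
            "watershed_unset": ws_report["n_unset"],
        },
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_stack(out / "movie.tif", stack)
        truth.save(out / "truth_particles.csv", out / "truth_events.csv")
        spots.to_csv(out / "spots.csv", index=False)
        tracks.to_csv(out / "tracks.csv", index=False)
        events_to_frame(events).to_csv(out / "events.csv", index=False)
        if len(kymo):
            kymo.to_csv(out / "track_kymo_metrics.csv", index=False)
        config.to_yaml(out / "config.yaml")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _movement_fraction(kymo: pd.DataFrame) -> dict:
    if len(kymo) == 0:
        return {"n_classified": 0, "percent_continuous": float("nan")}
    classed = kymo.dropna(subset=["qualifying_run_um"])
    classed = classed[classed["movement_class"].notna()]
    n = len(classed)
    if n == 0:
        return {"n_classified": 0, "percent_continuous": float("nan")}
    frac = (classed["movement_class"] == "continuous").mean()
    return {"n_classified": int(n), "percent_continuous": float(100.0 * frac)}


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------


def speed_recovery_experiment(
    preset_name: str,
    n_tracks: int = 20,
    n_frames: int = 200,
    frame_interval: float = 0.1,
    seed: int = 0,
    kind: str | None = None,
    n_movies: int = 4,
    min_dynamic_speed: float = 1.0,
) -> dict:
    """Recover the preset go-phase speed through the full imaging chain.

    Simulates ``n_tracks`` particles (continuous motion for early-endosome
    presets, stop-and-go for late ones unless ``kind`` overrides) spread
    over ``n_movies`` movies to stay in the density regime where linking
    is reliable, renders with default spinning-disc optics, detects, links,
    filters, and reads each track's maximum speed off its guided kymograph
    ridge. Following the measurement protocol for maximum speeds, only
    dynamic tracks enter the statistic: fragments whose kymograph shows no
    movement faster than ``min_dynamic_speed`` carry no steepest-slope
    information and are excluded. Reports the mean per-track maximum speed.
    """
    preset = get_preset(preset_name)
    if kind is None:
        kind = "continuous" if preset.endosome_class == "early" else "stop_and_go"
    geometry = RootHairGeometry.for_stage("growing")
    duration = n_frames * frame_interval
    rng = np.random.default_rng(seed)
    movie_seeds = rng.integers(0, 2**31 - 1, size=n_movies)
    per_movie = max(1, n_tracks // n_movies)
    speeds: list[float] = []
    for ms in movie_seeds:
        truth = simulate_population(
            geometry, preset, per_movie, duration,
            motion_overrides=MotionModel(kind=kind, v=preset.v_max),
            seed=int(ms), frame_interval=frame_interval,
            n_dancing_pairs=0, n_fusion_pairs=0)
        stack = render_movie(truth, OpticsConfig(
            frame_interval=frame_interval, seed=int(ms) % (2**31 - 2) + 1))
        spots = detect_stack(stack, _default_detection({}))
        params = _default_linking(preset, frame_interval, {})
        tracks = filter_tracks(link_spots(spots, params), params)
        kymo = per_track_kymo_metrics(stack, tracks, geometry, classify=False)
        speeds += kymo["max_speed_kymo"].dropna().tolist()
    dynamic = np.asarray([s for s in speeds if s >= min_dynamic_speed])
    return {
        "true_speed": preset.v_max,
        "mean_max_speed": float(dynamic.mean()) if len(dynamic) else float("nan"),
        "per_track": dynamic.tolist(),
        "n_tracks": int(len(dynamic)),
    }


def motility_fraction_experiment(
    preset_name: str,
    n_tracks: int = 50,
    n_frames: int = 200,
    frame_interval: float = 0.1,
    seed: int = 0,
    n_movies: int = 10,
) -> dict:
    """Recover the continuous-movement fraction of a preset's mixture.

    The population is spread over several movies to keep the spot density
    in the regime where linking is reliable (~0.01 spots/um^2). Tracks are
    classified from guided kymograph ridges with the 15 um straight-run
    rule; reports the percentage classified continuous.
    """
    preset = get_preset(preset_name)
    geometry = RootHairGeometry.for_stage("growing")
    duration = n_frames * frame_interval
    rng = np.random.default_rng(seed)
    movie_seeds = rng.integers(0, 2**31 - 1, size=n_movies)
    per_movie = int(np.ceil(n_tracks / n_movies))
    # allocate the exact mixture over the whole population, then deal the
    # kinds out movie by movie (a per-movie rounding would distort small
    # populations)
    total = per_movie * n_movies
    pool = ["continuous"] * int(round(preset.continuous_fraction * total))
    pool += ["stop_and_go"] * (total - len(pool))
    rng.shuffle(pool)
    n_cont = n_disc = 0.0
    n_frag = 0
    for m, ms in enumerate(movie_seeds):
        kinds = pool[m * per_movie:(m + 1) * per_movie]
        truth = simulate_population(
            geometry, preset, per_movie, duration, seed=int(ms),
            frame_interval=frame_interval, n_dancing_pairs=0, n_fusion_pairs=0,
            n_continuous=sum(k == "continuous" for k in kinds))
        stack = render_movie(truth, OpticsConfig(frame_interval=frame_interval,
                                                 seed=int(ms) % (2**31 - 2) + 1))
        spots = detect_stack(stack, _default_detection({}))
        params = _default_linking(preset, frame_interval, {})
        tracks = filter_tracks(link_spots(spots, params), params)
        kymo = per_track_kymo_metrics(stack, tracks, geometry)
        classed = kymo[kymo["movement_class"].notna()]
        # weight each classified fragment by its observed duration so that
        # a particle split into several fragments still counts once
        durations = tracks.groupby("track_id").size()
        for _, row in classed.iterrows():
            w = float(durations.get(row["track_id"], 0))
            if row["movement_class"] == "continuous":
                n_cont += w
            else:
                n_disc += w
        n_frag += len(classed)
    total = n_cont + n_disc
    return {
        "true_percent": 100.0 * preset.continuous_fraction,
        "percent_continuous": 100.0 * n_cont / total if total else float("nan"),
        "n_classified": n_frag,
    }


def size_recovery_experiment(
    preset_name: str,
    n: int | None = None,
    seed: int = 0,
) -> dict:
    """Round-trip apparent sizes through SIM-mode rendering and FWHM
    measurement.

    Renders ``n`` particles (sizes drawn from the preset's distribution)
    on a grid in a single SIM frame and measures each with a horizontal
    profile through its known centre. Late-endosome rings are measured
    with the first/last half-maximum (outer extent) convention.
    """
    from .sizing import fwhm_profile

    preset = get_preset(preset_name)
    if n is None:
        n = 76 if preset.endosome_class == "early" else 62
    rng = np.random.default_rng(seed)
    diameters = draw_apparent_diameters(preset, n, rng)
    side = int(np.ceil(np.sqrt(n)))
    spacing = 1.8
    particles = []
    for i in range(n):
        r, c = divmod(i, side)
        particles.append((1.2 + c * spacing, 1.2 + r * spacing,
                          float(diameters[i]), preset.endosome_class))
    optics = OpticsConfig.sim_defaults(seed=seed + 1)
    frame = render_sim_frame(
        particles, optics,
        fov_um=(1.2 + side * spacing, 1.2 + side * spacing))
    measured, n_peaks = [], []
    for i, (x, y, d, _) in enumerate(particles):
        rec = fwhm_profile(frame, (x, y), length_um=max(1.5, 2.5 * d / 1000.0),
                           particle_ref=i)
        measured.append(rec.fwhm_nm)
        n_peaks.append(rec.n_peaks)
    measured = np.asarray(measured)
    return {
        "true_mean": float(np.mean(diameters)),
        "preset_mean": preset.apparent_diameter_mean,
        "measured_mean": float(measured.mean()),
        "measured_sd": float(measured.std(ddof=1)),
        "n": n,
        "fraction_two_peaked": float(np.mean(np.asarray(n_peaks) >= 2)),
        "measured": measured.tolist(),
    }


def growth_rate_experiment(
    rate_um_min: float | None = None,
    n_points: int = 21,
    interval_s: float = 60.0,
    noise_um: float = 0.2,
    seed: int = 0,
) -> dict:
    """Recover the tip elongation rate from noisy tip positions.

    A growing hair advances at the preset line's rate; the tip is localized
    every minute for 20 minutes with Gaussian error, then fit by
    :func:`growth_rate`.
    """
    if rate_um_min is None:
        rate_um_min = get_preset("FYVE").growth_rate
    geometry = RootHairGeometry.for_stage("growing", growth_rate=rate_um_min)
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * interval_s
    tip = np.array([geometry.tip_x(tt) for tt in t])
    tip_noisy = tip + rng.normal(0.0, noise_um, size=n_points)
    return {
        "true_rate": rate_um_min,
        "measured_rate": growth_rate(t, tip_noisy),
        "n_points": n_points,
    }


def dancing_recovery_experiment(
    n_events: int = 50,
    pairs_per_movie: int = 5,
    distractors_per_movie: int = 10,
    duration: float = 60.0,
    seed: int = 0,
    preset_name: str = "FYVE",
) -> dict:
    """Detect scripted dancing events among distractor tracks.

    Events are detected on the ground-truth trajectories (the detector's
    input contract is tracks, however obtained). A detected event matches a
    scripted one when member identities agree and the windows overlap;
    reports recall, precision and the recovered durations.
    """
    preset = get_preset(preset_name)
    geometry = RootHairGeometry.for_stage("growing")
    rng = np.random.default_rng(seed)
    n_movies = int(np.ceil(n_events / pairs_per_movie))
    movie_seeds = rng.integers(0, 2**31 - 1, size=n_movies)
    tp = 0
    fp = 0
    n_scripted = 0
    durations, scripted_durations, duration_errors = [], [], []
    for ms in movie_seeds:
        n_part = 2 * pairs_per_movie + distractors_per_movie
        truth = simulate_population(
            geometry, preset, n_part, duration, seed=int(ms),
            n_dancing_pairs=pairs_per_movie, n_fusion_pairs=0)
        tracks = truth.as_tracks()
        detected = detect_dancing(tracks)
        scripted = truth.events[truth.events["type"] == "dancing"]
        n_scripted += len(scripted)
        matched_scripted = set()
        n_true_det = 0
        for ev in detected:
            members = set(ev.member_track_ids)
            hit = None
            for _, se in scripted.iterrows():
                sm = set(int(v) for v in se["member_ids"].split(";"))
                if sm == members and ev.t_start < se["t_end"] \
                        and ev.t_end > se["t_start"]:
                    hit = se
                    break
            if hit is not None and ev.type == "dancing":
                n_true_det += 1
                if hit["event_id"] not in matched_scripted:
                    matched_scripted.add(hit["event_id"])
                    durations.append(ev.t_end - ev.t_start)
                    duration_errors.append(
                        abs((ev.t_end - ev.t_start)
                            - (hit["t_end"] - hit["t_start"])))
            else:
                fp += 1
        tp += len(matched_scripted)
        fp += n_true_det - len(matched_scripted)  # split detections
        scripted_durations.extend(
            (scripted["t_end"] - scripted["t_start"]).tolist())
    return {
        "n_scripted": n_scripted,
        "recall": tp / n_scripted if n_scripted else float("nan"),
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
        "durations": durations,
        "scripted_durations": scripted_durations,
        "duration_errors": duration_errors,
    }


def fusion_recovery_experiment(
    n_events: int = 20,
    pairs_per_movie: int = 4,
    transient_per_movie: int = 2,
    occlusion_per_movie: int = 2,
    distractors_per_movie: int = 6,
    duration: float = 60.0,
    seed: int = 0,
    preset_name: str = "FYVE",
) -> dict:
    """Detect scripted fusions; transient co-localizations must not count.

    Each movie carries scripted fusion pairs (sustained summed intensity),
    5-s transient co-localization pairs and occlusion pairs (merge-like
    topology without intensity conservation) as negative controls.
    """
    preset = get_preset(preset_name)
    geometry = RootHairGeometry.for_stage("growing")
    rng = np.random.default_rng(seed)
    n_movies = int(np.ceil(n_events / pairs_per_movie))
    movie_seeds = rng.integers(0, 2**31 - 1, size=n_movies)
    tp = fp = n_scripted = 0
    ratios = []
    for ms in movie_seeds:
        n_part = 2 * (pairs_per_movie + transient_per_movie
                      + occlusion_per_movie) + distractors_per_movie
        truth = simulate_population(
            geometry, preset, n_part, duration, seed=int(ms),
            n_dancing_pairs=0, n_fusion_pairs=pairs_per_movie,
            n_transient_pairs=transient_per_movie,
            n_occlusion_pairs=occlusion_per_movie)
        tracks = truth.as_tracks()
        detected = detect_cluster_fusion(tracks)
        scripted = truth.events[truth.events["type"] == "cluster_fusion"]
        n_scripted += len(scripted)
        for ev in detected:
            members = set(ev.member_track_ids)
            hit = any(
                set(int(v) for v in se["member_ids"].split(";")) == members
                for _, se in scripted.iterrows())
            if hit:
                tp += 1
                ratios.append(ev.intensity_ratio)
            else:
                fp += 1
    return {
        "n_scripted": n_scripted,
        "recall": tp / n_scripted if n_scripted else float("nan"),
        "false_positives": fp,
        "intensity_ratios": ratios,
    }


def recovery_experiment(
    preset_name: str,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeat simulate+analyze and tabulate recovery of the key quantities.

    Returns rows of (quantity, true_value, recovered_mean, recovered_sd);
    sd is NaN for a single replicate. Problem sizes are kept moderate so a
    full table runs in minutes on one CPU.
    """
    preset = get_preset(preset_name)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    per_quantity: dict[str, tuple[float, list]] = {
        "max_speed_um_s": (preset.v_max, []),
        "percent_continuous": (100 * preset.continuous_fraction, []),
        "mean_size_nm": (preset.apparent_diameter_mean, []),
    }
    for s in seeds:
        sp = speed_recovery_experiment(preset_name, n_tracks=10,
                                       n_frames=150, seed=int(s))
        per_quantity["max_speed_um_s"][1].append(sp["mean_max_speed"])
        mo = motility_fraction_experiment(preset_name, n_tracks=20,
                                          n_frames=150, n_movies=2,
                                          seed=int(s) // 2)
        per_quantity["percent_continuous"][1].append(mo["percent_continuous"])
        sz = size_recovery_experiment(preset_name, n=20, seed=int(s) // 3)
        per_quantity["mean_size_nm"][1].append(sz["measured_mean"])
    if preset.endosome_class == "late":
        lo, hi = 10.0, 35.0
        da = dancing_recovery_experiment(n_events=3 * n_replicates,
                                         pairs_per_movie=3,
                                         distractors_per_movie=4,
                                         seed=seed)
        per_quantity["dancing_duration_s"] = ((lo + hi) / 2.0, da["durations"])
    rows = []
    for qty, (true_val, vals) in per_quantity.items():
        vals = np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
        rows.append({
            "quantity": qty,
            "true_value": true_val,
            "recovered_mean": float(vals.mean()) if vals.size else float("nan"),
            "recovered_sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            "n": int(vals.size),
        })
    return pd.DataFrame(rows)
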