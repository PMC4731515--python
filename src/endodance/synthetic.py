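"""Ground-truthed synthetic root-hair endosome movies.

The generator emulates what a spinning-disc time-lapse of fluorescently
labelled endosomes in an Arabidopsis root hair looks like, with the full
per-particle ground truth retained, so every downstream analysis stage can
be validated without microscope data.

Motion repertoire
-----------------
* ``continuous`` — constant-speed bidirectional shuttling along the hair
  axis (reflecting at the ends), the signature of early endosomes;
* ``stop_and_go`` — alternating immobile (stop) and constant-speed (go)
  phases, the signature of late endosomes;
* ``dancing_pair`` — two particles tethered for tens of seconds: their pair
  separation relaxes around an equilibrium ``d_eq`` as an
  Ornstein-Uhlenbeck process while the pair's centre jiggles and drifts
  together, producing the synchronized close-range motion of
  dancing-endosomes;
* ``cluster_fusion`` — two particles converge and merge into a product
  whose pre-noise intensity is exactly the sum of the members and whose
  diameter follows volume conservation, ``d = (d1^3 + d2^3)^(1/3)``.

Optics
------
Spinning-disc movies render each particle as a 2D Gaussian whose FWHM is
the larger of the PSF and the particle's apparent diameter, with Poisson
shot noise and Gaussian read noise. SIM-mode single frames render early
endosomes as Gaussian spots and late endosomes as ring-like shells; in both
modalities the *measured* FWHM of a rendered particle equals its apparent
diameter by construction (the PSF is folded into the apparent size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0e
from scipy.stats import truncnorm

from .io import ImageStack
from .presets import MarkerPreset, get_preset
from .regions import AxisFrame

__all__ = [
    "RootHairGeometry",
    "MotionModel",
    "OpticsConfig",
    "SimulationGroundTruth",
    "simulate_population",
    "render_movie",
    "render_sim_frame",
    "draw_apparent_diameters",
]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

_STAGE_DEFAULTS = {
    # shank length (um), radius (um), growth rate (um/min)
    "bulge": (2.0, 4.0, 0.0),
    "growing": (50.0, 5.0, 1.941),
    "mature": (50.0, 5.0, 0.0),
}


@dataclass
class RootHairGeometry:
    """Root-hair shape: a tube with a hemispherical tip cap.

    Coordinates are image-physical micrometres: the hair base sits at
    ``x = margin`` and the axis runs along +x at ``y = margin + radius``.
    For ``stage="growing"`` the tip advances at ``growth_rate`` um/min.
    """

    stage: str = "growing"
    shank_length: float = 50.0
    radius: float = 5.0
    growth_rate: float = 0.0
    margin: float = 1.0

    def __post_init__(self) -> None:
        if self.stage not in _STAGE_DEFAULTS:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.radius <= 0 or self.shank_length < 0 or self.growth_rate < 0:
            raise ValueError("invalid geometry: radius > 0, lengths/rates >= 0")
        if self.stage != "growing" and self.growth_rate > 0:
            raise ValueError(f"stage {self.stage!r} does not grow")

    @classmethod
    def for_stage(cls, stage: str, **overrides) -> "RootHairGeometry":
        shank, radius, rate = _STAGE_DEFAULTS[stage]
        kw = dict(stage=stage, shank_length=shank, radius=radius, growth_rate=rate)
        kw.update(overrides)
        return cls(**kw)

    # -- coordinate helpers -------------------------------------------------
    @property
    def base_x(self) -> float:
        return self.margin

    @property
    def axis_y(self) -> float:
        return self.margin + self.radius

    def tip_x(self, t: float = 0.0, duration_hint: float = 0.0) -> float:
        del duration_hint
        return self.base_x + self.shank_length + self.growth_rate / 60.0 * t

    def fov_um(self, duration: float = 0.0) -> tuple[float, float]:
        """(width, height) of the rendered field of view in micrometres."""
        width = self.tip_x(duration) + self.margin
        height = 2.0 * (self.radius + self.margin)
        return width, height

    def axis_frame(self, t: float = 0.0) -> AxisFrame:
        """Hair axis polyline, tip first (so arc length = distance below tip)."""
        return AxisFrame([[self.tip_x(t), self.axis_y],
                          [self.base_x, self.axis_y]])

    def axial_extent(self, lane_offset: float, t: float = 0.0,
                     margin: float = 0.5) -> tuple[float, float]:
        """Admissible axial range for a particle riding at a fixed transverse
        lane offset, keeping it inside the hemispherical tip cap."""
        tip = self.tip_x(t)
        cap_centre = tip - self.radius
        half = math.sqrt(max(self.radius**2 - lane_offset**2, 0.0))
        x_max = cap_centre + half - margin
        x_min = self.base_x + margin
        if x_max <= x_min:  # very short hairs (bulge): fall back to mid point
            x_max = x_min + 1e-3
        return x_min, x_max

    def contains(self, x, y, t: float = 0.0) -> np.ndarray:
        """Boolean mask: are physical points (x, y) inside the hair?"""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        tip = self.tip_x(t)
        cap_centre = tip - self.radius
        dy = y - self.axis_y
        in_tube = (x >= self.base_x) & (x <= cap_centre) & (np.abs(dy) <= self.radius)
        in_cap = ((x - cap_centre) ** 2 + dy**2 <= self.radius**2) & (x > cap_centre)
        return in_tube | in_cap

    def hair_mask(self, frame_shape: tuple[int, int], pixel_size: float,
                  t: float = 0.0) -> np.ndarray:
        h, w = frame_shape
        cols, rows = np.meshgrid(np.arange(w), np.arange(h))
        return self.contains(cols * pixel_size, rows * pixel_size, t)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass
class MotionModel:
    """Kinetic parameters of one motion kind.

    Stop phases of stop-and-go motion last U(0.5 tau_stop, 1.5 tau_stop)
    seconds; go phases are parameterized by run *length*, drawn uniformly
    from ``go_run_um``, so that a discontinuous mover never produces the
    long straight excursions that define the continuous class at any
    speed (length, not duration, is what the classification criterion
    measures).
    """

    kind: str = "stop_and_go"      # continuous | stop_and_go | dancing_pair | cluster_fusion
    v: float = 5.5                 # go-phase / constant speed, um/s
    tau_go: float = 1.5            # mean go-phase duration, s (secondary paths)
    tau_stop: float = 1.5          # mean stop-phase duration, s
    go_run_um: tuple = (4.0, 12.0)  # go-run length range of discontinuous movers
    jitter_sigma: float = 0.05     # stationary sd of positional jitter, um
    d_eq: float = 0.7              # dancing equilibrium separation, um
    T_dance: float | None = None   # dancing duration, s; None -> U(10, 35)
    relax_time: float = 2.0        # tether relaxation time, s

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if self.kind == "stop_and_go" and (self.tau_go <= 0 or self.tau_stop <= 0):
            raise ValueError("stop_and_go needs positive tau_go and tau_stop")
        if not self.d_eq < 2.0:
            raise ValueError("d_eq must be < 2 um")
        if self.T_dance is not None and self.T_dance <= 0:
            raise ValueError("T_dance must be positive")


DANCE_DURATION_RANGE_S = (10.0, 35.0)


@dataclass
class OpticsConfig:
    """Acquisition model: calibration, PSF and noise.

    Spinning-disc defaults follow the acquisition settings the analysis
    assumes (0.26 um/px, 0.1 s/frame, PSF FWHM ~0.25 um, 8-bit-like SNR of
    about 10 at the default particle intensity). SIM-mode defaults emulate
    already-reconstructed super-resolution frames (~100 nm lateral
    resolution sampled at 40 nm/px, high SNR).
    """

    modality: str = "spinning_disc"    # spinning_disc | sim
    pixel_size: float = 0.26           # um / px
    frame_interval: float = 0.1        # s (ignored for sim single frames)
    psf_fwhm: float = 0.25             # um
    background: float = 10.0           # photons / px
    photon_scale: float = 50.0         # peak photons per unit intensity
    read_noise_sigma: float = 2.0      # photons RMS
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0 or self.psf_fwhm <= 0:
            raise ValueError("pixel_size, frame_interval, psf_fwhm must be positive")

    @classmethod
    def sim_defaults(cls, **overrides) -> "OpticsConfig":
        kw = dict(modality="sim", pixel_size=0.04, frame_interval=1.0,
                  psf_fwhm=0.1, background=5.0, photon_scale=200.0,
                  read_noise_sigma=1.0)
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

PARTICLE_COLUMNS = ["particle_id", "frame", "t", "x", "y", "intensity",
                    "apparent_diameter_nm", "motion_state", "kind"]
EVENT_COLUMNS = ["event_id", "type", "member_ids", "product_id",
                 "t_start", "t_end"]


@dataclass
class SimulationGroundTruth:
    """Per-particle per-frame truth plus the scripted event log.

    ``particles`` columns: particle_id, frame, t (s), x/y (um), intensity
    (a.u., pre-noise), apparent_diameter_nm, motion_state
    (go/stop/dancing/fused), kind. ``events`` columns: event_id, type
    (dancing | cluster_fusion), member_ids ("a;b"), product_id (fusion
    product particle, -1 otherwise), t_start, t_end (s).
    """

    particles: pd.DataFrame
    events: pd.DataFrame
    frame_interval: float
    n_frames: int
    fov_um: tuple[float, float]
    geometry: RootHairGeometry
    preset: MarkerPreset | None = None

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def as_tracks(self) -> pd.DataFrame:
        """Ground-truth trajectories in the linked-track table layout
        (track_id = particle_id), for analyses that bypass imaging."""
        df = self.particles.rename(columns={"particle_id": "track_id"}).copy()
        df["inferred"] = False
        return df[["track_id", "frame", "t", "x", "y", "intensity", "inferred"]]

    def save(self, particles_path, events_path) -> None:
        out = self.events.copy()
        self.particles.to_csv(particles_path, index=False)
        out.to_csv(events_path, index=False)


# ---------------------------------------------------------------------------
# elementary random paths
# ---------------------------------------------------------------------------


def _ou(rng, n, dt, sigma, tau, x0=None):
    """Stationary Ornstein-Uhlenbeck series of length n."""
    a = math.exp(-dt / tau)
    s = sigma * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma) if x0 is None else x0
    noise = rng.normal(0.0, s, size=n - 1) if n > 1 else np.empty(0)
    for k in range(1, n):
        x[k] = x[k - 1] * a + noise[k - 1]
    return x


def _phase_states(rng, n, dt, tau_go, tau_stop, start_go=None,
                  v=None, go_run_um=None):
    """Per-frame go/stop labels.

    Stop phases last U(0.5 tau_stop, 1.5 tau_stop) seconds. Go phases last
    U(0.5 tau_go, 1.5 tau_go) seconds, unless ``v`` and ``go_run_um`` are
    given, in which case their duration realises a run length drawn from
    ``go_run_um`` at speed ``v``.
    """
    states = np.empty(n, dtype=object)
    go = bool(rng.integers(2)) if start_go is None else start_go
    k = 0
    while k < n:
        if go and v and go_run_um is not None:
            dur = rng.uniform(*go_run_um) / v
        else:
            tau = tau_go if go else tau_stop
            dur = rng.uniform(0.5 * tau, 1.5 * tau)
        m = max(1, int(round(dur / dt)))
        states[k:k + m] = "go" if go else "stop"
        k += m
        go = not go
    return states


def _bounded_walk(rng, n, dt, v, x0, xmin, xmax, states=None):
    """Axial coordinate: constant speed |v| while in 'go', reflecting at the
    bounds; immobile while in 'stop'. Returns (x, states)."""
    if states is None:
        states = np.full(n, "go", dtype=object)
    x = np.empty(n)
    x[0] = min(max(x0, xmin), xmax)
    direction = rng.choice([-1.0, 1.0])
    prev = states[0]
    for k in range(1, n):
        if states[k] == "go" and prev == "stop":
            direction = rng.choice([-1.0, 1.0])  # new go phase, new heading
        step = direction * v * dt if states[k] == "go" else 0.0
        xk = x[k - 1] + step
        if xk > xmax:
            xk = 2 * xmax - xk
            direction = -direction
        if xk < xmin:
            xk = 2 * xmin - xk
            direction = -direction
        x[k] = min(max(xk, xmin), xmax)
        prev = states[k]
    return x, states


# ---------------------------------------------------------------------------
# particle builders
# ---------------------------------------------------------------------------


class _Builder:
    """Accumulates per-particle frame records and events."""

    def __init__(self, geometry, preset, motion, n_frames, dt, rng):
        self.geo = geometry
        self.preset = preset
        self.motion = motion
        self.n = n_frames
        self.dt = dt
        self.rng = rng
        self.times = np.arange(n_frames) * dt
        self.rows: list[pd.DataFrame] = []
        self.events: list[dict] = []
        self._next_pid = 0
        self._next_eid = 0

    def new_pid(self) -> int:
        pid = self._next_pid
        self._next_pid += 1
        return pid

    def draw_intensity(self) -> float:
        return float(self.preset.intensity_mean * math.exp(self.rng.normal(0.0, 0.3)))

    def draw_diameter(self) -> float:
        return float(draw_apparent_diameters(self.preset, 1, self.rng)[0])

    def lane(self, frac: float = 0.8) -> float:
        return float(self.rng.uniform(-frac, frac) * self.geo.radius)

    def initial_x(self, lane: float) -> float:
        xmin, xmax = self.geo.axial_extent(lane)
        if self.rng.uniform() < self.preset.tip_enrichment:
            return float(self.rng.uniform(max(xmax - 10.0, xmin), xmax))
        return float(self.rng.uniform(xmin, xmax))

    def emit(self, pid, frames, x, y, intensity, diameter_nm, state, kind):
        n = len(frames)
        # containment guard: the motion models are constructed to stay inside,
        # clip any numerical stragglers back into the hair
        y = np.clip(y, self.geo.axis_y - self.geo.radius + 0.05,
                    self.geo.axis_y + self.geo.radius - 0.05)
        self.rows.append(pd.DataFrame({
            "particle_id": pid,
            "frame": np.asarray(frames, dtype=int),
            "t": np.asarray(frames, dtype=float) * self.dt,
            "x": x, "y": y,
            "intensity": np.full(n, intensity) if np.isscalar(intensity) else intensity,
            "apparent_diameter_nm": diameter_nm,
            "motion_state": state,
            "kind": kind,
        }))

    def add_event(self, type_, members, t_start, t_end, product_id=-1):
        self.events.append(dict(event_id=self._next_eid, type=type_,
                                member_ids=";".join(str(m) for m in members),
                                product_id=product_id,
                                t_start=float(t_start), t_end=float(t_end)))
        self._next_eid += 1

    # -- single movers ------------------------------------------------------
    def add_single(self, kind: str) -> int:
        m = self.motion
        lane = self.lane()
        # pad the lane by the jitter envelope so the tip cap stays containing
        xmin, xmax = self.geo.axial_extent(abs(lane) + 0.4)
        x0 = self.initial_x(lane)
        states = (None if kind == "continuous"
                  else _phase_states(self.rng, self.n, self.dt, m.tau_go,
                                     m.tau_stop, v=m.v, go_run_um=m.go_run_um))
        x, states = _bounded_walk(self.rng, self.n, self.dt, m.v, x0, xmin, xmax, states)
        x = x + _ou(self.rng, self.n, self.dt, m.jitter_sigma * 0.5, 1.0)
        y = (self.geo.axis_y + lane
             + _ou(self.rng, self.n, self.dt, m.jitter_sigma, 1.0))
        pid = self.new_pid()
        self.emit(pid, np.arange(self.n), np.clip(x, xmin - 0.3, xmax + 0.3), y,
                  self.draw_intensity(), self.draw_diameter(), states, kind)
        return pid

    # -- dancing pair -------------------------------------------------------
    def add_dancing_pair(self) -> tuple[int, int]:
        m = self.motion
        duration = self.n * self.dt
        T = m.T_dance
        if T is None:
            lo, hi = DANCE_DURATION_RANGE_S
            hi = min(hi, max(lo, duration - 5.0))
            T = float(self.rng.uniform(lo, hi))
        if duration < T + 4.5:
            raise ValueError(
                f"movie of {duration:.1f} s too short for a {T:.1f} s dancing event")
        t0 = float(self.rng.uniform(2.5, duration - T - 2.0))
        t1 = t0 + T

        lane = self.lane(0.55)
        xmin, xmax = self.geo.axial_extent(lane, margin=3.5)
        # common (centre-of-pair) path: slow shuttling plus a shared jiggle
        cx, _ = _bounded_walk(self.rng, self.n, self.dt, 0.5,
                              self.initial_x(lane), xmin, xmax)
        cx = cx + _ou(self.rng, self.n, self.dt, 0.18, 1.0)
        cy = (self.geo.axis_y + lane + _ou(self.rng, self.n, self.dt, 0.12, 1.0))

        # pair separation magnitude: far -> ramp in -> OU tether -> ramp out
        t = self.times
        far, t_ramp, v_sep = 3.2, 1.0, 2.3
        rho = np.full(self.n, far)
        in_win = (t >= t0) & (t <= t1)
        rho[in_win] = m.d_eq + _ou(self.rng, int(in_win.sum()), self.dt,
                                   0.1, m.relax_time)
        pre = (t >= t0 - t_ramp) & (t < t0)
        rho[pre] = m.d_eq + (t0 - t[pre]) / t_ramp * (far - m.d_eq)
        post = (t > t1) & (t <= t1 + (far - m.d_eq) / v_sep)
        rho[post] = m.d_eq + (t[post] - t1) * v_sep
        rho = np.clip(rho, 0.2, None)

        theta = np.cumsum(np.concatenate([[self.rng.uniform(0, 2 * np.pi)],
                                          self.rng.normal(0, 0.25 * math.sqrt(self.dt),
                                                          self.n - 1)]))
        ux, uy = np.cos(theta), np.sin(theta) * 0.5  # flatter than round: hair is a tube
        norm = np.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm

        state = np.where(in_win, "dancing", "go").astype(object)
        pids = []
        diam = self.draw_diameter(), self.draw_diameter()
        inten = self.draw_intensity(), self.draw_intensity()
        for sgn, d, i in zip((0.5, -0.5), diam, inten):
            # outside the tether window each partner wobbles independently
            extra = _ou(self.rng, self.n, self.dt, 0.08, 1.0)
            extra_y = _ou(self.rng, self.n, self.dt, 0.08, 1.0)
            free = ~in_win
            px = cx + sgn * rho * ux + np.where(free, extra, 0.0)
            py = cy + sgn * rho * uy + np.where(free, extra_y, 0.0)
            pid = self.new_pid()
            self.emit(pid, np.arange(self.n), px, py, i, d, state, "dancing_pair")
            pids.append(pid)
        self.add_event("dancing", pids, t0, t1)
        return tuple(pids)

    # -- clustering / fusion pair -------------------------------------------
    def add_fusion_pair(self, intensities=None, t_fusion=None) -> tuple[int, int, int]:
        m = self.motion
        duration = self.n * self.dt
        if duration < 30.0:
            raise ValueError("movies shorter than 30 s cannot script a fusion "
                             "with a 20 s persistence window")
        if t_fusion is None:
            t_fusion = float(self.rng.uniform(4.0, duration - 25.0))
        if not 0 < t_fusion < duration - 25.0 + 1e-9:
            raise ValueError("t_fusion leaves < 25 s of product observation")
        k_f = int(round(t_fusion / self.dt))
        t_fusion = k_f * self.dt

        lane = self.lane(0.55)
        xmin, xmax = self.geo.axial_extent(lane, margin=3.0)
        cx, cstates = _bounded_walk(
            self.rng, self.n, self.dt, 0.8, self.initial_x(lane), xmin, xmax,
            _phase_states(self.rng, self.n, self.dt, m.tau_go, m.tau_stop))
        cx = cx + _ou(self.rng, self.n, self.dt, 0.04, 1.0)
        cy = self.geo.axis_y + lane + _ou(self.rng, self.n, self.dt, 0.05, 1.0)

        t = self.times
        delta = np.full(self.n, 2.0)
        t_app = 3.0
        ramp = (t >= t_fusion - t_app) & (t < t_fusion)
        delta[ramp] = 0.12 + (t_fusion - t[ramp]) / t_app * (2.0 - 0.12)
        delta[t >= t_fusion] = 0.0

        ia = self.draw_intensity() if intensities is None else float(intensities[0])
        ib = self.draw_intensity() if intensities is None else float(intensities[1])
        da, db = self.draw_diameter(), self.draw_diameter()
        member_frames = np.arange(0, k_f)
        pids = []
        for sgn, d, i in zip((1.0, -1.0), (da, db), (ia, ib)):
            jit = _ou(self.rng, self.n, self.dt, 0.05, 1.0)
            px = cx + sgn * delta + jit * 0.5
            py = cy + jit
            pid = self.new_pid()
            self.emit(pid, member_frames, px[:k_f], py[:k_f], i, d,
                      cstates[:k_f], "cluster_fusion")
            pids.append(pid)
        # product: intensity is the exact member sum, diameter by volume
        d_prod = (da**3 + db**3) ** (1.0 / 3.0)
        prod = self.new_pid()
        prod_frames = np.arange(k_f, self.n)
        self.emit(prod, prod_frames, cx[k_f:], cy[k_f:], ia + ib, d_prod,
                  np.full(self.n - k_f, "fused", dtype=object), "cluster_fusion")
        self.add_event("cluster_fusion", pids, t_fusion, duration, product_id=prod)
        return pids[0], pids[1], prod

    # -- negative controls --------------------------------------------------
    def add_transient_pair(self, dwell_s: float = 5.0) -> tuple[int, int]:
        """Unsynchronized 'passer-by' encounter: B pauses within < 1 um of a
        stationary A for ``dwell_s`` seconds, then leaves. Must trigger
        neither dancing (no synchrony) nor fusion (no merge, no intensity
        rise)."""
        duration = self.n * self.dt
        t0 = float(self.rng.uniform(3.0, max(3.1, duration - dwell_s - 4.0)))
        lane = self.lane(0.5)
        xmin, xmax = self.geo.axial_extent(lane, margin=4.5)
        xa = float(self.rng.uniform(xmin, xmax))
        ya = self.geo.axis_y + lane
        ja = _ou(self.rng, self.n, self.dt, 0.06, 1.0)
        jay = _ou(self.rng, self.n, self.dt, 0.06, 1.0)
        pid_a = self.new_pid()
        self.emit(pid_a, np.arange(self.n), xa + ja, ya + jay,
                  self.draw_intensity(), self.draw_diameter(), "stop", "transient_pair")

        t = self.times
        v_in = 1.2
        sep = np.full(self.n, 4.0)
        ramp_in = (t >= t0 - 4.0 / v_in) & (t < t0)
        sep[ramp_in] = 0.5 + (t0 - t[ramp_in]) * v_in
        dwell = (t >= t0) & (t <= t0 + dwell_s)
        sep[dwell] = 0.5
        ramp_out = t > t0 + dwell_s
        sep[ramp_out] = np.minimum(0.5 + (t[ramp_out] - t0 - dwell_s) * v_in, 6.0)
        jb = _ou(self.rng, self.n, self.dt, 0.06, 1.0)
        jby = _ou(self.rng, self.n, self.dt, 0.06, 1.0)
        pid_b = self.new_pid()
        self.emit(pid_b, np.arange(self.n), np.clip(xa + sep, xmin - 1, xmax + 4.0) + jb,
                  ya + jby, self.draw_intensity(), self.draw_diameter(),
                  "go", "transient_pair")
        return pid_a, pid_b

    def add_occlusion_pair(self) -> tuple[int, int]:
        """Track A blinks out of focus right next to passing track B while
        B's intensity stays its own: merge-like topology without intensity
        conservation, so no fusion may be called."""
        m = self.motion
        duration = self.n * self.dt
        t_x = float(self.rng.uniform(0.3 * duration, 0.6 * duration))
        k_x = max(2, int(round(t_x / self.dt)))
        lane = self.lane(0.5)
        xmin, xmax = self.geo.axial_extent(lane, margin=1.0)
        xb, sb = _bounded_walk(
            self.rng, self.n, self.dt, m.v * 0.6, self.initial_x(lane), xmin, xmax,
            _phase_states(self.rng, self.n, self.dt, m.tau_go, m.tau_stop))
        yb = self.geo.axis_y + lane + _ou(self.rng, self.n, self.dt, 0.05, 1.0)
        pid_b = self.new_pid()
        self.emit(pid_b, np.arange(self.n), xb, yb, self.draw_intensity(),
                  self.draw_diameter(), sb, "occlusion_pair")
        # A sits where B will be at t_x, offset 0.3 um, and dies there
        ja = _ou(self.rng, self.n, self.dt, 0.05, 1.0)
        jay = _ou(self.rng, self.n, self.dt, 0.05, 1.0)
        pid_a = self.new_pid()
        self.emit(pid_a, np.arange(k_x), xb[k_x] + 0.3 + ja[:k_x], yb[k_x] + jay[:k_x],
                  self.draw_intensity(), self.draw_diameter(), "stop", "occlusion_pair")
        return pid_a, pid_b


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


def draw_apparent_diameters(preset: MarkerPreset, n: int, rng) -> np.ndarray:
    """Apparent diameters (nm) from the preset's size distribution.

    Normal with the preset mean/sd, truncated below at
    ``max(150 nm, mean - 2.5 sd)`` — sizes far below the optical resolution
    are neither generated nor measurable.
    """
    mu, sd = preset.apparent_diameter_mean, preset.apparent_diameter_sd
    lo = max(150.0, mu - 2.5 * sd)
    a = (lo - mu) / sd
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def simulate_population(
    geometry: RootHairGeometry,
    preset: MarkerPreset | str,
    n_particles: int,
    duration: float,
    motion_overrides: MotionModel | None = None,
    seed: int = 0,
    frame_interval: float = 0.1,
    n_dancing_pairs: int | None = None,
    n_fusion_pairs: int | None = None,
    n_transient_pairs: int = 0,
    n_occlusion_pairs: int = 0,
    fusion_specs: list[tuple[float, float, float]] | None = None,
    n_continuous: int | None = None,
) -> SimulationGroundTruth:
    """Simulate a ground-truthed endosome population in a root hair.

    ``n_particles`` counts every simulated particle, interaction-pair
    members included (fusion products are extra). Single movers split into
    continuous and stop-and-go kinds with *exactly*
    ``round(continuous_fraction * n_singles)`` continuous ones —
    ``n_continuous`` overrides that count, e.g. to allocate an exact
    mixture across several movies. Pair counts default to
    ``round(rate * duration)`` from the preset's dancing/fusion rates.
    Identical seeds and configurations give identical output.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    if isinstance(preset, str):
        preset = get_preset(preset)
    motion = motion_overrides or MotionModel(kind="stop_and_go", v=preset.v_max)
    rng = np.random.default_rng(seed)
    n_frames = max(1, int(round(duration / frame_interval)))

    if fusion_specs is not None and n_fusion_pairs is None:
        n_fusion_pairs = len(fusion_specs)
    if n_dancing_pairs is None:
        n_dancing_pairs = int(round(preset.dancing_rate * duration))
    if n_fusion_pairs is None:
        n_fusion_pairs = int(round(preset.fusion_rate * duration))
    if n_dancing_pairs > 0 and n_particles < 2:
        raise ValueError("dancing requires at least 2 particles")
    n_paired = 2 * (n_dancing_pairs + n_fusion_pairs
                    + n_transient_pairs + n_occlusion_pairs)
    if n_paired > n_particles:
        raise ValueError(
            f"{n_paired} particles needed for the requested pair events "
            f"but only n_particles={n_particles} given")
    n_singles = n_particles - n_paired

    b = _Builder(geometry, preset, motion, n_frames, frame_interval, rng)
    if n_continuous is None and motion_overrides is not None \
            and motion_overrides.kind in ("continuous", "stop_and_go"):
        kinds = [motion_overrides.kind] * n_singles
    else:
        n_cont = (int(round(preset.continuous_fraction * n_singles))
                  if n_continuous is None else int(n_continuous))
        if not 0 <= n_cont <= n_singles:
            raise ValueError("n_continuous out of range")
        kinds = ["continuous"] * n_cont + ["stop_and_go"] * (n_singles - n_cont)
        rng.shuffle(kinds)
    for kind in kinds:
        b.add_single(kind)
    for _ in range(n_dancing_pairs):
        b.add_dancing_pair()
    for j in range(n_fusion_pairs):
        if fusion_specs is not None:
            ia, ib, tf = fusion_specs[j]
            b.add_fusion_pair(intensities=(ia, ib), t_fusion=tf)
        else:
            b.add_fusion_pair()
    for _ in range(n_transient_pairs):
        b.add_transient_pair()
    for _ in range(n_occlusion_pairs):
        b.add_occlusion_pair()

    particles = (pd.concat(b.rows, ignore_index=True) if b.rows
                 else pd.DataFrame(columns=PARTICLE_COLUMNS))
    events = (pd.DataFrame(b.events) if b.events
              else pd.DataFrame(columns=EVENT_COLUMNS))
    return SimulationGroundTruth(
        particles=particles, events=events, frame_interval=frame_interval,
        n_frames=n_frames, fov_um=geometry.fov_um(duration), geometry=geometry,
        preset=preset)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _add_gaussian(img, x_px, y_px, sigma_px, amplitude):
    """Accumulate a 2D Gaussian (peak = amplitude) into img, windowed."""
    h, w = img.shape
    r = max(2, int(math.ceil(4.0 * sigma_px)))
    c0, r0 = int(round(x_px)), int(round(y_px))
    cs, ce = max(c0 - r, 0), min(c0 + r + 1, w)
    rs, re = max(r0 - r, 0), min(r0 + r + 1, h)
    if cs >= ce or rs >= re:
        return False
    cols = np.arange(cs, ce) - x_px
    rows = np.arange(rs, re) - y_px
    g = np.exp(-(rows[:, None] ** 2 + cols[None, :] ** 2) / (2.0 * sigma_px**2))
    img[rs:re, cs:ce] += amplitude * g
    return True


def render_movie(truth: SimulationGroundTruth, optics: OpticsConfig) -> ImageStack:
    """Render ground truth into a spinning-disc movie.

    One frame per time point; each particle is a 2D Gaussian of FWHM
    ``max(psf_fwhm, apparent diameter)`` whose *integrated* photon count
    scales with its ground-truth intensity (so fusion conserves summed
    photons). Poisson shot noise on (background + signal), then Gaussian
    read noise. Particles outside the field of view are clipped silently
    and counted in ``stack.meta["render_report"]``.
    """
    if optics.modality != "spinning_disc":
        raise ValueError("render_movie expects spinning_disc optics")
    px = optics.pixel_size
    w = int(math.ceil(truth.fov_um[0] / px))
    h = int(math.ceil(truth.fov_um[1] / px))
    frames = np.zeros((truth.n_frames, h, w))
    sigma_ref = optics.psf_fwhm / 2.355 / px
    clipped = 0
    p = truth.particles
    if len(p):
        fwhm_um = np.maximum(optics.psf_fwhm,
                             p["apparent_diameter_nm"].to_numpy() / 1000.0)
        sig_px = fwhm_um / 2.355 / px
        amp = (p["intensity"].to_numpy() * optics.photon_scale
               * (sigma_ref / sig_px) ** 2)
        xs = p["x"].to_numpy() / px
        ys = p["y"].to_numpy() / px
        fr = p["frame"].to_numpy()
        for k in range(len(p)):
            ok = _add_gaussian(frames[fr[k]], xs[k], ys[k], sig_px[k], amp[k])
            clipped += not ok
    frames += optics.background
    if optics.noise:
        rng = np.random.default_rng(optics.seed)
        frames = rng.poisson(frames).astype(float)
        frames += rng.normal(0.0, optics.read_noise_sigma, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)
    return ImageStack(frames, px, truth.frame_interval,
                      meta={"modality": "spinning_disc",
                            "render_report": {"clipped_particles": int(clipped)}})


# -- SIM-mode rendering ------------------------------------------------------


def _ring_radial_profile(r, shell_radius, sigma):
    """Cross-section of a thin circular shell convolved with a 2D Gaussian
    PSF: exp(-(r-R)^2 / 2 sigma^2) * i0e(r R / sigma^2), unnormalized."""
    z = r * shell_radius / sigma**2
    return np.exp(-((r - shell_radius) ** 2) / (2.0 * sigma**2)) * i0e(z)


def _ring_outer_fwhm(shell_radius, sigma):
    """Outer extent at half maximum of the rendered ring profile."""
    r = np.linspace(0.0, shell_radius + 6.0 * sigma, 2000)
    p = _ring_radial_profile(r, shell_radius, sigma)
    half = 0.5 * p.max()
    above = np.nonzero(p >= half)[0]
    i = above[-1]
    if i == len(r) - 1:
        return 2.0 * r[-1]
    # linear interpolation of the outer half-max crossing
    f = (p[i] - half) / (p[i] - p[i + 1])
    return 2.0 * (r[i] + f * (r[i + 1] - r[i]))


def _solve_shell_radius(target_fwhm_um, sigma_um):
    """Shell radius whose rendered outer-extent FWHM equals the target, so
    a ring's measured apparent diameter matches its drawn value by
    construction."""
    lo, hi = 1e-4, target_fwhm_um
    f = lambda R: _ring_outer_fwhm(R, sigma_um) - target_fwhm_um
    if f(lo) >= 0:  # target at/below the PSF: degenerate, nearly filled disk
        return lo
    return brentq(f, lo, hi, xtol=1e-4)


def render_sim_frame(particles, optics: OpticsConfig,
                     fov_um: tuple[float, float] | None = None) -> ImageStack:
    """Render a single SIM-like super-resolution frame.

    Parameters
    ----------
    particles : sequence of (x_um, y_um, apparent_diameter_nm, endosome_class)
        ``endosome_class`` "early" renders a Gaussian spot whose FWHM equals
        the apparent diameter; "late" renders a thin circular shell
        convolved with the SIM PSF, sized so the outer-extent FWHM of its
        two-peaked cross profile equals the apparent diameter.
    optics : OpticsConfig with ``modality="sim"``.
    fov_um : field of view; inferred from particle positions when omitted.

    Rings whose apparent diameter falls below ~1.2x the PSF FWHM are still
    rendered but listed under ``meta["render_report"]["unresolvable"]``.
    """
    if optics.modality != "sim":
        raise ValueError("render_sim_frame expects sim optics")
    px = optics.pixel_size
    parts = [(float(x), float(y), float(d), str(c)) for x, y, d, c in particles]
    if fov_um is None:
        if parts:
            xs = [p[0] for p in parts]
            ys = [p[1] for p in parts]
            pad = 1.0
            fov_um = (max(xs) + pad, max(ys) + pad)
        else:
            fov_um = (5.0, 5.0)
    w = int(math.ceil(fov_um[0] / px))
    h = int(math.ceil(fov_um[1] / px))
    img = np.zeros((h, w))
    sigma_psf = optics.psf_fwhm / 2.355
    unresolvable = []
    for i, (x, y, d_nm, cls) in enumerate(parts):
        d_um = d_nm / 1000.0
        amp = optics.photon_scale * 2.3  # nominal particle intensity, a.u.
        if cls == "early":
            sigma = max(d_um, optics.psf_fwhm) / 2.355
            if d_um < optics.psf_fwhm:
                unresolvable.append(i)
            _add_gaussian(img, x / px, y / px, sigma / px, amp)
        else:
            if d_um < 1.2 * optics.psf_fwhm:
                unresolvable.append(i)
            shell_r = _solve_shell_radius(d_um, sigma_psf)
            ext = shell_r + 6.0 * sigma_psf
            c0, r0 = x / px, y / px
            cs = max(int(c0 - ext / px), 0)
            ce = min(int(c0 + ext / px) + 2, w)
            rs = max(int(r0 - ext / px), 0)
            re = min(int(r0 + ext / px) + 2, h)
            if cs >= ce or rs >= re:
                continue
            cols = (np.arange(cs, ce) - c0) * px
            rows = (np.arange(rs, re) - r0) * px
            rr = np.hypot(rows[:, None], cols[None, :])
            prof = _ring_radial_profile(rr, shell_r, sigma_psf)
            img[rs:re, cs:ce] += amp * prof / prof.max()
    img += optics.background
    if optics.noise:
        rng = np.random.default_rng(optics.seed)
        img = rng.poisson(img).astype(float)
        img += rng.normal(0.0, optics.read_noise_sigma, size=img.shape)
        np.clip(img, 0.0, None, out=img)
    return ImageStack(img[None], px, optics.frame_interval,
                      meta={"modality": "sim",
                            "render_report": {"unresolvable": unresolvable}})
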