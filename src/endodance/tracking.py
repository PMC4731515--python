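"""Spot linking, trajectory filtering and speed analysis.

Frame-to-frame linking is an optimal bipartite assignment (Hungarian
algorithm) on squared displacement, gated by a maximum per-frame
displacement, with birth/death handled by augmenting the cost matrix.
Tracks missed for up to ``max_gap`` frames are bridged by linear
interpolation; interpolated spots are flagged ``inferred`` and carry no
intensity so that intensity-based analyses skip them. Trajectories whose
path length falls below 5 um are excluded, the standard short-trajectory
filter for endosome tracking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["track_id", "frame", "t", "x", "y", "intensity", "inferred"]

_INF = 1e12


@dataclass
class LinkingParams:
    max_displacement: float = 2.0   # um per frame
    max_gap: int = 1                # frames bridged by interpolation
    min_path_length: float = 5.0    # um; the short-trajectory exclusion rule
    filter_on: str = "path"         # "path" length or "net" displacement

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")
        if self.max_gap < 0 or self.min_path_length < 0:
            raise ValueError("max_gap and min_path_length must be >= 0")
        if self.filter_on not in ("path", "net"):
            raise ValueError("filter_on must be 'path' or 'net'")


@dataclass
class Track:
    """One time-ordered trajectory (a view over the track table)."""

    track_id: int
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    inferred: np.ndarray

    @property
    def n_spots(self) -> int:
        return len(self.frames)

    @property
    def path_length(self) -> float:
        """Sum of consecutive displacements, um."""
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    @property
    def net_displacement(self) -> float:
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))

    @property
    def max_speed(self) -> float:
        prof = speed_profile(self)
        return float(prof["speed"].max())

    @property
    def mean_speed(self) -> float:
        prof = speed_profile(self)
        return float(np.average(prof["speed"], weights=prof["dt"]))


def iter_tracks(tracks: pd.DataFrame):
    """Yield :class:`Track` objects from a linked track table."""
    for tid, g in tracks.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        yield Track(
            int(tid), g["frame"].to_numpy(), g["t"].to_numpy(),
            g["x"].to_numpy(), g["y"].to_numpy(),
            g["intensity"].to_numpy(dtype=float),
            g["inferred"].to_numpy(dtype=bool),
        )


def _assign(prev_xy: np.ndarray, new_xy: np.ndarray, max_d: np.ndarray):
    """Gated optimal assignment with birth/death.

    ``max_d[i]`` is the per-candidate displacement gate (grows with the
    frame gap). Returns list of (i_prev, j_new) links.
    """
    n1, n2 = len(prev_xy), len(new_xy)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((prev_xy[:, None, :] - new_xy[None, :, :]) ** 2).sum(axis=2)
    gate = max_d[:, None] ** 2
    cost = np.where(d2 <= gate, d2, _INF)
    # the no-link alternative must not undercut any gated link, otherwise
    # gap-closing links near their gate would be dropped for a death+birth
    alt = float(np.max(max_d) ** 2)
    size = n1 + n2
    big = np.full((size, size), _INF)
    big[:n1, :n2] = cost
    big[np.arange(n1), n2 + np.arange(n1)] = alt
    big[n1 + np.arange(n2), np.arange(n2)] = alt
    big[n1:, n2:] = 0.0
    ri, ci = linear_sum_assignment(big)
    return [(int(i), int(j)) for i, j in zip(ri, ci)
            if i < n1 and j < n2 and big[i, j] < _INF]


def link_spots(spots: pd.DataFrame, params: LinkingParams | None = None) -> pd.DataFrame:
    """Link per-frame spots into trajectories.

    Parameters
    ----------
    spots : DataFrame with columns frame, t, x, y (um) and optionally
        intensity; all frames pooled in one table.
    params : LinkingParams

    Returns a track table (``TRACK_COLUMNS``); gap-bridging spots are
    linearly interpolated with ``inferred=True`` and NaN intensity.
    """
    params = params or LinkingParams()
    if spots is None or len(spots) == 0:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    spots = spots.sort_values(["frame"]).reset_index(drop=True)
    if "intensity" not in spots:
        spots = spots.assign(intensity=np.nan)

    frames = np.sort(spots["frame"].unique())
    by_frame = {int(f): g for f, g in spots.groupby("frame")}
    # frame interval for interpolated time stamps
    tracks: list[dict] = []   # each: frames, t, x, y, intensity, inferred
    active: list[dict] = []

    def new_track(row):
        tr = {"frames": [int(row.frame)], "t": [float(row.t)],
              "x": [float(row.x)], "y": [float(row.y)],
              "intensity": [float(row.intensity)], "inferred": [False]}
        tracks.append(tr)
        active.append(tr)

    for f in frames:
        f = int(f)
        g = by_frame[f]
        new_xy = g[["x", "y"]].to_numpy(dtype=float)
        rows = list(g.itertuples())
        # retire tracks that exceeded the allowed gap
        still = [tr for tr in active if f - tr["frames"][-1] <= 1 + params.max_gap]
        active[:] = still
        cands = [tr for tr in active if tr["frames"][-1] < f]
        if cands:
            prev_xy = np.array([[tr["x"][-1], tr["y"][-1]] for tr in cands])
            gaps = np.array([f - tr["frames"][-1] for tr in cands], dtype=float)
            links = _assign(prev_xy, new_xy, params.max_displacement * gaps)
        else:
            links = []
        matched_new = set()
        for i, j in links:
            tr = cands[i]
            row = rows[j]
            gap = f - tr["frames"][-1]
            if gap > 1:  # bridge the gap with inferred spots
                x0, y0, t0 = tr["x"][-1], tr["y"][-1], tr["t"][-1]
                for k in range(1, gap):
                    a = k / gap
                    tr["frames"].append(tr["frames"][-1] + 1)
                    tr["t"].append(t0 + a * (row.t - t0))
                    tr["x"].append(x0 + a * (row.x - x0))
                    tr["y"].append(y0 + a * (row.y - y0))
                    tr["intensity"].append(np.nan)
                    tr["inferred"].append(True)
            tr["frames"].append(f)
            tr["t"].append(float(row.t))
            tr["x"].append(float(row.x))
            tr["y"].append(float(row.y))
            tr["intensity"].append(float(row.intensity))
            tr["inferred"].append(False)
            matched_new.add(j)
        for j, row in enumerate(rows):
            if j not in matched_new:
                new_track(row)

    out = []
    for tid, tr in enumerate(tracks):
        out.append(pd.DataFrame({
            "track_id": tid, "frame": tr["frames"], "t": tr["t"],
            "x": tr["x"], "y": tr["y"], "intensity": tr["intensity"],
            "inferred": tr["inferred"],
        }))
    return pd.concat(out, ignore_index=True)


def track_summary(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track path length, net displacement and speed statistics."""
    recs = []
    for tr in iter_tracks(tracks):
        rec = {"track_id": tr.track_id, "n_spots": tr.n_spots,
               "path_length": tr.path_length,
               "net_displacement": tr.net_displacement}
        if tr.n_spots >= 2:
            rec["max_speed"] = tr.max_speed
            rec["mean_speed"] = tr.mean_speed
        else:
            rec["max_speed"] = np.nan
            rec["mean_speed"] = np.nan
        recs.append(rec)
    return pd.DataFrame(recs)


def filter_tracks(tracks: pd.DataFrame, params: LinkingParams | None = None) -> pd.DataFrame:
    """Drop trajectories shorter than ``min_path_length`` (default 5 um).

    Length is the summed path length ("trajectory" length); set
    ``params.filter_on="net"`` to filter on net displacement instead.
    Idempotent.
    """
    params = params or LinkingParams()
    if len(tracks) == 0:
        return tracks.copy()
    keep = []
    removed = 0
    for tr in iter_tracks(tracks):
        length = tr.path_length if params.filter_on == "path" else tr.net_displacement
        if length >= params.min_path_length:
            keep.append(tr.track_id)
        else:
            removed += 1
    logger.info("filter_tracks: removed %d of %d tracks below %.1f um",
                removed, removed + len(keep), params.min_path_length)
    return tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)


def speed_profile(track: Track | pd.DataFrame) -> pd.DataFrame:
    """Frame-to-frame speed series of one track.

    ``speed_i = |displacement_i| / dt_i`` over consecutive retained spots;
    the returned table has one row per interval with its start time ``t``
    and duration ``dt``. Single-spot tracks are rejected.
    """
    if isinstance(track, pd.DataFrame):
        track = next(iter_tracks(track))
    if track.n_spots < 2:
        raise ValueError("speed profile needs >= 2 spots")
    dt = np.diff(track.t)
    dist = np.hypot(np.diff(track.x), np.diff(track.y))
    return pd.DataFrame({"t": track.t[:-1], "dt": dt, "speed": dist / dt})


def segment_stop_go(
    profile: pd.DataFrame,
    v_stop: float = 0.5,
    min_phase: float = 0.3,
) -> list[tuple[str, float, float]]:
    """Partition a speed profile into stop and go phases.

    Contiguous runs with speed below ``v_stop`` lasting at least
    ``min_phase`` seconds are stop phases; everything else is go. The
    returned phases tile the track's time span exactly.
    """
    if len(profile) == 0:
        raise ValueError("empty speed profile")
    t = profile["t"].to_numpy()
    dt = profile["dt"].to_numpy()
    slow = profile["speed"].to_numpy() < v_stop

    # candidate runs of slow intervals; short ones are absorbed into go
    labels = np.empty(len(t), dtype=object)
    i = 0
    while i < len(t):
        j = i
        while j < len(t) and slow[j] == slow[i]:
            j += 1
        dur = float(t[j - 1] + dt[j - 1] - t[i])
        labels[i:j] = "stop" if (slow[i] and dur >= min_phase) else "go"
        i = j
    phases = []
    i = 0
    while i < len(t):
        j = i
        while j < len(t) and labels[j] == labels[i]:
            j += 1
        phases.append((labels[i], float(t[i]), float(t[j - 1] + dt[j - 1])))
        i = j
    return phases
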