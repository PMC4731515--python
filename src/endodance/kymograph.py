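"""Kymographs: distance-along-line x time maps and what they reveal.

A kymograph samples the movie's intensity along a fixed polyline (1 px
wide by default, averaged across the width otherwise), one column per
frame. Moving particles appear as sloped ridges; the slope is the speed.
The maximum speed is recovered automatically from the steepest
piecewise-linear segment of the traced ridges — an automated stand-in for
reading steepest slopes off the kymograph by eye — and a trajectory is
classified *continuous* when some ridge keeps a straight constant-speed
course over at least ``continuous_min_length`` (default 15 um, the
permissive end of the 15-20 um rule), otherwise *discontinuous*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from shapely.geometry import LineString

from .io import ImageStack

CONTINUOUS_MIN_LENGTH_UM = 15.0


@dataclass
class Kymograph:
    values: np.ndarray        # (distance, time)
    line: np.ndarray          # polyline in um, as sampled
    distances: np.ndarray     # arc-length positions of the rows, um
    pixel_size: float         # um per distance step
    frame_interval: float     # s per column
    line_width: int = 1

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class MovementClass:
    label: str                    # "continuous" | "discontinuous"
    qualifying_run_length: float  # um, longest straight constant-speed run


def build_kymograph(stack: ImageStack, line, width: int = 1) -> Kymograph:
    """Sample the stack along a polyline, one column per frame.

    ``line`` is an (N, 2) polyline in micrometres. With the default width
    of 1 px each row is the nearest-pixel sample of the line; wider (odd)
    settings average across perpendicular offsets. A line leaving the image
    is rejected with the offending coordinates.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be a positive odd pixel count")
    px = stack.pixel_size
    ls = LineString(np.atleast_2d(np.asarray(line, dtype=float)))
    n_steps = max(2, int(np.floor(ls.length / px)) + 1)
    distances = np.arange(n_steps) * px
    pts = np.array([ls.interpolate(d).coords[0] for d in distances])

    # unit normals for width > 1, from the local tangent
    tang = np.gradient(pts, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    normals = np.column_stack([-tang[:, 1] / norm, tang[:, 0] / norm])

    h, w = stack.frame_shape
    offsets = (np.arange(width) - width // 2) * px
    cols_idx = np.empty((width, n_steps), dtype=int)
    rows_idx = np.empty((width, n_steps), dtype=int)
    for k, off in enumerate(offsets):
        sample = pts + off * normals
        c = np.round(sample[:, 0] / px).astype(int)
        r = np.round(sample[:, 1] / px).astype(int)
        bad = (c < 0) | (c >= w) | (r < 0) | (r >= h)
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"kymograph line exits the image at ({sample[i, 0]:.2f}, "
                f"{sample[i, 1]:.2f}) um")
        cols_idx[k], rows_idx[k] = c, r
    values = stack.data[:, rows_idx, cols_idx].mean(axis=1).T  # (dist, time)
    return Kymograph(values, pts, distances, px, stack.frame_interval, width)


# ---------------------------------------------------------------------------
# ridge tracing
# ---------------------------------------------------------------------------


def _refine_peak(col: np.ndarray, i: int) -> float:
    """Sub-pixel peak position by a 3-point parabola."""
    if i <= 0 or i >= len(col) - 1:
        return float(i)
    denom = col[i - 1] - 2.0 * col[i] + col[i + 1]
    if denom >= 0:
        return float(i)
    return float(i + np.clip(0.5 * (col[i - 1] - col[i + 1]) / denom, -0.5, 0.5))


def trace_ridges(
    k: Kymograph,
    min_height: float | None = None,
    max_jump_px: float = 6.0,
    max_missing: int = 2,
    min_length: int = 5,
) -> list[np.ndarray]:
    """Link per-column intensity maxima into ridge lines.

    Returns a list of (n, 2) arrays of (column index, sub-pixel row).
    ``min_height`` defaults to background + 20% of the dynamic range.
    """
    v = k.values
    if min_height is None:
        bg = float(np.median(v))
        rng_ = float(v.max() - bg)
        if rng_ <= 0:
            return []
        min_height = bg + 0.2 * rng_
    open_ridges: list[dict] = []
    done: list[list] = []
    for t in range(k.n_frames):
        col = v[:, t]
        idx, _ = find_peaks(col, height=min_height)
        peaks = [_refine_peak(col, int(i)) for i in idx]
        used = set()
        for ridge in open_ridges:
            last = ridge["pts"][-1][1]
            best, bestd = None, max_jump_px
            for j, p in enumerate(peaks):
                if j in used:
                    continue
                if abs(p - last) <= bestd:
                    best, bestd = j, abs(p - last)
            if best is None:
                ridge["miss"] += 1
            else:
                ridge["pts"].append((t, peaks[best]))
                ridge["miss"] = 0
                used.add(best)
        still = []
        for ridge in open_ridges:
            if ridge["miss"] > max_missing:
                done.append(ridge["pts"])
            else:
                still.append(ridge)
        open_ridges = still
        for j, p in enumerate(peaks):
            if j not in used:
                open_ridges.append({"pts": [(t, p)], "miss": 0})
    done.extend(r["pts"] for r in open_ridges)
    return [np.asarray(r, dtype=float) for r in done if len(r) >= min_length]


def guided_ridge(k: Kymograph, guide: pd.DataFrame, search_px: int = 2) -> np.ndarray:
    """Refine a known trajectory into a kymograph ridge.

    ``guide`` has columns ``frame`` and ``distance`` (um along the line,
    e.g. a linked track projected onto the kymograph line); each guide
    point is snapped to the nearest intensity maximum within
    ``search_px`` rows and refined to sub-pixel.
    """
    v = k.values
    pts = []
    for frame, dist in zip(guide["frame"].to_numpy(), guide["distance"].to_numpy()):
        tcol = int(frame)
        if not 0 <= tcol < k.n_frames:
            continue
        i0 = dist / k.pixel_size
        # points whose search window would clip at the line ends produce
        # clamped, spurious ridge positions; skip them
        if not search_px <= i0 <= k.n_positions - 1 - search_px:
            continue
        lo = int(round(i0)) - search_px
        hi = int(round(i0)) + search_px + 1
        col = v[:, tcol]
        i = lo + int(np.argmax(col[lo:hi]))
        pts.append((tcol, _refine_peak(col, i)))
    return np.asarray(pts, dtype=float)


# ---------------------------------------------------------------------------
# slope extraction and movement classification
# ---------------------------------------------------------------------------


class _LineFit:
    """O(1) straight-line fits over index ranges of (t, d) via prefix sums."""

    def __init__(self, t: np.ndarray, d: np.ndarray):
        self.t = t - t.mean()  # centring keeps the normal equations stable
        self.d = d
        z = np.zeros(1)
        self.ct = np.concatenate([z, np.cumsum(self.t)])
        self.ctt = np.concatenate([z, np.cumsum(self.t * self.t)])
        self.cd = np.concatenate([z, np.cumsum(d)])
        self.cdd = np.concatenate([z, np.cumsum(d * d)])
        self.ctd = np.concatenate([z, np.cumsum(self.t * d)])

    def fit(self, i: int, j: int) -> tuple[float, float]:
        """(slope, rms residual) of the LS line over points i..j inclusive."""
        n = j - i + 1
        st = self.ct[j + 1] - self.ct[i]
        stt = self.ctt[j + 1] - self.ctt[i]
        sd = self.cd[j + 1] - self.cd[i]
        sdd = self.cdd[j + 1] - self.cdd[i]
        std = self.ctd[j + 1] - self.ctd[i]
        det = n * stt - st * st
        if det <= 0:
            return 0.0, np.inf
        a = (n * std - st * sd) / det
        b = (sd - a * st) / n
        rss = (sdd - 2 * a * std - 2 * b * sd + a * a * stt
               + 2 * a * b * st + b * b * n)
        return float(a), float(np.sqrt(max(rss, 0.0) / n))


def _straight_runs(ridge: np.ndarray, k: Kymograph, residual_tol_px: float,
                   max_outlier_streak: int = 2, max_outlier_frac: float = 0.15):
    """Maximal piecewise-linear segments of a ridge, robust to outliers.

    Runs grow while one straight line fits the accepted points within
    ``residual_tol_px`` RMS. Isolated aberrant points (localization
    glitches, brief occlusions by a crossing particle) are skipped rather
    than terminating the run; a run ends when ``max_outlier_streak``
    consecutive points fail, or the outlier fraction exceeds
    ``max_outlier_frac``, or the line no longer fits. Yields dicts with
    slope (um/s), spatial extent (um) and duration (s) per run — the
    automated counterpart of reading straight stripes off a kymograph.
    """
    t = ridge[:, 0] * k.frame_interval
    d = ridge[:, 1] * k.pixel_size
    tol = residual_tol_px * k.pixel_size
    n = len(ridge)
    i = 0
    while i < n - 1:
        inl_t = [t[i], t[i + 1]]
        inl_d = [d[i], d[i + 1]]
        last = i + 1
        streak = 0
        n_out = 0
        j = i + 2
        while j < n:
            ts = np.asarray(inl_t + [t[j]])
            ds = np.asarray(inl_d + [d[j]])
            coef = np.polyfit(ts, ds, 1)
            rms = np.sqrt(np.mean((ds - np.polyval(coef, ts)) ** 2))
            if rms <= tol:
                inl_t.append(t[j])
                inl_d.append(d[j])
                last = j
                streak = 0
            else:
                streak += 1
                n_out += 1
                if streak > max_outlier_streak or \
                        n_out > max_outlier_frac * (len(inl_t) + n_out):
                    break
            j += 1
        ts = np.asarray(inl_t)
        ds = np.asarray(inl_d)
        slope = float(np.polyfit(ts, ds, 1)[0]) if len(ts) > 1 else 0.0
        yield {"slope": slope, "extent": abs(float(ds[-1] - ds[0])),
               "duration": float(ts[-1] - ts[0])}
        i = max(last, i + 1)


def _scan_window_slopes(ridges, k: Kymograph, window_s: float,
                        rms_tol_px: float, jump_tol_px: float,
                        z: float) -> float:
    """Steepest straight sliding-window slope over a set of ridges.

    A window is accepted when a line fits it within ``rms_tol_px`` RMS and
    no single point deviates more than ``jump_tol_px`` (which rejects
    identity handoffs between crossing ridges). The reported slope is the
    lower confidence bound |slope| - z * SE(slope): taking a plain maximum
    over many overlapping noisy windows is biased upward by the noise
    extreme, and penalizing each window by its own uncertainty removes
    most of that bias.
    """
    best = np.nan
    for ridge in ridges:
        if len(ridge) < 2:
            continue
        t = ridge[:, 0] * k.frame_interval
        d = ridge[:, 1] * k.pixel_size
        n = max(5, int(round(window_s / k.frame_interval)))
        if len(ridge) < n:
            n = len(ridge)
        lf = _LineFit(t, d)
        for s in range(len(ridge) - n + 1):
            if t[s + n - 1] - t[s] <= 0:
                continue
            slope, rms = lf.fit(s, s + n - 1)
            if rms > rms_tol_px * k.pixel_size:
                continue
            ts, ds = t[s:s + n], d[s:s + n]
            res = ds - (ds.mean() + slope * (ts - ts.mean()))
            if np.abs(res).max() > jump_tol_px * k.pixel_size:
                continue
            se = rms / np.sqrt(((ts - ts.mean()) ** 2).sum()) \
                * np.sqrt(n / max(n - 2, 1))
            val = max(abs(slope) - z * se, 0.0)
            if np.isnan(best) or val > best:
                best = val
    return float(best)


def max_speed_from_kymograph(
    k: Kymograph,
    guide: pd.DataFrame | None = None,
    window_s: float = 0.7,
    fallback_window_s: float = 0.5,
    v_stop: float = 0.5,
    rms_tol_px: float = 1.0,
    jump_tol_px: float = 1.5,
    z: float = 1.5,
    search_px: int = 2,
) -> float:
    """Maximum speed from the steepest straight ridge segment, in um/s.

    Ridges are traced from per-column maxima (or refined around ``guide``),
    and short sliding windows are fit with straight lines at a primary
    temporal scale of ``window_s``. If no window reveals movement (best
    slope below ``v_stop``), the ridge is re-scanned at
    ``fallback_window_s``: short track fragments may contain go-phases
    briefer than the primary window which would otherwise read as
    immobile. A purely vertical (stationary) ridge yields 0; a featureless
    kymograph yields NaN.
    """
    if k.n_frames < 5:
        raise ValueError("kymograph needs >= 5 columns")
    ridges = ([guided_ridge(k, guide, search_px=search_px)]
              if guide is not None else trace_ridges(k))
    best = _scan_window_slopes(ridges, k, window_s, rms_tol_px, jump_tol_px, z)
    if np.isnan(best) or best < v_stop:
        alt = _scan_window_slopes(ridges, k, fallback_window_s,
                                  rms_tol_px, jump_tol_px, z)
        if np.isnan(best) or (not np.isnan(alt) and alt > best):
            best = alt
    return float(best)


def ridge_segments_table(k: Kymograph, residual_tol_px: float = 1.0) -> pd.DataFrame:
    """All traced ridges' straight segments as a table of
    (ridge, slope_um_s, extent_um, duration_s) — the exportable companion
    of the kymograph image."""
    rows = []
    for ridx, ridge in enumerate(trace_ridges(k)):
        if len(ridge) < 2:
            continue
        for run in _straight_runs(ridge, k, residual_tol_px):
            rows.append({"ridge": ridx, "slope_um_s": run["slope"],
                         "extent_um": run["extent"],
                         "duration_s": run["duration"]})
    return pd.DataFrame(rows, columns=["ridge", "slope_um_s", "extent_um",
                                       "duration_s"])


def classify_movement(
    k: Kymograph,
    continuous_min_length: float = CONTINUOUS_MIN_LENGTH_UM,
    guide: pd.DataFrame | None = None,
    residual_tol_px: float = 1.0,
    search_px: int = 2,
) -> MovementClass:
    """Continuous vs discontinuous movement from ridge straightness.

    A ridge qualifies when one straight constant-speed run spans at least
    ``continuous_min_length`` um; any qualifying ridge makes the kymograph
    continuous. No ridges (or only short/stationary ones) means
    discontinuous with the longest observed run reported.
    """
    ridges = ([guided_ridge(k, guide, search_px=search_px)]
              if guide is not None else trace_ridges(k))
    longest = 0.0
    for ridge in ridges:
        if len(ridge) < 2:
            continue
        for run in _straight_runs(ridge, k, residual_tol_px):
            longest = max(longest, run["extent"])
    label = "continuous" if longest >= continuous_min_length else "discontinuous"
    return MovementClass(label, longest)
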