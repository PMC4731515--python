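"""Pairwise endosome interactions: dancing and clustering/fusion.

Dancing-endosomes are transient tethered pairs: two late endosomes at
close range (sub-micrometre at closest approach) moving in a synchronized
manner for tens of seconds before separating, without merging. They are
detected as maximal time windows in which the pair distance stays within
``d_dance`` *and* the per-frame displacement vectors of the two tracks
correlate (rolling Pearson over a short window) above ``sync_min``, for at
least ``min_dance_duration`` seconds.

Clustering/fusion is a merge: member tracks end next to a product track
whose summed fluorescence intensity approximately equals the members' sum
and *stays* elevated for longer than ``fusion_persistence`` (default 20 s)
— a transient co-localization with a temporary intensity rise does not
qualify. A pair satisfying the fusion criterion is never reported as
dancing (fusion takes precedence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import RegionMask
from .tracking import Track, iter_tracks

EVENT_COLUMNS = ["event_id", "type", "member_track_ids", "product_track_id",
                 "t_start", "t_end", "min_distance", "sync_score",
                 "intensity_ratio", "physical", "x", "y", "zone"]


@dataclass
class InteractionParams:
    d_interact: float = 1.0            # um; physical-interaction / merge distance
    d_dance: float = 2.0               # um; outer envelope of a dancing pair
    min_dance_duration: float = 5.0    # s; below the 10-35 s range on purpose,
    #                                    so the range is measured, not imposed
    sync_min: float = 0.5              # Pearson correlation of displacements
    sync_window: float = 1.5           # s; rolling window for the correlation
    sync_gap_tolerance: float = 3.0    # s; bridge brief synchrony dips while
    #                                    the pair stays within d_dance (the
    #                                    rolling estimate can dip for up to
    #                                    ~2x its own window on noise alone)
    fusion_persistence: float = 20.0   # s; sustained intensity-increase rule
    fusion_intensity_ratio_tol: float = 0.3  # fractional band around the sum
    min_overlap_frames: int = 5
    require_separation: bool = True    # dancing must be observed to begin and
    #                                    end: the pair approaches from beyond
    #                                    d_dance and departs beyond it again

    def __post_init__(self) -> None:
        if self.d_interact > self.d_dance:
            raise ValueError("d_interact must be <= d_dance")
        if self.min_dance_duration <= 0 or self.fusion_persistence <= 0:
            raise ValueError("durations must be positive")


@dataclass
class InteractionEvent:
    type: str                       # "dancing" | "cluster_fusion"
    member_track_ids: tuple
    t_start: float
    t_end: float
    min_distance: float = np.nan
    sync_score: float = np.nan
    intensity_ratio: float = np.nan
    physical: bool = False          # distance < d_interact for >= 1 s
    product_track_id: int = -1
    x: float = np.nan               # mean member position at t_start, um
    y: float = np.nan
    zone: str = ""
    extras: dict = field(default_factory=dict)


def events_to_frame(events: list[InteractionEvent]) -> pd.DataFrame:
    rows = []
    for i, e in enumerate(events):
        rows.append({
            "event_id": i, "type": e.type,
            "member_track_ids": ";".join(str(m) for m in e.member_track_ids),
            "product_track_id": e.product_track_id,
            "t_start": e.t_start, "t_end": e.t_end,
            "min_distance": e.min_distance, "sync_score": e.sync_score,
            "intensity_ratio": e.intensity_ratio, "physical": e.physical,
            "x": e.x, "y": e.y, "zone": e.zone,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# distance and synchrony machinery
# ---------------------------------------------------------------------------


def _common_frames(a: Track, b: Track):
    frames, ia, ib = np.intersect1d(a.frames, b.frames, return_indices=True)
    return frames, ia, ib


def pairwise_distance_series(tracks: pd.DataFrame, pair: tuple[int, int]) -> pd.DataFrame:
    """Euclidean distance between two tracks at each common frame.

    Rejects pairs overlapping in fewer than two frames.
    """
    by_id = {tr.track_id: tr for tr in iter_tracks(tracks)
             if tr.track_id in pair}
    if len(by_id) != 2:
        raise ValueError(f"pair {pair} not found in track table")
    a, b = by_id[pair[0]], by_id[pair[1]]
    frames, ia, ib = _common_frames(a, b)
    if len(frames) < 2:
        raise ValueError(f"tracks {pair} have no usable temporal overlap")
    dist = np.hypot(a.x[ia] - b.x[ib], a.y[ia] - b.y[ib])
    return pd.DataFrame({"frame": frames, "t": a.t[ia], "distance": dist})


def _rolling_sync(dxy1: np.ndarray, dxy2: np.ndarray, w: int) -> np.ndarray:
    """Centred rolling Pearson correlation of displacement vectors.

    ``dxy1``/``dxy2`` have shape (n, 2) (per-interval dx, dy); x and y
    samples are pooled inside each window. Returns one value per interval
    (NaN where a window has no variance).
    """
    n = len(dxy1)
    u = dxy1.reshape(-1)   # [dx0, dy0, dx1, dy1, ...]
    v = dxy2.reshape(-1)
    z = np.zeros(1)
    cu, cv = np.concatenate([z, np.cumsum(u)]), np.concatenate([z, np.cumsum(v)])
    cuu = np.concatenate([z, np.cumsum(u * u)])
    cvv = np.concatenate([z, np.cumsum(v * v)])
    cuv = np.concatenate([z, np.cumsum(u * v)])
    half = w // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + half + 1, n)
        a, b = 2 * lo, 2 * hi
        m = b - a
        su, sv = cu[b] - cu[a], cv[b] - cv[a]
        suu, svv = cuu[b] - cuu[a], cvv[b] - cvv[a]
        suv = cuv[b] - cuv[a]
        varu = suu - su * su / m
        varv = svv - sv * sv / m
        if varu <= 0 or varv <= 0:
            continue
        out[i] = (suv - su * sv / m) / np.sqrt(varu * varv)
    return out


def _pre_intensity(track: Track, before_frame: int, n_frames: int = 10) -> float:
    """Robust intensity of a track shortly before a given frame (inferred
    spots carry NaN and are ignored)."""
    sel = track.frames < before_frame
    vals = track.intensity[sel][-n_frames:]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        vals = track.intensity[~np.isnan(track.intensity)][:n_frames]
    return float(np.median(vals)) if len(vals) else np.nan


def _sustained_sum(values: np.ndarray, t: np.ndarray, target: float,
                   tol: float, persistence: float) -> tuple[bool, float]:
    """Is there a window of >= persistence seconds in which ``values`` stays
    within (1 +/- tol) * target for >= 90% of samples? Returns the flag and
    the mean over the first qualifying window (NaN if none)."""
    ok = np.abs(values / target - 1.0) <= tol
    n = len(values)
    eps = 1e-6 * max(persistence, 1.0)  # float-accumulated time stamps
    for s in range(n):
        e = s
        while e + 1 < n and t[e + 1] - t[s] <= persistence + eps:
            e += 1
        if t[e] - t[s] < persistence - eps:
            break
        window = ok[s:e + 1]
        if window.mean() >= 0.9:
            return True, float(np.nanmean(values[s:e + 1]))
    return False, np.nan


# ---------------------------------------------------------------------------
# dancing detection
# ---------------------------------------------------------------------------


def detect_dancing(
    tracks: pd.DataFrame,
    params: InteractionParams | None = None,
    mask: RegionMask | None = None,
) -> list[InteractionEvent]:
    """Find dancing-endosome events among all overlapping track pairs.

    A window qualifies when pair distance <= ``d_dance`` and rolling
    displacement synchrony >= ``sync_min`` for >= ``min_dance_duration``.
    Windows satisfying the sustained intensity-sum criterion are routed to
    clustering/fusion instead (they are one object seen twice, not a
    dancing pair). The ``physical`` flag marks events whose distance drops
    below ``d_interact`` for at least one second.
    """
    params = params or InteractionParams()
    trs = [tr for tr in iter_tracks(tracks) if tr.n_spots >= params.min_overlap_frames]
    events: list[InteractionEvent] = []
    for i in range(len(trs)):
        for j in range(i + 1, len(trs)):
            a, b = trs[i], trs[j]
            if (a.frames[-1] < b.frames[0] or b.frames[-1] < a.frames[0]):
                continue
            frames, ia, ib = _common_frames(a, b)
            if len(frames) < max(params.min_overlap_frames, 3):
                continue
            dist = np.hypot(a.x[ia] - b.x[ib], a.y[ia] - b.y[ib])
            if dist.min() > params.d_dance:
                continue
            t = a.t[ia]
            dt = np.median(np.diff(t))
            d1 = np.column_stack([np.diff(a.x[ia]), np.diff(a.y[ia])])
            d2 = np.column_stack([np.diff(b.x[ib]), np.diff(b.y[ib])])
            w = max(3, int(round(params.sync_window / dt)))
            sync = _rolling_sync(d1, d2, w)
            gate = (dist[:-1] <= params.d_dance) & (sync >= params.sync_min)
            gate = _close_gate_gaps(gate, dist[:-1] <= params.d_dance, t,
                                    params.sync_gap_tolerance)
            events.extend(_gate_runs_to_events(
                a, b, ia, ib, t, dist, sync, gate, params, mask))
    events.sort(key=lambda e: (e.t_start, e.member_track_ids))
    return events


def _close_gate_gaps(gate: np.ndarray, close_enough: np.ndarray,
                     t: np.ndarray, gap_tol_s: float) -> np.ndarray:
    """Bridge brief gate drop-outs inside a dancing window.

    The rolling synchrony estimate is noisy; a dip of less than
    ``gap_tol_s`` seconds between two qualifying stretches does not end the
    interaction as long as the pair stays within the distance envelope.
    """
    out = gate.copy()
    n = len(gate)
    i = 0
    while i < n:
        if out[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not out[j + 1]:
            j += 1
        interior = i > 0 and j < n - 1
        if interior and t[j + 1] - t[i] <= gap_tol_s \
                and close_enough[i:j + 1].all():
            out[i:j + 1] = True
        i = j + 1
    return out


def _gate_runs_to_events(a, b, ia, ib, t, dist, sync, gate, params, mask):
    """Convert maximal qualifying runs of one pair into events."""
    events = []
    n = len(gate)
    i = 0
    while i < n:
        if not gate[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and gate[j + 1]:
            j += 1
        t0, t1 = float(t[i]), float(t[j + 1])
        seg = slice(i, j + 2)
        min_d = float(dist[seg].min())
        # a dancing pair must actually come close at some point: windows
        # that never approach within d_interact are parallel travel, not
        # an interaction
        if t1 - t0 >= params.min_dance_duration and min_d < params.d_interact:
            # physical interaction: closer than d_interact for >= 1 s
            close = dist[seg] < params.d_interact
            dtm = float(np.median(np.diff(t[seg]))) if j + 1 > i else 0.0
            physical = bool(close.sum() * dtm >= 1.0)
            x0 = float((a.x[ia][i] + b.x[ib][i]) / 2.0)
            y0 = float((a.y[ia][i] + b.y[ib][i]) / 2.0)
            ev = _maybe_fusion_override(a, b, ia, ib, seg, t, params)
            if ev is not None:
                ev.x, ev.y = x0, y0
            else:
                if params.require_separation and not (
                        (dist[:i] > params.d_dance).any()
                        and (dist[j + 2:] > params.d_dance).any()):
                    # never seen apart on both sides: parallel travellers or
                    # a window truncated by the observation, not a complete
                    # approach-dance-departure cycle
                    i = j + 1
                    continue
                ev = InteractionEvent(
                    type="dancing", member_track_ids=(a.track_id, b.track_id),
                    t_start=t0, t_end=t1, min_distance=min_d,
                    sync_score=float(np.nanmean(sync[i:j + 1])),
                    physical=physical, x=x0, y=y0)
            if mask is not None:
                ev.zone = mask.zone_of((ev.x, ev.y))
            events.append(ev)
        i = j + 1
    return events


def _maybe_fusion_override(a, b, ia, ib, seg, t, params):
    """Within a candidate dancing window, a sustained intensity at the
    members' summed level means the pair already merged: route to fusion."""
    i1 = _pre_intensity(a, int(a.frames[ia[seg.start]]))
    i2 = _pre_intensity(b, int(b.frames[ib[seg.start]]))
    if np.isnan(i1) or np.isnan(i2):
        return None
    inten = np.fmax(a.intensity[ia][seg], b.intensity[ib][seg])
    valid = ~np.isnan(inten)
    if valid.sum() < 3:
        return None
    fused, mean_post = _sustained_sum(
        inten[valid], t[seg][valid], i1 + i2,
        params.fusion_intensity_ratio_tol, params.fusion_persistence)
    if not fused:
        return None
    return InteractionEvent(
        type="cluster_fusion", member_track_ids=(a.track_id, b.track_id),
        t_start=float(t[seg][0]), t_end=float(t[seg][-1]),
        min_distance=float("nan"),
        intensity_ratio=mean_post / min(i1, i2), physical=True)


# ---------------------------------------------------------------------------
# clustering / fusion detection
# ---------------------------------------------------------------------------


def detect_cluster_fusion(
    tracks: pd.DataFrame,
    params: InteractionParams | None = None,
    mask: RegionMask | None = None,
) -> list[InteractionEvent]:
    """Find clustering/fusion events by merge topology + intensity budget.

    Two patterns are recognised: (a) two member tracks end next to a track
    that starts at the next frames (fusion product), and (b) one member
    ends next to a continuing track. In both, the post-merge intensity must
    approximate the summed pre-merge member intensities within
    ``fusion_intensity_ratio_tol`` and stay there for
    ``fusion_persistence`` seconds (inferred spots are excluded). The
    reported intensity ratio is the post-merge intensity normalized to the
    dimmer member, mirroring normalization to one individual endosome.
    """
    params = params or InteractionParams()
    trs = list(iter_tracks(tracks))
    by_id = {tr.track_id: tr for tr in trs}
    gap_tol = 2  # frames between member end and product appearance

    candidates = []  # (t_merge, members, product, mean_post, ratio, xy)
    # pattern (a): dedicated product track
    for prod in trs:
        f0 = prod.frames[0]
        enders = [m for m in trs
                  if m.track_id != prod.track_id
                  and 0 < f0 - m.frames[-1] <= gap_tol
                  and np.hypot(m.x[-1] - prod.x[0], m.y[-1] - prod.y[0])
                  <= params.d_interact]
        if len(enders) < 2:
            continue
        for i in range(len(enders)):
            for j in range(i + 1, len(enders)):
                cand = _fusion_intensity_check(
                    enders[i], enders[j], prod, prod.frames[0], params)
                if cand is not None:
                    candidates.append(cand)
    # pattern (b): merge into a continuing track
    for member in trs:
        fe = member.frames[-1]
        for cont in trs:
            if cont.track_id == member.track_id or cont.frames[0] >= fe \
                    or cont.frames[-1] <= fe + 1:
                continue
            k = np.searchsorted(cont.frames, fe)
            if k >= cont.n_spots:
                continue
            if np.hypot(member.x[-1] - cont.x[k], member.y[-1] - cont.y[k]) \
                    > params.d_interact:
                continue
            cand = _fusion_intensity_check(member, cont, cont, fe + 1, params)
            if cand is not None:
                candidates.append(cand)

    candidates.sort(key=lambda c: c[0])
    used: set[int] = set()
    events = []
    for t_merge, members, prod, ratio, t_end, xy in candidates:
        if any(m in used for m in members):
            continue
        used.update(members)
        ev = InteractionEvent(
            type="cluster_fusion", member_track_ids=members,
            t_start=t_merge, t_end=t_end, intensity_ratio=ratio,
            physical=True, product_track_id=prod, x=xy[0], y=xy[1])
        if mask is not None:
            ev.zone = mask.zone_of(xy)
        events.append(ev)
    return events


def _fusion_intensity_check(m1: Track, m2: Track, prod: Track,
                            merge_frame: int, params: InteractionParams):
    """Validate the intensity budget of a candidate merge."""
    pre1 = _pre_intensity(m1, merge_frame)
    pre2 = _pre_intensity(m2, merge_frame)
    if np.isnan(pre1) or np.isnan(pre2):
        return None
    sel = prod.frames >= merge_frame
    post = prod.intensity[sel]
    tpost = prod.t[sel]
    valid = ~np.isnan(post)
    if valid.sum() < 3:
        return None
    ok, mean_post = _sustained_sum(post[valid], tpost[valid], pre1 + pre2,
                                   params.fusion_intensity_ratio_tol,
                                   params.fusion_persistence)
    if not ok:
        return None
    t_merge = float(tpost[0])
    xy = (float(prod.x[sel][0]), float(prod.y[sel][0]))
    return (t_merge, (m1.track_id, m2.track_id), prod.track_id,
            mean_post / min(pre1, pre2), float(prod.t[-1]), xy)


# ---------------------------------------------------------------------------
# population composition and event rates
# ---------------------------------------------------------------------------


def classify_population(
    tracks: pd.DataFrame,
    events: list[InteractionEvent],
    mask: RegionMask | None = None,
) -> dict:
    """Label every track individual / dancing / clustered and count them.

    A track in any clustering/fusion event (member or product) is
    *clustered*; otherwise a track in any dancing event is *dancing*;
    the rest are *individual* (fusion takes precedence). The endosome
    population size is the number of tracks present in the first frame
    within the tip-ROI (all first-frame tracks when no mask is given).
    """
    clustered: set = set()
    dancing: set = set()
    for e in events:
        target = clustered if e.type == "cluster_fusion" else dancing
        target.update(e.member_track_ids)
        if e.type == "cluster_fusion" and e.product_track_id >= 0:
            clustered.add(e.product_track_id)
    dancing -= clustered
    labels = {}
    population = 0
    for tr in iter_tracks(tracks):
        if tr.track_id in clustered:
            labels[tr.track_id] = "clustered"
        elif tr.track_id in dancing:
            labels[tr.track_id] = "dancing"
        else:
            labels[tr.track_id] = "individual"
        if tr.frames[0] == 0:
            xy = (tr.x[0], tr.y[0])
            if mask is None or mask.in_tip_roi(xy):
                population += 1
    counts = {"individual": 0, "dancing": 0, "clustered": 0}
    for lab in labels.values():
        counts[lab] += 1
    counts["population_first_frame"] = population
    counts["labels"] = labels
    return counts


def event_rates(
    events: list[InteractionEvent],
    mask: RegionMask,
    observation_duration: float,
) -> dict:
    """Events per second per zone, split by type.

    The zone of an event is that of its mean member position at onset.
    """
    if observation_duration <= 0:
        raise ValueError("observation_duration must be positive")
    rates = {z: {"dancing": 0.0, "cluster_fusion": 0.0}
             for z in ("apical", "subapical")}
    for e in events:
        zone = e.zone or mask.zone_of((e.x, e.y))
        rates[zone][e.type] += 1.0
    for z in rates:
        for k in rates[z]:
            rates[z][k] /= observation_duration
    return rates
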