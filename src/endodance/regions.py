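"""Root-hair coordinate frames, zone masks and tip growth rate.

The root hair is a tube growing at its tip. All zone definitions are
arc-length distances measured *below the tip* along the hair axis:

* apical zone: the first ``apical_length`` micrometres below the tip
  (default 10 um), subapical the rest of the hair;
* tip-ROI: the first ``tip_roi_length`` micrometres (default 30 um), the
  window inside which the endosome population is counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import LineString, Point

APICAL_LENGTH_UM = 10.0
TIP_ROI_LENGTH_UM = 30.0

#: integer labels used in :class:`RegionMask` arrays
OUTSIDE, APICAL, SUBAPICAL = 0, 1, 2


@dataclass
class AxisFrame:
    """Arc-length parameterization of the root-hair axis.

    ``points`` is an ordered polyline in micrometres whose *first* vertex is
    the hair tip, so the arc-length coordinate of any position is its
    distance below the tip.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValueError("axis polyline needs >= 2 (x, y) points")
        self._line = LineString(self.points)

    @property
    def tip_point(self) -> np.ndarray:
        return self.points[0]

    @property
    def length(self) -> float:
        return self._line.length

    def distance_below_tip(self, xy) -> np.ndarray:
        """Arc-length distance below the tip for one or many (x, y) positions.

        Positions are projected orthogonally onto the axis polyline; the tip
        maps to 0 and distances are always non-negative.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = np.array([self._line.project(Point(p)) for p in xy])
        return d if d.size > 1 else d[0:1].reshape(())


@dataclass
class RegionMask:
    """Per-pixel zone labels (apical / subapical / outside) plus the tip-ROI.

    ``labels`` uses :data:`APICAL`, :data:`SUBAPICAL`, :data:`OUTSIDE`;
    ``tip_roi`` flags in-hair pixels within ``tip_roi_length`` of the tip.
    """

    labels: np.ndarray
    tip_roi: np.ndarray
    pixel_size: float
    axis: AxisFrame
    apical_length: float = APICAL_LENGTH_UM
    tip_roi_length: float = TIP_ROI_LENGTH_UM
    meta: dict = field(default_factory=dict)

    def zone_of(self, xy) -> str:
        """Zone name for a physical position (um), via the axis coordinate.

        Uses the axis directly rather than the rasterized mask so that
        positions between pixel centres resolve unambiguously.
        """
        d = float(np.asarray(self.axis.distance_below_tip(xy)).ravel()[0])
        return "apical" if d <= self.apical_length else "subapical"

    def in_tip_roi(self, xy) -> bool:
        d = float(np.asarray(self.axis.distance_below_tip(xy)).ravel()[0])
        return d <= self.tip_roi_length


def make_zone_mask(
    frame_shape: tuple[int, int],
    axis: AxisFrame,
    hair_mask: np.ndarray,
    pixel_size: float,
    apical_length: float = APICAL_LENGTH_UM,
    tip_roi_length: float = TIP_ROI_LENGTH_UM,
) -> RegionMask:
    """Label every in-hair pixel apical or subapical and flag the tip-ROI.

    Parameters
    ----------
    frame_shape : (H, W)
    axis : AxisFrame
        Hair axis in micrometres, tip first. Must lie inside the frame.
    hair_mask : bool ndarray, shape (H, W)
        Pixels belonging to the hair (synthetic geometry mask or a
        user-supplied outline); the apical/subapical partition covers
        exactly these pixels.
    pixel_size : float
        um per pixel; pixel centres sit at ``index * pixel_size``.
    """
    h, w = frame_shape
    pts = axis.points / pixel_size
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1):
        raise ValueError("axis polyline exits the frame")
    hair_mask = np.asarray(hair_mask, dtype=bool)
    if hair_mask.shape != (h, w):
        raise ValueError("hair_mask shape does not match frame_shape")

    rows, cols = np.nonzero(hair_mask)
    xy = np.column_stack([cols, rows]).astype(float) * pixel_size
    labels = np.full((h, w), OUTSIDE, dtype=np.uint8)
    tip_roi = np.zeros((h, w), dtype=bool)
    if rows.size:
        d = np.asarray(axis.distance_below_tip(xy)).ravel()
        labels[rows, cols] = np.where(d <= apical_length, APICAL, SUBAPICAL)
        tip_roi[rows, cols] = d <= tip_roi_length
    return RegionMask(labels, tip_roi, pixel_size, axis, apical_length, tip_roi_length)


def growth_rate(times_s, tip_um) -> float:
    """Tip elongation rate in um/min from a series of tip positions.

    Least-squares slope of tip arc-length position versus time. Invariant
    to uniform time translation and to rigid coordinate translation.

    Parameters
    ----------
    times_s : array-like
        Sampling times in seconds, strictly increasing.
    tip_um : array-like
        Tip positions along the growth axis, in micrometres.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(tip_um, dtype=float)
    if t.size < 2 or t.size != y.size:
        raise ValueError("need >= 2 matched (time, position) samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sampling times must be strictly increasing")
    slope_um_per_s = stats.linregress(t, y).slope
    return float(slope_um_per_s * 60.0)
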