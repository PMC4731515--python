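"""Endosome size from FWHM of normalized intensity profiles.

Near the resolution limit, apparent size is measured as the full width at
half maximum of a background-subtracted, min-max-normalized intensity
profile drawn across the particle. The width is taken between the *first*
and *last* half-maximum crossings, so a two-peaked ring profile (a late
endosome imaged as a hollow shell) yields its outer extent; the
peak-to-peak distance is recorded as an auxiliary metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .io import ImageStack


@dataclass
class SizeRecord:
    particle_ref: int
    fwhm_nm: float
    n_peaks: int
    peak_to_peak_nm: float       # distance between outermost peaks (0 if unimodal)
    positions_nm: np.ndarray     # sample positions along the profile
    profile: np.ndarray          # normalized intensity (max 1)


def _spline_profile(img: np.ndarray, center_px, direction, length_px, step_px):
    """Sample the image along a line segment by cubic-spline interpolation.

    Linear interpolation broadens a near-resolution Gaussian by ~2% at
    sigma = 2 px; a cubic spline keeps the profile faithful to ~0.1%.
    """
    d = np.asarray(direction, dtype=float)
    d /= np.hypot(*d)
    s = np.arange(-length_px / 2.0, length_px / 2.0 + step_px / 2.0, step_px)
    xs = center_px[0] + s * d[0]
    ys = center_px[1] + s * d[1]
    vals = ndimage.map_coordinates(img, np.vstack([ys, xs]), order=3,
                                   mode="nearest")
    return s, vals


def fwhm_profile(
    frame: ImageStack | np.ndarray,
    center_um,
    direction=(1.0, 0.0),
    length_um: float = 1.5,
    pixel_size: float | None = None,
    particle_ref: int = -1,
) -> SizeRecord:
    """Measure one particle's FWHM from a linear intensity profile.

    The profile is sampled at ``pixel_size / 4`` steps by cubic-spline
    interpolation, background-subtracted (median of the profile endpoints),
    normalized to its fitted peak, and the FWHM taken between the first and
    last 0.5 crossings (linear interpolation between samples). Profiles
    that never cross half maximum (flat or saturated) are rejected.
    """
    if isinstance(frame, ImageStack):
        img = frame.frame(0)
        pixel_size = frame.pixel_size if pixel_size is None else pixel_size
    else:
        img = np.asarray(frame, dtype=float)
        if pixel_size is None:
            raise ValueError("pixel_size required for bare arrays")
    step_px = 0.25
    center_px = (center_um[0] / pixel_size, center_um[1] / pixel_size)
    s, vals = _spline_profile(img, center_px, direction,
                                length_um / pixel_size, step_px)

    # background: median of the three outermost samples on each side
    bkg = float(np.median(np.concatenate([vals[:3], vals[-3:]])))
    prof = vals - bkg
    # peak amplitude by a local quadratic fit (robust to per-sample noise)
    imax = int(np.argmax(prof))
    half_w = max(2, int(round(1.0 / step_px / 2)))  # +/- half a pixel
    lo, hi = max(imax - half_w, 0), min(imax + half_w + 1, len(prof))
    if hi - lo >= 3:
        coef = np.polyfit(s[lo:hi], prof[lo:hi], 2)
        peak = float(np.polyval(coef, -coef[1] / (2 * coef[0]))) \
            if coef[0] < 0 else float(prof[imax])
        peak = max(peak, float(prof[imax]) * 0.8)
    else:
        peak = float(prof[imax])
    if peak <= 0:
        raise ValueError("flat profile: no intensity above background")
    prof = prof / peak

    above = prof >= 0.5
    if not above.any() or above.all():
        raise ValueError("profile has no half-maximum crossing "
                         "(flat or saturated)")
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    if i0 == 0 or i1 == len(prof) - 1:
        raise ValueError("half-maximum crossing lies outside the profile; "
                         "increase length_um")

    def crossing(ia, ib):  # linear interpolation of the 0.5 crossing
        f = (0.5 - prof[ia]) / (prof[ib] - prof[ia])
        return s[ia] + f * (s[ib] - s[ia])

    left = crossing(i0 - 1, i0)
    right = crossing(i1 + 1, i1)
    fwhm_nm = abs(right - left) * pixel_size * 1000.0

    pk, _ = find_peaks(prof, height=0.5, prominence=0.15)
    n_peaks = max(1, len(pk))
    p2p = 0.0
    if len(pk) >= 2:
        p2p = (s[pk[-1]] - s[pk[0]]) * pixel_size * 1000.0
    return SizeRecord(particle_ref, float(fwhm_nm), int(n_peaks), float(p2p),
                      s * pixel_size * 1000.0, prof)


def size_distribution(records, bin_width: float = 20.0) -> dict:
    """Histogram and summary statistics of measured sizes.

    ``records`` may be :class:`SizeRecord` objects or plain diameters (nm).
    Returns mean, sd (ddof=1, 0 for n=1), min, max, n and the histogram
    (counts, bin edges). Rejects empty input.
    """
    vals = np.asarray([r.fwhm_nm if isinstance(r, SizeRecord) else float(r)
                       for r in records], dtype=float)
    if vals.size == 0:
        raise ValueError("no size records")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n": int(vals.size),
        "counts": counts,
        "bin_edges": edges,
    }
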