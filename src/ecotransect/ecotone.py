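"""Ecotone geometry from fuzzy-membership profiles.

A cluster's membership values along the transect are regressed on distance
with a cubic smoothing spline; the transitions between cluster plateaus are
then read off the derivatives of the smooth:

* location  — position of a local maximum of |f'| (the steepest point),
* slope     — the value of |f'| there (abruptness, 1/km),
* transition width — the distance between the two flanking extrema of f''
  that bracket the steepest point (for a logistic edge of scale s this is
  2 s ln((3+sqrt(3))/(3-sqrt(3))) ~= 2.634 s),
* patch widths — distances between consecutive |f'| extrema, a proxy for
  the extent of the plateaus on either side of the boundary.

Smoothing uses generalized cross-validation by default; for short profiles
(the 8 community stations) the equivalent degrees of freedom are capped at
n - 2 to avoid interpolation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline
from scipy.signal import argrelextrema, find_peaks

from .errors import ConfigurationError

__all__ = [
    "MembershipProfile",
    "TransitionRecord",
    "smooth_profile",
    "detect_transitions",
    "pair_transitions",
    "boundaries_from_records",
]


@dataclass
class MembershipProfile:
    """Smoothed membership-vs-distance curve with analytic derivatives."""

    cluster_id: str
    grid: np.ndarray
    values: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    spline: BSpline
    smoother: dict


@dataclass
class TransitionRecord:
    """One detected boundary on a membership profile."""

    cluster_id: str
    location: float  # km, argmax of |f'|
    slope: float  # 1/km, max |f'|
    direction: int  # +1 rising edge, -1 falling edge
    transition_width: float  # km between flanking f'' extrema
    patch_width_left: float  # km to previous |f'| extremum (nan at ends)
    patch_width_right: float
    prominence: float


def _hat_edf(x: np.ndarray, lam: float) -> float:
    """Trace of the smoothing-spline hat matrix (equivalent df) at lam."""
    n = x.size
    tr = 0.0
    e = np.zeros(n)
    for j in range(n):
        e[j] = 1.0
        tr += make_smoothing_spline(x, e, lam=lam)(x[j])
        e[j] = 0.0
    return float(tr)


def _gcv_spline(x: np.ndarray, y: np.ndarray, max_edf: float | None) -> tuple[BSpline, dict]:
    """Explicit GCV over a log-spaced lambda grid with an edf ceiling.

    Used for short profiles, where the hat matrix is cheap and the edf cap
    matters; long, dense profiles go through scipy's built-in GCV.
    """
    n = x.size
    span = x[-1] - x[0]
    lams = np.geomspace(1e-8 * span**3, 1e3 * span**3, 40)
    best = None
    for lam in lams:
        edf = _hat_edf(x, lam)
        if max_edf is not None and edf > max_edf:
            continue
        spl = make_smoothing_spline(x, y, lam=lam)
        rss = float(np.sum((y - spl(x)) ** 2))
        denom = max(n - edf, 1e-6)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, edf, spl)
    if best is None:  # every lambda exceeded the cap: take the smoothest
        lam = lams[-1]
        best = (np.inf, lam, _hat_edf(x, lam), make_smoothing_spline(x, y, lam=lam))
    _, lam, edf, spl = best
    return spl, {"lam": float(lam), "edf": float(edf)}


def smooth_profile(
    positions,
    memberships,
    cluster_id: str = "",
    grid_step: float = 0.05,
    lam: float | None = None,
    max_edf: float | None = None,
    small_n: int = 30,
) -> MembershipProfile:
    """Fit a cubic smoothing spline to membership vs distance.

    ``lam=None`` selects the penalty by generalized cross-validation.  For
    profiles with fewer than ``small_n`` support points the GCV search is
    done explicitly with the equivalent degrees of freedom capped at
    ``max_edf`` (default n - 2).  Derivatives are evaluated analytically on
    a dense grid (step <= 0.1 km) spanning the data range only — no
    extrapolation.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(memberships, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ConfigurationError("positions and memberships must be equal-length 1-D")
    if x.size < 4:
        raise ConfigurationError("need at least 4 support points to smooth a profile")
    if np.any(np.diff(x) <= 0):
        raise ConfigurationError("positions must be strictly increasing")
    if y.min() < -1e-9 or y.max() > 1 + 1e-9:
        raise ConfigurationError("memberships must lie in [0, 1]")
    if grid_step > 0.1:
        raise ConfigurationError("derivative grid step must be <= 0.1 km")

    if lam is not None:
        spl = make_smoothing_spline(x, y, lam=lam)
        smoother = {"lam": float(lam), "edf": None, "method": "fixed"}
    elif x.size < small_n:
        cap = (x.size - 2.0) if max_edf is None else max_edf
        spl, info = _gcv_spline(x, y, cap)
        smoother = {**info, "method": "gcv_capped"}
    else:
        spl = make_smoothing_spline(x, y, lam=None)
        smoother = {"lam": None, "edf": None, "method": "gcv"}

    grid = np.arange(x[0], x[-1] + grid_step / 2, grid_step)
    grid = np.clip(grid, x[0], x[-1])
    vals = np.clip(spl(grid), 0.0, 1.0)
    d1 = spl.derivative(1)(grid)
    d2 = spl.derivative(2)(grid)
    return MembershipProfile(cluster_id, grid, vals, d1, d2, spl, smoother)


def _flanking_extrema(d2_signed: np.ndarray, i_peak: int) -> tuple[int | None, int | None]:
    """Indices of the f'' maximum before and minimum after a (sign-corrected)
    rising edge peak of f'."""
    maxima = argrelextrema(d2_signed, np.greater_equal, order=2)[0]
    minima = argrelextrema(d2_signed, np.less_equal, order=2)[0]
    # the bracketing extrema are the nearest ones of the correct sign:
    # curvature is positive approaching a rising edge and negative leaving it
    left = maxima[(maxima < i_peak) & (d2_signed[maxima] > 0)]
    right = minima[(minima > i_peak) & (d2_signed[minima] < 0)]
    il = int(left[-1]) if left.size else None
    ir = int(right[0]) if right.size else None
    return il, ir


def detect_transitions(
    profile: MembershipProfile, min_prominence: float = 0.05
) -> list[TransitionRecord]:
    """Locate boundaries as prominent local extrema of the first derivative.

    Prominence is measured in membership units: a |f'| peak is kept when the
    membership change it mediates (peak slope x local width, bounded by the
    profile's own range) exceeds ``min_prominence``.  For each kept extremum
    the two flanking second-derivative extrema bracket the transition; the
    distances to neighbouring |f'| extrema give the flanking patch widths.
    Records are sorted by location.  No qualifying extremum -> empty list.
    """
    g, d1, d2 = profile.grid, profile.d1, profile.d2
    step = g[1] - g[0]
    records: list[TransitionRecord] = []

    # membership rise/fall across an edge ~ integral of f' between the
    # surrounding zero-ish crossings; approximate prominence via peak
    # prominence of f' scaled to membership units using peak width.
    all_ext: list[tuple[int, int]] = []  # (grid index, direction)
    for sign in (+1, -1):
        peaks, _ = find_peaks(sign * d1, height=0.0)
        all_ext.extend((int(p), sign) for p in peaks)
    all_ext.sort()

    kept: list[tuple[int, int, float]] = []
    for i_peak, sign in all_ext:
        sig = sign * d1
        # membership swing mediated by this edge: integrate the sign-corrected
        # derivative over the lobe around the peak (out to its zero crossings)
        left_stop = i_peak
        while left_stop > 0 and sig[left_stop - 1] > 0:
            left_stop -= 1
        right_stop = i_peak
        while right_stop < g.size - 1 and sig[right_stop + 1] > 0:
            right_stop += 1
        seg = slice(left_stop, right_stop + 1)
        swing = float(np.trapezoid(sig[seg], g[seg]))
        if swing >= min_prominence:
            kept.append((i_peak, sign, swing, left_stop))

    # collapse multiple peaks inside one derivative lobe to the steepest
    by_lobe: dict[tuple[int, int], tuple[int, int, float]] = {}
    for i_peak, sign, swing, lobe in kept:
        key = (sign, lobe)
        if key not in by_lobe or abs(d1[i_peak]) > abs(d1[by_lobe[key][0]]):
            by_lobe[key] = (i_peak, sign, swing)
    kept = sorted(by_lobe.values())

    for pos, (i_peak, sign, swing) in enumerate(kept):
        il, ir = _flanking_extrema(sign * d2, i_peak)
        if il is None or ir is None:
            continue
        width = float(g[ir] - g[il])
        if width <= 0:
            continue
        pw_left = float(g[i_peak] - g[kept[pos - 1][0]]) if pos > 0 else float("nan")
        pw_right = (
            float(g[kept[pos + 1][0]] - g[i_peak]) if pos + 1 < len(kept) else float("nan")
        )
        records.append(
            TransitionRecord(
                cluster_id=profile.cluster_id,
                location=float(g[i_peak]),
                slope=float(abs(d1[i_peak])),
                direction=sign,
                transition_width=width,
                patch_width_left=pw_left,
                patch_width_right=pw_right,
                prominence=swing,
            )
        )
    records.sort(key=lambda r: r.location)
    return records


def pair_transitions(
    env: list[TransitionRecord],
    community: list[TransitionRecord],
    max_offset_km: float = 5.0,
) -> tuple[list[tuple[TransitionRecord, TransitionRecord, float]], list[TransitionRecord], list[TransitionRecord]]:
    """Greedy nearest-location matching of community to environmental boundaries.

    Pairs are formed in order of increasing |offset| until either list is
    exhausted or the remaining offsets exceed ``max_offset_km``; leftover
    records on both sides are returned as unmatched.
    """
    cands = sorted(
        ((abs(e.location - c.location), i, j) for i, e in enumerate(env) for j, c in enumerate(community)),
        key=lambda t: t[0],
    )
    used_e: set[int] = set()
    used_c: set[int] = set()
    pairs = []
    for off, i, j in cands:
        if off > max_offset_km:
            break
        if i in used_e or j in used_c:
            continue
        pairs.append((env[i], community[j], env[i].location - community[j].location))
        used_e.add(i)
        used_c.add(j)
    un_e = [e for i, e in enumerate(env) if i not in used_e]
    un_c = [c for j, c in enumerate(community) if j not in used_c]
    return pairs, un_e, un_c


def boundaries_from_records(
    records_by_cluster: dict[str, list[TransitionRecord]],
    order: list[str],
    max_gap_km: float = 8.0,
) -> list[dict]:
    """Boundary estimates between spatially consecutive clusters.

    For each adjacent pair (A, B) in spatial ``order``, a falling edge of A
    is matched with a rising edge of B no further than ``max_gap_km`` away,
    preferring the pair whose weaker member has the largest prominence (noise
    wiggles pair up as easily as real edges if gap alone decides); the
    boundary location is the mean of the two edge locations and the boundary
    slope/width the mean of the two records'.  With no valid pair the most
    prominent single edge is used.
    """
    out = []
    for a, b in zip(order, order[1:]):
        falls = [r for r in records_by_cluster.get(a, []) if r.direction < 0]
        rises = [r for r in records_by_cluster.get(b, []) if r.direction > 0]
        best = None
        for rf in falls:
            for rr in rises:
                gap = abs(rf.location - rr.location)
                if gap > max_gap_km:
                    continue
                score = (min(rf.prominence, rr.prominence), -gap)
                if best is None or score > best[0]:
                    best = (score, rf, rr)
        if best is not None:
            _, rf, rr = best
            rec = {
                "pair": f"{a}|{b}",
                "location_km": 0.5 * (rf.location + rr.location),
                "slope_per_km": 0.5 * (rf.slope + rr.slope),
                "transition_width_km": 0.5 * (rf.transition_width + rr.transition_width),
            }
        elif falls or rises:
            r = max(falls + rises, key=lambda r: r.prominence)
            rec = {
                "pair": f"{a}|{b}",
                "location_km": r.location,
                "slope_per_km": r.slope,
                "transition_width_km": r.transition_width,
            }
        else:
            rec = {
                "pair": f"{a}|{b}",
                "location_km": float("nan"),
                "slope_per_km": float("nan"),
                "transition_width_km": float("nan"),
            }
        out.append(rec)
    return out
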