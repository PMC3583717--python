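"""Circumferential tissue spreading: measured from cross-sections, and the
coplanar-division theory it is compared against.

The embryo midpoint cross-section is treated as a circle; a tissue's spread at
a timepoint is the percentage of the circumference its cells occupy. The
theoretical curve assumes perfectly symmetric cell divisions oriented at an
angle theta to the A-P axis: a dividing cell's footprint stretches x2 along
the spindle (in-plane perpendicular x1, thickness x1/2, conserving volume), so
its circumferential extent grows by

    g(theta) = sqrt(4 sin^2(theta) + cos^2(theta)),

the circumferential semi-axis of the stretched unit footprint. g(0) = 1 (a
division along the A-P axis spreads nothing circumferentially), g(90) = 2
(pure circumferential doubling). Per division round the tissue spread is
multiplied by the mean of g over that round's divisions and capped at 100%.
This closed form is this package's reconstruction of the stated assumptions
(symmetric division, measured timings, mean spindle angle); see
docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class DivisionEvent:
    """One cell division: parent lineage name, time, spindle angle to the A-P axis."""

    parent: str
    time: float  # s
    angle: float  # degrees, folded into [0, 90]

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("division time must be >= 0")
        self.angle = fold_angle(self.angle)


def fold_angle(angle: float) -> float:
    """Fold an angle in degrees into [0, 90] (axis direction is unsigned)."""
    a = abs(float(angle)) % 180.0
    return 180.0 - a if a > 90.0 else a


@dataclass
class CrossSection:
    """Angular occupancy of tissues around the midpoint circumference at one time."""

    time: float  # s
    intervals: list  # of (tissue_label, theta_start_deg, theta_end_deg), within [0, 360)
    embryo: str = ""

    def __post_init__(self) -> None:
        for tissue, a, b in self.intervals:
            if not (0 <= a < 360 and 0 < b <= 360 and a < b):
                raise ValueError(
                    f"interval [{a}, {b}) for {tissue!r} must satisfy 0 <= start < end <= 360; "
                    "split wrap-around intervals at 360"
                )


@dataclass
class SpreadSeries:
    """Tissue spread (% of circumference) over time, mean +/- SD across embryos."""

    times: np.ndarray  # s
    spread: np.ndarray  # %
    sd: np.ndarray  # %
    tissue: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any((self.spread < -1e-9) | (self.spread > 100 + 1e-9)):
            raise ValueError("spread must lie in [0, 100] %")
        if np.any(self.sd < -1e-9):
            raise ValueError("SD must be non-negative")


def _merge_extent(intervals: list[tuple[float, float]], tissue: str) -> float:
    """Total angular extent of a set of [start, end) intervals, merging overlaps."""
    if not intervals:
        return 0.0
    ivs = sorted(intervals)
    total = 0.0
    cur_a, cur_b = ivs[0]
    overlapped = False
    for a, b in ivs[1:]:
        if a < cur_b:  # overlap
            overlapped = True
            cur_b = max(cur_b, b)
        else:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
    total += cur_b - cur_a
    if overlapped:
        warnings.warn(f"overlapping {tissue!r} intervals merged", stacklevel=3)
    return total


def measured_spread(sections: Sequence[CrossSection], tissue: str) -> SpreadSeries:
    """Measured circumferential spread of one tissue over time.

    Per timepoint the angular extents of all intervals carrying the tissue
    label (both lateral halves) are summed and expressed as % of 360 degrees;
    sections from multiple embryos at the same timepoint are aggregated as
    mean +/- SD.
    """
    if not sections:
        raise ValueError("no cross-sections given")
    per_time: dict[float, list[float]] = {}
    for sec in sections:
        ivs = [(a, b) for lab, a, b in sec.intervals if lab == tissue]
        if not ivs:
            warnings.warn(f"tissue {tissue!r} absent from section at t={sec.time}; spread 0%", stacklevel=2)
        pct = _merge_extent(ivs, tissue) / 360.0 * 100.0
        per_time.setdefault(sec.time, []).append(pct)
    times = np.array(sorted(per_time))
    means = np.array([np.mean(per_time[t]) for t in times])
    sds = np.array([np.std(per_time[t], ddof=1) if len(per_time[t]) > 1 else 0.0 for t in times])
    return SpreadSeries(times, means, sds, tissue=tissue)


def g_factor(angle_deg) -> np.ndarray | float:
    """Circumferential growth factor of one symmetric division at spindle angle theta."""
    a = np.radians(np.vectorize(fold_angle)(angle_deg).astype(float)) if np.ndim(angle_deg) else np.radians(fold_angle(angle_deg))
    return np.sqrt(4.0 * np.sin(a) ** 2 + np.cos(a) ** 2)


def theoretical_spread(
    initial_spread: float,
    divisions: Sequence[DivisionEvent],
    times: Sequence[float],
    mean_angle: float | None = None,
    tissue: str = "",
) -> SpreadSeries:
    """Theoretical spread under coplanar symmetric divisions.

    Division timing is taken from the supplied events; per round (unique
    division time) the spread is multiplied by the mean of g(theta) over that
    round's events — or by g(mean_angle) for every round when ``mean_angle``
    is given (the fixed-mean-angle mode, e.g. 36 degrees) — and capped at
    100%.
    """
    if not (0 < initial_spread <= 100):
        raise ValueError("initial_spread must lie in (0, 100]")
    times = np.asarray(times, dtype=float)
    div_times = sorted({d.time for d in divisions})
    if list(d.time for d in divisions) != sorted(d.time for d in divisions):
        raise ValueError("divisions must be sorted by time")
    spread = np.full(len(times), float(initial_spread))
    value = float(initial_spread)
    for t_div in div_times:
        if mean_angle is not None:
            factor = float(g_factor(mean_angle))
        else:
            gs = [float(g_factor(d.angle)) for d in divisions if d.time == t_div]
            factor = float(np.mean(gs))
        value = min(value * factor, 100.0)
        spread[times >= t_div] = value
    return SpreadSeries(times, spread, np.zeros_like(spread), tissue=tissue)


def compare_spread(measured: SpreadSeries, theoretical: SpreadSeries) -> tuple[np.ndarray, np.ndarray, float]:
    """Residuals (measured - theoretical) on the measured time grid, and their RMS (%).

    The theoretical series is interpolated linearly onto the measured times;
    only the overlapping time range is compared. No hypothesis test is
    attached — the comparison is a descriptive overlay.
    """
    lo = max(measured.times[0], theoretical.times[0])
    hi = min(measured.times[-1], theoretical.times[-1])
    if lo > hi:
        raise ValueError("measured and theoretical series cover disjoint time ranges")
    mask = (measured.times >= lo) & (measured.times <= hi)
    t = measured.times[mask]
    resid = measured.spread[mask] - np.interp(t, theoretical.times, theoretical.spread)
    rms = float(np.sqrt(np.mean(resid**2)))
    return t, resid, rms
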