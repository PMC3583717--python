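"""Time-shifted coupling between cortical contraction intensity and extension advancement.

During internalisation, contraction pulses of the apical actomyosin cortex are
followed — after a lag of roughly 20 s attributed to cortex viscoelasticity —
by advancement of the neighbouring cells' extensions. This module quantifies
that coupling: traces are normalised (intensity to its maximum, extension to
its final tip position), and a lag scan fits extension position against
intensity shifted by each candidate lag, reporting r^2 per lag and the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .morpho import Outline


def _check_uniform_times(times: np.ndarray, what: str) -> float:
    diffs = np.diff(times)
    if len(times) < 2 or np.any(diffs <= 0):
        raise ValueError(f"{what}: times must be strictly increasing")
    if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{what}: times must be uniformly spaced")
    return float(diffs[0])


@dataclass
class IntensityTrace:
    """Integrated local fluorescence intensity over time (AU)."""

    times: np.ndarray  # s, uniform
    values: np.ndarray  # AU
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        self.dt = _check_uniform_times(self.times, "intensity trace")
        if self.normalized and not np.isclose(self.values.max(), 1.0):
            raise ValueError("normalized intensity must have max 1")


@dataclass
class ExtensionTrace:
    """Extension tip position over time (um, or fraction of final position)."""

    times: np.ndarray  # s, uniform
    tip_position: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tip_position = np.asarray(self.tip_position, dtype=float)
        if len(self.times) != len(self.tip_position):
            raise ValueError("times and tip_position must have equal length")
        self.dt = _check_uniform_times(self.times, "extension trace")
        if self.normalized and not np.isclose(self.tip_position[-1], 1.0):
            raise ValueError("normalized extension must end at 1")


@dataclass
class LagScan:
    """r^2 of the extension-vs-lagged-intensity fit over a lag grid."""

    lags: np.ndarray  # s
    r_squared: np.ndarray
    peak_lag: float  # s
    peak_r2: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.r_squared = np.asarray(self.r_squared, dtype=float)
        if np.any((self.r_squared < -1e-9) | (self.r_squared > 1 + 1e-9)):
            raise ValueError("r_squared values must lie in [0, 1]")
        if not np.isclose(self.peak_r2, np.nanmax(self.r_squared)):
            raise ValueError("peak_r2 must equal max(r_squared)")

    def r2_at(self, lag: float) -> float:
        """r^2 at the grid lag closest to ``lag`` (must be on the grid)."""
        i = int(np.argmin(np.abs(self.lags - lag)))
        if not np.isclose(self.lags[i], lag, atol=1e-6):
            raise ValueError(f"lag {lag} s is not on the scanned grid")
        return float(self.r_squared[i])


def normalize_traces(i: IntensityTrace, e: ExtensionTrace) -> tuple[IntensityTrace, ExtensionTrace]:
    """Apply the standard normalisation conventions to a paired trace set.

    Intensity is divided by its maximum; extension position is divided by its
    final value so the tip ends at 1. A constant extension trace has no
    defined final-position scale and is rejected.
    """
    if len(i.values) == 0 or len(e.tip_position) == 0:
        raise ValueError("traces must be non-empty")
    imax = i.values.max()
    if imax <= 0:
        raise ValueError("intensity maximum must be positive for normalisation")
    if np.isclose(e.tip_position[-1], e.tip_position[0]):
        raise ValueError("constant extension trace: final-position normalisation undefined")
    ni = IntensityTrace(i.times, i.values / imax, normalized=True)
    ne = ExtensionTrace(e.times, e.tip_position / e.tip_position[-1], normalized=True)
    return ni, ne


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation = r^2 of the simple linear fit."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def lag_scan(
    i: IntensityTrace,
    e: ExtensionTrace,
    lag_grid: Sequence[float] | None = None,
    max_lag: float = 60.0,
    allow_negative: bool = False,
    min_overlap: int = 10,
    use_velocity: bool = False,
) -> LagScan:
    """Scan candidate lags and fit extension against lagged intensity.

    For each lag tau the extension value at time t is regressed against the
    intensity at (t - tau) over the overlapping window, and r^2 of the linear
    fit recorded. Positive lags mean intensity leads extension. Ties in the
    peak are broken toward the smaller lag. Lags that are not multiples of the
    sampling interval are handled by linear interpolation of the intensity
    trace.

    Extension *position* is regressed by default; ``use_velocity=True``
    switches to per-step advancement increments.
    """
    if not np.allclose(i.dt, e.dt):
        raise ValueError("traces must share one sampling interval")
    dt = i.dt
    if lag_grid is None:
        lo = -max_lag if allow_negative else 0.0
        lag_grid = np.arange(lo, max_lag + dt / 2, dt)
    lags = np.asarray(lag_grid, dtype=float)

    y_full = np.diff(e.tip_position) if use_velocity else e.tip_position
    t_y = e.times[1:] if use_velocity else e.times

    r2s = np.empty(len(lags))
    for k, tau in enumerate(lags):
        t_query = t_y - tau
        ok = (t_query >= i.times[0] - 1e-9) & (t_query <= i.times[-1] + 1e-9)
        if ok.sum() < min_overlap:
            raise ValueError(
                f"lag {tau:g} s leaves {int(ok.sum())} overlapping samples; "
                f"at least {min_overlap} are required"
            )
        x = np.interp(t_query[ok], i.times, i.values)
        r2s[k] = _r2(x, y_full[ok])
    peak_idx = int(np.argmax(r2s))  # argmax returns the first max: smaller lag wins ties
    return LagScan(lags=lags, r_squared=r2s, peak_lag=float(lags[peak_idx]), peak_r2=float(r2s[peak_idx]))


def advancement_from_outlines(
    outlines: Sequence[Outline],
    direction: Sequence[float],
    frame_interval: float,
) -> ExtensionTrace:
    """Extension-tip position per frame: maximal outline extent along a direction.

    ``direction`` is the advancement direction in the outline coordinate frame
    (um); the returned positions are the per-frame maxima of the vertex
    projections onto it.
    """
    if len(outlines) < 2:
        raise ValueError("need at least 2 outlines to form a trace")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    d = d / norm
    tips = np.array([float((o.vertices @ d).max()) for o in outlines])
    times = np.arange(len(outlines), dtype=float) * frame_interval
    return ExtensionTrace(times, tips)
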