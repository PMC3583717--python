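"""Shape morphometrics, covering-fraction kinetics and the bleb regression.

All polygon geometry is exact (shapely); a Monte-Carlo oracle is used only in
the test suite. Flatness is defined as ``1 - min_extent / max_extent`` over the
two in-section axes, bounded in [0, 1]; this definition is printed in every
CSV header this module writes so downstream users can audit it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from shapely.geometry import Polygon
from shapely.ops import unary_union

FLATNESS_DEFINITION = "flatness = 1 - (min axis extent / max axis extent)"


@dataclass
class Outline:
    """A closed simple 2-D polygon (cell apical boundary, bleb, covered region)."""

    vertices: np.ndarray  # (N, 2) um, ordered, not repeating the first point
    frame: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("an outline needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"outline {self.label!r} at frame {self.frame} is not a simple polygon")
        if poly.area <= 0:
            raise ValueError("outline must enclose a positive area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


@dataclass
class ShapeMeasure:
    """Apical/basolateral axis lengths and derived shape indices at one time."""

    time: float  # s
    apical: float  # um
    basolateral: float  # um
    ratio: float
    flatness: float

    def __post_init__(self) -> None:
        if self.apical <= 0 or self.basolateral <= 0:
            raise ValueError("axis lengths must be positive")
        if not (0 <= self.flatness <= 1):
            raise ValueError("flatness must lie in [0, 1]")


@dataclass
class RegressionResult:
    """Ordinary least-squares line fit with its goodness of fit."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_stderr: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a regression needs at least 2 points")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared must lie in [0, 1]")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the slope (t distribution, n-2 df)."""
        tcrit = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return (self.slope - tcrit * self.slope_stderr, self.slope + tcrit * self.slope_stderr)


def _extent(vertices: np.ndarray, direction: np.ndarray) -> float:
    """Extent of a polygon along a direction = extent of its vertex projections."""
    proj = vertices @ direction
    return float(proj.max() - proj.min())


def axis_ratio(outline: Outline, apical_direction: Sequence[float], time: float = 0.0) -> ShapeMeasure:
    """Apical and basolateral axis lengths of a cell cross-section.

    The apical axis is the outline's extent along ``apical_direction``; the
    basolateral axis is the extent along the in-section perpendicular. The
    ratio apical/basolateral tracks the cuboidal -> columnar -> cuboidal shape
    cycle of dividing surface cells.
    """
    d = np.asarray(apical_direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("apical direction must be a non-zero vector")
    d = d / norm
    perp = np.array([-d[1], d[0]])
    apical = _extent(outline.vertices, d)
    basolateral = _extent(outline.vertices, perp)
    if apical <= 0 or basolateral <= 0:
        raise ValueError("degenerate outline: zero extent along an axis")
    long_, short = max(apical, basolateral), min(apical, basolateral)
    return ShapeMeasure(
        time=time,
        apical=apical,
        basolateral=basolateral,
        ratio=apical / basolateral,
        flatness=1.0 - short / long_,
    )


def fit_ratio_timecourse(measures: Sequence[ShapeMeasure], degree: int = 3) -> tuple[np.ndarray, float]:
    """Least-squares polynomial fit of the axis ratio over time.

    Returns ``(coefficients, residual_sd)`` with coefficients in ascending
    order (constant term first). Repeated times are averaged before fitting,
    mirroring a mean-over-embryos curve.
    """
    if not measures:
        raise ValueError("no measurements given")
    times = np.array([m.time for m in measures], dtype=float)
    ratios = np.array([m.ratio for m in measures], dtype=float)
    uniq = np.unique(times)
    mean_ratio = np.array([ratios[times == t].mean() for t in uniq])
    if len(uniq) < degree + 1:
        raise ValueError(f"need at least {degree + 1} distinct timepoints for degree {degree}")
    # Vandermonde least squares; rank check guards against degenerate designs
    V = np.vander(uniq, degree + 1, increasing=True)
    coeffs, _, rank, _ = np.linalg.lstsq(V, mean_ratio, rcond=None)
    if rank < degree + 1:
        raise ValueError("rank-deficient design: timepoints do not support this degree")
    resid = mean_ratio - V @ coeffs
    dof = max(len(uniq) - (degree + 1), 1)
    return coeffs, float(np.sqrt(resid @ resid / dof))


def covering_fraction(target: Outline, covering: Sequence[Outline]) -> float:
    """Fraction of the target outline's area covered by the union of outlines.

    Used for the covering-of-endoderm kinetics: the target is the exposed
    apical surface of the internalising cells, the covering outlines are the
    extensions of the surrounding cells, all in one projected frame.
    """
    tgt = target.polygon
    if not covering:
        return 0.0
    union = unary_union([o.polygon for o in covering])
    return float(tgt.intersection(union).area / tgt.area)


def bleb_regression(events: Sequence) -> RegressionResult:
    """OLS of anterior translocation (um) on maximal bleb area (um^2).

    ``events`` may be BlebEvent objects (attributes ``area`` and
    ``translocation``) or (area, translocation) pairs.
    """
    if len(events) < 3:
        raise ValueError("need at least 3 bleb events for a regression")
    areas, trans = [], []
    for e in events:
        if hasattr(e, "area"):
            areas.append(e.area)
            trans.append(e.translocation)
        else:
            a, tr = e
            areas.append(a)
            trans.append(tr)
    areas = np.asarray(areas, dtype=float)
    trans = np.asarray(trans, dtype=float)
    if np.ptp(areas) == 0:
        raise ValueError("bleb areas have zero variance; slope is undefined")
    fit = stats.linregress(areas, trans)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(areas),
        slope_stderr=float(fit.stderr),
    )
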