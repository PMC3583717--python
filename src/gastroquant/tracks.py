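"""Migration-path analysis from lineage track tables.

Embryo coordinates follow the A-P / D-V / L-R convention: x is
anterior-posterior with anterior = +x, y is dorsal-ventral, z is left-right.
Lineage names use the binary a/p/l/r (and d/v) suffix nomenclature rooted at
founders such as AB, MS, E and P4.

Pairwise movement correlation uses per-step displacement increments along the
L/R axis by default: raw-position correlation is dominated by shared drift of
the whole embryo, whereas increments compare the cells' actual movements. A
positions mode is provided for comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

_NAME_RE = re.compile(r"^(AB|MS|E|C|D|P[0-4]|Z[23]|EMS|P)[aplrdv]*$")


def valid_lineage_name(name: str) -> bool:
    return bool(_NAME_RE.match(name))


@dataclass
class CellTrack:
    """One cell's 3-D centroid path in embryo axes, with its lineage identity."""

    name: str
    times: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # (N, 3) um: x=A-P (anterior +), y=D-V, z=L-R
    parent: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"track {self.name}: times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"track {self.name}: positions must be finite")
        if not valid_lineage_name(self.name):
            raise ValueError(f"{self.name!r} is not a valid lineage name")

    @property
    def birth(self) -> float:
        return float(self.times[0])

    @property
    def death(self) -> float:
        return float(self.times[-1])

    def at(self, t: float) -> np.ndarray:
        """Position at time t (must be a sampled timepoint)."""
        i = np.flatnonzero(np.isclose(self.times, t))
        if len(i) == 0:
            raise KeyError(f"track {self.name} has no sample at t={t}")
        return self.positions[i[0]]


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise movement correlations with a display clip."""

    names: list[str]
    values: np.ndarray  # correlations in [-1, 1]; NaN = undefined (short overlap)
    clip: float = 0.8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match the number of names")
        finite = np.isfinite(self.values)
        if np.any(np.abs(self.values[finite]) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(self.values[finite], self.values.T[finite], equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def clipped(self) -> np.ndarray:
        """Values clipped to +/-clip for heat-map display; stored values untouched."""
        return np.clip(self.values, -self.clip, self.clip)

    def plot(self, ax=None):
        """Render the clipped heat map (display only)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.clipped(), cmap="RdBu_r", vmin=-self.clip, vmax=self.clip)
        ax.set_xticks(range(len(self.names)), self.names, rotation=90, fontsize=6)
        ax.set_yticks(range(len(self.names)), self.names, fontsize=6)
        return im


def smooth_path(track: CellTrack, window: int = 5) -> CellTrack:
    """Centered moving average of each coordinate; width-5 default.

    Ends use shrinking (still centered) windows so the track keeps its length
    and timestamps.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd count >= 1")
    n = len(track.times)
    if window > n:
        raise ValueError(f"window {window} exceeds track length {n}")
    half = window // 2
    sm = np.empty_like(track.positions)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sm[i] = track.positions[lo:hi].mean(axis=0)
    return CellTrack(track.name, track.times.copy(), sm, parent=track.parent)


def _shared_times(a: CellTrack, b: CellTrack) -> np.ndarray:
    # exact matching on the sampled grid; lineaged data share one time base
    common = np.intersect1d(np.round(a.times, 6), np.round(b.times, 6))
    return common


def lr_correlation(a: CellTrack, b: CellTrack, use_increments: bool = True) -> float:
    """Pearson correlation of two cells' movement along the L/R axis.

    Computed over the time window in which both cells are present; returns
    NaN (undefined) when fewer than 3 shared timepoints exist. By default the
    per-step L/R displacement increments are correlated; with
    ``use_increments=False`` the raw L/R positions are used.
    """
    common = _shared_times(a, b)
    if len(common) < 3:
        return float("nan")
    za = np.array([a.at(t)[2] for t in common])
    zb = np.array([b.at(t)[2] for t in common])
    if use_increments:
        za, zb = np.diff(za), np.diff(zb)
    if np.ptp(za) == 0 or np.ptp(zb) == 0:
        return float("nan")
    return float(np.corrcoef(za, zb)[0, 1])


def _sister_name(name: str) -> str | None:
    """Sister = same name with the final a<->p (or l<->r, d<->v) suffix swapped."""
    swap = {"a": "p", "p": "a", "l": "r", "r": "l", "d": "v", "v": "d"}
    if name and name[-1] in swap:
        return name[:-1] + swap[name[-1]]
    return None


def combine_sisters(tracks: Sequence[CellTrack]) -> list[CellTrack]:
    """Average each sister pair's positions over shared times into one path.

    The combined path keeps the alphabetically first sister's name with a
    ``*`` marker; unpaired tracks pass through unchanged.
    """
    by_name = {t.name: t for t in tracks}
    out: list[CellTrack] = []
    done: set[str] = set()
    for t in tracks:
        if t.name in done:
            continue
        sis = _sister_name(t.name)
        if sis and sis in by_name and sis not in done:
            s = by_name[sis]
            common = _shared_times(t, s)
            if len(common) >= 2:
                pos = np.array([(t.at(tt) + s.at(tt)) / 2 for tt in common])
                first = min(t.name, s.name)
                out.append(CellTrack(first, common, pos, parent=t.parent))
                done.update({t.name, s.name})
                continue
        out.append(t)
        done.add(t.name)
    return out


def correlation_matrix(
    tracks: Sequence[CellTrack],
    clip: float = 0.8,
    use_increments: bool = True,
    combine_sister_pairs: bool = False,
) -> CorrelationMatrix:
    """All pairwise L/R movement correlations.

    The clip range only affects rendering; stored values are the raw
    coefficients. Pairs with under 3 shared timepoints are NaN.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    tr = combine_sisters(tracks) if combine_sister_pairs else list(tracks)
    n = len(tr)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = lr_correlation(tr[i], tr[j], use_increments=use_increments)
    return CorrelationMatrix([t.name for t in tr], mat, clip=clip)


def displacement_metrics(
    track: CellTrack,
    axis: Sequence[float],
    embryo_length: float,
    t0: float,
    t1: float,
) -> float:
    """Net displacement between t0 and t1 projected on an axis, as % embryo length.

    Positive values mean movement along +axis (e.g. anterior for the +x
    axis). This is the statistic behind statements such as a cell moving
    anteriorly by ~11% of the embryo length during rosette formation.
    """
    ax = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(ax)
    if norm == 0:
        raise ValueError("axis must be a non-zero vector")
    if embryo_length <= 0:
        raise ValueError("embryo_length must be positive")
    if not (track.birth <= t0 < t1 <= track.death):
        raise ValueError(f"window [{t0}, {t1}] outside track span [{track.birth}, {track.death}]")
    ax = ax / norm
    disp = track.at(t1) - track.at(t0)
    return float(disp @ ax / embryo_length * 100.0)


def embryo_length(tracks: Sequence[CellTrack], t0: float | None = None) -> float:
    """A-P extent of the bounding box of all track positions (at t0 if given)."""
    xs = []
    for t in tracks:
        if t0 is None:
            xs.append(t.positions[:, 0])
        else:
            try:
                xs.append(t.at(t0)[:1])
            except KeyError:
                continue
    if not xs:
        raise ValueError("no track positions available to measure embryo length")
    allx = np.concatenate(xs)
    return float(allx.max() - allx.min())


def _mirror_name(name: str) -> str:
    return name.translate(str.maketrans("lr", "rl"))


def midline_angle(
    left: Sequence[CellTrack],
    right: Sequence[CellTrack],
    t: float,
) -> float:
    """Angle (degrees) between the fitted left/right midline and the A-P axis.

    Left/right partners are matched by mirroring lineage names (l <-> r); the
    midline is the total-least-squares line through the pair midpoints in the
    surface (A-P x L-R) plane. The sign convention: positive angles mean the
    midline tilts toward +z (left) with increasing anterior position. A
    perfectly mirrored configuration gives 0 degrees; the angle decreasing
    over time indicates bilateral symmetrisation.
    """
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least 2 cells per side")
    rights = {r.name: r for r in right}
    midpoints = []
    missing = []
    for lt in left:
        partner = _mirror_name(lt.name)
        if partner not in rights:
            missing.append(lt.name)
            continue
        try:
            pl, pr = lt.at(t), rights[partner].at(t)
        except KeyError:
            missing.append(lt.name)
            continue
        midpoints.append((pl + pr) / 2)
    if missing:
        raise ValueError(f"unmatched or unsampled left/right pairs at t={t}: {sorted(missing)}")
    if len(midpoints) < 2:
        raise ValueError("need at least 2 matched pairs to fit a midline")
    pts = np.array(midpoints)[:, [0, 2]]  # (x, z) surface plane
    pts = pts - pts.mean(axis=0)
    # principal direction via SVD = total least squares line
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    dx, dz = vt[0]
    if dx < 0:  # orient along +x (anterior)
        dx, dz = -dx, -dz
    return float(np.degrees(np.arctan2(dz, dx)))
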