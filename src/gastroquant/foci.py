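"""Detection and tracking of cortical myosin foci, contraction-event counting,
and bleb-event extraction from outline series.

Foci are transient punctate myosin accumulations that emerge at the cell
periphery and flow centripetally; converging streams of foci that cluster and
brighten constitute an apical contraction. A bleb is a transient protrusion
of the cell outline beyond its baseline that later regresses.

Detection thresholds and radii are configuration, not calibrated constants:
the imaging studies this targets report foci and contractions visually, so
defaults here are documented as uncalibrated working values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.feature import peak_local_max

from .morpho import Outline


@dataclass
class FocusTrack:
    """One focus followed over contiguous frames."""

    id: int
    frames: np.ndarray  # contiguous ints
    xy: np.ndarray  # (N, 2) px
    intensity: np.ndarray  # AU, local integrated signal

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.frames) == len(self.xy) == len(self.intensity)):
            raise ValueError("frames, xy and intensity must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) != 1):
            raise ValueError("track frames must be contiguous")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def birth(self) -> int:
        return int(self.frames[0])

    @property
    def death(self) -> int:
        return int(self.frames[-1])


@dataclass
class ContractionEvent:
    """A pulse of converging foci: rise then fall of the group's summed intensity."""

    onset: int  # frame
    peak: int  # frame
    centroid: tuple[float, float]  # px
    focus_ids: list[int]
    intensity_gain: float  # AU, summed-intensity rise from onset to peak

    def __post_init__(self) -> None:
        if self.onset > self.peak:
            raise ValueError("onset must not exceed peak")
        if not self.focus_ids:
            raise ValueError("an event references at least one focus")


@dataclass
class BlebEvent:
    """A transient protrusion: appearance, maximal area, retraction, translocation."""

    onset: float  # s
    retraction: float  # s
    area: float  # um^2, maximal cross-sectional area
    translocation: float  # um, anterior displacement of the outline centroid

    def __post_init__(self) -> None:
        if self.retraction <= self.onset:
            raise ValueError("retraction must come after onset")
        if self.area <= 0:
            raise ValueError("bleb area must be positive")


def detect_foci(
    frame: np.ndarray,
    min_intensity: float,
    min_sep: float = 3.0,
    integration_radius: float = 3.0,
) -> list[tuple[float, float, float]]:
    """Detect foci in one frame as suppressed local maxima.

    Returns ``(x, y, intensity)`` triples where intensity is the integrated
    signal in a disk of ``integration_radius`` px around the peak. Peaks
    closer than ``min_sep`` px are suppressed (brightest wins).
    """
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1 px")
    img = np.asarray(frame, dtype=float)
    peaks = peak_local_max(img, min_distance=int(round(min_sep)), threshold_abs=min_intensity)
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    out = []
    for y, x in peaks:
        disk = (yy - y) ** 2 + (xx - x) ** 2 <= integration_radius**2
        out.append((float(x), float(y), float(img[disk].sum())))
    # deterministic order: by (y, x)
    out.sort(key=lambda p: (p[1], p[0]))
    return out


def track_foci(
    detections: Sequence[Sequence[tuple[float, float, float]]],
    max_link_dist: float = 5.0,
) -> list[FocusTrack]:
    """Link per-frame detections into tracks by greedy nearest-neighbour matching.

    Candidate links between consecutive frames are taken in order of
    increasing distance (ties broken by coordinates, making the result
    independent of detection order within a frame); detections that remain
    unlinked start new tracks. Tracks are returned sorted by birth frame,
    then by first position.
    """
    if max_link_dist <= 0:
        raise ValueError("max_link_dist must be positive")
    open_tracks: list[dict] = []  # each: {"frames": [...], "xy": [...], "I": [...]}
    finished: list[dict] = []
    for f, dets in enumerate(detections):
        dets = sorted(dets, key=lambda p: (p[0], p[1]))  # canonical order
        assigned_det: set[int] = set()
        assigned_trk: set[int] = set()
        candidates = []
        for ti, trk in enumerate(open_tracks):
            tx, ty = trk["xy"][-1]
            for di, (x, y, _) in enumerate(dets):
                d = float(np.hypot(x - tx, y - ty))
                if d <= max_link_dist:
                    candidates.append((d, tx, ty, x, y, ti, di))
        for d, _, _, _, _, ti, di in sorted(candidates):
            if ti in assigned_trk or di in assigned_det:
                continue
            x, y, inten = dets[di]
            open_tracks[ti]["frames"].append(f)
            open_tracks[ti]["xy"].append((x, y))
            open_tracks[ti]["I"].append(inten)
            assigned_trk.add(ti)
            assigned_det.add(di)
        still_open = []
        for ti, trk in enumerate(open_tracks):
            (still_open if ti in assigned_trk else finished).append(trk)
        open_tracks = still_open
        for di, (x, y, inten) in enumerate(dets):
            if di not in assigned_det:
                open_tracks.append({"frames": [f], "xy": [(x, y)], "I": [inten]})
    finished.extend(open_tracks)
    finished.sort(key=lambda trk: (trk["frames"][0], trk["xy"][0]))
    return [
        FocusTrack(i, np.array(trk["frames"]), np.array(trk["xy"]), np.array(trk["I"]))
        for i, trk in enumerate(finished)
    ]


def _groups_by_convergence(tracks: Sequence[FocusTrack], cluster_radius: float) -> list[list[int]]:
    """Group tracks whose final positions converge within cluster_radius (union-find)."""
    n = len(tracks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ends = [t.xy[-1] for t in tracks]
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(ends[i] - ends[j])) <= cluster_radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def count_contractions(
    tracks: Sequence[FocusTrack],
    cluster_radius: float = 5.0,
    min_gain: float = 0.0,
) -> list[ContractionEvent]:
    """Extract contraction events from focus tracks.

    Tracks whose paths converge (final positions within ``cluster_radius``)
    form a group; the group's summed intensity over frames is scanned for
    rise-then-fall pulses, and each rise of at least ``min_gain`` that is
    followed by a decline is emitted as one event. Events are ordered by
    onset frame.
    """
    if not tracks:
        return []
    events: list[ContractionEvent] = []
    for group in _groups_by_convergence(tracks, cluster_radius):
        members = [tracks[i] for i in group]
        f0 = min(t.birth for t in members)
        f1 = max(t.death for t in members)
        total = np.zeros(f1 - f0 + 1)
        for t in members:
            total[t.frames - f0] += t.intensity
        # pulse scan: local minima delimit candidate rises
        i = 0
        while i < len(total) - 1:
            # find next rise start
            while i < len(total) - 1 and total[i + 1] <= total[i]:
                i += 1
            onset = i
            while i < len(total) - 1 and total[i + 1] >= total[i]:
                i += 1
            peak = i
            gain = total[peak] - total[onset]
            falls = peak < len(total) - 1 and total[peak + 1] < total[peak]
            if gain >= min_gain and gain > 0 and falls:
                pts = np.array([t.xy[np.argmin(np.abs(t.frames - (f0 + peak)))] for t in members])
                events.append(
                    ContractionEvent(
                        onset=f0 + onset,
                        peak=f0 + peak,
                        centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                        focus_ids=[tracks[i_].id for i_ in group],
                        intensity_gain=float(gain),
                    )
                )
    events.sort(key=lambda e: (e.onset, e.peak))
    return events


def detect_blebs(
    outlines: Sequence[Outline],
    baseline: Outline,
    min_area: float,
    frame_interval: float = 1.0,
    anterior_axis: Sequence[float] = (1.0, 0.0),
    align: str = "none",
) -> list[BlebEvent]:
    """Extract bleb events from an outline time series against a baseline shape.

    A bleb is a contiguous run of frames in which the area of
    ``outline \\ baseline`` exceeds ``min_area`` and that later regresses
    (the excess drops back below the threshold). Each event records its
    maximal excess area, onset and retraction times, and the displacement of
    the outline centroid along the anterior axis from the last bleb-free
    frame before onset to the frame after retraction.

    ``align='posterior'`` translates the baseline along the anterior axis so
    its posterior extent matches each frame's outline before differencing —
    appropriate when the cell body translocates between blebs (anterior
    protrusions leave the posterior edge untouched). ``align='none'``
    compares against the baseline as given.
    """
    if align not in ("none", "posterior"):
        raise ValueError("align must be 'none' or 'posterior'")
    ax = np.asarray(anterior_axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    base = baseline.polygon
    if align == "posterior":
        from shapely.affinity import translate

        base_min = float((baseline.vertices @ ax).min())
        excess = []
        for o in outlines:
            shift = float((o.vertices @ ax).min()) - base_min
            excess.append(o.polygon.difference(translate(base, ax[0] * shift, ax[1] * shift)).area)
        excess = np.asarray(excess)
    else:
        excess = np.array([o.polygon.difference(base).area for o in outlines])
    above = excess > min_area
    events: list[BlebEvent] = []
    i = 0
    n = len(outlines)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j < n:  # regressed within the series: a complete bleb cycle
            onset_t = i * frame_interval
            retract_t = j * frame_interval
            c0 = outlines[max(i - 1, 0)].centroid  # last bleb-free reference
            c1 = outlines[min(j, n - 1)].centroid
            events.append(
                BlebEvent(
                    onset=onset_t,
                    retraction=retract_t,
                    area=float(excess[i:j].max()),
                    translocation=float((c1 - c0) @ ax),
                )
            )
        i = j
    return events
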