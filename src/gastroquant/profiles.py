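"""Line-profile measurement and kymograph construction from image stacks.

Conventions (used throughout the package): pixel coordinates are 0-based and
pixel-centered, with x increasing to the right and y increasing downward.
Sampling along a line uses bilinear interpolation at an exactly 1-pixel step,
and the position axis of a profile is reported in micrometres via the stack's
pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class ImageStack:
    """A T x Z x Y x X single-channel intensity movie with acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (T, Z, Y, X)
        Non-negative finite intensities. Z may be 1 (projected or single-plane
        acquisitions).
    frame_interval : float
        Seconds between consecutive frames.
    pixel_size : float
        Micrometres per pixel in x and y.
    z_spacing : float
        Micrometres between z sections (0.7-1 um is typical for the confocal
        stacks this package targets).
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float
    z_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack data must be 4-D (T,Z,Y,X), got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all stack dimensions must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be non-negative")
        for name in ("frame_interval", "pixel_size", "z_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def times(self) -> np.ndarray:
        """Frame times in seconds from stack start."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class LineProfile:
    """Mean +/- SD fluorescence along a line, averaged across parallel lines."""

    positions: np.ndarray  # um along the line, strictly increasing
    mean: np.ndarray  # AU
    sd: np.ndarray  # AU, sample SD across lines (0 when n_lines == 1)
    n_lines: int = 2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.positions) == len(self.mean) == len(self.sd)):
            raise ValueError("positions, mean and sd must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.sd < -1e-12):
            raise ValueError("sd must be non-negative")


@dataclass
class Kymograph:
    """Space-time image: row t is the line profile at frame t."""

    data: np.ndarray  # (T, S)
    line: tuple[tuple[float, float], tuple[float, float]]  # ((x0,y0),(x1,y1)) px
    frames: range

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D (T, S)")
        if self.data.shape[0] != len(self.frames):
            raise ValueError("kymograph row count must match the frame range")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("kymograph values must be finite")


def max_project(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection over z; returns a stack with Z == 1."""
    proj = stack.data.max(axis=1, keepdims=True)
    return ImageStack(proj, stack.frame_interval, stack.pixel_size, stack.z_spacing)


def _line_samples(p0, p1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample coordinates at 1-px spacing from p0 to p1 (inclusive of p0).

    Returns (xs, ys, perpendicular unit vector). The number of samples is
    floor(length) + 1 so the step is exactly one pixel along the line.
    """
    x0, y0 = float(p0[0]), float(p0[1])
    x1, y1 = float(p1[0]), float(p1[1])
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length == 0:
        raise ValueError("line has zero length")
    n = int(np.floor(length)) + 1
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    s = np.arange(n, dtype=float)
    xs = x0 + s * ux
    ys = y0 + s * uy
    perp = np.array([-uy, ux])
    return xs, ys, perp


def _check_inside(xs: np.ndarray, ys: np.ndarray, shape: tuple[int, int], what: str) -> None:
    h, w = shape
    for label, arr, hi in (("x", xs, w - 1), ("y", ys, h - 1)):
        bad = (arr < 0) | (arr > hi)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"{what}: sample point ({xs[i]:.2f}, {ys[i]:.2f}) falls outside the "
                f"image (valid {label} range 0..{hi})"
            )


def _sample(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    # bilinear interpolation, pixel-centered coordinates
    return ndimage.map_coordinates(np.asarray(image, dtype=float), [ys, xs], order=1, mode="nearest")


def _line_offsets(n_lines: int, spacing_px: float) -> np.ndarray:
    """Perpendicular offsets of the parallel sampling lines.

    Even counts start one-sided at 0 (two lines: the requested line and one
    parallel line one spacing away, matching the two-line measurement
    convention); odd counts are symmetric about the requested line.
    """
    if n_lines % 2 == 0:
        k = np.arange(n_lines, dtype=float)
    else:
        k = np.arange(n_lines, dtype=float) - (n_lines - 1) / 2
    return k * spacing_px


def line_profile(
    stack: ImageStack,
    t: int,
    line: tuple[tuple[float, float], tuple[float, float]],
    n_lines: int = 2,
    spacing_px: float = 1.0,
    z: int = 0,
) -> LineProfile:
    """Measure mean +/- SD fluorescence along parallel lines at one frame.

    The image is sampled with bilinear interpolation at 1-px steps along
    ``n_lines`` lines parallel to ``line``, offset perpendicular to it at
    ``spacing_px``. The SD is the sample standard deviation (n-1 denominator)
    across lines; with two lines this is ``|a - b| / sqrt(2)``.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    image = stack.data[t, z]
    xs, ys, perp = _line_samples(*line)
    rows = []
    for off in _line_offsets(n_lines, spacing_px):
        ox, oy = xs + off * perp[0], ys + off * perp[1]
        _check_inside(ox, oy, image.shape, f"line offset {off:+g} px")
        rows.append(_sample(image, ox, oy))
    samples = np.vstack(rows)
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1) if n_lines > 1 else np.zeros_like(mean)
    positions = np.arange(samples.shape[1], dtype=float) * stack.pixel_size
    return LineProfile(positions, mean, sd, n_lines=n_lines)


def kymograph(
    stack: ImageStack,
    line: tuple[tuple[float, float], tuple[float, float]],
    frames: range | None = None,
    z: int = 0,
) -> Kymograph:
    """Build a kymograph: one single-line interpolated profile per frame."""
    if frames is None:
        frames = range(stack.n_frames)
    if len(frames) == 0:
        raise ValueError("frame range is empty")
    xs, ys, _ = _line_samples(*line)
    _check_inside(xs, ys, stack.data.shape[2:], "kymograph line")
    rows = [_sample(stack.data[t, z], xs, ys) for t in frames]
    return Kymograph(np.vstack(rows), (tuple(line[0]), tuple(line[1])), frames)


def superimpose(stack: ImageStack, t0: int = 0, k: int = 5, z: int = 0) -> np.ndarray:
    """Pixelwise maximum over k consecutive frames starting at t0.

    With movies recorded at short intervals this renders flowing foci as a
    trail, the standard way of visualising cortical flow directions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if t0 < 0 or t0 + k > stack.n_frames:
        raise ValueError(
            f"frame window [{t0}, {t0 + k}) exceeds the stack's {stack.n_frames} frames"
        )
    return stack.data[t0 : t0 + k, z].max(axis=0)
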