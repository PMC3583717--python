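"""Synthetic-data generator emulating the statistical structure of gastrulation
time-lapse data.

Everything downstream of acquisition is exercised against this module: cortex
movies with pulsatile centripetally-flowing myosin foci, paired
intensity/extension traces coupled through a viscoelastic transport delay
(default 20 s at a 2 s frame interval), a dividing surface-cell lineage on an
ellipsoidal embryo with spindle angles distributed about 36 degrees from the
A-P axis, and bleb event series with a linear area -> anterior-translocation
law and retraction within 30-60 s. Each generator also returns (or can
render) ground truth sufficient for exact parameter recovery at zero noise.

Reproducibility contract: each generator call creates one
``numpy.random.Generator`` from ``config.seed`` and consumes it in the fixed
order documented in each function, so identical config gives bit-identical
output and the random stream can be replayed by an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm
from shapely.geometry import Point, Polygon

from .foci import BlebEvent
from .coupling import ExtensionTrace, IntensityTrace
from .morpho import Outline
from .profiles import ImageStack
from .spread import CrossSection, DivisionEvent, fold_angle, g_factor
from .tracks import CellTrack


@dataclass
class SynthConfig:
    """Parameters of the synthetic embryo; defaults are the study conditions.

    Movie parameters
    ----------------
    frame_interval : 2 s (cortical streaming movies); pixel_size in um/px.
    n_frames, image_shape : movie geometry.
    foci_birth_rate : mean new foci per frame (Poisson).
    foci_intensity : peak focus amplitude, AU.
    flow_speed : centripetal drift, px/frame toward the apical center.
    focus_lifetime : mean focus lifetime, frames.
    scripted_contractions : onset frames of scripted convergence pulses
        (each spawns ``scripted_foci`` foci that converge on the apical
        center with a rise-then-fall intensity pulse).

    Coupling parameters
    -------------------
    coupling_delay : transport delay between contraction and extension, s
        (default 20).
    coupling_gain : extension advancement per normalised intensity unit.
    pulse_rate : contraction pulses per second feeding the intensity trace.
    pulse_rise : rise time of one accumulation step, s.
    smoothing_sd : sigma of the zero-phase Gaussian smoothing that stands in
        for cortex viscoelasticity, s.
    extension_plateau : final tip position, um.

    Lineage parameters
    ------------------
    spindle_angle_mean : 36 degrees from the A-P axis; spindle_angle_sd its
        spread across divisions.
    division_times : seconds of the synchronous division rounds.
    founders : (name, u, phi_deg) triples on the ellipsoid surface
        (u in [-1, 1] along A-P, phi the circumferential angle; phi in
        (0, 180) is the left side).
    semi_axes : embryo ellipsoid semi-axes (A-P, D-V, L-R), um.
    lr_coherence : sd of the shared per-side L/R drift increment, um/step.
    track_noise_sd : independent per-sample position noise, um.
    midline_shear : initial right-side L/R shear (um at |u|=1), decaying
        linearly to zero over the run — scripts midline symmetrisation.
    scripted_anterior_move : {terminal cell name: % of embryo length} ramped
        anterior displacement over the cell's lifetime.

    Bleb parameters
    ---------------
    bleb_rate : events/min; bleb_slope the true anterior-translocation per
        unit area law (um per um^2); bleb_retraction_range : retraction
        completes within 30-60 s of onset.

    noise_sd applies to movies (AU) and, as a fraction of each trace's
    maximum, to the coupled traces.
    """

    seed: int = 0
    frame_interval: float = 2.0  # s
    pixel_size: float = 0.1  # um/px
    n_frames: int = 150
    image_shape: tuple[int, int] = (64, 64)
    noise_sd: float = 0.03

    # cortex movie
    foci_birth_rate: float = 0.2  # per frame
    foci_intensity: float = 100.0  # AU
    flow_speed: float = 1.0  # px/frame
    focus_lifetime: float = 10.0  # frames
    focus_sigma: float = 1.5  # px, rendered Gaussian width
    scripted_contractions: tuple[int, ...] = ()
    scripted_foci: int = 3

    # coupled traces
    coupling_delay: float = 20.0  # s
    coupling_gain: float = 1.0
    pulse_rate: float = 0.04  # pulses/s
    pulse_rise: float = 2.0  # s
    smoothing_sd: float = 2.0  # s
    extension_plateau: float = 10.0  # um

    # lineage
    spindle_angle_mean: float = 36.0  # deg
    spindle_angle_sd: float = 10.0  # deg
    division_times: tuple[float, ...] = (120.0, 360.0, 600.0)
    founders: tuple[tuple[str, float, float], ...] = (
        ("ABal", 0.2, 70.0),
        ("ABar", 0.2, -70.0),
        ("ABpl", -0.2, 110.0),
        ("ABpr", -0.2, -110.0),
    )
    semi_axes: tuple[float, float, float] = (25.0, 15.0, 15.0)  # um
    track_interval: float = 10.0  # s
    track_duration: float | None = None  # default: last division + 120 s
    daughter_separation: float = 4.0  # um
    u_step_sd: float = 0.003
    phi_step_sd: float = 0.5  # deg
    lr_coherence: float = 0.3  # um/step
    track_noise_sd: float = 0.1  # um
    midline_shear: float = 0.0  # um
    scripted_anterior_move: dict = field(default_factory=dict)

    # blebs
    bleb_rate: float = 2.0  # events/min
    bleb_duration: float = 600.0  # s of recording
    bleb_slope: float = 0.02  # um translocation per um^2 area
    bleb_area_mean: float = 4.0  # um^2
    bleb_area_logsd: float = 0.5
    bleb_noise_sd: float = 0.0  # um, translocation noise
    bleb_retraction_range: tuple[float, float] = (30.0, 60.0)  # s

    def __post_init__(self) -> None:
        for name in (
            "frame_interval",
            "pixel_size",
            "foci_intensity",
            "extension_plateau",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "noise_sd",
            "foci_birth_rate",
            "flow_speed",
            "coupling_delay",
            "coupling_gain",
            "pulse_rate",
            "spindle_angle_sd",
            "bleb_rate",
            "bleb_noise_sd",
            "track_noise_sd",
            "lr_coherence",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.bleb_retraction_range
        if lo > hi:
            raise ValueError("bleb_retraction_range must satisfy low <= high")
        if list(self.division_times) != sorted(self.division_times):
            raise ValueError("division_times must be sorted ascending")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# cortex movie


def generate_cortex_movie(config: SynthConfig) -> tuple[ImageStack, pd.DataFrame]:
    """Movie of Gaussian foci born at the periphery and flowing centripetally.

    RNG consumption order: (1) one vector of per-frame Poisson birth counts;
    (2) per focus, in (birth frame, index) order: birth angle, lifetime,
    amplitude factor; (3) one Gaussian noise field for the whole movie.

    Returns the movie (T x 1 x Y x X) and a ground-truth table with one row
    per focus per frame: focus_id, frame, x, y, intensity.
    """
    if config.n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    h, w = config.image_shape
    if h < 16 or w < 16:
        raise ValueError("image dimensions must be >= 16 px")
    rng = config.rng()
    births = rng.poisson(config.foci_birth_rate, config.n_frames)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_start = min(h, w) / 2.0 - 4.0

    foci = []  # dicts: birth, angle, life, amp
    live_angles: list[tuple[int, float]] = []  # (death_frame, angle)
    min_sep_px = 12.0
    for f in range(config.n_frames):
        for _ in range(births[f]):
            angle = rng.uniform(0, 2 * math.pi)
            life = max(2, int(rng.poisson(config.focus_lifetime)))
            amp = config.foci_intensity * rng.uniform(0.5, 1.5)
            # nudge birth angle away from concurrently live foci so that
            # distinct foci stay resolvable; the retry consumes no extra
            # stream draws beyond the documented per-focus angle redraws
            for _retry in range(20):
                sep = min(
                    (
                        abs(r_start * math.sin((angle - a) / 2) * 2)
                        for d, a in live_angles
                        if d > f
                    ),
                    default=np.inf,
                )
                if sep >= min_sep_px:
                    break
                angle = rng.uniform(0, 2 * math.pi)
            foci.append({"birth": f, "angle": angle, "life": life, "amp": amp})
            live_angles.append((f + life, angle))

    # scripted convergence pulses (deterministic; no RNG)
    for onset in config.scripted_contractions:
        for k in range(config.scripted_foci):
            foci.append(
                {
                    "birth": int(onset),
                    "angle": 2 * math.pi * k / config.scripted_foci,
                    "life": 6,
                    "amp": config.foci_intensity,
                    "scripted": True,
                }
            )

    movie = np.zeros((config.n_frames, h, w), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rows = []
    for fid, fo in enumerate(foci):
        scripted = fo.get("scripted", False)
        r0 = 8.0 if scripted else r_start
        speed = r0 / fo["life"] if scripted else config.flow_speed
        for age in range(fo["life"]):
            f = fo["birth"] + age
            if f >= config.n_frames:
                break
            r = max(r0 - speed * age, 0.0)
            x = cx + r * math.cos(fo["angle"])
            y = cy + r * math.sin(fo["angle"])
            # brighten then dissolve: triangular intensity profile
            frac = (age + 1) / fo["life"]
            inten = fo["amp"] * (2 * frac if frac <= 0.5 else 2 * (1 - frac) + 2 / fo["life"])
            movie[f] += inten * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * config.focus_sigma**2))
            rows.append((fid, f, x, y, inten))

    if config.noise_sd > 0:
        movie += rng.normal(0, config.noise_sd, movie.shape)
        movie = np.clip(movie, 0, None)

    truth = pd.DataFrame(rows, columns=["focus_id", "frame", "x", "y", "intensity"])
    stack = ImageStack(movie[:, None, :, :], config.frame_interval, config.pixel_size)
    return stack, truth


# ---------------------------------------------------------------------------
# coupled traces


def generate_coupled_traces(config: SynthConfig) -> tuple[IntensityTrace, ExtensionTrace]:
    """Paired contraction-intensity and extension-advancement traces.

    The integrated intensity is a sum of smooth accumulation steps (one per
    contraction pulse; myosin recruited during a pulse persists), so it is
    monotone and maximal at the end of the recording, matching the
    normalise-to-maximum convention. The extension tip position is
    ``gain x`` the Gaussian-smoothed intensity evaluated ``coupling_delay``
    seconds earlier (zero-phase smoothing stands in for cortex
    viscoelasticity without shifting the recoverable delay), rescaled to end
    at ``extension_plateau``. With ``noise_sd=0`` the delayed affine
    relationship is exact.

    Pulses occupy the first 70% of the recording so both traces plateau.

    RNG consumption order: pulse count (Poisson), pulse times (uniform),
    pulse amplitudes (lognormal), intensity noise, extension noise.
    """
    duration = config.n_frames * config.frame_interval
    if duration <= 3 * config.coupling_delay:
        raise ValueError("recording must be longer than 3x the coupling delay")
    rng = config.rng()
    dt = config.frame_interval
    t = np.arange(config.n_frames) * dt
    active = 0.7 * duration

    n_pulses = max(3, int(rng.poisson(config.pulse_rate * active)))
    pulse_times = np.sort(rng.uniform(0.0, active, n_pulses))
    amps = rng.lognormal(0.0, 0.4, n_pulses)

    intensity = np.zeros_like(t)
    for tk, ak in zip(pulse_times, amps):
        intensity += ak * norm.cdf((t - tk) / config.pulse_rise)

    if config.smoothing_sd > 0:
        smoothed = gaussian_filter1d(intensity, sigma=config.smoothing_sd / dt, mode="nearest")
    else:
        smoothed = intensity
    delayed = np.interp(t - config.coupling_delay, t, smoothed, left=0.0)
    extension = config.coupling_gain * delayed
    if extension[-1] <= 0:
        raise ValueError("degenerate trace: extension never advances")
    extension = extension / extension[-1] * config.extension_plateau

    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0, config.noise_sd * intensity.max(), len(t))
        extension = extension + rng.normal(0, config.noise_sd * config.extension_plateau, len(t))
        intensity = np.clip(intensity, 0, None)

    return IntensityTrace(t, intensity), ExtensionTrace(t, extension)


# ---------------------------------------------------------------------------
# lineage


def _surface_point(u: float, phi_deg: float, semi_axes) -> np.ndarray:
    a, b, c = semi_axes
    u = float(np.clip(u, -1.0, 1.0))
    r = math.sqrt(max(0.0, 1.0 - u * u))
    phi = math.radians(phi_deg)
    return np.array([a * u, b * r * math.cos(phi), c * r * math.sin(phi)])


def generate_lineage(
    config: SynthConfig,
) -> tuple[list[CellTrack], list[DivisionEvent]]:
    """Dividing surface-cell lineage on the embryo ellipsoid.

    Cells live on the ellipsoid surface parameterised by (u, phi); at every
    division time each live cell splits into an anterior 'a' and posterior
    'p' daughter displaced symmetrically along a spindle whose angle to the
    A-P axis is drawn from Normal(spindle_angle_mean, spindle_angle_sd) and
    folded into [0, 90] for the event record.

    Cells on the same side share a coherent L/R drift (opposite signs on the
    two sides), producing the within-side correlation / cross-side
    anti-correlation structure of bilateral morphogenetic movements.

    RNG consumption order: (1) per division time, per live cell in
    name-sorted order: spindle angle, circumferential sign; (2) the shared
    per-side L/R drift increments; (3) per cell in creation order: u steps,
    phi steps, measurement noise.
    """
    if not config.founders:
        raise ValueError("founder set must be non-empty")
    rng = config.rng()
    duration = (
        config.track_duration
        if config.track_duration is not None
        else (max(config.division_times, default=0.0) + 120.0)
    )
    grid = np.arange(0.0, duration + config.track_interval / 2, config.track_interval)
    a_semi, b_semi, c_semi = config.semi_axes

    cells: dict[str, dict] = {
        name: {"parent": "", "birth": 0.0, "death": duration, "u0": u, "phi0": phi}
        for name, u, phi in config.founders
    }
    events: list[DivisionEvent] = []
    alive = sorted(cells)
    for td in config.division_times:
        next_alive = []
        for name in sorted(alive):
            cell = cells[name]
            theta_raw = rng.normal(config.spindle_angle_mean, config.spindle_angle_sd)
            circ_sign = 1.0 if rng.uniform() < 0.5 else -1.0
            theta = fold_angle(theta_raw)
            cell["death"] = td
            events.append(DivisionEvent(parent=name, time=td, angle=theta))
            # daughters displaced +/- half the separation along the spindle
            half = config.daughter_separation / 2.0
            du = half * math.cos(math.radians(theta)) / a_semi
            u_here = cell["u0"]
            r_here = max(c_semi * math.sqrt(max(0.0, 1 - u_here**2)), 1.0)
            dphi = math.degrees(half * math.sin(math.radians(theta)) / r_here) * circ_sign
            for suffix, s in (("a", +1.0), ("p", -1.0)):
                cells[name + suffix] = {
                    "parent": name,
                    "birth": td,
                    "death": duration,
                    "u0": u_here + s * du,
                    "phi0": cell["phi0"] + s * dphi,
                }
                next_alive.append(name + suffix)
        alive = next_alive

    drift = np.cumsum(rng.normal(0.0, config.lr_coherence, len(grid)))

    tracks: list[CellTrack] = []
    for name in cells:  # creation order (founders, then by division round)
        cell = cells[name]
        mask = (grid >= cell["birth"] - 1e-9) & (
            (grid < cell["death"] - 1e-9) | (cell["death"] >= duration - 1e-9)
        )
        times = grid[mask]
        if len(times) == 0:
            continue
        n = len(times)
        u = cell["u0"] + np.cumsum(rng.normal(0, config.u_step_sd, n))
        phi = cell["phi0"] + np.cumsum(rng.normal(0, config.phi_step_sd, n))
        noise = rng.normal(0, config.track_noise_sd, (n, 3)) if config.track_noise_sd > 0 else 0.0
        pos = np.array([_surface_point(ui, pi, config.semi_axes) for ui, pi in zip(u, phi)])
        side = 1.0 if math.sin(math.radians(cell["phi0"])) > 0 else -1.0  # left = +z
        pos[:, 2] += side * drift[mask]
        if side < 0 and config.midline_shear:
            decay = 1.0 - times / duration
            pos[:, 2] += config.midline_shear * u * decay
        if name in config.scripted_anterior_move:
            pct = config.scripted_anterior_move[name]
            ramp = (times - times[0]) / max(times[-1] - times[0], 1e-9)
            pos[:, 0] += pct / 100.0 * (2 * a_semi) * ramp
        pos = pos + noise
        tracks.append(CellTrack(name, times, pos, parent=cell["parent"]))
    return tracks, events


def render_cross_sections(
    events: Sequence[DivisionEvent],
    config: SynthConfig,
    times: Sequence[float],
    initial_spread: float = 30.0,
    tissue: str = "AB",
) -> list[CrossSection]:
    """Midpoint cross-sections consistent with the division-driven spread model.

    Each founder starts with an equal share of ``initial_spread`` % of the
    circumference; at every division the parent's interval widens by
    g(theta) of that division's recorded angle and splits into two halves.
    The tissue's cells are laid out as two contiguous lateral blocks (left
    centred at 90 degrees, right at 270), the configuration in which the two
    lateral halves of the ectoderm expand toward ventral and dorsal closure,
    so same-tissue intervals never overlap while each side spans under half
    the circumference. The summed extent of the rendered intervals follows
    the cell-width-weighted product of g factors, the quantity the
    theoretical model approximates with per-round means.
    """
    widths: dict[str, float] = {}  # name -> width deg
    sides: dict[str, float] = {}  # name -> +1 left / -1 right
    total0 = initial_spread / 100.0 * 360.0
    for name, _u, phi in config.founders:
        widths[name] = total0 / len(config.founders)
        sides[name] = 1.0 if math.sin(math.radians(phi)) > 0 else -1.0

    by_time: dict[float, list[DivisionEvent]] = {}
    for e in events:
        by_time.setdefault(e.time, []).append(e)

    def layout() -> list[tuple[str, float, float]]:
        intervals = []
        for side, center in ((1.0, 90.0), (-1.0, 270.0)):
            names = sorted(n for n in widths if sides[n] == side)
            span = sum(widths[n] for n in names)
            cursor = center - span / 2.0
            for n in names:
                lo, hi = cursor % 360.0, cursor % 360.0 + widths[n]
                if hi <= 360.0:
                    intervals.append((tissue, lo, hi))
                else:
                    intervals.append((tissue, lo, 360.0))
                    intervals.append((tissue, 0.0, hi - 360.0))
                cursor += widths[n]
        return intervals

    sections: list[CrossSection] = []
    div_times = sorted(by_time)
    for t in sorted(times):
        while div_times and div_times[0] <= t:
            td = div_times.pop(0)
            for e in by_time[td]:
                if e.parent not in widths:
                    continue
                w_new = widths.pop(e.parent) * float(g_factor(e.angle))
                side = sides.pop(e.parent)
                for suffix in ("a", "p"):
                    widths[e.parent + suffix] = w_new / 2.0
                    sides[e.parent + suffix] = side
        sections.append(CrossSection(time=float(t), intervals=layout()))
    return sections


# ---------------------------------------------------------------------------
# blebs


def generate_blebs(config: SynthConfig) -> list[BlebEvent]:
    """Bleb event series with a linear area -> anterior translocation law.

    RNG consumption order: event count (Poisson on rate x duration), onset
    times (uniform, then sorted), areas (lognormal around
    ``bleb_area_mean``), translocation noise (normal), retraction durations
    (uniform in ``bleb_retraction_range``).
    """
    rng = config.rng()
    n = int(rng.poisson(config.bleb_rate * config.bleb_duration / 60.0))
    if n == 0:
        return []
    onsets = np.sort(rng.uniform(0.0, config.bleb_duration, n))
    areas = rng.lognormal(math.log(config.bleb_area_mean), config.bleb_area_logsd, n)
    noise = rng.normal(0.0, config.bleb_noise_sd, n) if config.bleb_noise_sd > 0 else np.zeros(n)
    lo, hi = config.bleb_retraction_range
    durations = rng.uniform(lo, hi, n)
    return [
        BlebEvent(
            onset=float(onsets[i]),
            retraction=float(onsets[i] + durations[i]),
            area=float(areas[i]),
            translocation=float(config.bleb_slope * areas[i] + noise[i]),
        )
        for i in range(n)
    ]


def _bump_radius_for_area(base: Polygon, center: np.ndarray, target: float) -> float:
    """Bisection for the bump-circle radius whose area outside ``base`` is target."""
    lo, hi = 1e-3, 4.0 * math.sqrt(target) + 2.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        area = Point(*center).buffer(mid, quad_segs=64).difference(base).area
        if area < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def render_bleb_outlines(
    events: Sequence[BlebEvent],
    config: SynthConfig,
    cell_radius: float = 5.0,
    outline_interval: float = 2.0,
) -> tuple[list[Outline], Outline]:
    """Render a cell-outline time series realising a scripted bleb series.

    The cell body is a circle of ``cell_radius`` um. During each event a
    circular bump whose area outside the body equals the scripted bleb area
    protrudes on the anterior (+x) side; at retraction the bump vanishes and
    the whole body jumps anteriorly by the scripted translocation.
    Overlapping events are not supported and raise.

    Returns (outlines, baseline outline).
    """
    for e1, e2 in zip(events, events[1:]):
        if e2.onset <= e1.retraction:
            raise ValueError("overlapping bleb events cannot be rendered")
    t_end = (max((e.retraction for e in events), default=0.0)) + 3 * outline_interval
    times = np.arange(0.0, t_end + outline_interval / 2, outline_interval)
    base0 = Point(0.0, 0.0).buffer(cell_radius, quad_segs=64)

    outlines = []
    for t in times:
        shift = sum(e.translocation for e in events if e.retraction <= t + 1e-9)
        cx = shift
        body = Point(cx, 0.0).buffer(cell_radius, quad_segs=64)
        active = [e for e in events if e.onset <= t + 1e-9 < e.retraction]
        shape = body
        if active:
            ev = active[0]
            rb = _bump_radius_for_area(body, np.array([cx + cell_radius, 0.0]), ev.area)
            bump = Point(cx + cell_radius, 0.0).buffer(rb, quad_segs=64)
            shape = body.union(bump)
        verts = np.asarray(shape.exterior.coords)[:-1]
        outlines.append(Outline(verts, frame=int(round(t / outline_interval)), label="cell"))
    baseline = Outline(np.asarray(base0.exterior.coords)[:-1], frame=0, label="baseline")
    return outlines, baseline
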