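"""End-to-end pipeline: synthetic generation followed by every analysis stage.

Stages run in dependency order (synth -> profiles/foci -> coupling;
synth lineage -> spread/tracks; synth blebs -> morpho). Every output CSV
carries a provenance header (package version, seed, parameter hash); with
``reproducible=True`` no timestamps are written anywhere, so two runs with
the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling, foci, io, morpho, spread, tracks as tracks_mod
from .profiles import kymograph, max_project
from .synth import (
    SynthConfig,
    generate_blebs,
    generate_cortex_movie,
    generate_coupled_traces,
    generate_lineage,
    render_bleb_outlines,
    render_cross_sections,
)

log = logging.getLogger("gastroquant")

ALL_STAGES = ("synth", "profiles", "foci", "coupling", "spread", "tracks", "morpho")


@dataclass
class RunConfig:
    """Pipeline run configuration.

    ``synth`` holds overrides for SynthConfig fields; unknown keys are
    rejected at validation time, before any stage runs.
    """

    out_dir: str = "gastroquant_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synth: dict = field(default_factory=dict)
    initial_spread: float = 30.0
    reproducible: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        valid = {f.name for f in dataclasses.fields(SynthConfig)}
        bad = set(self.synth) - valid
        if bad:
            raise ValueError(f"unknown synth config keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - valid
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def synth_config(self) -> SynthConfig:
        return SynthConfig(seed=self.seed, **self.synth)


def run_pipeline(config: RunConfig) -> Path:
    """Run the selected stages; returns the output directory.

    A failing stage raises RuntimeError naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.synth_config()
    hk = {"seed": config.seed, "params": dataclasses.asdict(sc) | {"_": 0}}
    # dataclass dicts may hold unhashable values; hash their repr instead
    hk["params"] = {k: repr(v) for k, v in hk["params"].items()}

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](sc, config, out, state, hk)
            log.info("stage %s done", stage)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _stage_synth(sc, config, out, state, hk):
    movie, truth = generate_cortex_movie(sc)
    io.write_stack(out / "cortex.tiff", movie)
    io.write_csv(out / "foci_truth.csv", truth, **hk)
    itrace, etrace = generate_coupled_traces(sc)
    io.write_traces(out / "traces.csv", itrace, etrace, **hk)
    cell_tracks, events = generate_lineage(sc)
    io.write_tracks(out / "tracks.csv", cell_tracks, **hk)
    ev_df = pd.DataFrame(
        [(e.parent, e.time, e.angle) for e in events], columns=["parent", "time_s", "angle_deg"]
    )
    io.write_csv(out / "divisions.csv", ev_df, **hk)
    blebs = generate_blebs(sc)
    bl_df = pd.DataFrame(
        [(b.onset, b.retraction, b.area, b.translocation) for b in blebs],
        columns=["onset_s", "retraction_s", "area_um2", "translocation_um"],
    )
    io.write_csv(out / "blebs.csv", bl_df, **hk)
    state.update(movie=movie, truth=truth, itrace=itrace, etrace=etrace,
                 tracks=cell_tracks, events=events, blebs=blebs)
    log.info("synth: %d foci, %d divisions, %d blebs", truth["focus_id"].nunique(), len(events), len(blebs))


def _stage_profiles(sc, config, out, state, hk):
    movie = state["movie"]
    proj = max_project(movie)
    h, w = proj.data.shape[2:]
    ky = kymograph(proj, ((2.0, h / 2.0), (w - 3.0, h / 2.0)))
    io.write_csv(out / "kymograph.csv", pd.DataFrame(ky.data), **hk)
    state["kymograph"] = ky


def _stage_foci(sc, config, out, state, hk):
    movie = state["movie"]
    threshold = max(0.25 * sc.foci_intensity, 6.0 * sc.noise_sd)
    dets = [
        foci.detect_foci(movie.data[t, 0], min_intensity=threshold, min_sep=3)
        for t in range(movie.n_frames)
    ]
    ftracks = foci.track_foci(dets, max_link_dist=4.0)
    rows = [
        (tr.id, f, x, y, i)
        for tr in ftracks
        for f, (x, y), i in zip(tr.frames, tr.xy, tr.intensity)
    ]
    io.write_csv(out / "foci_tracks.csv", pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "intensity"]), **hk)
    state["foci_tracks"] = ftracks
    state["detections"] = dets
    log.info("foci: %d detections, %d tracks", sum(len(d) for d in dets), len(ftracks))


def _stage_coupling(sc, config, out, state, hk):
    ni, ne = coupling.normalize_traces(state["itrace"], state["etrace"])
    scan = coupling.lag_scan(ni, ne, max_lag=60.0)
    df = pd.DataFrame({"lag_s": scan.lags, "r_squared": scan.r_squared})
    io.write_csv(out / "lag_scan.csv", df, extra=f"peak_lag_s: {scan.peak_lag}; peak_r2: {scan.peak_r2:.4f}", **hk)
    state["lag_scan"] = scan
    log.info("coupling: peak lag %.1f s, r2 %.3f", scan.peak_lag, scan.peak_r2)


def _stage_spread(sc, config, out, state, hk):
    events = state["events"]
    times = np.arange(0.0, max(e.time for e in events) + 120.0 + 1e-9, sc.track_interval)
    sections = render_cross_sections(events, sc, times, initial_spread=config.initial_spread)
    meas = spread.measured_spread(sections, "AB")
    theo = spread.theoretical_spread(config.initial_spread, sorted(events, key=lambda e: e.time), times)
    t, resid, rms = spread.compare_spread(meas, theo)
    df = pd.DataFrame(
        {"time_s": meas.times, "measured_pct": meas.spread,
         "theoretical_pct": np.interp(meas.times, theo.times, theo.spread),
         "residual_pct": np.interp(meas.times, t, resid)}
    )
    io.write_csv(out / "spread.csv", df, extra=f"rms_pct: {rms:.4f}", **hk)
    state["spread_rms"] = rms
    log.info("spread: RMS %.3f %%", rms)


def _stage_tracks(sc, config, out, state, hk):
    cell_tracks = state["tracks"]
    terminal = [t for t in cell_tracks if not any(o.parent == t.name for o in cell_tracks)]
    smoothed = [tracks_mod.smooth_path(t, 5) if len(t.times) >= 5 else t for t in terminal]
    mat = tracks_mod.correlation_matrix(smoothed, clip=0.8)
    io.write_csv(out / "lr_correlation.csv", mat.to_frame().reset_index(names="cell"), **hk)
    state["corr"] = mat


def _stage_morpho(sc, config, out, state, hk):
    blebs = state["blebs"]
    if len(blebs) >= 3:
        fit = morpho.bleb_regression(blebs)
        df = pd.DataFrame(
            [{"slope_um_per_um2": fit.slope, "intercept_um": fit.intercept, "r_squared": fit.r_squared, "n": fit.n}]
        )
        io.write_csv(out / "bleb_regression.csv", df, extra=morpho.FLATNESS_DEFINITION, **hk)
        state["bleb_fit"] = fit
    # render a few non-overlapping events (the renderer models one bleb at a time)
    chosen, last_end = [], -1.0
    for b in blebs:
        if b.onset > last_end and len(chosen) < 3:
            chosen.append(b)
            last_end = b.retraction
    rendered, baseline = render_bleb_outlines(chosen, sc) if chosen else ([], None)
    if rendered:
        det = foci.detect_blebs(rendered, baseline, min_area=0.5, frame_interval=2.0, align="posterior")
        df = pd.DataFrame(
            [(b.onset, b.retraction, b.area, b.translocation) for b in det],
            columns=["onset_s", "retraction_s", "area_um2", "translocation_um"],
        )
        io.write_csv(out / "bleb_detected.csv", df, **hk)
        state["bleb_detected"] = det


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "profiles": _stage_profiles,
    "foci": _stage_foci,
    "coupling": _stage_coupling,
    "spread": _stage_spread,
    "tracks": _stage_tracks,
    "morpho": _stage_morpho,
}
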