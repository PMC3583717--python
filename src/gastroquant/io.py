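"""Readers and writers for the package's on-disk formats.

Canonical tabular format is headered CSV. Image stacks are multi-page TIFF
(T pages of Y x X, or T*Z pages) with acquisition metadata in a YAML sidecar
(``<stack>.yaml``) or passed explicitly — metadata is never silently
defaulted. The AceTree-style nuclei listing is accepted read-only.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .coupling import ExtensionTrace, IntensityTrace
from .morpho import Outline
from .profiles import ImageStack
from .tracks import CellTrack


# ---------------------------------------------------------------------------
# image stacks


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    t, z, y, x = stack.shape
    tifffile.imwrite(path, stack.data.reshape(t * z, y, x), photometric="minisblack")
    meta = {
        "frame_interval_s": float(stack.frame_interval),
        "pixel_size_um": float(stack.pixel_size),
        "z_spacing_um": float(stack.z_spacing),
        "n_frames": int(t),
        "n_z": int(z),
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))


def read_stack(
    path: str | Path,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
    z_spacing: float | None = None,
    n_z: int | None = None,
) -> ImageStack:
    """Read a multi-page TIFF stack.

    Metadata comes from the YAML sidecar written by :func:`write_stack`, or
    from the explicit arguments (which take precedence). Missing frame
    interval or pixel size is an error.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = []
            i = 0
            it = iter(tif.pages)
            while True:
                try:
                    page = next(it)
                except StopIteration:
                    break
                except Exception as exc:  # truncated page directory
                    raise IOError(f"failed to read TIFF page {i} of {path}: {exc}") from exc
                try:
                    pages.append(page.asarray())
                except Exception as exc:  # truncated / corrupt page data
                    raise IOError(f"failed to read TIFF page {i} of {path}: {exc}") from exc
                i += 1
    except IOError:
        raise
    except Exception as exc:
        raise IOError(f"failed to parse TIFF file {path} at page 0: {exc}") from exc
    if not pages:
        raise IOError(f"{path} contains no image pages")
    data = np.stack(pages)

    sidecar = path.with_suffix(path.suffix + ".yaml")
    meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
    expected_pages = meta.get("n_frames", 0) * meta.get("n_z", 1)
    if expected_pages and len(pages) != expected_pages:
        raise IOError(
            f"{path} is truncated or corrupt: parsing failed at page {len(pages)} "
            f"({expected_pages} pages expected)"
        )
    frame_interval = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    z_spacing = z_spacing if z_spacing is not None else meta.get("z_spacing_um", 1.0)
    n_z = n_z if n_z is not None else meta.get("n_z", 1)
    if frame_interval is None or pixel_size is None:
        raise ValueError(
            f"no frame interval / pixel size for {path}: provide a {sidecar.name} sidecar "
            "or pass them explicitly"
        )
    if data.shape[0] % n_z:
        raise ValueError(f"{data.shape[0]} pages do not divide into z-stacks of {n_z}")
    t = data.shape[0] // n_z
    return ImageStack(
        data.reshape(t, n_z, *data.shape[1:]).astype(float),
        frame_interval,
        pixel_size,
        z_spacing,
    )


# ---------------------------------------------------------------------------
# CSV headers


def csv_header(seed: int | None = None, params: dict | None = None, extra: str = "") -> str:
    """Provenance header written atop every output CSV."""
    lines = [f"# gastroquant {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if params:
        digest = hashlib.sha256(repr(sorted(params.items())).encode()).hexdigest()[:12]
        lines.append(f"# params_sha: {digest}")
    if extra:
        lines.append(f"# {extra}")
    return "\n".join(lines) + "\n"


def write_csv(path: str | Path, df: pd.DataFrame, seed: int | None = None, params: dict | None = None, extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(csv_header(seed, params, extra))
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# tracks


def write_tracks(path: str | Path, tracks: Sequence[CellTrack], **header_kw) -> None:
    rows = []
    for tr in tracks:
        for t, (x, y, z) in zip(tr.times, tr.positions):
            rows.append((tr.name, t, x, y, z, tr.parent))
    df = pd.DataFrame(rows, columns=["cell", "t_s", "x_um", "y_um", "z_um", "parent"])
    write_csv(path, df, **header_kw)


def read_tracks(path: str | Path, dialect: str = "csv") -> list[CellTrack]:
    """Read cell tracks.

    ``dialect='csv'`` expects columns cell, t_s, x_um, y_um, z_um[, parent].
    ``dialect='acetree-nuclei'`` reads a simplified AceTree nuclei listing:
    comma-separated records ``time, index, status, predecessor, x, y, z,
    diameter, name`` (status != 0 means a live nucleus).
    """
    if dialect == "csv":
        return _read_tracks_csv(Path(path))
    if dialect == "acetree-nuclei":
        return _read_acetree_nuclei(Path(path))
    raise ValueError(f"unknown track dialect {dialect!r}")


def _read_tracks_csv(path: Path) -> list[CellTrack]:
    df = read_csv(path)
    required = {"cell", "t_s", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["cell", "t_s"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (cell, time) record at data row {int(dup.idxmax())}")
    tracks = []
    for cell, grp in df.groupby("cell", sort=True):
        times = grp["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0])
            raise ValueError(f"{path}: non-monotone time for cell {cell} at data row {int(grp.index[bad + 1])}")
        parent = str(grp["parent"].iloc[0]) if "parent" in grp and not pd.isna(grp["parent"].iloc[0]) else ""
        tracks.append(
            CellTrack(str(cell), times, grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float), parent=parent)
        )
    return tracks


def _read_acetree_nuclei(path: Path) -> list[CellTrack]:
    per_cell: dict[str, list[tuple[float, float, float, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 fields, got {len(parts)}")
            try:
                t = float(parts[0])
                status = int(parts[2])
                x, y, z = (float(parts[i]) for i in (4, 5, 6))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            name = parts[8]
            if status == 0:
                continue
            per_cell.setdefault(name, []).append((t, x, y, z))
    tracks = []
    for name in sorted(per_cell):
        recs = sorted(per_cell[name])
        times = np.array([r[0] for r in recs])
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: duplicate or non-monotone times for nucleus {name}")
        tracks.append(CellTrack(name, times, np.array([r[1:] for r in recs])))
    return tracks


# ---------------------------------------------------------------------------
# outlines


def write_outlines(path: str | Path, outlines: Sequence[Outline], **header_kw) -> None:
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(o.vertices):
            rows.append((o.frame, o.label, i, x, y))
    df = pd.DataFrame(rows, columns=["frame", "label", "vertex_index", "x", "y"])
    write_csv(path, df, **header_kw)


def read_outlines(path: str | Path) -> list[Outline]:
    df = read_csv(path)
    outlines = []
    for (frame, label), grp in df.groupby(["frame", "label"], sort=True):
        grp = grp.sort_values("vertex_index")
        outlines.append(Outline(grp[["x", "y"]].to_numpy(dtype=float), frame=int(frame), label=str(label)))
    return outlines


# ---------------------------------------------------------------------------
# traces


def write_traces(path: str | Path, i: IntensityTrace, e: ExtensionTrace, **header_kw) -> None:
    df = pd.DataFrame({"time_s": i.times, "intensity_au": i.values, "tip_um": e.tip_position})
    write_csv(path, df, **header_kw)


def read_traces(path: str | Path) -> tuple[IntensityTrace, ExtensionTrace]:
    df = read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    return (
        IntensityTrace(t, df["intensity_au"].to_numpy(dtype=float)),
        ExtensionTrace(t, df["tip_um"].to_numpy(dtype=float)),
    )
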