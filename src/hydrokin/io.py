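"""On-disk formats: extended XYZ trajectories, minimal multi-MODEL PDB,
rate CSV tables, channel-path JSON/CSV, and JSON reports.

Extended XYZ is the canonical trajectory format here: human readable,
easy to fixture, closed under the package's own generators.  Each frame is

    <n_particles>
    time_ps=<t> box=<Lx>,<Ly>,<Lz> wrapped=<0|1>
    <id> <x> <y> <z>
    ...

with box/wrapped optional.  PDB support is read-only and minimal
(CRYST1 box, ATOM/HETATM coordinates, MODEL/ENDMDL framing).  All
numbers are written dot-decimal, locale independent; reports embed units
in key names and carry a provenance block.  Reports are deterministic:
identical inputs, settings and seed give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import __version__
from .channels import ChannelPath, WaterCountSeries
from .errors import FormatError
from .kinetics import RateSeries, SuperArrheniusFit, activation_energy
from .msd import DiffusionEstimate, MSDCurve, Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_rate_csv",
    "write_rate_csv",
    "write_msd_csv",
    "read_channel_json",
    "write_channel_json",
    "read_channel_csv",
    "write_water_counts_csv",
    "fit_report",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------- trajectories

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as extended XYZ (6-decimal coordinates)."""
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_particles))
        comment = f"time_ps={traj.times[f]:.6f}"
        if traj.box is not None:
            comment += " box=" + ",".join(f"{b:.6f}" for b in traj.box)
        comment += f" wrapped={int(traj.wrapped)}"
        lines.append(comment)
        for pid, (x, y, z) in zip(traj.particle_ids, traj.positions[f]):
            lines.append(f"{pid} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_xyz_comment(comment: str, frame: int) -> dict:
    out: dict = {}
    for token in comment.split():
        if "=" not in token:
            continue
        key, val = token.split("=", 1)
        try:
            if key == "time_ps":
                out["time"] = float(val)
            elif key == "box":
                out["box"] = [float(v) for v in val.split(",")]
            elif key == "wrapped":
                out["wrapped"] = bool(int(val))
        except ValueError as exc:
            raise FormatError(f"frame {frame}: bad comment token {token!r}") from exc
    return out


def _read_xyz(path: Path, dt: float) -> Trajectory:
    raw = path.read_text().splitlines()
    i, frame = 0, 0
    frames, times, boxes = [], [], []
    ids: list[str] | None = None
    wrapped = False
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            n = int(raw[i].strip())
        except ValueError as exc:
            raise FormatError(f"frame {frame}: expected atom count, got {raw[i]!r}") from exc
        if i + 1 + n >= len(raw) + 1:
            raise FormatError(f"frame {frame}: truncated ({n} atoms declared)")
        meta = _parse_xyz_comment(raw[i + 1], frame)
        coords = np.empty((n, 3))
        frame_ids = []
        for j in range(n):
            parts = raw[i + 2 + j].split()
            if len(parts) < 4:
                raise FormatError(f"frame {frame}, atom {j}: short line {raw[i + 2 + j]!r}")
            frame_ids.append(parts[0])
            try:
                coords[j] = [float(v) for v in parts[1:4]]
            except ValueError as exc:
                raise FormatError(f"frame {frame}, atom {j}: bad coordinate") from exc
        if ids is None:
            ids = frame_ids
        elif frame_ids != ids:
            raise FormatError(f"frame {frame}: particle ids/count differ from frame 0")
        frames.append(coords)
        times.append(meta.get("time", frame * dt))
        boxes.append(meta.get("box"))
        wrapped = meta.get("wrapped", wrapped)
        i += 2 + n
        frame += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    box = boxes[0]
    return Trajectory(
        times=np.asarray(times),
        positions=np.stack(frames),
        box=None if box is None else np.asarray(box),
        particle_ids=tuple(ids or ()),
        wrapped=wrapped,
    )


def _read_pdb(path: Path, dt: float) -> Trajectory:
    """Minimal multi-MODEL PDB reader: CRYST1 + ATOM/HETATM coordinates.

    Frame times are synthesized as 0, dt, 2 dt, ... (PDB carries none).
    """
    box = None
    frames: list[np.ndarray] = []
    ids: list[str] | None = None
    current: list[list[float]] | None = None
    current_ids: list[str] = []
    model_no = 0
    saw_model = False

    def close_frame(where: str) -> None:
        nonlocal current, ids
        if current is None:
            return
        if ids is None:
            ids = list(current_ids)
        elif current_ids != ids:
            raise FormatError(
                f"model {model_no}: atom records differ from the first model ({where})"
            )
        frames.append(np.asarray(current))
        current = None

    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "CRYST1":
            box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
        elif rec == "MODEL":
            if current is not None:
                raise FormatError(f"model {model_no}: MODEL before previous ENDMDL")
            saw_model = True
            model_no = int(line[6:].split()[0]) if line[6:].split() else model_no + 1
            current, current_ids = [], []
        elif rec == "ENDMDL":
            if current is None:
                raise FormatError(f"model {model_no}: ENDMDL without matching MODEL")
            close_frame("ENDMDL")
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if saw_model:
                    raise FormatError(
                        f"model {model_no}: atom record outside MODEL/ENDMDL"
                    )
                current, current_ids = [], []  # single implicit model
            name = line[12:16].strip()
            resseq = line[22:26].strip()
            current_ids.append(f"{name}_{resseq}_{len(current_ids)}")
            try:
                current.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise FormatError(f"model {model_no}: bad coordinates: {line!r}") from exc
    if current is not None:
        if saw_model:
            raise FormatError(f"model {model_no}: missing ENDMDL at end of file")
        close_frame("EOF")
    if not frames:
        raise FormatError(f"{path}: no coordinates found")
    times = np.arange(len(frames)) * dt
    return Trajectory(
        times=times,
        positions=np.stack(frames),
        box=box,
        particle_ids=tuple(ids or ()),
        wrapped=False,
    )


def read_trajectory(path: str | Path, format: str | None = None, dt: float = 1.0) -> Trajectory:
    """Read an extended-XYZ or minimal multi-MODEL PDB trajectory.

    ``format`` defaults from the file suffix; ``dt`` (ps) supplies frame
    times when the file carries none.
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() == ".pdb" else "xyz"
    if format == "xyz":
        return _read_xyz(path, dt)
    if format == "pdb":
        return _read_pdb(path, dt)
    raise FormatError(f"unknown trajectory format {format!r}")


# ----------------------------------------------------------------- rate tables

def read_rate_csv(path: str | Path, value_kind: str = "rate", label: str = "") -> RateSeries:
    """Read a `temperature_K,value` CSV (comment lines start with '#').

    Out-of-order temperatures are canonicalized ascending by RateSeries;
    duplicates and non-numeric cells raise with the offending line number.
    """
    temps, vals = [], []
    header_seen = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if not header_seen:
            cols = [c.strip() for c in s.split(",")]
            if cols[:2] != ["temperature_K", "value"]:
                raise FormatError(
                    f"line {lineno}: expected header 'temperature_K,value', got {s!r}"
                )
            header_seen = True
            continue
        parts = s.split(",")
        if len(parts) < 2:
            raise FormatError(f"line {lineno}: expected 2 columns, got {s!r}")
        try:
            temps.append(float(parts[0]))
            vals.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric cell in {s!r}") from exc
    if not header_seen:
        raise FormatError(f"{path}: missing 'temperature_K,value' header")
    return RateSeries(np.asarray(temps), np.asarray(vals), value_kind=value_kind, label=label)


def write_rate_csv(series: RateSeries, path: str | Path) -> None:
    lines = ["temperature_K,value"]
    for T, v in zip(series.temperatures, series.values):
        lines.append(f"{T:.6f},{v:.10e}")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ MSD tables

def write_msd_csv(curve: MSDCurve, path: str | Path) -> None:
    lines = ["lag_ps,msd_A2,n_samples"]
    for lag, m, n in zip(curve.lags, curve.msd, curve.n_samples):
        lines.append(f"{lag:.6f},{m:.10e},{int(n)}")
    Path(path).write_text("\n".join(lines) + "\n")


# -------------------------------------------------------------- channel paths

def write_channel_json(path_obj: ChannelPath, path: str | Path) -> None:
    doc = {
        "label": path_obj.label,
        "points": [[float(v) for v in p] for p in path_obj.points],
    }
    if path_obj.radii is not None:
        doc["radii"] = [float(r) for r in path_obj.radii]
    if path_obj.lining_residues is not None:
        doc["lining_residues"] = [[n, i] for n, i in path_obj.lining_residues]
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_channel_json(path: str | Path) -> ChannelPath:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if "points" not in doc:
        raise FormatError(f"{path}: channel JSON must contain 'points'")
    return ChannelPath(
        points=np.asarray(doc["points"], dtype=float),
        radii=np.asarray(doc["radii"], dtype=float) if "radii" in doc else None,
        lining_residues=tuple((n, int(i)) for n, i in doc["lining_residues"])
        if "lining_residues" in doc
        else None,
        label=doc.get("label", "other"),
    )


def read_channel_csv(path: str | Path, label: str = "other") -> ChannelPath:
    """Read an `x,y,z,radius` centerline CSV (radius column optional)."""
    pts, radii = [], []
    header_seen = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        parts = s.split(",")
        try:
            pts.append([float(v) for v in parts[:3]])
            if len(parts) >= 4 and parts[3].strip():
                radii.append(float(parts[3]))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric cell in {s!r}") from exc
    if not pts:
        raise FormatError(f"{path}: no centerline points")
    return ChannelPath(
        points=np.asarray(pts),
        radii=np.asarray(radii) if len(radii) == len(pts) else None,
        label=label,
    )


def write_water_counts_csv(series: WaterCountSeries, path: str | Path) -> None:
    lines = ["time_ps,count"]
    for t, c in zip(series.frame_times, series.counts):
        lines.append(f"{t:.6f},{int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------- reports

def _provenance(inputs: Mapping | None, settings: Mapping | None, seed) -> dict:
    return {
        "inputs": dict(inputs or {}),
        "settings": dict(settings or {}),
        "seed": seed,
        "package_version": __version__,
    }


def fit_report(
    fit: SuperArrheniusFit,
    ea_temperatures: Iterable[float] = (290.0, 300.0, 310.0),
) -> dict:
    """Serializable summary of one deformed-Arrhenius fit.

    Energies in key names carry explicit units; Ea values are kJ/mol
    (the single J -> kJ conversion at the reporting boundary).
    """
    return {
        "ln_pre": fit.ln_pre,
        "B_J_per_mol": fit.B,
        "C_J2_per_mol2": fit.C,
        "r_squared": fit.r_squared,
        "value_kind": fit.value_kind,
        "n_points": fit.n_points,
        "Ea_kJ_per_mol": {
            f"{T:g}": activation_energy(fit, T) / 1000.0 for T in ea_temperatures
        },
    }


def diffusion_report(est: DiffusionEstimate) -> dict:
    return {
        "D_m2_per_s": est.D,
        "stderr_D_m2_per_s": est.stderr_D,
        "V_A_per_ps": est.V,
        "fit_window_ps": list(est.fit_window),
        "msd_model": est.msd_model,
        "n_dim": est.n_dim,
        "clamped": est.clamped,
    }


def write_report(
    payload: Mapping,
    path: str | Path,
    *,
    inputs: Mapping | None = None,
    settings: Mapping | None = None,
    seed=None,
) -> None:
    """Write a JSON report with a provenance block, deterministically."""
    doc = dict(payload)
    doc["provenance"] = _provenance(inputs, settings, seed)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
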