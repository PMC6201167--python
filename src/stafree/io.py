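"""File formats: TRC and CSV marker files, topology/config YAML, result files.

Marker files hold one movement cycle of planar trajectories.  The TRC dialect
is the standard tab-separated motion-capture text format (DataRate header,
marker labels, X/Y/Z sub-columns); the two axes that carry the planar data are
configurable (default X, Y) and the third axis is written as zeros.  Units are
meters internally; TRC files declaring ``mm`` are converted on read.  The CSV
dialect has one row per sample with ``<label>_x, <label>_y`` columns and an
optional leading ``time`` column.  Marker labels default to ``<link>_<j>``; a
label map in the config can rename them onto topology slots.

Results are serialized as CSV time series plus a JSON file with coefficients,
shapes, diagnostics and seeds, so a run is reproducible from its artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ParseError
from .fourier import CycleGrid, FourierCoeffs2D
from .frames import (
    JointSpec,
    LinkSpec,
    LinkageTopology,
    MarkerTrajectorySet,
    PoseSeries,
)
from .gait import GaitModelParams, GroundReaction, StaProfileSet
from .results import AssimilationResult

__all__ = [
    "read_markers",
    "write_markers",
    "read_topology",
    "write_topology",
    "read_params",
    "write_params",
    "write_result",
    "read_poses",
    "write_poses",
    "read_joint_trajectories",
    "read_angles",
    "write_grf",
    "read_grf",
    "write_sta_profiles",
    "read_sta_profiles",
]

TRC_AXES = ("X", "Y", "Z")


def _slot_label(slot: tuple[str, int]) -> str:
    return f"{slot[0]}_{slot[1]}"


def _resolve_labels(
    topology: LinkageTopology, label_map: dict[str, tuple[str, int]] | None
) -> dict[str, tuple[str, int]]:
    if label_map is not None:
        return {lab: (link, int(j)) for lab, (link, j) in label_map.items()}
    return {_slot_label(s): s for s in topology.marker_slots()}


# ---------------------------------------------------------------------------
# Markers


def write_markers(
    path,
    markers: MarkerTrajectorySet,
    topology: LinkageTopology,
    fmt: str | None = None,
    axes: tuple[str, str] = ("X", "Y"),
    units: str = "m",
) -> None:
    path = Path(path)
    fmt = fmt or ("trc" if path.suffix.lower() == ".trc" else "csv")
    grid = markers.grid
    duration = grid.duration if grid.duration is not None else 1.0
    time = np.arange(grid.n_samples) * duration / grid.n_samples
    slots = topology.marker_slots()
    scale = 1000.0 if units == "mm" else 1.0
    if fmt == "trc":
        ia, ib = TRC_AXES.index(axes[0]), TRC_AXES.index(axes[1])
        rate = grid.n_samples / duration
        lines = [
            f"PathFileType\t4\t({'/'.join(TRC_AXES)})\t{path.name}",
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
            "OrigDataStartFrame\tOrigNumFrames",
            f"{rate:g}\t{rate:g}\t{grid.n_samples}\t{len(slots)}\t{units}\t"
            f"{rate:g}\t1\t{grid.n_samples}",
            "Frame#\tTime\t" + "\t\t\t".join(_slot_label(s) for s in slots) + "\t\t",
            "\t\t" + "\t".join(
                f"{ax}{i + 1}" for i in range(len(slots)) for ax in TRC_AXES
            ),
            "",
        ]
        for n in range(grid.n_samples):
            row = [str(n + 1), f"{time[n]:.9f}"]
            for slot in slots:
                xyz = [0.0, 0.0, 0.0]
                xyz[ia] = markers.positions[slot][n, 0] * scale
                xyz[ib] = markers.positions[slot][n, 1] * scale
                row += [f"{v:.12g}" for v in xyz]
            lines.append("\t".join(row))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "csv":
        data = {"time": time}
        for slot in slots:
            data[f"{_slot_label(slot)}_x"] = markers.positions[slot][:, 0]
            data[f"{_slot_label(slot)}_y"] = markers.positions[slot][:, 1]
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise InputError(f"unknown marker format {fmt!r}")


def read_markers(
    path,
    topology: LinkageTopology,
    fmt: str | None = None,
    label_map: dict[str, tuple[str, int]] | None = None,
    axes: tuple[str, str] = ("X", "Y"),
    duration: float | None = None,
) -> tuple[MarkerTrajectorySet, CycleGrid]:
    """Read one cycle of marker trajectories; returns the set and its grid."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"marker file not found: {path}")
    fmt = fmt or ("trc" if path.suffix.lower() == ".trc" else "csv")
    labels = _resolve_labels(topology, label_map)
    if fmt == "trc":
        positions, grid = _read_trc(path, labels, axes)
    elif fmt == "csv":
        positions, grid = _read_marker_csv(path, labels)
    else:
        raise InputError(f"unknown marker format {fmt!r}")
    if duration is not None:
        grid = CycleGrid(grid.n_samples, duration=duration)
    missing = [s for s in topology.marker_slots() if s not in positions]
    if missing:
        raise ParseError(
            f"marker file {path.name} is missing trajectories for slots {missing}"
        )
    return MarkerTrajectorySet(positions, grid), grid


def _check_uniform_time(time: np.ndarray, path: Path) -> float | None:
    if len(time) < 2:
        return None
    steps = np.diff(time)
    if np.any(np.abs(steps - steps[0]) > 1e-6):
        raise ParseError(f"{path.name}: timestamps are not uniform (tolerance 1e-6 s)")
    return float(steps[0] * len(time))


def _read_trc(path: Path, labels, axes) -> tuple[dict, CycleGrid]:
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path.name}: too short to be a TRC file")
    header = lines[2].split("\t")
    meta_keys = lines[1].split("\t")
    meta = dict(zip(meta_keys, header))
    try:
        n_frames = int(meta["NumFrames"])
        rate = float(meta["DataRate"])
        units = meta.get("Units", "m")
    except (KeyError, ValueError) as err:
        raise ParseError(f"{path.name}: malformed TRC header: {err}") from None
    scale = 1e-3 if units.lower() == "mm" else 1.0
    marker_names = [m for m in lines[3].split("\t")[2:] if m]
    ia, ib = TRC_AXES.index(axes[0]), TRC_AXES.index(axes[1])
    rows = []
    times = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 + 3 * len(marker_names):
            raise ParseError(
                f"{path.name}: ragged data row (expected {2 + 3 * len(marker_names)} "
                f"fields, got {len(parts)})"
            )
        times.append(float(parts[1]))
        rows.append([float(v) for v in parts[2:]])
    if len(rows) != n_frames:
        raise ParseError(
            f"{path.name}: header declares {n_frames} frames but file has {len(rows)}"
        )
    data = np.asarray(rows) * scale
    _check_uniform_time(np.asarray(times), path)
    positions = {}
    for i, name in enumerate(marker_names):
        if name not in labels:
            continue
        xyz = data[:, 3 * i : 3 * i + 3]
        positions[labels[name]] = np.column_stack([xyz[:, ia], xyz[:, ib]])
    grid = CycleGrid(len(rows), duration=len(rows) / rate if rate > 0 else None)
    return positions, grid


def _read_marker_csv(path: Path, labels) -> tuple[dict, CycleGrid]:
    try:
        df = pd.read_csv(path)
    except Exception as err:  # pandas raises various parse errors
        raise ParseError(f"{path.name}: {err}") from None
    duration = None
    if "time" in df.columns:
        duration = _check_uniform_time(df["time"].to_numpy(), path)
    positions = {}
    for label, slot in labels.items():
        cx, cy = f"{label}_x", f"{label}_y"
        if cx not in df.columns or cy not in df.columns:
            continue
        positions[slot] = np.column_stack([df[cx].to_numpy(), df[cy].to_numpy()])
    if not positions:
        raise ParseError(f"{path.name}: no '<label>_x/<label>_y' marker columns found")
    grid = CycleGrid(len(df), duration=duration)
    return positions, grid


# ---------------------------------------------------------------------------
# Topology / parameters


def write_topology(path, topology: LinkageTopology) -> None:
    doc = {
        "links": {
            name: {
                "landmarks_local": None
                if spec.landmarks_local is None
                else spec.landmarks_local.tolist()
            }
            for name, spec in topology.links.items()
        },
        "joints": [
            {
                "name": j.name,
                "proximal": j.proximal,
                "distal": j.distal,
                "angle_offset": float(j.angle_offset),
            }
            for j in topology.joints
        ],
        "root": topology.root,
        "root_angle_offset": float(topology.root_angle_offset),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_topology(path) -> LinkageTopology:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"topology file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
        links = {
            name: LinkSpec(name, entry.get("landmarks_local"))
            for name, entry in doc["links"].items()
        }
        joints = [
            JointSpec(
                j["name"], j["proximal"], j["distal"], float(j.get("angle_offset", 0.0))
            )
            for j in doc["joints"]
        ]
        return LinkageTopology(
            links, joints, doc.get("root"), float(doc.get("root_angle_offset", 0.0))
        )
    except (KeyError, TypeError, yaml.YAMLError) as err:
        raise ParseError(f"{path.name}: malformed topology: {err}") from None


def write_params(path, params: GaitModelParams) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(params), sort_keys=False))


def read_params(path) -> GaitModelParams:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"parameter file not found: {path}")
    try:
        return GaitModelParams(**yaml.safe_load(path.read_text()))
    except (TypeError, yaml.YAMLError) as err:
        raise ParseError(f"{path.name}: malformed parameters: {err}") from None


# ---------------------------------------------------------------------------
# Time-series artifacts


def _time_column(grid: CycleGrid) -> np.ndarray:
    duration = grid.duration if grid.duration is not None else 1.0
    return np.arange(grid.n_samples) * duration / grid.n_samples


def write_poses(path, poses: dict[str, PoseSeries], grid: CycleGrid) -> None:
    data: dict[str, np.ndarray] = {"time": _time_column(grid)}
    for name, series in poses.items():
        data[f"{name}_x"] = series.origins[:, 0]
        data[f"{name}_y"] = series.origins[:, 1]
        data[f"{name}_angle"] = series.angles
    pd.DataFrame(data).to_csv(path, index=False)


def read_poses(path) -> tuple[dict[str, PoseSeries], CycleGrid]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"pose file not found: {path}")
    df = pd.read_csv(path)
    duration = _check_uniform_time(df["time"].to_numpy(), path)
    grid = CycleGrid(len(df), duration=duration)
    names = [c[:-6] for c in df.columns if c.endswith("_angle")]
    poses = {
        name: PoseSeries.from_angles(
            np.column_stack([df[f"{name}_x"], df[f"{name}_y"]]),
            df[f"{name}_angle"].to_numpy(),
        )
        for name in names
    }
    return poses, grid


def _write_xy_series(path, series: dict[str, np.ndarray], grid: CycleGrid) -> None:
    data: dict[str, np.ndarray] = {"time": _time_column(grid)}
    for name, arr in series.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            data[f"{name}_x"], data[f"{name}_y"] = arr[:, 0], arr[:, 1]
        else:
            data[name] = arr
    pd.DataFrame(data).to_csv(path, index=False)


def read_joint_trajectories(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    names = [c[:-2] for c in df.columns if c.endswith("_x")]
    return {
        name: np.column_stack([df[f"{name}_x"], df[f"{name}_y"]]) for name in names
    }


def read_angles(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {c: df[c].to_numpy() for c in df.columns if c != "time"}


def write_grf(path, grf: GroundReaction, grid: CycleGrid) -> None:
    data: dict[str, np.ndarray] = {"time": _time_column(grid)}
    for side in grf.forces:
        data[f"{side}_fx"] = grf.forces[side][:, 0]
        data[f"{side}_fy"] = grf.forces[side][:, 1]
        data[f"{side}_copx"] = grf.cops[side][:, 0]
        data[f"{side}_copy"] = grf.cops[side][:, 1]
        data[f"{side}_stance"] = grf.stance[side].astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


def read_grf(path) -> GroundReaction:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"GRF file not found: {path}")
    df = pd.read_csv(path)
    sides = sorted({c.split("_")[0] for c in df.columns if c.endswith("_fx")})
    forces = {s: np.column_stack([df[f"{s}_fx"], df[f"{s}_fy"]]) for s in sides}
    cops = {s: np.column_stack([df[f"{s}_copx"], df[f"{s}_copy"]]) for s in sides}
    stance = {s: df[f"{s}_stance"].to_numpy().astype(bool) for s in sides}
    return GroundReaction(forces, cops, stance)


def write_sta_profiles(path, profiles: StaProfileSet) -> None:
    doc = {
        "seed": profiles.seed,
        "amplitude": profiles.amplitude,
        "order": profiles.order,
        "profiles": {
            _slot_label(slot): {"qx": c.qx.tolist(), "qy": c.qy.tolist()}
            for slot, c in profiles.profiles.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_sta_profiles(path) -> StaProfileSet:
    doc = json.loads(Path(path).read_text())
    profiles = {}
    for label, entry in doc["profiles"].items():
        link, j = label.rsplit("_", 1)
        profiles[(link, int(j))] = FourierCoeffs2D(
            doc["order"], np.asarray(entry["qx"]), np.asarray(entry["qy"])
        )
    return StaProfileSet(profiles, doc["seed"], doc["amplitude"], doc["order"])


# ---------------------------------------------------------------------------
# Assimilation results


def _jsonable(obj):
    """Recursively convert a report to JSON-safe types, dropping heavy objects."""
    if isinstance(obj, dict):
        return {
            str(k): _jsonable(v)
            for k, v in obj.items()
            if k != "candidates"  # ShapeParams lists; summarized elsewhere
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


def write_result(
    out_dir, result: AssimilationResult, grid: CycleGrid, meta: dict | None = None
) -> None:
    """Serialize an assimilation result: CSV time series plus result.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_xy_series(out / "angles.csv", result.joint_angles, grid)
    _write_xy_series(out / "joints.csv", result.joint_trajectories, grid)
    _write_xy_series(out / "lengths.csv", result.link_lengths, grid)
    write_poses(out / "poses.csv", result.link_frames, grid)
    write_poses(out / "landmark_frames.csv", result.landmark_frames, grid)
    doc: dict = {"report": _jsonable(result.report), "meta": meta or {}}
    doc["joint_locals"] = {
        f"{link}:{joint}": v.tolist() for (link, joint), v in result.joint_locals.items()
    }
    if result.shapes is not None:
        doc["shapes"] = {
            name: {
                "C": s.C,
                "xi_x": s.xi_x.tolist(),
                "xi_y": s.xi_y.tolist(),
                "residual_norm": s.diagnostics.get("residual_norm"),
                "n_candidates": s.diagnostics.get("n_candidates"),
            }
            for name, s in result.shapes.items()
        }
    if result.sta is not None:
        doc["sta"] = {
            _slot_label(slot): {"qx": c.qx.tolist(), "qy": c.qy.tolist()}
            for slot, c in result.sta.items()
        }
    (out / "result.json").write_text(json.dumps(doc, indent=1))
    if result.landmark_markers is not None:
        _write_xy_series(
            out / "landmark_markers.csv",
            {_slot_label(s): arr for s, arr in result.landmark_markers.positions.items()},
            grid,
        )
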