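"""File formats and run configuration.

Conventions: coordinates are millimetres in files and containers; angles
are degrees at the I/O boundary; CSV files are comma-separated, UTF-8,
'.' decimal, with a mandatory header row. Trajectories travel as long
CSV (frame, time_s, point_id, x_mm, y_mm, z_mm) with generator ground
truth in a JSON sidecar; landmark configurations travel as tps-dialect
files (LM= blocks with ID= keys and optional SCALE=) or wide CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometrics import ShapeSet
from .recording import FlightRecording, THORAX_LABELS, WING_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_landmark_file",
    "read_landmark_file",
    "write_shapes_csv",
    "read_shapes_csv",
]

_TRAJ_COLUMNS = ["frame", "time_s", "point_id", "x_mm", "y_mm", "z_mm"]


@dataclass
class RunConfig:
    """Run options recorded in every output for provenance."""

    seed: int = 0
    smoothing_window: int | None = None
    midstroke_rule: str = "angle-midpoint"
    beam_constant_k: float = 3.0
    load_distances_l_m: dict[int, float] = field(default_factory=dict)
    tangent_projection: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trajectory_csv(recording: FlightRecording, path: str | Path) -> Path:
    """Long-format trajectory CSV; ground truth (if any) to a JSON sidecar."""
    path = Path(path)
    rows = []
    for label_set, store in (
        (THORAX_LABELS, recording.thorax_points),
        (WING_LABELS, recording.wing_points),
    ):
        for label in label_set:
            arr = store[label]
            for i in range(recording.n_frames):
                rows.append(
                    (i, recording.times[i], label, arr[i, 0], arr[i, 1], arr[i, 2])
                )
    df = pd.DataFrame(rows, columns=_TRAJ_COLUMNS)
    df.to_csv(path, index=False)
    if recording.ground_truth is not None:
        serializable = _jsonify(recording.ground_truth)
        _sidecar(path).write_text(json.dumps(serializable))
    return path


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_trajectory_csv(path: str | Path) -> FlightRecording:
    """Read a long-format trajectory CSV back into a recording.

    Out-of-order frames are sorted (with a warning); duplicated
    (frame, point_id) pairs or missing columns are errors. A validation
    pass checks that every point shares the common frame set.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file missing columns: {missing}")
    if df.duplicated(subset=["frame", "point_id"]).any():
        dupes = df[df.duplicated(subset=["frame", "point_id"], keep=False)]
        raise ValueError(
            f"duplicate (frame, point_id) rows: {dupes[['frame', 'point_id']].values[:5].tolist()}"
        )
    if not df["frame"].is_monotonic_increasing:
        logger.warning("frames out of order in %s; sorting", path)
    df = df.sort_values(["point_id", "frame"], kind="mergesort")
    frames = np.sort(df["frame"].unique())
    times = (
        df.drop_duplicates("frame").set_index("frame")["time_s"].sort_index().to_numpy()
    )
    gaps = [
        pid
        for pid, sub in df.groupby("point_id")
        if len(sub) != len(frames)
    ]
    if gaps:
        raise ValueError(f"points with missing frames: {gaps}")
    store: dict[str, np.ndarray] = {}
    for pid, sub in df.groupby("point_id"):
        store[str(pid)] = sub.sort_values("frame")[["x_mm", "y_mm", "z_mm"]].to_numpy()
    thorax = {l: store[l] for l in THORAX_LABELS if l in store}
    wing = {l: store[l] for l in WING_LABELS if l in store}
    truth = None
    if _sidecar(path).exists():
        truth = json.loads(_sidecar(path).read_text())
    return FlightRecording(
        times=times, thorax_points=thorax, wing_points=wing, ground_truth=truth
    )


def write_landmark_file(shapes: ShapeSet, path: str | Path) -> Path:
    """tps-dialect landmark file: LM= count, coordinate lines, ID= key."""
    path = Path(path)
    lines = []
    for config, sid in zip(shapes.configurations, shapes.specimen_ids):
        lines.append(f"LM={config.shape[0]}")
        for x, y in config:
            lines.append(f"{x:.10g} {y:.10g}")
        lines.append(f"ID={sid}")
        lines.append("")
    path.write_text("\n".join(lines))
    return path


def _species_from_id(sid: str) -> str:
    return sid.rsplit("_", 1)[0] if "_" in sid else sid


def read_landmark_file(path: str | Path) -> ShapeSet:
    """Read tps-dialect (.tps) or wide CSV landmark files.

    In tps blocks, SCALE= (if present) multiplies the coordinates; species
    labels are parsed from ID= keys of the form ``species_specimen``.
    Inconsistent landmark counts across specimens are an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_shapes_csv(path)
    configs, ids = [], []
    current: list[list[float]] | None = None
    expected = None
    sid = None
    scale = 1.0

    def _flush():
        nonlocal current, sid, scale
        if current is None:
            return
        arr = np.asarray(current, float) * scale
        if len(arr) != expected:
            raise ValueError(
                f"specimen {sid or len(configs)}: {len(arr)} landmarks, LM={expected}"
            )
        configs.append(arr)
        ids.append(sid or f"specimen_{len(configs)}")
        current, sid, scale = None, None, 1.0

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            _flush()
            expected = int(line.split("=", 1)[1])
            current = []
        elif upper.startswith("ID="):
            sid = line.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            scale = float(line.split("=", 1)[1])
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            continue  # IMAGE= and other metadata keys
        else:
            if current is None:
                raise ValueError("coordinate line before any LM= header")
            parts = line.replace(",", " ").split()
            current.append([float(parts[0]), float(parts[1])])
    _flush()
    if not configs:
        raise ValueError(f"no landmark blocks found in {path}")
    counts = {c.shape[0] for c in configs}
    if len(counts) != 1:
        bad = [i for i, c in zip(ids, configs) if c.shape[0] != configs[0].shape[0]]
        raise ValueError(f"inconsistent landmark counts for specimens: {bad}")
    return ShapeSet(
        configurations=np.stack(configs),
        specimen_ids=ids,
        species_labels=[_species_from_id(s) for s in ids],
    )


def write_shapes_csv(shapes: ShapeSet, path: str | Path) -> Path:
    """Wide CSV: specimen_id, species, then x1,y1,...,xk,yk columns."""
    path = Path(path)
    k = shapes.n_landmarks
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
    flat = shapes.configurations.reshape(len(shapes.specimen_ids), -1)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "species", shapes.species_labels)
    df.insert(0, "specimen_id", shapes.specimen_ids)
    df.to_csv(path, index=False)
    return path


def read_shapes_csv(path: str | Path) -> ShapeSet:
    df = pd.read_csv(path)
    for col in ("specimen_id", "species"):
        if col not in df.columns:
            raise ValueError(f"shapes CSV missing column {col!r}")
    coord_cols = [c for c in df.columns if c[0] in "xy" and c[1:].isdigit()]
    k = len(coord_cols) // 2
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
    configs = df[cols].to_numpy().reshape(len(df), k, 2)
    return ShapeSet(
        configurations=configs,
        specimen_ids=df["specimen_id"].astype(str).tolist(),
        species_labels=df["species"].astype(str).tolist(),
    )
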