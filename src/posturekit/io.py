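"""Reading and writing landmark recordings and feature tables.

Two on-disk dialects are supported:

``landmark_csv``
    Header ``time_s,view,landmark,x_m,y_m,z_m``, one row per landmark per
    frame, UTF-8.  Optional leading comment lines carry metadata::

        # subject_id: s01
        # window frontal_relaxed 0 5

``kinect_json``
    JSON-lines: one object per frame with fields ``time_s``, ``view`` and
    ``joints`` (Kinect-v2 joint name -> [x, y, z] metres).  An optional
    object without a ``joints`` field (any position in the file) carries
    ``subject_id`` and/or ``windows`` metadata.  Landmarks are derived from
    the skeleton per frame (:func:`derive_landmarks`).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .session import (
    ANKLE_JOINTS,
    LANDMARKS,
    LandmarkFrame,
    Session,
    SkeletonFrame,
    infer_windows,
)

DIALECTS = ("landmark_csv", "kinect_json")

#: Anatomical landmark -> Kinect-v2 joint. LM and FC have procedural
#: definitions (ankle midpoint; spine-curve search) and are not listed.
DEFAULT_JOINT_MAP = {
    "MH": "Head",
    "MN": "Neck",
    "C7": "SpineShoulder",
    "L5": "SpineBase",
}

#: Joints the vertebral-fulcrum search interpolates through, cranial first.
SPINE_CURVE_JOINTS = ("SpineShoulder", "SpineMid", "SpineBase")

#: Number of samples along the spine curve when locating the fulcrum.
FC_SAMPLES = 51

_FEATURE_COLUMNS = ("F1", "F2", "F3", "F4", "F5", "F7")
_CORE_COLUMNS = ("subject_id", "group") + _FEATURE_COLUMNS + ("IPA",)


def bezier_spine(p0, p1, p2, t):
    """Quadratic Bezier curve through the three spine joints, vectorised in t."""
    t = np.asarray(t, dtype=float)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def derive_landmarks(
    sk: SkeletonFrame,
    joint_map: Mapping[str, str] | None = None,
    n_samples: int = FC_SAMPLES,
) -> LandmarkFrame:
    """Map a Kinect-v2 skeleton frame to the six anatomical landmarks.

    MH/MN/C7/L5 map directly onto joints (configurable via ``joint_map``),
    LM is the midpoint of the available ankle joints, and FC -- the most
    convex point of the spine -- is the point of maximal perpendicular
    distance to the C7-L5 chord, searched along a quadratic Bezier curve
    through (SpineShoulder, SpineMid, SpineBase) at ``n_samples`` equally
    spaced parameters, with the distance evaluated in the sagittal (Y-Z)
    projection.  Ties go to the most cranial sample.
    """
    jm = dict(DEFAULT_JOINT_MAP)
    if joint_map:
        jm.update(joint_map)
    joints = sk.joints
    positions: dict[str, np.ndarray] = {}
    for landmark, joint in jm.items():
        if joint not in joints:
            raise ValueError(
                f"frame t={sk.time:g}: joint {joint!r} (for landmark {landmark!r}) missing"
            )
        positions[landmark] = joints[joint]

    ankles = [joints[a] for a in ANKLE_JOINTS if a in joints]
    if not ankles:
        raise ValueError(f"frame t={sk.time:g}: both ankle joints missing")
    positions["LM"] = np.mean(ankles, axis=0)

    p0, p1, p2 = (joints[j] for j in SPINE_CURVE_JOINTS)
    curve = bezier_spine(p0, p1, p2, np.linspace(0.0, 1.0, n_samples))
    # Sagittal projection: (z, y); distance to the projected C7-L5 chord.
    a = positions["C7"][[2, 1]]
    b = positions["L5"][[2, 1]]
    chord = b - a
    norm = np.hypot(*chord)
    if norm == 0.0:
        raise ValueError(f"frame t={sk.time:g}: C7 and L5 coincide in the sagittal plane")
    rel = curve[:, [2, 1]] - a
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    # ties (within float noise) go to the first, i.e. most cranial, sample
    best = int(np.flatnonzero(dist >= dist.max() - 1e-12)[0])
    positions["FC"] = curve[best]

    return LandmarkFrame(time=sk.time, view=sk.view, positions=positions)


# ---------------------------------------------------------------------------
# landmark_csv


def _format_float(x: float) -> str:
    return repr(float(x))  # shortest exact decimal round trip


def write_landmarks(session: Session, path) -> None:
    """Write a session in the landmark_csv dialect (lossless round trip)."""
    lines = [f"# subject_id: {session.subject_id}"]
    for name in sorted(session.windows):
        start, end = session.windows[name]
        lines.append(f"# window {name} {_format_float(start)} {_format_float(end)}")
    lines.append("time_s,view,landmark,x_m,y_m,z_m")
    for frame in session.frames:
        for landmark in LANDMARKS:
            x, y, z = frame[landmark]
            lines.append(
                f"{_format_float(frame.time)},{frame.view},{landmark},"
                f"{_format_float(x)},{_format_float(y)},{_format_float(z)}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_landmark_csv(path) -> Session:
    subject_id = Path(path).stem
    windows: dict[str, tuple[float, float]] = {}
    body_lines = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            meta = line.lstrip("#").strip()
            if meta.startswith("subject_id:"):
                subject_id = meta.split(":", 1)[1].strip()
            elif meta.startswith("window "):
                try:
                    _, name, start, end = meta.split()
                    windows[name] = (float(start), float(end))
                except ValueError as exc:
                    raise ValueError(f"malformed window metadata line: {line!r}") from exc
        elif line.strip():
            body_lines.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    expected = ["time_s", "view", "landmark", "x_m", "y_m", "z_m"]
    if list(df.columns) != expected:
        raise ValueError(f"landmark_csv header must be {','.join(expected)}")

    frames = []
    for (t, view), rows in df.groupby(["time_s", "view"], sort=True):
        positions = {
            r.landmark: np.array([r.x_m, r.y_m, r.z_m]) for r in rows.itertuples()
        }
        frames.append(LandmarkFrame(time=float(t), view=str(view), positions=positions))
    if not windows:
        windows = infer_windows(frames)
    return Session(subject_id=subject_id, frames=frames, windows=windows)


# ---------------------------------------------------------------------------
# kinect_json


def write_kinect_json(frames, path, subject_id: str = "", windows=None) -> None:
    """Write skeleton frames as JSON lines (with an optional metadata line)."""
    records = []
    meta: dict = {}
    if subject_id:
        meta["subject_id"] = subject_id
    if windows:
        meta["windows"] = {k: list(v) for k, v in windows.items()}
    if meta:
        records.append(meta)
    for f in frames:
        records.append(
            {
                "time_s": f.time,
                "view": f.view,
                "joints": {k: [float(c) for c in v] for k, v in f.joints.items()},
            }
        )
    Path(path).write_text(
        "\n".join(json.dumps(r) for r in records) + "\n", encoding="utf-8"
    )


def _read_kinect_json(path, joint_map=None) -> Session:
    subject_id = Path(path).stem
    windows: dict[str, tuple[float, float]] = {}
    frames = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: line {lineno} is not valid JSON") from exc
        if "joints" not in obj:
            subject_id = obj.get("subject_id", subject_id)
            for name, (start, end) in obj.get("windows", {}).items():
                windows[name] = (float(start), float(end))
            continue
        sk = SkeletonFrame(
            time=float(obj["time_s"]),
            view=str(obj["view"]),
            joints={k: np.asarray(v, dtype=float) for k, v in obj["joints"].items()},
        )
        frames.append(derive_landmarks(sk, joint_map=joint_map))
    if not windows:
        windows = infer_windows(frames)
    return Session(subject_id=subject_id, frames=frames, windows=windows)


def read_landmarks(path, dialect: str = "landmark_csv", joint_map=None) -> Session:
    """Read a recording session in the named dialect.

    Window boundaries come from file metadata when present, otherwise the
    default acquisition protocol (5 s relaxed, 5 s corrected per view) is
    inferred from the frame timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "landmark_csv":
        return _read_landmark_csv(path)
    if dialect == "kinect_json":
        return _read_kinect_json(path, joint_map=joint_map)
    raise ValueError(f"unknown dialect {dialect!r} (expected one of {DIALECTS})")


# ---------------------------------------------------------------------------
# feature tables


def write_features(table: pd.DataFrame, path) -> None:
    """Write a cohort feature table as CSV with a stable column order.

    Column order is subject_id, group, F1..F5, F7, IPA, then any remaining
    (clinical-scale) columns in their existing order.  Missing values are
    written as empty cells; re-reading with :func:`read_features`
    reproduces the table.
    """
    if "subject_id" not in table.columns:
        raise ValueError("feature table must have a 'subject_id' column")
    df = table.copy()
    for col in _CORE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    extras = [c for c in table.columns if c not in _CORE_COLUMNS]
    df = df[list(_CORE_COLUMNS) + extras]
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_features`."""
    df = pd.read_csv(
        path, dtype={"subject_id": str, "group": str}, float_precision="round_trip"
    )
    for col in df.columns:
        # whole-valued measurements must not silently become integers
        if pd.api.types.is_integer_dtype(df[col]):
            df[col] = df[col].astype(float)
    return df
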