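"""Core in-memory containers for landmark recordings.

A recording session follows a fixed acquisition script: the subject stands
~2 m in front of the depth camera, holds a relaxed stance for 5 s, actively
corrects their posture for 5 s, then turns 90 degrees and repeats, giving
four protocol windows (frontal/lateral x relaxed/corrected).

Coordinates are metres in the camera frame: X lateral, Y vertical up,
Z depth toward the subject.  The camera is assumed level; no gravity
calibration is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: The six anatomical landmarks the feature set is defined on:
#: MH midpoint of head, MN midpoint of neck, C7 7th cervical spinous
#: process, L5 5th lumbar spinous process, FC vertebral fulcrum (most
#: convex point of the spine), LM lateral malleolus.
LANDMARKS = ("MH", "MN", "C7", "L5", "FC", "LM")

VIEWS = ("frontal", "lateral")

#: Protocol windows in acquisition order.
WINDOW_NAMES = (
    "frontal_relaxed",
    "frontal_corrected",
    "lateral_relaxed",
    "lateral_corrected",
)

#: Default duration of each protocol window (seconds).
WINDOW_SECONDS = 5.0


def _as_point(value, *, context: str) -> np.ndarray:
    p = np.asarray(value, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"{context}: expected a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{context}: non-finite coordinate {p.tolist()}")
    return p


@dataclass(frozen=True)
class LandmarkFrame:
    """One timestamped view of the six anatomical landmarks.

    Parameters
    ----------
    time : float
        Seconds from the start of the recording (>= 0).
    view : str
        ``"frontal"`` or ``"lateral"``.
    positions : mapping
        Landmark name -> 3D position in metres.
    """

    time: float
    view: str
    positions: Mapping[str, np.ndarray]

    def __post_init__(self):
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ValueError(f"frame time must be finite and >= 0, got {self.time}")
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r} (expected one of {VIEWS})")
        pos = {}
        for name in LANDMARKS:
            if name not in self.positions:
                raise ValueError(
                    f"frame t={self.time:g}: missing landmark {name!r}"
                )
            pos[name] = _as_point(
                self.positions[name], context=f"frame t={self.time:g}, landmark {name!r}"
            )
        extra = set(self.positions) - set(LANDMARKS)
        if extra:
            raise ValueError(
                f"frame t={self.time:g}: unknown landmark(s) {sorted(extra)}"
            )
        # Standing-subject sanity: head above pelvis above ankle.
        if not (pos["MH"][1] > pos["L5"][1] > pos["LM"][1]):
            raise ValueError(
                f"frame t={self.time:g}: vertical ordering Y(MH) > Y(L5) > Y(LM) violated"
            )
        object.__setattr__(self, "positions", pos)

    def __getitem__(self, landmark: str) -> np.ndarray:
        return self.positions[landmark]


#: Kinect-v2 joints required to derive the six landmarks.
REQUIRED_JOINTS = ("Head", "Neck", "SpineShoulder", "SpineMid", "SpineBase")
ANKLE_JOINTS = ("AnkleLeft", "AnkleRight")


@dataclass(frozen=True)
class SkeletonFrame:
    """One timestamped 25-joint (or partial) Kinect-v2 skeleton."""

    time: float
    view: str
    joints: Mapping[str, np.ndarray]

    def __post_init__(self):
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ValueError(f"frame time must be finite and >= 0, got {self.time}")
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r} (expected one of {VIEWS})")
        joints = {}
        for name, value in self.joints.items():
            joints[name] = _as_point(
                value, context=f"frame t={self.time:g}, joint {name!r}"
            )
        for name in REQUIRED_JOINTS:
            if name not in joints:
                raise ValueError(f"frame t={self.time:g}: missing joint {name!r}")
        if not any(a in joints for a in ANKLE_JOINTS):
            raise ValueError(
                f"frame t={self.time:g}: both ankle joints missing "
                f"(need at least one of {ANKLE_JOINTS})"
            )
        object.__setattr__(self, "joints", joints)


@dataclass
class Session:
    """An ordered landmark recording plus its protocol window boundaries.

    ``windows`` maps a window name to a half-open ``[start, end)`` time
    interval in seconds.  Declared windows must be non-overlapping, contain
    at least one frame, and contain only frames of the matching view.
    """

    subject_id: str
    frames: list[LandmarkFrame] = field(default_factory=list)
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.frames = sorted(self.frames, key=lambda f: f.time)
        self._validate()

    def _validate(self) -> None:
        intervals = []
        for name, (start, end) in self.windows.items():
            if name not in WINDOW_NAMES:
                raise ValueError(f"unknown window name {name!r}")
            if not (start < end):
                raise ValueError(f"window {name!r}: empty interval [{start}, {end})")
            intervals.append((start, end, name))
        intervals.sort()
        for (s0, e0, n0), (s1, e1, n1) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise ValueError(f"windows {n0!r} and {n1!r} overlap")
        for name in self.windows:
            frames = self.frames_in(name)
            if not frames:
                raise ValueError(f"window {name!r} contains no frames")
            view = name.split("_")[0]
            for f in frames:
                if f.view != view:
                    raise ValueError(
                        f"window {name!r} contains a {f.view}-view frame at t={f.time:g}"
                    )

    def frames_in(self, window: str) -> list[LandmarkFrame]:
        """Frames whose timestamp falls in the named declared window."""
        if window not in self.windows:
            return []
        start, end = self.windows[window]
        return [f for f in self.frames if start <= f.time < end]


def infer_windows(frames: Iterable[LandmarkFrame]) -> dict[str, tuple[float, float]]:
    """Default protocol windows: per view, first 5 s relaxed, next 5 s corrected.

    Boundaries are anchored at the first frame time of each view.  Only
    windows that actually contain a frame are declared.  Raises if the two
    views overlap in time (then the file must carry explicit window
    metadata).
    """
    frames = list(frames)
    out: dict[str, tuple[float, float]] = {}
    spans = {}
    for view in VIEWS:
        times = [f.time for f in frames if f.view == view]
        if not times:
            continue
        spans[view] = (min(times), max(times))
        t0 = min(times)
        for i, phase in enumerate(("relaxed", "corrected")):
            start = t0 + i * WINDOW_SECONDS
            end = start + WINDOW_SECONDS
            if any(start <= t < end for t in times):
                out[f"{view}_{phase}"] = (start, end)
    intervals = sorted((v, k) for k, v in out.items())
    for ((s0, e0), n0), ((s1, e1), n1) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise ValueError(
                f"inferred windows {n0!r} and {n1!r} overlap in time; "
                "provide explicit window metadata"
            )
    return out
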