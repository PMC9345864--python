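"""Six-feature posture geometry.

The stance is summarized by six scalar features measured against VL, the
vertical line of the ground:

* F1 -- lateral flexion of the head: angle between the MH-C7 line and VL
  on the coronal plane (degrees).
* F2 -- lateral flexion of the trunk: angle between the C7-L5 line and VL
  on the coronal plane (degrees).
* F3 -- forward flexion of the head: angle between the MH-MN line and VL
  on the sagittal plane (degrees).
* F4 -- total forward flexion of the trunk: angle between the L5-LM line
  and the C7-L5 line on the sagittal plane (degrees).
* F5 -- forward flexion at the waist: angle between the L5-LM line and the
  FC-L5 line on the sagittal plane (degrees).
* F7 -- 100 * D1 / D2 (percent), where D1 is the distance from FC to the
  C7-L5 line and D2 = |C7-L5|, both sagittal; the normalization removes
  anthropometric scale.

Angles are unsigned deviations from neutral: a perfectly erect stance
scores zero on every feature.  F4/F5 use the deviation-from-collinearity
convention (180 degrees minus the angle between the two direction
vectors), so an erect L5->LM (down) against L5->C7 (up) also gives zero.

Coronal-plane features are measured on frontal-view frames (drop Z),
sagittal-plane features on lateral-view frames (drop X); V is the vertical
camera axis Y in both projections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .session import Session

FEATURE_NAMES = ("F1", "F2", "F3", "F4", "F5", "F7")

WINDOW_POLICIES = ("relaxed", "corrected")


class PlanePoint(NamedTuple):
    """A point in an anatomical plane: u horizontal in-plane, v vertical."""

    u: float
    v: float


def project(p, plane: str) -> PlanePoint:
    """Project a 3D camera-frame point onto the coronal or sagittal plane.

    coronal: (u, v) = (X, Y); sagittal: (u, v) = (Z, Y).
    """
    p = np.asarray(p, dtype=float)
    if plane == "coronal":
        return PlanePoint(float(p[0]), float(p[1]))
    if plane == "sagittal":
        return PlanePoint(float(p[2]), float(p[1]))
    raise ValueError(f"unknown plane {plane!r} (expected 'coronal' or 'sagittal')")


def angle_to_vertical(a: PlanePoint, b: PlanePoint) -> float:
    """Unsigned acute angle (degrees, [0, 90]) between the line a-b and vertical."""
    du = abs(b.u - a.u)
    dv = abs(b.v - a.v)
    if du == 0.0 and dv == 0.0:
        raise ValueError("degenerate segment: coincident points")
    return math.degrees(math.atan2(du, dv))


def angle_between(a1: PlanePoint, a2: PlanePoint, b1: PlanePoint, b2: PlanePoint) -> float:
    """Deviation-from-collinearity angle (degrees, [0, 180]) between two segments.

    Returns 180 minus the angle between direction vectors (a2 - a1) and
    (b2 - b1), so antiparallel segments (an erect trunk over a vertical
    leg) score zero.
    """
    v1 = np.array([a2.u - a1.u, a2.v - a1.v])
    v2 = np.array([b2.u - b1.u, b2.v - b1.v])
    n1 = np.hypot(*v1)
    n2 = np.hypot(*v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("degenerate segment: coincident points")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return 180.0 - math.degrees(math.acos(cosang))


def perp_distance(p: PlanePoint, l1: PlanePoint, l2: PlanePoint) -> float:
    """Perpendicular distance from p to the infinite line through l1, l2 (metres)."""
    d = np.array([l2.u - l1.u, l2.v - l1.v])
    norm = np.hypot(*d)
    if norm == 0.0:
        raise ValueError("degenerate line: coincident points")
    r = np.array([p.u - l1.u, p.v - l1.v])
    return float(abs(r[0] * d[1] - r[1] * d[0]) / norm)


@dataclass(frozen=True)
class FeatureVector:
    """The six features for one session, aggregated over protocol windows.

    F1..F5 in degrees, F7 in percent; each is the per-frame median over the
    relevant window (frontal for F1/F2, lateral for F3/F4/F5/F7).
    """

    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f7: float
    n_frontal: int = 1
    n_lateral: int = 1
    window_policy: str = "relaxed"
    aggregation: str = "median"

    def __post_init__(self):
        for name in ("f1", "f2", "f3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name.upper()} must be in [0, 90], got {v}")
        for name in ("f4", "f5"):
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ValueError(f"{name.upper()} must be in [0, 180], got {v}")
        if self.f7 < 0.0:
            raise ValueError(f"F7 must be >= 0, got {self.f7}")
        if min(self.n_frontal, self.n_lateral) < 1:
            raise ValueError("frame counts must be >= 1")

    def values(self) -> np.ndarray:
        """Features in canonical order (F1, F2, F3, F4, F5, F7)."""
        return np.array([self.f1, self.f2, self.f3, self.f4, self.f5, self.f7])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values()))


def _frontal_features(frame) -> tuple[float, float]:
    mh = project(frame["MH"], "coronal")
    c7 = project(frame["C7"], "coronal")
    l5 = project(frame["L5"], "coronal")
    return angle_to_vertical(mh, c7), angle_to_vertical(c7, l5)


def _lateral_features(frame) -> tuple[float, float, float, float]:
    mh = project(frame["MH"], "sagittal")
    mn = project(frame["MN"], "sagittal")
    c7 = project(frame["C7"], "sagittal")
    l5 = project(frame["L5"], "sagittal")
    fc = project(frame["FC"], "sagittal")
    lm = project(frame["LM"], "sagittal")
    f3 = angle_to_vertical(mh, mn)
    f4 = angle_between(l5, lm, l5, c7)
    f5 = angle_between(l5, lm, l5, fc)
    d2 = math.hypot(c7.u - l5.u, c7.v - l5.v)
    if d2 == 0.0:
        raise ValueError("degenerate segment: C7 and L5 coincide")
    f7 = 100.0 * perp_distance(fc, c7, l5) / d2
    return f3, f4, f5, f7


def compute_features(session: Session, window_policy: str = "relaxed") -> FeatureVector:
    """Extract the six-feature vector from a session.

    F1/F2 are computed per frame of the frontal window selected by
    ``window_policy``, F3/F4/F5/F7 per frame of the matching lateral
    window; each feature is the median over its window.  A frame with
    degenerate geometry is excluded with a warning; it is an error only if
    a whole window degenerates.

    The relaxed windows are the default: the features quantify the
    habitual stance, while the actively-corrected stance is kept for
    optional reporting.
    """
    if window_policy not in WINDOW_POLICIES:
        raise ValueError(
            f"unknown window policy {window_policy!r} (expected one of {WINDOW_POLICIES})"
        )
    per_window = {}
    for view, extract in (("frontal", _frontal_features), ("lateral", _lateral_features)):
        window = f"{view}_{window_policy}"
        frames = session.frames_in(window)
        if not frames:
            raise ValueError(f"window {window!r} is empty or undeclared")
        rows = []
        for frame in frames:
            try:
                rows.append(extract(frame))
            except ValueError as exc:
                warnings.warn(
                    f"window {window!r}, frame t={frame.time:g} excluded: {exc}",
                    stacklevel=2,
                )
        if not rows:
            raise ValueError(f"window {window!r}: every frame has degenerate geometry")
        per_window[view] = np.median(np.asarray(rows), axis=0), len(rows)

    (f1, f2), n_frontal = per_window["frontal"]
    (f3, f4, f5, f7), n_lateral = per_window["lateral"]
    return FeatureVector(
        f1=float(f1),
        f2=float(f2),
        f3=float(f3),
        f4=float(f4),
        f5=float(f5),
        f7=float(f7),
        n_frontal=n_frontal,
        n_lateral=n_lateral,
        window_policy=window_policy,
    )
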