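"""Acquisition-pose planning for circle and linear fistula scans.

A scan is planned from at least three user-marked sites on the access:
the arterial anastomosis (A), the loop (L) and the venous anastomosis (V).
For a looped fistula the probe travels an arc: the circle through the
three sites is constructed classically from perpendicular bisectors of
two chords (through the chord midpoints), and acquisition poses are
sampled along the arc from the first site to the last, passing through
the middle one.  For a straight access the poses lie on the polyline
through the sites with no probe rotation.

Each pose carries the rotation angle ``theta`` about the z axis that the
3D reconstruction applies to that frame: the polar angle about the circle
centre for arc scans, zero for linear scans.

The native capture spacing is ``speed / frame_rate`` (the probe moves at
0.5 cm/s and frames are captured once per second, i.e. 5 mm between
captured slices); a plan whose requested slice spacing exceeds this is
flagged as requiring interpolated slices in the reconstruction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, InvalidArgumentError, OutOfRangeError

__all__ = [
    "ScanPoint",
    "Waypoint",
    "ScanPlan",
    "circle_from_points",
    "build_plan",
    "frame_angle",
    "DEFAULT_SPEED_CM_S",
    "DEFAULT_FRAME_RATE_HZ",
]

DEFAULT_SPEED_CM_S = 0.5
DEFAULT_FRAME_RATE_HZ = 1.0

#: Reachable workspace of the scanning arm, mm (soft limits: a plan
#: outside them triggers a warning flag, never an error, since this
#: artifact drives no hardware).
WORKSPACE_LIMITS_MM = ((-400.0, 400.0), (-400.0, 400.0), (0.0, 500.0))


@dataclass(frozen=True)
class ScanPoint:
    """A user-marked site on the fistula, workspace coordinates in mm."""

    site: str  # 'A', 'L', 'V' or 'other'
    position: tuple[float, float, float]

    def __post_init__(self):
        if self.site not in {"A", "L", "V", "other"}:
            raise InvalidArgumentError(
                f"site must be one of A, L, V, other; got {self.site!r}"
            )
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise InvalidArgumentError("position must be a finite (x, y, z) triple")
        object.__setattr__(self, "position", tuple(float(v) for v in p))


@dataclass(frozen=True)
class Waypoint:
    """One acquisition pose along the plan."""

    position: tuple[float, float, float]  # mm
    theta: float  # rad, rotation about z applied to the frame
    axial_position: float  # mm of path length from the first waypoint


@dataclass
class ScanPlan:
    """Ordered acquisition poses for one scan."""

    method: str  # 'circle' | 'linear'
    waypoints: list[Waypoint]
    speed: float = DEFAULT_SPEED_CM_S  # cm/s
    frame_rate: float = DEFAULT_FRAME_RATE_HZ  # Hz
    slice_spacing: float = 5.0  # mm
    # circle geometry, populated for method == 'circle'
    center: tuple[float, float] | None = None
    radius: float | None = None
    outside_workspace: bool = False

    def __post_init__(self):
        if len(self.waypoints) < 2:
            raise InvalidArgumentError("a plan needs at least 2 waypoints")
        ax = np.array([w.axial_position for w in self.waypoints])
        if not np.all(np.diff(ax) > 0):
            raise InvalidArgumentError("axial positions must strictly increase")

    @property
    def native_spacing(self) -> float:
        """Spacing between captured slices at the set speed, mm."""
        return self.speed * 10.0 / self.frame_rate

    @property
    def requires_interpolation(self) -> bool:
        """True when slices are farther apart than the native capture."""
        return self.slice_spacing > self.native_spacing + 1e-9

    @property
    def length(self) -> float:
        return self.waypoints[-1].axial_position

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "speed_cm_s": self.speed,
            "frame_rate_hz": self.frame_rate,
            "slice_spacing_mm": self.slice_spacing,
            "native_spacing_mm": self.native_spacing,
            "requires_interpolation": self.requires_interpolation,
            "center_mm": list(self.center) if self.center else None,
            "radius_mm": self.radius,
            "outside_workspace": self.outside_workspace,
            "waypoints": [
                {
                    "position_mm": list(w.position),
                    "theta_rad": w.theta,
                    "axial_position_mm": w.axial_position,
                }
                for w in self.waypoints
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanPlan":
        return cls(
            method=d["method"],
            waypoints=[
                Waypoint(
                    position=tuple(w["position_mm"]),
                    theta=w["theta_rad"],
                    axial_position=w["axial_position_mm"],
                )
                for w in d["waypoints"]
            ],
            speed=d["speed_cm_s"],
            frame_rate=d["frame_rate_hz"],
            slice_spacing=d["slice_spacing_mm"],
            center=tuple(d["center_mm"]) if d.get("center_mm") else None,
            radius=d.get("radius_mm"),
            outside_workspace=d.get("outside_workspace", False),
        )

    @classmethod
    def from_json(cls, path) -> "ScanPlan":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def circle_from_points(p1, p2, p3, tol: float = 1e-9):
    """Circumscribed circle through three planar points.

    The centre is the intersection of the perpendicular bisectors of the
    chords ``p1 p2`` and ``p2 p3`` (each passing through its chord
    midpoint).

    Returns
    -------
    (center, radius) : ((float, float), float)

    Raises
    ------
    DegenerateGeometryError
        If the points are (near-)collinear — use a linear plan instead.
    """
    a = np.asarray(p1, dtype=float)[:2]
    b = np.asarray(p2, dtype=float)[:2]
    c = np.asarray(p3, dtype=float)[:2]
    if np.allclose(a, b) or np.allclose(b, c) or np.allclose(a, c):
        raise InvalidArgumentError("circle points must be distinct")
    # twice the signed triangle area
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a))
    if abs(cross) <= tol * scale * scale:
        raise DegenerateGeometryError(
            "sites are collinear; no circumscribed circle exists "
            "(use the linear scan method)"
        )
    # perpendicular-bisector intersection as a 2x2 linear system
    mid_ab = (a + b) / 2.0
    mid_bc = (b + c) / 2.0
    d_ab = b - a
    d_bc = c - b
    mat = np.array([d_ab, d_bc])
    rhs = np.array([d_ab @ mid_ab, d_bc @ mid_bc])
    center = np.linalg.solve(mat, rhs)
    radius = float(np.linalg.norm(a - center))
    return (float(center[0]), float(center[1])), radius


def _arc_angles(center, start, mid, end):
    """Angles of the traversed arc from start to end passing through mid."""
    def ang(p):
        return math.atan2(p[1] - center[1], p[0] - center[0])

    th0, thm, th1 = ang(start), ang(mid), ang(end)
    # counter-clockwise sweep sizes from th0
    ccw = lambda t: (t - th0) % (2 * math.pi)
    if ccw(thm) <= ccw(th1):
        sweep = ccw(th1)  # counter-clockwise contains mid
        direction = 1.0
    else:
        sweep = (th0 - th1) % (2 * math.pi)  # clockwise contains mid
        direction = -1.0
    return th0, direction, sweep


def build_plan(
    points: Sequence[ScanPoint],
    method: str,
    speed: float = DEFAULT_SPEED_CM_S,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    slice_spacing: float = 5.0,
) -> ScanPlan:
    """Compute acquisition poses from marked sites.

    Parameters
    ----------
    points : sequence of ScanPoint
        At least three sites.  The circle method fits the circumscribed
        circle through the first, middle and last site and samples the
        arc from the first to the last through the middle one; the linear
        method follows the polyline through all sites.
    slice_spacing : float
        Separation between consecutive poses along the path, mm.
    """
    if len(points) < 3:
        raise InvalidArgumentError(
            f"at least 3 scan points are required, got {len(points)}"
        )
    if method not in {"circle", "linear"}:
        raise InvalidArgumentError("method must be 'circle' or 'linear'")
    if speed <= 0 or frame_rate <= 0 or slice_spacing <= 0:
        raise InvalidArgumentError(
            "speed, frame_rate and slice_spacing must be positive"
        )

    pos = np.array([p.position for p in points], dtype=float)
    center = radius = None

    if method == "circle":
        start, mid, end = pos[0], pos[len(points) // 2], pos[-1]
        center, radius = circle_from_points(start, mid, end)
        th0, direction, sweep = _arc_angles(center, start, mid, end)
        arc_len = radius * sweep
        n = int(math.floor(arc_len / slice_spacing + 1e-9)) + 1
        z_mean = float(pos[:, 2].mean())
        waypoints = []
        for k in range(n):
            s = k * slice_spacing
            th = th0 + direction * s / radius
            waypoints.append(
                Waypoint(
                    position=(
                        center[0] + radius * math.cos(th),
                        center[1] + radius * math.sin(th),
                        z_mean,
                    ),
                    theta=float(th),
                    axial_position=float(s),
                )
            )
    else:
        seg = np.diff(pos, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        if np.any(seg_len <= 0):
            raise InvalidArgumentError("consecutive scan points must be distinct")
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = float(cum[-1])
        n = int(math.floor(total / slice_spacing + 1e-9)) + 1
        waypoints = []
        for k in range(n):
            s = min(k * slice_spacing, total)
            i = int(np.searchsorted(cum, s, side="right") - 1)
            i = min(i, len(seg_len) - 1)
            f = (s - cum[i]) / seg_len[i]
            p = pos[i] + f * seg[i]
            waypoints.append(
                Waypoint(
                    position=tuple(float(v) for v in p),
                    theta=0.0,
                    axial_position=float(k * slice_spacing),
                )
            )

    outside = any(
        not (lo - 1e-9 <= w.position[i] <= hi + 1e-9)
        for w in waypoints
        for i, (lo, hi) in enumerate(WORKSPACE_LIMITS_MM)
    )
    return ScanPlan(
        method=method,
        waypoints=waypoints,
        speed=speed,
        frame_rate=frame_rate,
        slice_spacing=slice_spacing,
        center=center,
        radius=radius,
        outside_workspace=outside,
    )


def frame_angle(plan: ScanPlan, k: int) -> float:
    """Rotation angle ``theta`` of frame ``k`` of the plan, radians."""
    if not 0 <= k < len(plan.waypoints):
        raise OutOfRangeError(
            f"frame index {k} out of range [0, {len(plan.waypoints)})"
        )
    return plan.waypoints[k].theta
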