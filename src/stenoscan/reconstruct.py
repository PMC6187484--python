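"""3D vessel reconstruction from per-frame contours.

Each segmented frame is rotated into a common world frame by the
rotation angle theta_n its acquisition pose carries:

    x' = x * cos(theta_n) + y * sin(theta_n)
    y' = y * cos(theta_n) - x * sin(theta_n)
    z' = z

(a clockwise in-plane rotation about the z axis, applied as printed and
covered by a round-trip test).  Contours are placed along the scan path
by arc length, intermediate contours are linearly interpolated wherever
captured slices are farther apart than the interpolation spacing
(default 20 mm, configurable down to the 5 mm native capture spacing),
and adjacent rings are triangulated into closed lumen and vessel-wall
surface meshes.

The world frame is the plan's geometry frame; all exported artifacts are
tagged with the coordinate convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import InsufficientDataError, InvalidArgumentError
from .scanpath import ScanPlan
from .segmentation import Contour

__all__ = [
    "OrientedContour",
    "VesselModel",
    "rotate_contour",
    "interpolate_contours",
    "align_rings",
    "build_model",
    "DEFAULT_INTERPOLATION_SPACING",
    "CONVENTION_TAG",
]

DEFAULT_INTERPOLATION_SPACING = 20.0  # mm

CONVENTION_TAG = (
    "world=scan-plan geometry frame; in-plane rotation x'=x cos(t)+y sin(t), "
    "y'=y cos(t)-x sin(t) (clockwise), z along the scan path"
)


def rotate_contour(vertices_mm: np.ndarray, theta: float) -> np.ndarray:
    """Rotate in-plane contour vertices (mm) by theta about the z axis.

    Applies the clockwise convention ``x' = x cos + y sin``,
    ``y' = y cos - x sin`` exactly; vertex count and pairwise distances
    are preserved (rigid rotation).
    """
    v = np.asarray(vertices_mm, dtype=float)
    c, s = math.cos(theta), math.sin(theta)
    return np.column_stack([v[:, 0] * c + v[:, 1] * s,
                            v[:, 1] * c - v[:, 0] * s])


@dataclass(frozen=True)
class OrientedContour:
    """One contour placed in the world frame.

    ``vertices`` are in-plane mm coordinates *after* rotation by theta;
    ``z`` is the position along the scan path (mm).
    """

    vertices: np.ndarray  # (n, 2) mm
    theta: float
    z: float
    source: str = "captured"  # 'captured' | 'interpolated'
    frame_index: int | None = None

    def __post_init__(self):
        if self.source not in {"captured", "interpolated"}:
            raise InvalidArgumentError("source must be captured|interpolated")
        if not np.isfinite(self.theta):
            raise InvalidArgumentError("theta must be finite")

    @property
    def points3d(self) -> np.ndarray:
        z = np.full(len(self.vertices), self.z)
        return np.column_stack([self.vertices, z])


def align_rings(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Re-index ring ``b`` (cyclic shift, optionally reversed) to minimize
    the summed squared vertex distance to ring ``a``.

    Both rings must have equal vertex counts; returns the re-indexed copy
    of ``b``.  This fixes the vertex correspondence used for linear
    interpolation and surface triangulation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise InvalidArgumentError("rings must have equal vertex counts")
    best, best_cost = None, np.inf
    for cand in (b, b[::-1]):
        for k in range(len(cand)):
            rolled = np.roll(cand, k, axis=0)
            cost = float(np.sum((rolled - a) ** 2))
            if cost < best_cost:
                best, best_cost = rolled, cost
    return best.copy()


def interpolate_contours(a: OrientedContour, b: OrientedContour,
                         n_intermediate: int) -> list[OrientedContour]:
    """Linearly interpolate ``n_intermediate`` contours between a and b.

    Corresponding vertices (after :func:`align_rings`), theta and z are
    interpolated at uniform fractions; the endpoints are not duplicated
    and outputs are tagged ``interpolated``.
    """
    if n_intermediate < 0:
        raise InvalidArgumentError("n_intermediate must be >= 0")
    if not a.z < b.z:
        raise InvalidArgumentError("contours must satisfy a.z < b.z")
    if n_intermediate == 0:
        return []
    vb = align_rings(a.vertices, b.vertices)
    out = []
    for j in range(1, n_intermediate + 1):
        f = j / (n_intermediate + 1)
        out.append(
            OrientedContour(
                vertices=(1 - f) * a.vertices + f * vb,
                theta=(1 - f) * a.theta + f * b.theta,
                z=(1 - f) * a.z + f * b.z,
                source="interpolated",
            )
        )
    return out


@dataclass
class VesselModel:
    """Stacked contours and triangulated surfaces for lumen and wall."""

    lumen_stack: list[OrientedContour]
    vessel_stack: list[OrientedContour]
    lumen_mesh: trimesh.Trimesh
    vessel_mesh: trimesh.Trimesh
    plan: ScanPlan | None = None
    interpolation_spacing: float = DEFAULT_INTERPOLATION_SPACING
    convention: str = CONVENTION_TAG

    @property
    def interpolated_count(self) -> int:
        return sum(c.source == "interpolated" for c in self.lumen_stack)

    def manifest(self) -> dict:
        return {
            "frames_used": [c.frame_index for c in self.lumen_stack
                            if c.source == "captured"],
            "interpolated_count": self.interpolated_count,
            "spacing_mm": self.interpolation_spacing,
            "convention_tags": self.convention,
            "lumen_volume_mm3": float(self.lumen_mesh.volume),
            "vessel_volume_mm3": float(self.vessel_mesh.volume),
        }

    def export(self, directory, stem: str = "vessel") -> dict:
        """Write STL (binary) and PLY (ascii) meshes, a point-cloud CSV
        and the JSON manifest; returns the file map."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = {}
        for name, mesh in (("lumen", self.lumen_mesh), ("wall", self.vessel_mesh)):
            stl = directory / f"{stem}_{name}.stl"
            ply = directory / f"{stem}_{name}.ply"
            mesh.export(stl)
            mesh.export(ply, encoding="ascii")
            files[f"{name}_stl"] = str(stl)
            files[f"{name}_ply"] = str(ply)
        csv = directory / f"{stem}_contours.csv"
        with open(csv, "w") as fh:
            fh.write("role,source,frame_index,x_mm,y_mm,z_mm\n")
            for role, stack in (("lumen", self.lumen_stack),
                                ("vessel", self.vessel_stack)):
                for c in stack:
                    fi = "" if c.frame_index is None else c.frame_index
                    for p in c.points3d:
                        fh.write(f"{role},{c.source},{fi},"
                                 f"{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")
        files["contours_csv"] = str(csv)
        man = directory / f"{stem}_manifest.json"
        with open(man, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
        files["manifest"] = str(man)
        return files


def _mesh_from_stack(stack: list[OrientedContour]) -> trimesh.Trimesh:
    """Triangulate a stack of corresponding rings into a closed surface."""
    rings = [stack[0].points3d]
    for prev, cur in zip(stack, stack[1:]):
        rings.append(
            np.column_stack([align_rings(rings[-1][:, :2], cur.vertices),
                             np.full(len(cur.vertices), cur.z)])
        )
    n = len(rings[0])
    vertices = np.vstack(rings)
    faces = []
    for k in range(len(rings) - 1):
        a0, b0 = k * n, (k + 1) * n
        for j in range(n):
            j1 = (j + 1) % n
            faces.append([a0 + j, b0 + j, b0 + j1])
            faces.append([a0 + j, b0 + j1, a0 + j1])
    # end caps: fans around the ring centroids
    c_start = len(vertices)
    vertices = np.vstack([vertices, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    last0 = (len(rings) - 1) * n
    for j in range(n):
        j1 = (j + 1) % n
        faces.append([c_start, j1, j])
        faces.append([c_start + 1, last0 + j, last0 + j1])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    return mesh


def build_model(
    contour_pairs,
    frames,
    plan: ScanPlan,
    interpolation_spacing: float = DEFAULT_INTERPOLATION_SPACING,
) -> VesselModel:
    """Assemble a :class:`VesselModel` from segmented frames.

    Parameters
    ----------
    contour_pairs : sequence of (lumen, vessel) Contour
        Pixel-space segmentation results, one pair per frame.
    frames : sequence of BModeFrame
        The frames the contours were segmented on (for pixel spacing,
        image centre and pose).
    plan : ScanPlan
        Supplies the circle radius for arc scans; positions come from
        each frame's axial position.
    interpolation_spacing : float
        Maximum allowed gap between consecutive contours, mm; larger
        gaps are filled with linearly interpolated contours.
    """
    if len(contour_pairs) < 2:
        raise InsufficientDataError(
            "3D reconstruction requires at least 2 captured frames"
        )
    if len(contour_pairs) != len(frames):
        raise InvalidArgumentError("contour_pairs and frames length mismatch")
    if interpolation_spacing <= 0:
        raise InvalidArgumentError("interpolation_spacing must be positive")

    radial_offset = plan.radius if (plan.method == "circle" and plan.radius) else 0.0

    def oriented(contour: Contour, frame) -> tuple[np.ndarray, float, float]:
        mm = contour.scaled(frame.pixel_spacing, origin=frame.center)
        mm = mm + np.array([radial_offset, 0.0])
        return rotate_contour(mm, frame.theta)

    stacks = {"lumen": [], "vessel": []}
    for (lum, ves), frame in sorted(zip(contour_pairs, frames),
                                    key=lambda t: t[1].axial_position):
        for role, contour in (("lumen", lum), ("vessel", ves)):
            stacks[role].append(
                OrientedContour(
                    vertices=oriented(contour, frame),
                    theta=frame.theta,
                    z=frame.axial_position,
                    source="captured",
                    frame_index=frame.frame_index,
                )
            )

    def densify(stack):
        out = [stack[0]]
        for a, b in zip(stack, stack[1:]):
            gap = b.z - a.z
            n_mid = max(0, int(math.ceil(gap / interpolation_spacing)) - 1)
            out.extend(interpolate_contours(a, b, n_mid))
            out.append(b)
        return out

    lumen_stack = densify(stacks["lumen"])
    vessel_stack = densify(stacks["vessel"])
    return VesselModel(
        lumen_stack=lumen_stack,
        vessel_stack=vessel_stack,
        lumen_mesh=_mesh_from_stack(lumen_stack),
        vessel_mesh=_mesh_from_stack(vessel_stack),
        plan=plan,
        interpolation_spacing=interpolation_spacing,
    )
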