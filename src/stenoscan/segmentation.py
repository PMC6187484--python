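"""Active-contour (snake) segmentation of vessel cross-sections.

A snake is a closed contour v(s) = (x(s), y(s)), s in [0, 1], that
minimizes

    E_snake = integral of E_int(v(s)) + E_ext(v(s)) ds,

with internal energy

    E_int = alpha(s) |dv/ds|^2 + beta(s) |d^2v/ds^2|^2

(elasticity and stiffness), and external energy E_ext = E_image + E_con
where the constraint energy E_con is fixed to zero and the image energy
combines three functionals,

    E_image = w_line * E_line + w_edge * E_edge + w_term * E_term,

E_line being the image intensity (attracts to dark lines), E_edge the
negative squared gradient magnitude (attracts to edges) and E_term the
curvature of level lines of a further-smoothed copy (attracts to
terminations and corners).  The E_edge and E_term fields are scaled to
unit maximum magnitude per frame so the default weights put image wells
and internal energy on comparable scales (see docs/methods.md).

The minimizer is a deterministic greedy neighborhood search: each
iteration visits vertices in index order and moves each vertex to the
position in its (2r+1)^2 neighborhood that lowers its local energy,
moving only on strict improvement.  The contour is resampled to uniform
arc-length spacing after an iteration whenever that does not increase
the total energy, so the total snake energy is non-increasing across
iterations by construction.

Derivatives are cyclic finite differences over the uniform vertex index
(one index step is one unit of s), so for a regular N-gon the per-vertex
elasticity term is alpha * (perimeter/N)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon

from .errors import (
    DegenerateContourError,
    InvalidArgumentError,
    PropagationError,
    SegmentationInconsistencyError,
)
from .phantom import BModeFrame

__all__ = [
    "Contour",
    "AcmParams",
    "EnergyFields",
    "EnergyBreakdown",
    "smooth_frame",
    "image_energy_field",
    "internal_energy",
    "snake_energy",
    "evolve_snake",
    "segment_frame",
    "propagate_series",
    "equivalent_diameters",
    "DEFAULT_SMOOTH_SIGMA_MM",
]

#: Default pre-segmentation smoothing, mm.  Matched to the renderer's
#: point-spread width: smoothing at the PSF scale suppresses speckle
#: while roughly preserving edge localization; smoothing well beyond it
#: widens the edge wells until the elasticity term drags contours off
#: the boundary by a pixel or more.
DEFAULT_SMOOTH_SIGMA_MM = 0.15

#: Tolerance (px) used when checking that the lumen contour is nested
#: inside the vessel contour.  At plaque-free slices the two contours
#: legitimately coincide on the same physical boundary, so nesting is
#: enforced only beyond their combined localization jitter and bias; a
#: genuinely inconsistent segmentation misses by many pixels.
NESTING_TOLERANCE_PX = 2.5


class Contour:
    """Closed contour as an ordered vertex ring in pixel coordinates.

    Pixel centres sit at integer coordinates, origin top-left, x
    rightward, y downward.  Vertices are stored so the ring runs
    counter-clockwise in the display sense (positive shoelace area under
    this axis convention).  The parameterization s is uniform over the
    vertex index.
    """

    def __init__(self, vertices, normalize_orientation: bool = True):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 8:
            raise InvalidArgumentError(
                "a contour needs >= 8 (x, y) vertices; got shape "
                f"{getattr(v, 'shape', None)}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("contour vertices must be finite")
        if normalize_orientation and _signed_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v

    def __len__(self):
        return len(self.vertices)

    @property
    def signed_area(self) -> float:
        return _signed_area(self.vertices)

    @property
    def area(self) -> float:
        """Enclosed area by the shoelace formula, px^2."""
        return abs(self.signed_area)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.linalg.norm(d, axis=1).sum())

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.vertices.mean(axis=0)
        return float(c[0]), float(c[1])

    def is_simple(self) -> bool:
        return Polygon(self.vertices).is_valid

    def resample(self, n: int | None = None) -> "Contour":
        """Resample to ``n`` vertices uniformly spaced in arc length,
        keeping vertex 0 anchored."""
        n = n or len(self)
        v = self.vertices
        closed = np.vstack([v, v[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        if total <= 0:
            raise DegenerateContourError("contour has zero perimeter")
        targets = np.arange(n) * total / n
        x = np.interp(targets, cum, closed[:, 0])
        y = np.interp(targets, cum, closed[:, 1])
        return Contour(np.column_stack([x, y]), normalize_orientation=False)

    def scaled(self, pixel_spacing: float, origin=(0.0, 0.0)) -> np.ndarray:
        """Vertices in mm, relative to ``origin`` (px)."""
        return (self.vertices - np.asarray(origin, dtype=float)) * pixel_spacing

    def to_polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @classmethod
    def circle(cls, center, radius: float, n: int = 64) -> "Contour":
        t = 2 * np.pi * np.arange(n) / n
        cx, cy = center
        return cls(np.column_stack([cx + radius * np.cos(t),
                                    cy + radius * np.sin(t)]))


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class AcmParams:
    """Snake weights and evolution controls.

    alpha, beta : elasticity and stiffness weights (constant over s).
    w_line, w_edge, w_term : image-functional weights.
    search_radius : half-width of the greedy move neighborhood, px.
    move_tolerance : stop when the moved-vertex fraction drops below this.
    """

    alpha: float = 0.1
    beta: float = 0.4
    w_line: float = 0.0
    w_edge: float = 1.0
    w_term: float = 0.3
    search_radius: int = 2
    max_iterations: int = 200
    move_tolerance: float = 0.05
    n_vertices: int = 64
    term_sigma_px: float = 2.0  # extra smoothing for the termination field

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InvalidArgumentError("alpha and beta must be >= 0")
        if self.max_iterations < 1:
            raise InvalidArgumentError("max_iterations must be >= 1")
        if not 0 <= self.move_tolerance < 1:
            raise InvalidArgumentError("move_tolerance must lie in [0, 1)")
        if self.search_radius < 1:
            raise InvalidArgumentError("search_radius must be >= 1")
        if self.n_vertices < 8:
            raise InvalidArgumentError("n_vertices must be >= 8")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "beta": self.beta,
            "w_line": self.w_line, "w_edge": self.w_edge,
            "w_term": self.w_term, "search_radius": self.search_radius,
            "max_iterations": self.max_iterations,
            "move_tolerance": self.move_tolerance,
            "n_vertices": self.n_vertices,
            "term_sigma_px": self.term_sigma_px,
        }


@dataclass(frozen=True)
class EnergyFields:
    """Per-pixel image-energy fields of one frame.

    ``e_edge`` and ``e_term`` are normalized to unit maximum magnitude;
    ``combined`` is the weighted sum actually sampled by the snake.
    """

    e_line: np.ndarray
    e_edge: np.ndarray
    e_term: np.ndarray
    combined: np.ndarray


@dataclass
class EnergyBreakdown:
    """Decomposition of one contour's snake energy (means over vertices)."""

    e_int: float
    e_image: float
    e_con: float  # fixed 0
    e_ext: float
    e_snake: float
    per_vertex_int: np.ndarray
    per_vertex_line: np.ndarray
    per_vertex_edge: np.ndarray
    per_vertex_term: np.ndarray
    clamped_samples: int  # vertices whose sample position was clamped


def smooth_frame(frame: BModeFrame, sigma: float) -> BModeFrame:
    """Gaussian-smooth a frame; ``sigma`` in mm (0 returns it unchanged)."""
    if sigma < 0:
        raise InvalidArgumentError("sigma must be >= 0")
    if sigma == 0:
        return frame
    img = ndimage.gaussian_filter(
        frame.intensity, sigma=sigma / frame.pixel_spacing, mode="nearest"
    )
    return replace(frame, intensity=np.clip(img, 0.0, 1.0))


def image_energy_field(frame: BModeFrame, params: AcmParams) -> EnergyFields:
    """Compute E_line, E_edge and E_term fields for a (smoothed) frame."""
    img = frame.intensity
    e_line = img

    gy, gx = np.gradient(img)
    e_edge = -(gx**2 + gy**2)
    m = np.abs(e_edge).max()
    if m > 0:
        e_edge = e_edge / m

    # termination field on an extra-smoothed copy: curvature of level lines
    soft = ndimage.gaussian_filter(img, sigma=params.term_sigma_px, mode="nearest")
    iy, ix = np.gradient(soft)
    iyy, iyx = np.gradient(iy)
    ixy, ixx = np.gradient(ix)
    denom = (ix**2 + iy**2) ** 1.5 + 1e-8
    e_term = (ixx * iy**2 - 2 * iyx * ix * iy + iyy * ix**2) / denom
    m = np.abs(e_term).max()
    if m > 0:
        e_term = e_term / m

    combined = params.w_line * e_line + params.w_edge * e_edge + params.w_term * e_term
    return EnergyFields(e_line=e_line, e_edge=e_edge, e_term=e_term,
                        combined=combined)


def _sample(field: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Bilinear sample at (x, y), clamping positions to the image domain.

    Returns (values, clamped_mask).
    """
    h, w = field.shape
    xc = np.clip(x, 0.0, w - 1.0)
    yc = np.clip(y, 0.0, h - 1.0)
    clamped = (xc != x) | (yc != y)
    x0 = np.floor(xc).astype(int)
    y0 = np.floor(yc).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = xc - x0
    fy = yc - y0
    v = (field[y0, x0] * (1 - fx) * (1 - fy)
         + field[y0, x1] * fx * (1 - fy)
         + field[y1, x0] * (1 - fx) * fy
         + field[y1, x1] * fx * fy)
    return v, clamped


def internal_energy(contour: Contour, params: AcmParams):
    """Per-vertex and total internal energy.

    Cyclic finite differences over the vertex index; the total is the
    mean over vertices (the discretized integral over s).
    Returns ``(per_vertex, total)``.
    """
    v = contour.vertices
    d1 = np.roll(v, -1, axis=0) - v  # v[i+1] - v[i]
    d2 = np.roll(v, -1, axis=0) - 2 * v + np.roll(v, 1, axis=0)
    per_vertex = (params.alpha * np.sum(d1**2, axis=1)
                  + params.beta * np.sum(d2**2, axis=1))
    return per_vertex, float(per_vertex.mean())


def snake_energy(contour: Contour, fields: EnergyFields,
                 params: AcmParams) -> EnergyBreakdown:
    """Evaluate the full energy decomposition of a contour.

    The integral over s is discretized as the mean over vertices; image
    terms are sampled at vertex positions by bilinear interpolation with
    out-of-domain positions clamped to the boundary (counted in
    ``clamped_samples``).
    """
    per_int, e_int = internal_energy(contour, params)
    x, y = contour.vertices[:, 0], contour.vertices[:, 1]
    line, cl1 = _sample(fields.e_line, x, y)
    edge, cl2 = _sample(fields.e_edge, x, y)
    term, cl3 = _sample(fields.e_term, x, y)
    e_image = float(np.mean(params.w_line * line + params.w_edge * edge
                            + params.w_term * term))
    e_con = 0.0
    e_ext = e_image + e_con
    return EnergyBreakdown(
        e_int=e_int,
        e_image=e_image,
        e_con=e_con,
        e_ext=e_ext,
        e_snake=e_int + e_ext,
        per_vertex_int=per_int,
        per_vertex_line=line,
        per_vertex_edge=edge,
        per_vertex_term=term,
        clamped_samples=int((cl1 | cl2 | cl3).sum()),
    )


def _local_energy(v: np.ndarray, i: int, cand: np.ndarray,
                  img_val: np.ndarray, params: AcmParams) -> np.ndarray:
    """Sum of all energy terms of the ring that involve vertex i, for each
    candidate position (vectorized over candidates)."""
    n = len(v)
    vm2, vm1 = v[(i - 2) % n], v[(i - 1) % n]
    vp1, vp2 = v[(i + 1) % n], v[(i + 2) % n]
    # elasticity: the two segments incident to v_i
    e = params.alpha * (np.sum((cand - vm1) ** 2, axis=1)
                        + np.sum((vp1 - cand) ** 2, axis=1))
    # stiffness: curvature terms centred at i-1, i, i+1
    c_m = cand - 2 * vm1 + vm2
    c_0 = vp1 - 2 * cand + vm1
    c_p = vp2 - 2 * vp1 + cand
    e += params.beta * (np.sum(c_m**2, axis=1) + np.sum(c_0**2, axis=1)
                        + np.sum(c_p**2, axis=1))
    return e + img_val


def evolve_snake(init: Contour, frame: BModeFrame, params: AcmParams = AcmParams(),
                 fields: EnergyFields | None = None):
    """Greedy discrete minimization of the snake energy.

    Each iteration visits vertices in index order and moves each to the
    best position in its (2r+1)^2 neighborhood; a vertex moves only on
    strict improvement, with ties among improving candidates broken by
    the smallest energy and then by row-major neighborhood offset order.
    After each pass the contour is resampled to uniform arc-length
    spacing if that does not increase the energy.  Stops when no vertex
    moved, when the moved fraction falls below ``move_tolerance``, or at
    ``max_iterations``.

    Returns ``(contour, EnergyBreakdown, iterations)``; the final energy
    never exceeds the initial energy.

    The ``frame`` is assumed pre-smoothed by the caller; pass ``fields``
    to reuse precomputed energy fields.
    """
    if fields is None:
        fields = image_energy_field(frame, params)
    contour = init.resample(params.n_vertices)
    h, w = frame.shape
    r = params.search_radius
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]  # row-major candidate order
    offsets = np.column_stack([dx.ravel(), dy.ravel()]).astype(float)
    center_idx = len(offsets) // 2  # the (0, 0) offset

    energy = snake_energy(contour, fields, params).e_snake
    energies = [energy]
    iterations = 0
    for _ in range(params.max_iterations):
        iterations += 1
        v = contour.vertices
        n = len(v)
        moved = 0
        for i in range(n):
            cand = v[i] + offsets
            inside = ((cand[:, 0] >= 0) & (cand[:, 0] <= w - 1)
                      & (cand[:, 1] >= 0) & (cand[:, 1] <= h - 1))
            img_val, _ = _sample(fields.combined, cand[:, 0], cand[:, 1])
            local = _local_energy(v, i, cand, img_val, params)
            local[~inside] = np.inf  # never move out of the image
            best = int(np.argmin(local))  # first minimum in row-major order
            if best != center_idx and local[best] < local[center_idx] - 1e-12:
                v[i] = cand[best]
                moved += 1
        _check_degenerate(contour)
        energy_now = snake_energy(contour, fields, params).e_snake
        energies.append(energy_now)

        if moved > 0:
            resampled = contour.resample(params.n_vertices)
            e_res = snake_energy(resampled, fields, params).e_snake
            if e_res <= energy_now + 1e-12:
                contour = resampled
                energies.append(e_res)
        if moved == 0 or moved / n < params.move_tolerance:
            break

    breakdown = snake_energy(contour, fields, params)
    breakdown.energy_history = energies  # attached for diagnostics/tests
    breakdown.iterations = iterations
    return contour, breakdown, iterations


def _check_degenerate(contour: Contour) -> None:
    distinct = np.unique(np.round(contour.vertices, 3), axis=0)
    if len(distinct) < 8 or contour.area < 1.0:
        raise DegenerateContourError(
            f"contour collapsed ({len(distinct)} distinct vertices, "
            f"area {contour.area:.2f} px^2)"
        )


# ---------------------------------------------------------------------------
# frame-level segmentation
# ---------------------------------------------------------------------------

def _ray_init(smoothed: np.ndarray, seed: tuple[float, float], threshold: float,
              n_rays: int, step: float = 0.5, last: bool = False) -> Contour:
    """Initial contour by marching rays outward from the seed.

    Each ray stops at the first radius where the smoothed intensity
    reaches ``threshold`` (the bore boundary seen from inside), or with
    ``last=True`` at the outermost radius still at/above it (the outer
    material boundary seen across the bright wall).
    """
    h, w = smoothed.shape
    sx, sy = seed
    angles = 2 * np.pi * np.arange(n_rays) / n_rays
    r_max = float(min(sx, sy, w - 1 - sx, h - 1 - sy)) - 1.0
    radii = np.arange(1.0, max(r_max, 2.0), step)
    cosv, sinv = np.cos(angles), np.sin(angles)
    pts_x = sx + radii[None, :] * cosv[:, None]
    pts_y = sy + radii[None, :] * sinv[:, None]
    vals, _ = _sample(smoothed, pts_x.ravel(), pts_y.ravel())
    vals = vals.reshape(n_rays, len(radii))
    hit = vals >= threshold
    any_hit = hit.any(axis=1)
    if last:
        idx = len(radii) - 1 - hit[:, ::-1].argmax(axis=1)
    else:
        idx = hit.argmax(axis=1)
    idx = np.where(any_hit, idx, len(radii) - 1)
    rr = radii[idx]
    # the threshold crossing only brackets the edge; localize it at the
    # radial gradient extremum (rising for the bore, falling for the
    # outer surface) with parabolic sub-sample refinement.  A threshold
    # crossing alone is one-sidedly biased under speckle (fluctuations
    # can only retreat it), while the gradient-peak jitter is symmetric.
    grad = np.gradient(vals, step, axis=1)
    if last:
        grad = -grad
    half_win = int(round(4.0 / step))
    rows = np.arange(n_rays)
    for i in rows:
        if not any_hit[i]:
            continue
        a = max(idx[i] - half_win, 1)
        b = min(idx[i] + half_win, len(radii) - 2)
        if b <= a:
            continue
        j = a + int(np.argmax(grad[i, a:b + 1]))
        g0, g1, g2 = grad[i, j - 1], grad[i, j], grad[i, j + 1]
        denom = g0 - 2 * g1 + g2
        frac = 0.5 * (g0 - g2) / denom if abs(denom) > 1e-12 else 0.0
        rr[i] = radii[j] + np.clip(frac, -1.0, 1.0) * step
    # the target boundaries are smooth rings: a circular median over the
    # per-ray radii rejects speckle-induced outliers in single rays
    rr = ndimage.median_filter(rr, size=5, mode="wrap")
    return Contour(np.column_stack([sx + rr * cosv, sy + rr * sinv]))


def _equalized(fields: EnergyFields, init: Contour,
               params: AcmParams, max_boost: float = 10.0) -> EnergyFields:
    """Rescale the edge term so the boundary this snake starts on has a
    well of unit depth.

    ``e_edge`` is normalized frame-globally, so a boundary whose
    contrast is weaker than the strongest edge in the frame sits in a
    proportionally shallower well and gets displaced further by the
    internal energy.  Sampling the edge field along the initialization
    ring measures this snake's own edge strength; dividing the edge
    weight by it equalizes the effective well depth across boundaries.
    The field is fixed before evolution, so greedy monotonicity is
    unaffected.
    """
    vals, _ = _sample(fields.e_edge, init.vertices[:, 0], init.vertices[:, 1])
    strength = float(np.percentile(np.abs(vals), 90))
    boost = min(max_boost, 1.0 / max(strength, 1.0 / max_boost))
    combined = (params.w_line * fields.e_line
                + params.w_edge * boost * fields.e_edge
                + params.w_term * fields.e_term)
    return EnergyFields(e_line=fields.e_line, e_edge=fields.e_edge,
                        e_term=fields.e_term, combined=combined)


def _offset_inward(contour: Contour, offset_px: float, n: int) -> Contour:
    """Contour offset inward by a fixed normal distance (px)."""
    poly = contour.to_polygon().buffer(-offset_px)
    if poly.is_empty:
        raise SegmentationInconsistencyError(
            f"inward offset by {offset_px:.1f} px annihilates the contour"
        )
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    ring = np.asarray(poly.exterior.coords)[:-1]
    return Contour(ring).resample(n)


def _nested(lumen: Contour, vessel: Contour,
            tolerance_px: float = NESTING_TOLERANCE_PX) -> bool:
    """True when the lumen ring lies inside the vessel ring up to a
    localization tolerance (they may coincide at plaque-free slices)."""
    vp = vessel.to_polygon().buffer(tolerance_px)
    return all(vp.contains(Point(p)) for p in lumen.vertices)


def segment_frame(
    frame: BModeFrame,
    seed_point: tuple[float, float],
    params: AcmParams = AcmParams(),
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA_MM,
    wall_offset_mm: float = 1.5,
    init_lumen: Contour | None = None,
    init_outer: Contour | None = None,
):
    """Delineate the lumen and vessel-wall boundaries of one frame.

    The frame is smoothed, then two snakes are initialized by casting
    rays outward from ``seed_point`` (which must lie inside the dark
    patent lumen): the lumen snake at the first rise above the
    bore/material threshold, the outer snake at the outermost crossing
    of the material/background threshold (the outer wall surface).  Both
    are refined by the greedy snake.  The vessel boundary (diameter D)
    is not itself echogenic — plaque and wall are one material — so the
    vessel contour is derived from the converged outer contour by a
    fixed inward offset of ``wall_offset_mm``, the phantom's wall
    thickness (the adventitia-to-lumen offset of the design).

    Either initialization can be overridden with a user-supplied polygon
    (the programmatic stand-in for the clinician's contour adjustment).

    Returns ``(lumen, vessel)`` contours in pixel coordinates.
    """
    h, w = frame.shape
    sx, sy = float(seed_point[0]), float(seed_point[1])
    if not (0 <= sx <= w - 1 and 0 <= sy <= h - 1):
        raise InvalidArgumentError(
            f"seed point ({sx}, {sy}) lies outside the {w}x{h} image"
        )
    smoothed = smooth_frame(frame, smooth_sigma)
    img = smoothed.intensity
    fields = image_energy_field(smoothed, params)

    # intensity anchors: dark level near the seed, bright level from the wall
    y0, y1 = int(max(sy - 1, 0)), int(min(sy + 2, h))
    x0, x1 = int(max(sx - 1, 0)), int(min(sx + 2, w))
    lo = float(img[y0:y1, x0:x1].mean())
    hi = float(np.percentile(img, 99.5))
    if hi <= lo:
        raise SegmentationInconsistencyError(
            "no bright wall visible above the seed intensity"
        )
    # thresholds at the half-height of each step: the crossing of a
    # blurred step at 50% of its height sits at the edge centre, so the
    # ray estimates are unbiased before snake refinement
    thr_lumen = lo + 0.50 * (hi - lo)
    thr_outer = lo + 0.70 * (hi - lo)  # ~midpoint of the wall/background step

    if init_lumen is None:
        init_lumen = _ray_init(img, (sx, sy), thr_lumen, params.n_vertices)
    if init_outer is None:
        init_outer = _ray_init(img, (sx, sy), thr_outer, params.n_vertices,
                               last=True)

    lumen, _, _ = evolve_snake(init_lumen, smoothed, params,
                               fields=_equalized(fields, init_lumen, params))
    outer, _, _ = evolve_snake(init_outer, smoothed, params,
                               fields=_equalized(fields, init_outer, params))
    vessel = _offset_inward(outer, wall_offset_mm / frame.pixel_spacing,
                            params.n_vertices)

    if not _nested(lumen, vessel):
        raise SegmentationInconsistencyError(
            "lumen contour is not nested inside the vessel contour"
        )
    return lumen, vessel


def propagate_series(
    frames,
    first_seed: tuple[float, float],
    params: AcmParams = AcmParams(),
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA_MM,
):
    """Segment a frame sequence, re-seeding each frame from its
    predecessor's converged lumen centroid.

    The warm start carries position information frame to frame; the
    contour shape is re-estimated per frame because the greedy snake has
    no inflation force and cannot expand across a homogeneous lumen when
    the vessel widens between slices.  Per-frame results depend only on
    earlier frames.

    Returns a list of ``(lumen, vessel)`` pairs.  On failure raises
    :class:`PropagationError` carrying the failing frame index and the
    results for all earlier frames.
    """
    if len(frames) == 0:
        raise InvalidArgumentError("propagate_series requires >= 1 frame")
    results = []
    seed = (float(first_seed[0]), float(first_seed[1]))
    for k, frame in enumerate(frames):
        try:
            lumen, vessel = segment_frame(
                frame, seed, params=params, smooth_sigma=smooth_sigma
            )
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PropagationError(frame_index=k, partial=results, cause=exc) from exc
        results.append((lumen, vessel))
        seed = lumen.centroid
    return results


def contour_energy_summary(contour: Contour, frame: BModeFrame,
                           params: AcmParams = AcmParams(),
                           smooth_sigma: float = DEFAULT_SMOOTH_SIGMA_MM) -> dict:
    """Scalar energy decomposition of a contour on its (smoothed) frame,
    for serialization alongside the contour."""
    smoothed = smooth_frame(frame, smooth_sigma)
    bd = snake_energy(contour, image_energy_field(smoothed, params), params)
    return {
        "e_int": bd.e_int,
        "e_image": bd.e_image,
        "e_con": bd.e_con,
        "e_ext": bd.e_ext,
        "e_snake": bd.e_snake,
        "clamped_samples": bd.clamped_samples,
    }


def equivalent_diameters(lumen: Contour, vessel: Contour,
                         pixel_spacing: float) -> tuple[float, float]:
    """Area-equivalent diameters (d, D) in mm from nested contours.

    ``2 * sqrt(area / pi)`` with polygon areas from the shoelace formula.
    ``d`` is clipped to ``D`` when the two contours coincide within
    localization jitter at plaque-free slices.
    """
    if pixel_spacing <= 0:
        raise InvalidArgumentError("pixel_spacing must be positive")
    if not _nested(lumen, vessel):
        raise SegmentationInconsistencyError(
            "contours are not nested; diameters undefined"
        )
    d = 2.0 * math.sqrt(lumen.area / math.pi) * pixel_spacing
    D = 2.0 * math.sqrt(vessel.area / math.pi) * pixel_spacing
    return min(d, D), D
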