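"""Ground-truthed stenosed-vessel phantoms and B-mode-like rendering.

This module stands in for the scanning hardware: it generates parametric
vessel phantoms with a known focal stenosis and renders grayscale
cross-section frames the way a B-mode probe would see them, so the
downstream segmentation and DOS quantification can be validated against
exact ground truth.

Geometry
--------
A phantom is a tube of outer lumen diameter ``D`` whose patent lumen
narrows to ``d`` at the stenosis centre.  The diameter profile along the
centreline is a symmetric cosine taper over the plaque extent, so it is
continuous, differentiable, and equals ``D`` outside the plaque and ``d``
exactly at its centre.  Nine presets (types A/B/C: D = 10/8/5 mm;
classes I/II/III: DOS near 20/40/80%) mirror the physical phantom grid
used to validate the scanning system.

Appearance
----------
A noise-free cross-section is piecewise constant at three levels: dark
patent lumen (water-filled bore), bright phantom material (the wall and
the plaque are one resin), and a mid-dark tank background.  Speckle is
modelled to first order as multiplicative unit-mean
gamma-distributed noise followed by a Gaussian point-spread blur; the
noise is fully determined by the seed, making every rendering a pure
function of its arguments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from .errors import InvalidArgumentError, OutOfRangeError
from .scanpath import ScanPlan
from .stenosis import dos

__all__ = [
    "PhantomSpec",
    "CrossSectionTruth",
    "BModeFrame",
    "NoiseParams",
    "make_phantom_spec",
    "lumen_profile",
    "render_truth",
    "render_bmode",
    "generate_series",
    "save_series",
    "load_series",
    "PRESET_DIAMETERS",
    "DEFAULT_PIXEL_SPACING",
    "DEFAULT_FRAME_SIZE",
]

#: Design (d, D) in mm for each (vessel_type, stenosis_class) preset.
PRESET_DIAMETERS = {
    ("A", "I"): (9.0, 10.0),
    ("A", "II"): (7.8, 10.0),
    ("A", "III"): (4.5, 10.0),
    ("B", "I"): (7.0, 8.0),
    ("B", "II"): (6.2, 8.0),
    ("B", "III"): (3.5, 8.0),
    ("C", "I"): (4.5, 5.0),
    ("C", "II"): (3.9, 5.0),
    ("C", "III"): (2.2, 5.0),
}

VESSEL_TYPES = ("A", "B", "C")
STENOSIS_CLASSES = ("I", "II", "III")

DEFAULT_PIXEL_SPACING = 0.1  # mm/px
DEFAULT_FRAME_SIZE = 256  # px
DEFAULT_LENGTH = 60.0  # mm of centreline
DEFAULT_STENOSIS_LENGTH = 10.0  # mm of plaque extent
DEFAULT_WALL_THICKNESS = 1.5  # mm


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one stenosed-vessel phantom.

    ``D`` and ``d`` are the outer lumen diameter and the residual patent
    diameter at maximal stenosis, mm.  ``path_kind`` describes the
    centreline in the workspace ('straight' or 'arc'); cross-sections are
    always taken perpendicular to it and parameterised by arc length.
    """

    vessel_type: str
    stenosis_class: str
    D: float
    d: float
    length: float = DEFAULT_LENGTH
    stenosis_center: float = DEFAULT_LENGTH / 2
    stenosis_length: float = DEFAULT_STENOSIS_LENGTH
    path_kind: str = "straight"
    path_params: dict = field(
        default_factory=lambda: {
            "start": (0.0, 0.0, 0.0),
            "end": (DEFAULT_LENGTH, 0.0, 0.0),
        }
    )
    wall_thickness: float = DEFAULT_WALL_THICKNESS
    eccentricity: float = 0.0  # 0 = concentric lumen; 1 = plaque fully one-sided

    def __post_init__(self):
        if not 0 < self.d <= self.D:
            raise InvalidArgumentError(f"need 0 < d <= D, got d={self.d}, D={self.D}")
        if self.stenosis_length <= 0:
            raise InvalidArgumentError("stenosis_length must be positive")
        if not 0 <= self.stenosis_center <= self.length:
            raise InvalidArgumentError("stenosis_center outside centreline extent")
        if self.path_kind not in {"straight", "arc"}:
            raise InvalidArgumentError("path_kind must be 'straight' or 'arc'")
        if not 0 <= self.eccentricity <= 1:
            raise InvalidArgumentError("eccentricity must lie in [0, 1]")

    @property
    def design_dos(self) -> float:
        """Design DOS in percent, from the (d, D) diameter pair."""
        return dos(self.d, self.D)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["path_params"] = {
            k: list(v) if isinstance(v, (tuple, list)) else v
            for k, v in self.path_params.items()
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["path_params"] = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.get("path_params", {}).items()
        }
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CrossSectionTruth:
    """Exact masks for one cross-section, the segmentation ground truth."""

    lumen_mask: np.ndarray  # bool, patent lumen disk
    vessel_mask: np.ndarray  # bool, full vessel lumen disk (diameter D)
    wall_mask: np.ndarray  # bool, bright wall annulus outside the D disk
    pixel_spacing: float  # mm/px
    axial_position: float  # mm

    def equivalent_diameter(self, mask: np.ndarray) -> float:
        """Area-equivalent diameter ``2*sqrt(area/pi)`` of a mask, mm."""
        area = float(mask.sum()) * self.pixel_spacing**2
        return 2.0 * math.sqrt(area / math.pi)

    @property
    def lumen_diameter(self) -> float:
        return self.equivalent_diameter(self.lumen_mask)

    @property
    def vessel_diameter(self) -> float:
        return self.equivalent_diameter(self.vessel_mask)


@dataclass(frozen=True)
class BModeFrame:
    """One grayscale cross-section frame with its acquisition pose."""

    intensity: np.ndarray  # float in [0, 1]
    pixel_spacing: float  # mm/px
    frame_index: int
    axial_position: float  # mm along the scan path
    theta: float  # rad, rotation of this frame about the z axis

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2 or not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("intensity must be a finite 2-D array")
        if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
            raise InvalidArgumentError("intensity must lie within [0, 1]")
        if self.pixel_spacing <= 0:
            raise InvalidArgumentError("pixel_spacing must be positive")
        object.__setattr__(self, "intensity", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def center(self) -> tuple[float, float]:
        """Image centre in (x, y) pixel coordinates."""
        return ((self.shape[1] - 1) / 2.0, (self.shape[0] - 1) / 2.0)


@dataclass(frozen=True)
class NoiseParams:
    """Speckle and point-spread parameters of the renderer.

    ``speckle_scale`` is the relative standard deviation of the
    multiplicative gamma noise (0.5 approximates the contrast of fully
    developed speckle); ``blur_sigma`` is the Gaussian point-spread width
    in mm.  The seed fully determines the rendered noise.
    """

    speckle_scale: float = 0.5
    blur_sigma: float = 0.15  # mm
    lumen_level: float = 0.05
    wall_level: float = 0.90
    background_level: float = 0.40
    seed: int = 0

    def __post_init__(self):
        if not self.wall_level > self.background_level > self.lumen_level:
            raise InvalidArgumentError(
                "levels must satisfy wall > background > lumen"
            )
        if self.speckle_scale < 0 or self.blur_sigma < 0:
            raise InvalidArgumentError("speckle_scale and blur_sigma must be >= 0")


def make_phantom_spec(vessel_type: str, stenosis_class: str, **overrides) -> PhantomSpec:
    """Preset phantom for a vessel type (A/B/C) and stenosis class (I/II/III).

    Diameters follow the design table of the physical phantom grid; all
    other geometric fields use the documented defaults and can be
    overridden by keyword.
    """
    if vessel_type not in VESSEL_TYPES:
        raise InvalidArgumentError(
            f"unknown vessel_type {vessel_type!r}; valid: {VESSEL_TYPES}"
        )
    if stenosis_class not in STENOSIS_CLASSES:
        raise InvalidArgumentError(
            f"unknown stenosis_class {stenosis_class!r}; valid: {STENOSIS_CLASSES}"
        )
    d, D = PRESET_DIAMETERS[(vessel_type, stenosis_class)]
    kw = dict(vessel_type=vessel_type, stenosis_class=stenosis_class, d=d, D=D)
    kw.update(overrides)
    return PhantomSpec(**kw)


def preset_from_name(name: str) -> PhantomSpec:
    """Parse a preset name like ``'A-I'`` or ``'C-III'``."""
    try:
        vt, sc = name.split("-")
    except ValueError:
        raise InvalidArgumentError(
            f"preset name must look like 'A-I', got {name!r}"
        ) from None
    return make_phantom_spec(vt, sc)


def lumen_profile(spec: PhantomSpec, z: float) -> float:
    """Patent lumen diameter at axial position ``z`` (mm).

    Cosine-tapered between ``D`` outside the plaque and ``d`` at its
    centre: symmetric, continuous and monotone on each flank.
    """
    if not 0 <= z <= spec.length:
        raise OutOfRangeError(
            f"z={z} outside centreline extent [0, {spec.length}]"
        )
    u = abs(z - spec.stenosis_center)
    half = spec.stenosis_length / 2.0
    if u >= half:
        return spec.D
    w = 0.5 * (1.0 + math.cos(math.pi * u / half))  # 1 at centre, 0 at edge
    return spec.D - (spec.D - spec.d) * w


def render_truth(
    spec: PhantomSpec,
    z: float,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING,
    size: int = DEFAULT_FRAME_SIZE,
) -> CrossSectionTruth:
    """Rasterize the exact cross-section masks at axial position ``z``.

    The vessel mask is the centred disk of diameter ``D``; the lumen mask
    the (optionally eccentric) disk of diameter ``lumen_profile(spec, z)``;
    the wall annulus extends ``wall_thickness`` beyond the vessel disk.
    """
    if pixel_spacing <= 0:
        raise InvalidArgumentError("pixel_spacing must be positive")
    if spec.D / pixel_spacing < 20:
        raise InvalidArgumentError(
            f"pixel_spacing {pixel_spacing} too coarse: D must span >= 20 px"
        )
    outer_px = (spec.D + 2 * spec.wall_thickness) / pixel_spacing
    if size < outer_px + 4:
        raise InvalidArgumentError(
            f"frame size {size} px cannot contain the vessel "
            f"({outer_px:.0f} px incl. wall)"
        )
    d_z = lumen_profile(spec, z)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    # eccentric mode: lumen centre offset toward +x so the plaque sits
    # one-sided; offset bounded so the lumen stays inside the vessel
    offset = spec.eccentricity * (spec.D - d_z) / 2.0 / pixel_spacing
    r_vessel = spec.D / 2.0 / pixel_spacing
    r_wall = (spec.D / 2.0 + spec.wall_thickness) / pixel_spacing
    r_lumen = d_z / 2.0 / pixel_spacing
    rr2_v = (xx - c) ** 2 + (yy - c) ** 2
    rr2_l = (xx - c - offset) ** 2 + (yy - c) ** 2
    vessel = rr2_v <= r_vessel**2
    lumen = rr2_l <= r_lumen**2
    wall = (rr2_v <= r_wall**2) & ~vessel
    return CrossSectionTruth(
        lumen_mask=lumen,
        vessel_mask=vessel,
        wall_mask=wall,
        pixel_spacing=pixel_spacing,
        axial_position=float(z),
    )


def render_bmode(
    truth: CrossSectionTruth,
    noise: NoiseParams = NoiseParams(),
    frame_index: int = 0,
    theta: float = 0.0,
) -> BModeFrame:
    """Render one speckle-corrupted B-mode-like frame from exact masks.

    Deterministic given the seed.  With ``speckle_scale == 0`` and
    ``blur_sigma == 0`` the output is piecewise constant at the three
    levels.

    The phantom is a single echogenic material (like a printed resin
    tube in a water tank): wall *and* plaque render at ``wall_level``,
    the patent bore at ``lumen_level``, the surroundings at
    ``background_level``.  The visible boundaries are therefore the
    lumen bore and the outer material surface; the plaque/wall interface
    at diameter D is not echogenic (same material on both sides).
    """
    base = np.full(truth.lumen_mask.shape, noise.background_level, dtype=float)
    material = (truth.vessel_mask | truth.wall_mask) & ~truth.lumen_mask
    base[material] = noise.wall_level
    base[truth.lumen_mask] = noise.lumen_level
    img = base
    if noise.speckle_scale > 0:
        rng = np.random.default_rng(noise.seed)
        k = 1.0 / noise.speckle_scale**2
        img = img * rng.gamma(shape=k, scale=1.0 / k, size=img.shape)
    if noise.blur_sigma > 0:
        img = ndimage.gaussian_filter(
            img, sigma=noise.blur_sigma / truth.pixel_spacing, mode="nearest"
        )
    img = np.clip(img, 0.0, 1.0)
    return BModeFrame(
        intensity=img,
        pixel_spacing=truth.pixel_spacing,
        frame_index=frame_index,
        axial_position=truth.axial_position,
        theta=theta,
    )


def _axial_position_on_phantom(spec: PhantomSpec, waypoint_position) -> float:
    """Arc-length coordinate of a workspace waypoint on the centreline."""
    p = np.asarray(waypoint_position, dtype=float)
    if spec.path_kind == "straight":
        start = np.asarray(spec.path_params["start"], dtype=float)
        end = np.asarray(spec.path_params["end"], dtype=float)
        axis = end - start
        norm = np.linalg.norm(axis)
        return float((p - start) @ axis / norm)
    center = np.asarray(spec.path_params["center"], dtype=float)[:2]
    radius = float(spec.path_params["radius"])
    theta0 = float(spec.path_params.get("theta0", 0.0))
    ang = math.atan2(p[1] - center[1], p[0] - center[0])
    # wrap to (-pi, pi] so a waypoint at theta0 maps to arc length 0
    # instead of a full turn under floating-point jitter
    wrapped = (ang - theta0 + math.pi) % (2 * math.pi) - math.pi
    if -1e-6 <= wrapped < 0:
        wrapped = 0.0
    return float(wrapped * radius)


def generate_series(
    spec: PhantomSpec,
    plan: ScanPlan,
    noise: NoiseParams = NoiseParams(),
    pixel_spacing: float = DEFAULT_PIXEL_SPACING,
    size: int = DEFAULT_FRAME_SIZE,
) -> list[tuple[BModeFrame, CrossSectionTruth]]:
    """Render one frame per plan waypoint, with the ground truth attached.

    Frame ``k`` uses noise seed ``noise.seed + k`` so the series is fully
    reproducible while frames stay mutually independent.  Raises
    :class:`OutOfRangeError` if any waypoint maps outside the phantom's
    centreline extent.
    """
    out = []
    for k, w in enumerate(plan.waypoints):
        z = _axial_position_on_phantom(spec, w.position)
        if not 0 <= z <= spec.length:
            raise OutOfRangeError(
                f"plan waypoint {k} maps to z={z:.2f} mm, outside the "
                f"phantom extent [0, {spec.length}] mm"
            )
        truth = render_truth(spec, z, pixel_spacing=pixel_spacing, size=size)
        frame_noise = NoiseParams(
            speckle_scale=noise.speckle_scale,
            blur_sigma=noise.blur_sigma,
            lumen_level=noise.lumen_level,
            wall_level=noise.wall_level,
            background_level=noise.background_level,
            seed=noise.seed + k,
        )
        frame = render_bmode(truth, frame_noise, frame_index=k, theta=w.theta)
        out.append((frame, truth))
    return out


# ---------------------------------------------------------------------------
# frame-series disk format: PNG/TIFF frames + JSON manifest.  The manifest
# schema is the hand-off point for real ultrasound captures.
# ---------------------------------------------------------------------------

def save_series(frames: Sequence[BModeFrame], directory, fmt: str = "png") -> Path:
    """Write frames as 8-bit grayscale images plus a JSON manifest.

    ``fmt='png'`` writes one PNG per frame; ``fmt='tiff'`` a single
    multi-page TIFF.  Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    data8 = [np.round(f.intensity * 255).astype(np.uint8) for f in frames]
    if fmt == "png":
        for f, arr in zip(frames, data8):
            name = f"frame_{f.frame_index:04d}.png"
            iio.imwrite(directory / name, arr)
            entries.append(_manifest_entry(f, name, None))
    elif fmt == "tiff":
        stack_name = "frames.tiff"
        tifffile.imwrite(directory / stack_name, np.stack(data8))
        for page, f in enumerate(frames):
            entries.append(_manifest_entry(f, stack_name, page))
    else:
        raise InvalidArgumentError("fmt must be 'png' or 'tiff'")
    manifest = directory / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"format": fmt, "frames": entries}, fh, indent=2, sort_keys=True)
    return manifest


def _manifest_entry(frame: BModeFrame, file: str, page):
    return {
        "frame_index": frame.frame_index,
        "file": file,
        "page": page,
        "axial_position_mm": frame.axial_position,
        "theta_rad": frame.theta,
        "pixel_spacing_mm": frame.pixel_spacing,
    }


def load_series(manifest_path) -> list[BModeFrame]:
    """Read a frame series written by :func:`save_series` (or real data
    following the same manifest schema)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    directory = manifest_path.parent
    frames = []
    tiff_cache: dict[str, np.ndarray] = {}
    for e in sorted(manifest["frames"], key=lambda e: e["frame_index"]):
        if e["page"] is None:
            arr = np.asarray(iio.imread(directory / e["file"]))
        else:
            if e["file"] not in tiff_cache:
                tiff_cache[e["file"]] = tifffile.imread(directory / e["file"])
            arr = tiff_cache[e["file"]][e["page"]]
        frames.append(
            BModeFrame(
                intensity=arr.astype(float) / 255.0,
                pixel_spacing=e["pixel_spacing_mm"],
                frame_index=e["frame_index"],
                axial_position=e["axial_position_mm"],
                theta=e["theta_rad"],
            )
        )
    return frames
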