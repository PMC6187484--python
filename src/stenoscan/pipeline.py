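"""End-to-end pipeline: phantom -> plan -> render -> segment -> 3D -> report.

Mirrors the operational flow of the scanning system: the scan plan is
computed from marked sites, frames are acquired along it, sequential
image processing (smoothing + boundary detection) runs automatically,
and the contour stack is reconstructed into a 3D model from which the
degree of stenosis is quantified and graded.

A run is fully described by a :class:`RunConfig`; for fixed seeds the
report is byte-for-byte reproducible.  Every stage writes its artifacts
into the run directory so stages can be re-run individually from
intermediate files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import phantom as ph
from . import scanpath as sp
from .errors import InvalidArgumentError, PipelineStageError
from .reconstruct import DEFAULT_INTERPOLATION_SPACING, build_model
from .segmentation import (
    AcmParams,
    DEFAULT_SMOOTH_SIGMA_MM,
    contour_energy_summary,
    equivalent_diameters,
    propagate_series,
)
from .stenosis import series_report
from .tables import validate_table_fixtures  # noqa: F401  (re-exported stage)

__all__ = ["RunConfig", "run_pipeline", "default_sites", "validate_table_fixtures"]


def default_sites(spec: ph.PhantomSpec, margin: float = 10.0) -> list[sp.ScanPoint]:
    """A/L/V site points along a straight phantom's centreline.

    The A and V sites sit ``margin`` mm inside the two ends and the loop
    site at the middle, so a linear plan between them stays on the
    phantom and samples the stenosis centre when it lies mid-vessel.
    """
    import numpy as np

    start = np.asarray(spec.path_params["start"], float)
    end = np.asarray(spec.path_params["end"], float)
    axis = (end - start) / np.linalg.norm(end - start)
    a = start + margin * axis
    v = start + (spec.length - margin) * axis
    loop = (a + v) / 2.0
    return [
        sp.ScanPoint("A", tuple(a)),
        sp.ScanPoint("L", tuple(loop)),
        sp.ScanPoint("V", tuple(v)),
    ]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    preset: str | None = "A-I"  # e.g. 'A-I' ... 'C-III'
    spec_file: str | None = None  # overrides preset when given
    method: str = "linear"
    sites: list | None = None  # [[x,y,z], ...]; defaults from the phantom
    slice_spacing: float = 5.0  # mm
    speed: float = sp.DEFAULT_SPEED_CM_S
    frame_rate: float = sp.DEFAULT_FRAME_RATE_HZ
    noise: dict = field(default_factory=dict)  # NoiseParams overrides
    seed: int = 0
    acm: dict = field(default_factory=dict)  # AcmParams overrides
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA_MM
    interpolation_spacing: float = DEFAULT_INTERPOLATION_SPACING
    pixel_spacing: float = ph.DEFAULT_PIXEL_SPACING
    frame_size: int = ph.DEFAULT_FRAME_SIZE
    frame_format: str = "png"
    out_dir: str = "runs/run"
    quiet: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _log(lines: list[str], quiet: bool, msg: str) -> None:
    lines.append(msg)
    if not quiet:
        print(msg)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline for one configuration.

    Returns the run directory.  Stage failures raise
    :class:`PipelineStageError` naming the stage; artifacts written by
    earlier stages are retained.
    """
    log: list[str] = []
    out = Path(config.out_dir)

    # ---- validation first: fail before rendering anything -----------------
    if config.spec_file:
        spec = ph.PhantomSpec.from_json(config.spec_file)
    elif config.preset:
        spec = ph.preset_from_name(config.preset)
    else:
        raise InvalidArgumentError("config needs a preset or a spec_file")
    if config.sites is not None and len(config.sites) < 3:
        raise InvalidArgumentError(
            f"at least 3 site points are required, got {len(config.sites)}"
        )
    noise = ph.NoiseParams(seed=config.seed, **config.noise)
    acm = AcmParams(**config.acm)

    out.mkdir(parents=True, exist_ok=True)
    spec.to_json(out / "phantom_spec.json")
    config.to_yaml(out / "config_used.yaml")
    _log(log, config.quiet, f"phantom: {spec.vessel_type}-{spec.stenosis_class} "
         f"d={spec.d} D={spec.D} (design DOS {spec.design_dos:.1f}%)")

    # ---- plan -------------------------------------------------------------
    try:
        if config.sites is not None:
            sites = [sp.ScanPoint("other", tuple(p)) for p in config.sites]
        else:
            sites = default_sites(spec)
        plan = sp.build_plan(
            sites, config.method, speed=config.speed,
            frame_rate=config.frame_rate, slice_spacing=config.slice_spacing,
        )
        plan.to_json(out / "scan_plan.json")
        _log(log, config.quiet,
             f"plan: {config.method}, {len(plan.waypoints)} poses, "
             f"spacing {plan.slice_spacing} mm")
    except Exception as exc:
        raise PipelineStageError("plan", exc) from exc

    # ---- render -----------------------------------------------------------
    try:
        series = ph.generate_series(
            spec, plan, noise,
            pixel_spacing=config.pixel_spacing, size=config.frame_size,
        )
        frames = [f for f, _ in series]
        ph.save_series(frames, out / "frames", fmt=config.frame_format)
        _log(log, config.quiet, f"render: {len(frames)} frames (seed {config.seed})")
    except Exception as exc:
        raise PipelineStageError("render", exc) from exc

    # ---- segment ----------------------------------------------------------
    try:
        seed_xy = frames[0].center
        pairs = propagate_series(frames, seed_xy, params=acm,
                                 smooth_sigma=config.smooth_sigma)
        diam_rows = []
        contour_records = []
        for frame, (lum, ves) in zip(frames, pairs):
            d, D = equivalent_diameters(lum, ves, frame.pixel_spacing)
            diam_rows.append((frame.frame_index, frame.axial_position, d, D))
            for role, c in (("lumen", lum), ("vessel", ves)):
                contour_records.append({
                    "frame_index": frame.frame_index,
                    "role": role,
                    "pixel_spacing_mm": frame.pixel_spacing,
                    "vertices": [[float(x), float(y)] for x, y in c.vertices],
                    "params_used": acm.to_dict(),
                    "energy_breakdown": contour_energy_summary(
                        c, frame, acm, config.smooth_sigma),
                    "convention": "pixel centres at integer coords, "
                                  "origin top-left, x right, y down",
                })
        with open(out / "contours.json", "w") as fh:
            json.dump(contour_records, fh, sort_keys=True)
        with open(out / "diameters.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame_index", "axial_position_mm", "d_mm", "D_mm"])
            for row in diam_rows:
                w.writerow([row[0], f"{row[1]:.3f}", f"{row[2]:.4f}",
                            f"{row[3]:.4f}"])
        _log(log, config.quiet, f"segment: {len(pairs)} frames segmented")
    except Exception as exc:
        raise PipelineStageError("segment", exc) from exc

    # ---- reconstruct ------------------------------------------------------
    try:
        model = build_model(pairs, frames, plan,
                            interpolation_spacing=config.interpolation_spacing)
        model.export(out / "model")
        _log(log, config.quiet,
             f"reconstruct: {model.interpolated_count} interpolated contours, "
             f"lumen volume {model.lumen_mesh.volume:.0f} mm^3")
    except Exception as exc:
        raise PipelineStageError("reconstruct", exc) from exc

    # ---- report -----------------------------------------------------------
    try:
        report = series_report(
            measures=[(d, D) for _, _, d, D in diam_rows],
            positions=[z for _, z, _, _ in diam_rows],
            frame_indices=[k for k, _, _, _ in diam_rows],
            params_used={
                "acm": acm.to_dict(),
                "smooth_sigma_mm": config.smooth_sigma,
                "noise_seed": config.seed,
                "pixel_spacing_mm": config.pixel_spacing,
            },
            provenance=config.preset or config.spec_file or "custom",
        )
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        _log(log, config.quiet,
             f"report: max DOS {report.max_dos_percent:.1f}% at "
             f"{report.max_dos_position:.0f} mm -> {report.severity}")
    except Exception as exc:
        raise PipelineStageError("report", exc) from exc

    (out / "run.log").write_text("\n".join(log) + "\n")
    return out
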