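"""Degree-of-stenosis (DOS) quantification, severity grading and agreement.

The clinical quantity of interest is the degree of stenosis of an
arteriovenous fistula,

    DOS% = (1 - d**2 / D**2) * 100,

where ``D`` is the vessel (lumen) diameter of the healthy segment and ``d``
the residual patent diameter at the plaque.  Squaring the diameter ratio
makes the figure an area ratio for circular cross-sections, which is how a
clinician reads it.  Severity grading follows the usual dialysis-access
thresholds: below 30% mild, 30-50% moderate, above 50% severe (severe
stenosis is the indication for percutaneous transluminal angioplasty).

Agreement between two raters (e.g. a robotic system and a clinician) is
summarised by per-case absolute differences in percentage points and the
R^2 of an ordinary least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError

__all__ = [
    "dos",
    "round_dos",
    "classify",
    "series_report",
    "agreement",
    "SliceMeasure",
    "StenosisReport",
    "AgreementStats",
    "SEVERITY_LABELS",
]

SEVERITY_LABELS = ("mild", "moderate", "severe")


def dos(d: float, D: float) -> float:
    """Degree of stenosis in percent from residual and vessel diameters.

    Parameters
    ----------
    d, D : float
        Residual patent diameter and vessel diameter, in the same unit
        (the formula is scale invariant, so pixels and millimetres agree).

    Returns
    -------
    float
        ``(1 - d**2/D**2) * 100`` at full floating precision.  Use
        :func:`round_dos` for presentation at the conventional 0.1
        resolution.
    """
    d = float(d)
    D = float(D)
    if not np.isfinite(d) or not np.isfinite(D) or d <= 0 or D <= 0:
        raise InvalidArgumentError(f"diameters must be positive, got d={d}, D={D}")
    if d > D:
        raise InvalidArgumentError(
            f"residual diameter d={d} exceeds vessel diameter D={D}"
        )
    return (1.0 - (d * d) / (D * D)) * 100.0


def round_dos(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in clinical tables.

    ``round_dos(43.75) == 43.8`` regardless of binary-float half-to-even
    behaviour.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def classify(dos_percent: float) -> str:
    """Severity label for a DOS percentage.

    ``[0, 30)`` -> mild, ``[30, 50]`` -> moderate, ``(50, 100)`` -> severe.
    The boundary values 30 and 50 are both graded moderate.
    """
    v = float(dos_percent)
    if not np.isfinite(v) or v < 0 or v >= 100:
        raise InvalidArgumentError(f"DOS percentage out of range [0, 100): {v}")
    if v < 30.0:
        return "mild"
    if v <= 50.0:
        return "moderate"
    return "severe"


@dataclass(frozen=True)
class SliceMeasure:
    """Per-slice diameter pair and its stenosis fraction."""

    frame_index: int
    axial_position: float  # mm along the scan path
    d: float  # mm
    D: float  # mm
    dos: float = field(init=False)  # fraction in [0, 1)

    def __post_init__(self):
        object.__setattr__(self, "dos", dos(self.d, self.D) / 100.0)

    @property
    def dos_percent(self) -> float:
        return self.dos * 100.0


@dataclass
class StenosisReport:
    """Whole-vessel stenosis summary.

    ``max_dos`` is a fraction in [0, 1); ``max_dos_percent`` is the same
    figure on the percent scale the clinic uses.  Ties in the per-slice
    maximum resolve to the smallest axial position.
    """

    slices: list[SliceMeasure]
    max_dos: float
    max_dos_position: float
    severity: str
    params_used: dict = field(default_factory=dict)
    provenance: str = ""

    @property
    def max_dos_percent(self) -> float:
        return self.max_dos * 100.0

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "max_dos_percent": self.max_dos_percent,
            "max_dos_percent_rounded": round_dos(self.max_dos_percent),
            "max_dos_position_mm": self.max_dos_position,
            "severity": self.severity,
            "params_used": self.params_used,
            "slices": [
                {
                    "frame_index": s.frame_index,
                    "axial_position_mm": s.axial_position,
                    "d_mm": s.d,
                    "D_mm": s.D,
                    "dos_percent": s.dos_percent,
                }
                for s in self.slices
            ],
        }


def series_report(
    measures: Sequence[tuple[float, float]],
    positions: Sequence[float],
    frame_indices: Sequence[int] | None = None,
    params_used: dict | None = None,
    provenance: str = "",
) -> StenosisReport:
    """Build a :class:`StenosisReport` from per-slice ``(d, D)`` pairs.

    Parameters
    ----------
    measures : sequence of (d, D)
        Millimetre diameter pairs, one per slice.
    positions : sequence of float
        Axial position of each slice along the scan path, mm.
    """
    if len(measures) == 0:
        raise InvalidArgumentError("series_report requires at least one slice")
    if len(measures) != len(positions):
        raise InvalidArgumentError("measures and positions length mismatch")
    if frame_indices is None:
        frame_indices = list(range(len(measures)))
    slices = [
        SliceMeasure(frame_index=int(k), axial_position=float(z), d=float(d), D=float(D))
        for k, z, (d, D) in zip(frame_indices, positions, measures)
    ]
    # tie rule: first (smallest axial position) among equal maxima, with
    # slices scanned in increasing axial order
    order = np.argsort([s.axial_position for s in slices], kind="stable")
    best = max((slices[i] for i in order), key=lambda s: s.dos)
    # max() keeps the first of equal keys, i.e. the smallest axial position
    return StenosisReport(
        slices=slices,
        max_dos=best.dos,
        max_dos_position=best.axial_position,
        severity=classify(best.dos_percent),
        params_used=dict(params_used or {}),
        provenance=provenance,
    )


@dataclass
class AgreementStats:
    """Paired agreement between two DOS raters (percent scale)."""

    dos_1: np.ndarray
    dos_2: np.ndarray
    abs_errors: np.ndarray  # percentage points
    mean_abs_error: float
    max_abs_error: float
    r_squared: float
    slope: float
    intercept: float

    def to_dict(self) -> dict:
        return {
            "abs_errors": self.abs_errors.tolist(),
            "mean_abs_error": self.mean_abs_error,
            "max_abs_error": self.max_abs_error,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
        }


def agreement(dos_1: Sequence[float], dos_2: Sequence[float]) -> AgreementStats:
    """Absolute per-pair error and OLS R^2 between two DOS sequences.

    ``dos_2`` is regressed on ``dos_1`` by ordinary least squares.  Errors
    are absolute differences in percentage points (the ratio-style wording
    sometimes attached to such tables is not used; see the methods note).
    """
    a = np.asarray(dos_1, dtype=float)
    b = np.asarray(dos_2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidArgumentError("agreement requires equal-length 1-D sequences")
    if a.size < 2:
        raise InvalidArgumentError("agreement requires at least two pairs")
    errors = np.abs(a - b)
    if np.allclose(a, a[0]):
        raise InvalidArgumentError("dos_1 is constant; regression undefined")
    fit = stats.linregress(a, b)
    return AgreementStats(
        dos_1=a,
        dos_2=b,
        abs_errors=errors,
        mean_abs_error=float(errors.mean()),
        max_abs_error=float(errors.max()),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
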