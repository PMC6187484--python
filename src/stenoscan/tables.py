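"""Bundled reference measurement tables and their self-consistency check.

Two small CSV fixtures ship with the package:

``phantom_table.csv``
    The nine stenosed-vessel phantom presets (types A/B/C at diameters
    10/8/5 mm, stenosis classes I/II/III near 20/40/80% DOS) with their
    design diameters, cone-beam CT (CBCT) reference measurements,
    robotic-ultrasound (RUS) measurements, and the two error columns.

``clinical_table.csv``
    Ten paired patient measurements: robotic-ultrasound versus clinician
    DOS with averaged diameters and repeat-measurement variation.

:func:`validate_table_fixtures` recomputes every cell that is derivable
from the printed diameter pairs via the DOS formula and flags cells that
do not reproduce.  A handful of cells in the source tables are internally
inconsistent (they do not follow from their own printed diameters); these
are pre-registered in :data:`DOCUMENTED_EXCEPTIONS` so regression tests
can distinguish "known discrepancy in the reference tables" from "we
broke something".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .stenosis import dos

__all__ = [
    "load_phantom_table",
    "load_clinical_table",
    "validate_table_fixtures",
    "CellCheck",
    "FixtureValidation",
    "DOCUMENTED_EXCEPTIONS",
    "MATCH_TOLERANCE",
]

#: Printed values are given at 0.1 resolution with mixed rounding and
#: truncation conventions; a recomputed cell is accepted when it lies
#: within one printed unit of the table value.
MATCH_TOLERANCE = 0.1 + 1e-9

#: Cells of the bundled tables that provably do not recompute from their
#: own printed inputs (checked by hand; see docs/methods.md).
DOCUMENTED_EXCEPTIONS = frozenset(
    {
        ("phantom", "design_dos", "A-II"),   # prints 40.2, (7.8,10) gives 39.2
        ("phantom", "design_dos", "A-III"),  # prints 80.2, (4.5,10) gives 79.8
        ("phantom", "design_dos", "B-I"),    # prints 23.0, (7,8) gives 23.4
        ("phantom", "cbct_dos", "A-I"),      # prints 20.6, (8.8,9.8) gives 19.4
        ("phantom", "cbct_dos", "A-II"),     # prints 42.6, (7.5,9.8) gives 41.4
        ("phantom", "cbct_dos", "C-II"),     # prints 43.3, (3.6,4.8) gives 43.8
        ("phantom", "err_cbct_rus", "A-III"),  # prints 1.0, |81.5-81.6| = 0.1
        ("phantom", "err_cbct_rus", "C-II"),   # prints 2.2, |43.3-44.5| = 1.2
        ("clinical", "avg_error", "2"),  # prints 2.9 = 100*(1-74.7/76.9), not |diff|
        ("clinical", "avg_error", "7"),  # prints 2.5 = 100*(1-31.3/32.1), not |diff|
    }
)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("stenoscan.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_phantom_table() -> pd.DataFrame:
    """Nine-row phantom preset table (design / CBCT / RUS measurements)."""
    return _read_csv("phantom_table.csv")


def load_clinical_table() -> pd.DataFrame:
    """Ten-row paired robot-vs-clinician DOS table."""
    return _read_csv("clinical_table.csv")


@dataclass(frozen=True)
class CellCheck:
    """Outcome of recomputing one printed table cell."""

    table: str
    column: str
    row: str
    printed: float
    recomputed: float
    matches: bool
    documented_exception: bool

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.table, self.column, self.row)


@dataclass
class FixtureValidation:
    """Summary returned by :func:`validate_table_fixtures`."""

    checks: list[CellCheck] = field(default_factory=list)

    @property
    def mismatches(self) -> list[CellCheck]:
        return [c for c in self.checks if not c.matches]

    @property
    def unexpected_mismatches(self) -> list[CellCheck]:
        return [c for c in self.mismatches if not c.documented_exception]

    @property
    def passed(self) -> bool:
        """True when every mismatch is a pre-registered exception."""
        return not self.unexpected_mismatches

    def summary(self) -> str:
        n_ok = sum(c.matches for c in self.checks)
        lines = [
            f"{n_ok}/{len(self.checks)} cells recompute within "
            f"{MATCH_TOLERANCE:.1f} of their printed value"
        ]
        for c in self.mismatches:
            tag = "documented exception" if c.documented_exception else "UNEXPECTED"
            lines.append(
                f"  {c.table}.{c.column}[{c.row}]: printed {c.printed} vs "
                f"recomputed {c.recomputed:.2f} ({tag})"
            )
        lines.append("PASS" if self.passed else "FAIL")
        return "\n".join(lines)


def _check(out: list[CellCheck], table: str, column: str, row: str,
           printed: float, recomputed: float) -> None:
    matches = abs(float(printed) - float(recomputed)) <= MATCH_TOLERANCE
    out.append(
        CellCheck(
            table=table,
            column=column,
            row=row,
            printed=float(printed),
            recomputed=float(recomputed),
            matches=matches,
            documented_exception=(table, column, row) in DOCUMENTED_EXCEPTIONS,
        )
    )


def validate_table_fixtures() -> FixtureValidation:
    """Recompute every derivable cell of the bundled tables.

    DOS columns are recomputed from their printed (d, D) pairs; error
    columns as absolute differences of the printed DOS columns.  Failures
    are reported, never raised.
    """
    out: list[CellCheck] = []

    pt = load_phantom_table()
    for _, r in pt.iterrows():
        row = f"{r.vessel_type}-{r.stenosis_class}"
        _check(out, "phantom", "design_dos", row, r.design_dos,
               dos(r.design_d, r.design_D))
        _check(out, "phantom", "cbct_dos", row, r.cbct_dos,
               dos(r.cbct_d, r.cbct_D))
        _check(out, "phantom", "rus_dos", row, r.rus_dos,
               dos(r.rus_d, r.rus_D))
        _check(out, "phantom", "err_design_cbct", row, r.err_design_cbct,
               abs(r.design_dos - r.cbct_dos))
        _check(out, "phantom", "err_cbct_rus", row, r.err_cbct_rus,
               abs(r.cbct_dos - r.rus_dos))

    ct = load_clinical_table()
    for _, r in ct.iterrows():
        row = str(int(r.patient))
        _check(out, "clinical", "rus_dos", row, r.rus_dos, dos(r.rus_d, r.rus_D))
        _check(out, "clinical", "doc_dos", row, r.doc_dos, dos(r.doc_d, r.doc_D))
        _check(out, "clinical", "avg_error", row, r.avg_error,
               abs(r.rus_dos - r.doc_dos))

    return FixtureValidation(checks=out)
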