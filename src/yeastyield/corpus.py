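"""Production corpus: records, file I/O in two dialects, and validation.

A corpus is a list of :class:`ProductionRecord`, one per literature
production result.  Each record carries the C-mol yield (mol carbon in
product per mol carbon in primary substrate), the enzymatic step counts of
the primary (substrate -> central precursor) and secondary (precursor ->
product) pathway segments, and six ordinal experimental-condition
variables: OVE (overexpression extent, C1-C3), KNO (knockouts, C1/C2),
NUT (medium richness), INT (intermediate feeding), CUL (cultivation
vessel) and OXY (oxygen limitation).

When an intermediate precursor is fed (INT = C2) a record stores two step
counts per pathway segment — one counted from the primary substrate and
one from the fed intermediate, printed as ``a(b)`` in the source table.
The averaging of the two happens downstream in :mod:`yeastyield.encoder`,
not here, so the raw bookkeeping stays auditable.

Two text dialects are supported:

``preencoded``
    Columns exactly as the curated training table: ``Reference Product
    Yield PrimaryStep SecondStep OVE_C2 OVE_C3 KNO_C2 NUT_C2 INT_C2
    CUL_C2 OXY_C2`` with 0/1 dummy columns and ``a(b)`` dual step counts.

``raw``
    Columns ``reference product yield pri_sub pri_int sec_sub sec_int OVE
    KNO NUT INT CUL OXY`` with category tokens C1/C2/C3 and the
    intermediate-side counts in their own (possibly empty) columns.

Both accept tab- or comma-separated text with a mandatory header.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .exceptions import DialectError, InvariantError, ParseError

__all__ = [
    "ProductionRecord",
    "Violation",
    "ValidationReport",
    "load_corpus",
    "write_corpus",
    "validate_corpus",
    "packaged_corpus_path",
    "load_packaged_corpus",
    "PREENCODED_COLUMNS",
    "RAW_COLUMNS",
]

Level = Literal["C1", "C2", "C3"]

PREENCODED_COLUMNS = [
    "Reference", "Product", "Yield", "PrimaryStep", "SecondStep",
    "OVE_C2", "OVE_C3", "KNO_C2", "NUT_C2", "INT_C2", "CUL_C2", "OXY_C2",
]
RAW_COLUMNS = [
    "reference", "product", "yield", "pri_sub", "pri_int", "sec_sub",
    "sec_int", "OVE", "KNO", "NUT", "INT", "CUL", "OXY",
]

_DUAL_RE = re.compile(r"^\s*([0-9.]+)\s*\(\s*([0-9.]+)\s*\)\s*$")


@dataclass(frozen=True)
class ProductionRecord:
    """One literature production result.

    ``pri_intermediate``/``sec_intermediate`` are the step counts from the
    fed intermediate; they are present exactly when ``int_add == "C2"``.
    """

    reference_id: str
    product: str
    yield_c: float
    pri_substrate: float
    sec_substrate: float
    pri_intermediate: float | None = None
    sec_intermediate: float | None = None
    ove: Level = "C1"
    kno: Level = "C1"
    nut: Level = "C1"
    int_add: Level = "C1"
    cul: Level = "C1"
    oxy: Level = "C1"


@dataclass(frozen=True)
class Violation:
    name: str
    message: str
    severity: Literal["error", "warning"] = "error"


@dataclass
class ValidationReport:
    record_index: int
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(v.severity == "error" for v in self.violations)


def _parse_steps(token: str, *, row: int, column: str) -> tuple[float, float | None]:
    """Parse a step-count cell, returning (substrate, intermediate_or_None).

    Accepts plain numbers and the dual ``a(b)`` notation used when an
    intermediate is fed.
    """
    token = str(token).strip()
    m = _DUAL_RE.match(token)
    if m:
        return float(m.group(1)), float(m.group(2))
    try:
        return float(token), None
    except ValueError:
        raise ParseError(
            f"malformed step count {token!r} at row {row}, column {column}"
        ) from None


def _parse_float(token, *, row: int, column: str) -> float:
    try:
        return float(token)
    except (TypeError, ValueError):
        raise ParseError(
            f"malformed number {token!r} at row {row}, column {column}"
        ) from None


def _parse_dummy(token, *, row: int, column: str) -> int:
    v = _parse_float(token, row=row, column=column)
    if v not in (0.0, 1.0):
        raise ParseError(
            f"dummy column {column} must be 0/1, got {token!r} at row {row}"
        )
    return int(v)


def _parse_level(token, allowed: tuple[str, ...], *, row: int, column: str) -> str:
    token = str(token).strip().upper()
    if token not in allowed:
        raise ParseError(
            f"category level {token!r} at row {row}, column {column}; "
            f"expected one of {allowed}"
        )
    return token


def _read_table(path) -> pd.DataFrame:
    text = Path(path).read_text(encoding="utf-8")
    first = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def load_corpus(path, dialect: str = "preencoded") -> list[ProductionRecord]:
    """Read a corpus file and return one :class:`ProductionRecord` per row."""
    if dialect not in ("preencoded", "raw"):
        raise DialectError(f"unknown dialect {dialect!r}")
    df = _read_table(path)
    expected = PREENCODED_COLUMNS if dialect == "preencoded" else RAW_COLUMNS
    if list(df.columns) != expected:
        raise DialectError(
            f"header does not match the {dialect!r} dialect: "
            f"got {list(df.columns)}, expected {expected}"
        )
    records: list[ProductionRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        if dialect == "preencoded":
            records.append(_record_from_preencoded(row, i))
        else:
            records.append(_record_from_raw(row, i))
    return records


def _record_from_preencoded(row, i: int) -> ProductionRecord:
    yield_c = _parse_float(row["Yield"], row=i, column="Yield")
    pri_sub, pri_int = _parse_steps(row["PrimaryStep"], row=i, column="PrimaryStep")
    sec_sub, sec_int = _parse_steps(row["SecondStep"], row=i, column="SecondStep")
    ove_c2 = _parse_dummy(row["OVE_C2"], row=i, column="OVE_C2")
    ove_c3 = _parse_dummy(row["OVE_C3"], row=i, column="OVE_C3")
    if ove_c2 and ove_c3:
        raise InvariantError(f"both OVE_C2 and OVE_C3 set at row {i}")
    ove = "C3" if ove_c3 else ("C2" if ove_c2 else "C1")
    binary = {}
    for col in ("KNO_C2", "NUT_C2", "INT_C2", "CUL_C2", "OXY_C2"):
        binary[col] = "C2" if _parse_dummy(row[col], row=i, column=col) else "C1"
    return ProductionRecord(
        reference_id=str(row["Reference"]).strip(),
        product=str(row["Product"]).strip(),
        yield_c=yield_c,
        pri_substrate=pri_sub,
        sec_substrate=sec_sub,
        pri_intermediate=pri_int,
        sec_intermediate=sec_int,
        ove=ove,
        kno=binary["KNO_C2"],
        nut=binary["NUT_C2"],
        int_add=binary["INT_C2"],
        cul=binary["CUL_C2"],
        oxy=binary["OXY_C2"],
    )


def _record_from_raw(row, i: int) -> ProductionRecord:
    def opt(token, column):
        token = str(token).strip()
        return None if token == "" else _parse_float(token, row=i, column=column)

    return ProductionRecord(
        reference_id=str(row["reference"]).strip(),
        product=str(row["product"]).strip(),
        yield_c=_parse_float(row["yield"], row=i, column="yield"),
        pri_substrate=_parse_float(row["pri_sub"], row=i, column="pri_sub"),
        sec_substrate=_parse_float(row["sec_sub"], row=i, column="sec_sub"),
        pri_intermediate=opt(row["pri_int"], "pri_int"),
        sec_intermediate=opt(row["sec_int"], "sec_int"),
        ove=_parse_level(row["OVE"], ("C1", "C2", "C3"), row=i, column="OVE"),
        kno=_parse_level(row["KNO"], ("C1", "C2"), row=i, column="KNO"),
        nut=_parse_level(row["NUT"], ("C1", "C2"), row=i, column="NUT"),
        int_add=_parse_level(row["INT"], ("C1", "C2"), row=i, column="INT"),
        cul=_parse_level(row["CUL"], ("C1", "C2"), row=i, column="CUL"),
        oxy=_parse_level(row["OXY"], ("C1", "C2"), row=i, column="OXY"),
    )


def _fmt_num(x: float) -> str:
    """Format a float so that it round-trips exactly through text."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _fmt_steps(sub: float, inter: float | None) -> str:
    if inter is None:
        return _fmt_num(sub)
    return f"{_fmt_num(sub)}({_fmt_num(inter)})"


def write_corpus(records: Iterable[ProductionRecord], path,
                 dialect: str = "preencoded", sep: str = "\t") -> None:
    """Write a corpus file; ``load_corpus(write_corpus(r))`` is the identity."""
    if dialect not in ("preencoded", "raw"):
        raise DialectError(f"unknown dialect {dialect!r}")
    rows = []
    for r in records:
        if dialect == "preencoded":
            rows.append({
                "Reference": r.reference_id,
                "Product": r.product,
                "Yield": repr(float(r.yield_c)),
                "PrimaryStep": _fmt_steps(r.pri_substrate, r.pri_intermediate),
                "SecondStep": _fmt_steps(r.sec_substrate, r.sec_intermediate),
                "OVE_C2": int(r.ove == "C2"),
                "OVE_C3": int(r.ove == "C3"),
                "KNO_C2": int(r.kno == "C2"),
                "NUT_C2": int(r.nut == "C2"),
                "INT_C2": int(r.int_add == "C2"),
                "CUL_C2": int(r.cul == "C2"),
                "OXY_C2": int(r.oxy == "C2"),
            })
        else:
            rows.append({
                "reference": r.reference_id,
                "product": r.product,
                "yield": repr(float(r.yield_c)),
                "pri_sub": _fmt_num(r.pri_substrate),
                "pri_int": "" if r.pri_intermediate is None else _fmt_num(r.pri_intermediate),
                "sec_sub": _fmt_num(r.sec_substrate),
                "sec_int": "" if r.sec_intermediate is None else _fmt_num(r.sec_intermediate),
                "OVE": r.ove, "KNO": r.kno, "NUT": r.nut,
                "INT": r.int_add, "CUL": r.cul, "OXY": r.oxy,
            })
    columns = PREENCODED_COLUMNS if dialect == "preencoded" else RAW_COLUMNS
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=sep, index=False)


def validate_corpus(records: Iterable[ProductionRecord]) -> list[ValidationReport]:
    """Check every record against the structural invariants.

    Reports, never throws: each record gets a :class:`ValidationReport`
    whose ``violations`` list is empty iff the record passes.
    """
    reports = []
    for i, r in enumerate(records):
        v: list[Violation] = []
        if not (r.yield_c > 0):
            v.append(Violation("yield_nonpositive",
                               f"yield_c must be > 0, got {r.yield_c}"))
        elif r.yield_c > 1:
            v.append(Violation("yield_exceeds_one",
                               f"C-mol yield {r.yield_c} exceeds 1"))
        for name, val in (("pri_substrate", r.pri_substrate),
                          ("sec_substrate", r.sec_substrate)):
            if not math.isfinite(val) or val < 0:
                v.append(Violation("step_count_invalid",
                                   f"{name} must be finite and >= 0, got {val}"))
        for name, val in (("pri_intermediate", r.pri_intermediate),
                          ("sec_intermediate", r.sec_intermediate)):
            if val is not None and (not math.isfinite(val) or val < 0):
                v.append(Violation("step_count_invalid",
                                   f"{name} must be finite and >= 0, got {val}"))
        has_inter = r.pri_intermediate is not None or r.sec_intermediate is not None
        if r.int_add == "C2" and not has_inter:
            v.append(Violation(
                "intermediate_steps_missing",
                "INT = C2 but no intermediate-side step counts present"))
        if r.int_add == "C1" and has_inter:
            v.append(Violation(
                "intermediate_steps_unexpected",
                "intermediate-side step counts present but INT = C1"))
        if r.ove not in ("C1", "C2", "C3"):
            v.append(Violation("bad_level", f"OVE level {r.ove!r}"))
        for name, val in (("KNO", r.kno), ("NUT", r.nut), ("INT", r.int_add),
                          ("CUL", r.cul), ("OXY", r.oxy)):
            if val not in ("C1", "C2"):
                v.append(Violation("bad_level", f"{name} level {val!r}"))
        for name, val in (("pri_substrate", r.pri_substrate),
                          ("sec_substrate", r.sec_substrate)):
            if math.isfinite(val) and val >= 0 and val != int(val):
                v.append(Violation(
                    "fractional_step_count",
                    f"{name} = {val} is not an integer", severity="warning"))
        reports.append(ValidationReport(record_index=i, violations=v))
    return reports


def packaged_corpus_path() -> Path:
    """Path to the packaged training corpus (preencoded dialect)."""
    return Path(resources.files("yeastyield.data") / "table2.tsv")


def load_packaged_corpus() -> list[ProductionRecord]:
    """Load the packaged literature training corpus (126 records)."""
    return load_corpus(packaged_corpus_path(), dialect="preencoded")
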