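"""Reading, writing and validating call-feature tables.

One row of a call table is one call: the identity of the calling male, the
group it belongs to (e.g. HIGH / LOW density, CLUMPED / ISOLATED), the call
duration in seconds and ten peak-frequency-contour (PFC) samples in Hz.

Two on-disk dialects are supported:

``flat``
    Delimited text (comma or tab, sniffed) with header columns
    ``individual_id, group_label, call_id, duration_s, pfc_01 .. pfc_10``.
    This is the package's canonical interchange format; writing always uses
    it, at full float precision, so a write/read round trip is exact.

``raven``
    A tab-delimited selection table in the shape exported by Raven-style
    measurement software: one selection per row with begin/end time columns
    and a variable number of contour columns sharing a configurable name
    prefix.  Contours are resampled to ten evenly spaced values on
    ingestion (see :mod:`hootid.contours`); duration is ``end - begin``.

Individuals with fewer than two calls are retained in the table but flagged:
within-individual variation is undefined for a single call, so downstream
metrics exclude them.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contours

logger = logging.getLogger("hootid.call_io")

__all__ = [
    "RawContour",
    "CallRecord",
    "CallTable",
    "ValidationReport",
    "CallTableFormatError",
    "CallValidationError",
    "read_call_table",
    "write_call_table",
    "validate_table",
    "N_PFC",
    "FLAT_COLUMNS",
]

N_PFC = 10
PFC_COLUMNS = [f"pfc_{i:02d}" for i in range(1, N_PFC + 1)]
FLAT_COLUMNS = ["individual_id", "group_label", "call_id", "duration_s"] + PFC_COLUMNS

#: default column names for the raven dialect (overridable per call)
RAVEN_BEGIN = "Begin Time (s)"
RAVEN_END = "End Time (s)"
RAVEN_INDIVIDUAL = "Individual"
RAVEN_GROUP = "Group"
RAVEN_CONTOUR_PREFIX = "Peak Freq Contour"


class CallTableFormatError(ValueError):
    """A file does not match the expected table layout (e.g. missing column)."""


class CallValidationError(ValueError):
    """A row or table violates the call-table contract."""


@dataclass
class RawContour:
    """A traced peak-frequency contour before resampling.

    ``freqs_hz`` are assumed uniformly spaced in time over
    ``[begin_s, end_s]``, endpoints included.
    """

    selection_id: str
    begin_s: float
    end_s: float
    freqs_hz: np.ndarray

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if not self.end_s > self.begin_s:
            raise CallValidationError(
                f"selection {self.selection_id!r}: end_s ({self.end_s}) must be "
                f"> begin_s ({self.begin_s})"
            )
        if self.freqs_hz.size < 2:
            raise CallValidationError(
                f"selection {self.selection_id!r}: contour needs >= 2 samples"
            )
        if not np.all(np.isfinite(self.freqs_hz)) or np.any(self.freqs_hz <= 0):
            raise CallValidationError(
                f"selection {self.selection_id!r}: contour values must be finite and > 0"
            )


@dataclass
class CallRecord:
    """A single call: labels, duration and the fixed-length PFC vector."""

    individual_id: str
    group_label: str
    call_id: str
    duration_s: float
    pfc_hz: np.ndarray

    def __post_init__(self):
        self.pfc_hz = np.asarray(self.pfc_hz, dtype=float)
        if not (isinstance(self.duration_s, (int, float)) and math.isfinite(self.duration_s)):
            raise CallValidationError(
                f"call {self.call_id!r}: duration_s must be a finite number"
            )
        if self.duration_s <= 0:
            raise CallValidationError(
                f"call {self.call_id!r}: duration_s must be > 0, got {self.duration_s}"
            )
        if self.pfc_hz.size != N_PFC:
            raise CallValidationError(
                f"call {self.call_id!r}: expected {N_PFC} PFC values, got {self.pfc_hz.size}"
            )
        if not np.all(np.isfinite(self.pfc_hz)):
            raise CallValidationError(f"call {self.call_id!r}: non-finite PFC value")


@dataclass
class CallTable:
    """An ordered collection of :class:`CallRecord` plus provenance metadata."""

    records: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)

    @property
    def individuals(self) -> list:
        seen = {}
        for r in self.records:
            seen.setdefault(r.individual_id, None)
        return list(seen)

    def call_counts(self) -> dict:
        counts: dict = {}
        for r in self.records:
            counts[r.individual_id] = counts.get(r.individual_id, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Flat-dialect DataFrame, one row per call, original order."""
        rows = [
            [r.individual_id, r.group_label, r.call_id, r.duration_s, *r.pfc_hz]
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=FLAT_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "CallTable":
        records = []
        for i, row in df.iterrows():
            dur = row["duration_s"]
            try:
                dur = float(dur)
            except (TypeError, ValueError):
                dur = float("nan")
            if not math.isfinite(dur) or dur <= 0:
                raise CallValidationError(
                    f"row {i}: duration_s must be a positive number, got {row['duration_s']!r}"
                )
            try:
                pfc = row[PFC_COLUMNS].to_numpy(dtype=float)
            except (TypeError, ValueError) as exc:
                raise CallValidationError(f"row {i}: non-numeric PFC value ({exc})") from None
            if not np.all(np.isfinite(pfc)):
                raise CallValidationError(f"row {i}: non-finite PFC value")
            records.append(
                CallRecord(
                    individual_id=str(row["individual_id"]),
                    group_label=str(row["group_label"]),
                    call_id=str(row["call_id"]),
                    duration_s=dur,
                    pfc_hz=pfc,
                )
            )
        table = cls(records=records, provenance=dict(provenance or {}))
        _flag_small_individuals(table)
        return table


def _flag_small_individuals(table: CallTable) -> None:
    small = [ind for ind, n in table.call_counts().items() if n < 2]
    if small:
        msg = f"individuals with < 2 calls (excluded from metrics): {small}"
        logger.warning(msg)
        table.provenance.setdefault("warnings", []).append(msg)


def read_call_table(
    path,
    dialect: str = "flat",
    *,
    contour_prefix: str = RAVEN_CONTOUR_PREFIX,
    begin_column: str = RAVEN_BEGIN,
    end_column: str = RAVEN_END,
    individual_column: str = RAVEN_INDIVIDUAL,
    group_column: str = RAVEN_GROUP,
) -> CallTable:
    """Read a call table from ``path`` in the given dialect.

    Raven-dialect rows are converted to ten evenly spaced PFC values via
    :func:`hootid.contours.resample_evenly`; row order is preserved in both
    dialects.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "flat":
        return _read_flat(path)
    if dialect == "raven":
        return _read_raven(
            path,
            contour_prefix=contour_prefix,
            begin_column=begin_column,
            end_column=end_column,
            individual_column=individual_column,
            group_column=group_column,
        )
    raise ValueError(f"unknown dialect {dialect!r}; expected 'flat' or 'raven'")


def _read_flat(path: Path) -> CallTable:
    # sniff the delimiter from the header line ('#' lines are metadata);
    # the round_trip parser keeps write/read exact to the last bit
    with open(path) as fh:
        header = ""
        for line in fh:
            if not line.startswith("#"):
                header = line
                break
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    missing = [c for c in FLAT_COLUMNS if c not in df.columns]
    if missing:
        raise CallTableFormatError(f"{path}: missing required column(s): {missing}")
    return CallTable.from_frame(df, provenance={"source": str(path), "dialect": "flat"})


def _natural_contour_order(columns, prefix):
    """Contour columns in numeric-suffix order ('... 2' before '... 10')."""
    def key(name):
        m = re.search(r"(\d+)", name[len(prefix):])
        return (0, int(m.group(1))) if m else (1, name)
    return sorted((c for c in columns if c.startswith(prefix)), key=key)


def _read_raven(path, *, contour_prefix, begin_column, end_column,
                individual_column, group_column) -> CallTable:
    df = pd.read_csv(path, sep="\t")
    for col in (begin_column, end_column, individual_column):
        if col not in df.columns:
            raise CallTableFormatError(f"{path}: missing required column {col!r}")
    contour_cols = _natural_contour_order(df.columns, contour_prefix)
    if len(contour_cols) < 2:
        raise CallTableFormatError(
            f"{path}: need >= 2 contour columns with prefix {contour_prefix!r}, "
            f"found {len(contour_cols)}"
        )
    has_group = group_column in df.columns
    records = []
    for i, row in df.iterrows():
        sel = str(row["Selection"]) if "Selection" in df.columns else str(i)
        begin, end = row[begin_column], row[end_column]
        try:
            begin, end = float(begin), float(end)
        except (TypeError, ValueError):
            raise CallValidationError(f"row {i}: non-numeric begin/end time") from None
        freqs = pd.to_numeric(row[contour_cols], errors="coerce").to_numpy(dtype=float)
        freqs = freqs[np.isfinite(freqs)]
        contour = RawContour(selection_id=sel, begin_s=begin, end_s=end, freqs_hz=freqs)
        records.append(
            CallRecord(
                individual_id=str(row[individual_column]),
                group_label=str(row[group_column]) if has_group else "NA",
                call_id=sel,
                duration_s=end - begin,
                pfc_hz=contours.resample_evenly(contour, k=N_PFC),
            )
        )
    table = CallTable(
        records=records,
        provenance={"source": str(path), "dialect": "raven", "contour_prefix": contour_prefix},
    )
    _flag_small_individuals(table)
    return table


def write_call_table(table: CallTable, path) -> None:
    """Write ``table`` in the flat dialect at full float precision.

    ``read_call_table(write_call_table(t))`` reproduces every field exactly:
    floats are serialised with Python's shortest round-trip representation.
    """
    if len(table) == 0:
        raise CallValidationError("refusing to write an empty call table")
    df = table.to_frame()
    for col in ["duration_s"] + PFC_COLUMNS:
        df[col] = df[col].map(repr)  # shortest exact round-trip form
    df.to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_table`: per-record violations + call counts.

    Each violation carries a severity: ``error`` (non-finite values,
    duplicate call ids — the table is unusable as-is) or ``warning``
    (out-of-band frequencies, individuals with too few calls — suspicious
    but handled downstream).  ``ok`` means no errors.
    """

    violations: list
    call_counts: dict

    @property
    def errors(self) -> list:
        return [v for v in self.violations if v["severity"] == "error"]

    @property
    def warnings(self) -> list:
        return [v for v in self.violations if v["severity"] == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_table(table: CallTable, freq_band_hz: tuple = (500.0, 2000.0)) -> ValidationReport:
    """Report out-of-band PFC values, non-finite values, duplicate call ids
    and individuals with too few calls.  Never mutates the table.

    The default band is the species' plausible fundamental-frequency range
    (500–2000 Hz); values outside it usually indicate contour-tracing errors.
    """
    low, high = freq_band_hz
    violations = []
    seen = set()
    for idx, rec in enumerate(table.records):
        key = (rec.individual_id, rec.call_id)
        if key in seen:
            violations.append(
                {"row": idx, "kind": "duplicate_call_id", "severity": "error",
                 "detail": f"duplicate (individual_id, call_id) {key}"}
            )
        seen.add(key)
        if not np.all(np.isfinite(rec.pfc_hz)):
            violations.append({"row": idx, "kind": "non_finite", "severity": "error",
                               "detail": f"call {rec.call_id!r} has non-finite PFC"})
            continue
        bad = rec.pfc_hz[(rec.pfc_hz < low) | (rec.pfc_hz > high)]
        if bad.size:
            violations.append(
                {"row": idx, "kind": "out_of_band", "severity": "warning",
                 "detail": f"call {rec.call_id!r}: {bad.size} PFC value(s) outside "
                           f"[{low}, {high}] Hz (e.g. {bad[0]:g})"}
            )
    counts = table.call_counts()
    for ind, n in counts.items():
        if n < 2:
            violations.append(
                {"row": None, "kind": "insufficient_calls", "severity": "warning",
                 "detail": f"individual {ind!r} has {n} call(s); metrics need >= 2"}
            )
    return ValidationReport(violations=violations, call_counts=counts)
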