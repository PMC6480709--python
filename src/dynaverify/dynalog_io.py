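"""Reading, writing and merging of MLC dynalog bank files.

A Varian MLC controller writes one log file per leaf carriage (bank A and
bank B) during every dynamic treatment field, inserting a record every
50 ms (20 ms on TrueBeam machines). Each record stores the beam status,
beam hold-off flag, segment number (the index of the transition interval
between two control points of the original plan), gantry angle, jaw
positions, cumulative fractional dose, and the *expected* and *actual*
position of every leaf of that bank.

The vendor never published a single canonical column layout, and several
text dialects exist in the wild, so this module parameterises the format
with a :class:`DynalogDialect` (delimiter, integer position units, gantry
and dose scaling). Two dialects ship by default:

``CLINAC_DIALECT``
    Integer positions in hundredths of a millimetre, gantry in tenths of a
    degree, dose fraction as an integer with full scale 25000 — the fixed
    point conventions of Clinac-era Millennium-120 logs.
``NATIVE_DIALECT``
    Plain floats (cm, degrees, fraction); exact round trip of any value.
    Used for synthetic fixtures.

Sign convention: every leaf position is a coordinate that *increases in the
leaf's opening direction*, so for a leaf pair the aperture spans
``[-pos_B, +pos_A]`` on the leaf-travel axis and its width is
``pos_A + pos_B``. Subtracting a positive quantity from any position always
shrinks the aperture; this is what makes the absolute-value error
magnification mode well defined (see :mod:`dynaverify.error_model`).

In memory all positions are float centimetres at the isocenter plane;
leaf-error statistics (RMS, MLE) are reported in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import (
    ConsistencyError,
    DynalogParseError,
    DynalogStructureError,
    MergeError,
)

logger = logging.getLogger(__name__)

#: Record tick spacing by linac type, milliseconds.
TICK_MS = {"Clinac": 50, "TrueBeam": 20}

CM_PER_MM = 0.1
MM_PER_CM = 10.0


@dataclass(frozen=True)
class DynalogDialect:
    """Describes the on-disk text encoding of a dynalog bank file.

    Parameters
    ----------
    name : str
        Dialect identifier (used by the CLI ``--dialect`` option).
    delimiter : str
        Column separator.
    position_units_per_cm : int or None
        If set, positions and jaws are stored as integers in units of
        ``1/position_units_per_cm`` cm (1000 = hundredths of a millimetre).
        ``None`` stores plain floats in cm.
    gantry_units_per_deg : int or None
        Integer gantry scaling (10 = tenths of a degree), or ``None``
        for float degrees.
    dose_full_scale : int or None
        Integer full-scale value of the cumulative dose counter
        (25000 on Clinac logs), or ``None`` for a float fraction in [0, 1].
    """

    name: str
    delimiter: str = ","
    position_units_per_cm: int | None = 1000
    gantry_units_per_deg: int | None = 10
    dose_full_scale: int | None = 25000

    # ---- scalar codecs ------------------------------------------------
    def encode_position(self, cm: float) -> str:
        if self.position_units_per_cm is None:
            return repr(float(cm))
        return str(int(round(cm * self.position_units_per_cm)))

    def decode_position(self, raw: str) -> float:
        if self.position_units_per_cm is None:
            return float(raw)
        return int(raw) / self.position_units_per_cm

    def encode_gantry(self, deg: float) -> str:
        if self.gantry_units_per_deg is None:
            return repr(float(deg))
        return str(int(round(deg * self.gantry_units_per_deg)))

    def decode_gantry(self, raw: str) -> float:
        if self.gantry_units_per_deg is None:
            return float(raw)
        return int(raw) / self.gantry_units_per_deg

    def encode_dose(self, fraction: float) -> str:
        if self.dose_full_scale is None:
            return repr(float(fraction))
        return str(int(round(fraction * self.dose_full_scale)))

    def decode_dose(self, raw: str) -> float:
        if self.dose_full_scale is None:
            return float(raw)
        return int(raw) / self.dose_full_scale

    # ---- quantisation -------------------------------------------------
    def quantize_position(self, cm: np.ndarray | float):
        """Snap positions to the nearest representable file value."""
        if self.position_units_per_cm is None:
            return cm
        u = self.position_units_per_cm
        return np.round(np.asarray(cm, dtype=float) * u) / u

    def quantize_gantry(self, deg: float) -> float:
        if self.gantry_units_per_deg is None:
            return deg
        u = self.gantry_units_per_deg
        return round(deg * u) / u

    def quantize_dose(self, fraction: float) -> float:
        if self.dose_full_scale is None:
            return fraction
        u = self.dose_full_scale
        return round(fraction * u) / u


CLINAC_DIALECT = DynalogDialect(name="clinac")
NATIVE_DIALECT = DynalogDialect(
    name="native",
    position_units_per_cm=None,
    gantry_units_per_deg=None,
    dose_full_scale=None,
)

DIALECTS = {d.name: d for d in (CLINAC_DIALECT, NATIVE_DIALECT)}


@dataclass
class DynalogRecord:
    """One controller tick: machine state plus one bank-or-field of leaves."""

    time_ms: int
    beam_on: bool
    beam_hold: bool
    segment: int
    gantry_deg: float
    jaws_cm: np.ndarray          # (4,): x-neg, x-pos, y-neg, y-pos openings
    dose_fraction: float
    expected_cm: np.ndarray      # (n_leaves,)
    actual_cm: np.ndarray        # (n_leaves,)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DynalogRecord):
            return NotImplemented
        return (
            self.time_ms == other.time_ms
            and self.beam_on == other.beam_on
            and self.beam_hold == other.beam_hold
            and self.segment == other.segment
            and self.gantry_deg == other.gantry_deg
            and np.array_equal(self.jaws_cm, other.jaws_cm)
            and self.dose_fraction == other.dose_fraction
            and np.array_equal(self.expected_cm, other.expected_cm)
            and np.array_equal(self.actual_cm, other.actual_cm)
        )


@dataclass
class DynalogBankFile:
    """A parsed single-carriage dynalog file (bank A or B)."""

    bank_id: str                      # "A" or "B"
    linac_type: str = "Clinac"        # "Clinac" (50 ms) or "TrueBeam" (20 ms)
    header: dict = field(default_factory=dict)
    records: list[DynalogRecord] = field(default_factory=list)

    @property
    def tick_ms(self) -> int:
        return TICK_MS[self.linac_type]

    @property
    def leaf_count(self) -> int:
        return len(self.records[0].expected_cm) if self.records else 0

    def validate(self) -> None:
        if self.bank_id not in ("A", "B"):
            raise DynalogStructureError(f"bank_id must be A or B, got {self.bank_id!r}")
        if self.linac_type not in TICK_MS:
            raise DynalogStructureError(f"unknown linac type {self.linac_type!r}")
        if len(self.records) < 2:
            raise DynalogStructureError(
                f"bank needs at least 2 records, got {len(self.records)}"
            )
        n = self.leaf_count
        for i, r in enumerate(self.records):
            if len(r.expected_cm) != n or len(r.actual_cm) != n:
                raise DynalogStructureError(
                    f"record {i}: leaf count differs from first record ({n})"
                )

    def quantized(self, dialect: DynalogDialect) -> "DynalogBankFile":
        """Copy with every value snapped to the dialect's file resolution."""
        recs = [
            replace(
                r,
                gantry_deg=dialect.quantize_gantry(r.gantry_deg),
                jaws_cm=np.asarray(dialect.quantize_position(r.jaws_cm)),
                dose_fraction=dialect.quantize_dose(r.dose_fraction),
                expected_cm=np.asarray(dialect.quantize_position(r.expected_cm)),
                actual_cm=np.asarray(dialect.quantize_position(r.actual_cm)),
            )
            for r in self.records
        ]
        return DynalogBankFile(self.bank_id, self.linac_type, dict(self.header), recs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DynalogBankFile):
            return NotImplemented
        return (
            self.bank_id == other.bank_id
            and self.linac_type == other.linac_type
            and self.header == other.header
            and self.records == other.records
        )


@dataclass
class DynalogField:
    """Merged A+B record stream for one treatment field.

    ``records[i].expected_cm`` holds bank A's leaves followed by bank B's
    (e.g. 60+60 for a Millennium 120).
    """

    records: list[DynalogRecord]
    leaf_count_per_bank: int
    tick_ms: int = 50

    # cached stacked views
    def _stack(self, attr: str) -> np.ndarray:
        return np.stack([getattr(r, attr) for r in self.records])

    @property
    def expected(self) -> np.ndarray:
        """(n_records, 2*leaf_count_per_bank) expected positions, cm."""
        return self._stack("expected_cm")

    @property
    def actual(self) -> np.ndarray:
        return self._stack("actual_cm")

    @property
    def time_ms(self) -> np.ndarray:
        return np.array([r.time_ms for r in self.records])

    @property
    def segment(self) -> np.ndarray:
        return np.array([r.segment for r in self.records])

    @property
    def dose_fraction(self) -> np.ndarray:
        return np.array([r.dose_fraction for r in self.records])

    @property
    def beam_on(self) -> np.ndarray:
        return np.array([r.beam_on for r in self.records])

    @property
    def beam_hold(self) -> np.ndarray:
        return np.array([r.beam_hold for r in self.records])

    @property
    def gantry_deg(self) -> np.ndarray:
        return np.array([r.gantry_deg for r in self.records])

    @property
    def jaws_cm(self) -> np.ndarray:
        return self._stack("jaws_cm")

    def split_banks(self) -> tuple["DynalogBankFile", "DynalogBankFile"]:
        """Inverse of :func:`merge_banks` (header metadata is not recovered)."""
        linac = {v: k for k, v in TICK_MS.items()}[self.tick_ms]
        n = self.leaf_count_per_bank
        banks = []
        for bank_id, sl in (("A", slice(0, n)), ("B", slice(n, 2 * n))):
            recs = [
                replace(r, expected_cm=r.expected_cm[sl].copy(),
                        actual_cm=r.actual_cm[sl].copy())
                for r in self.records
            ]
            banks.append(DynalogBankFile(bank_id, linac, {}, recs))
        return banks[0], banks[1]


# ----------------------------------------------------------------------
# file I/O
# ----------------------------------------------------------------------

_HEADER_SENTINEL = "records"


def parse_bank_file(path, dialect: DynalogDialect = CLINAC_DIALECT) -> DynalogBankFile:
    """Parse one dynalog bank file.

    The file is a header of ``key<delim>value`` lines terminated by a line
    reading ``records``, followed by one record per line::

        time_ms, beam_on, beam_hold, segment, gantry, jaw_xn, jaw_xp,
        jaw_yn, jaw_yp, dose, expected[0..n-1], actual[0..n-1]

    Positions are converted to cm at isocenter, the gantry to degrees and
    the dose counter to a fraction of full scale, per the dialect.
    A time gap larger than the declared tick is preserved and logged as a
    warning (it usually signals a dropped record).
    """
    path = Path(path)
    header: dict[str, str] = {}
    records: list[DynalogRecord] = []
    bank_id = None
    linac_type = "Clinac"
    n_leaves = None
    in_records = False

    with open(path, "r") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line or line.startswith("#"):
                continue
            if not in_records:
                if line == _HEADER_SENTINEL:
                    in_records = True
                    continue
                if dialect.delimiter not in line:
                    raise DynalogParseError(
                        f"expected 'key{dialect.delimiter}value' header line, got {line!r}",
                        lineno,
                    )
                key, _, value = line.partition(dialect.delimiter)
                key = key.strip()
                value = value.strip()
                if key == "bank":
                    bank_id = value
                elif key == "linac":
                    linac_type = value
                elif key == "leaves":
                    n_leaves = int(value)
                else:
                    header[key] = value
                continue

            parts = line.split(dialect.delimiter)
            if n_leaves is None:
                raise DynalogParseError("header lacks a 'leaves' count", lineno)
            want = 10 + 2 * n_leaves
            if len(parts) != want:
                raise DynalogParseError(
                    f"expected {want} fields for {n_leaves} leaves, got {len(parts)}",
                    lineno,
                )
            try:
                time_ms = int(parts[0])
                beam_on = bool(int(parts[1]))
                beam_hold = bool(int(parts[2]))
                segment = int(parts[3])
                gantry = dialect.decode_gantry(parts[4])
                jaws = np.array([dialect.decode_position(p) for p in parts[5:9]])
                dose = dialect.decode_dose(parts[9])
                expected = np.array(
                    [dialect.decode_position(p) for p in parts[10:10 + n_leaves]]
                )
                actual = np.array(
                    [dialect.decode_position(p) for p in parts[10 + n_leaves:]]
                )
            except ValueError as exc:
                raise DynalogParseError(str(exc), lineno) from exc
            records.append(
                DynalogRecord(time_ms, beam_on, beam_hold, segment, gantry,
                              jaws, dose, expected, actual)
            )

    if bank_id is None:
        raise DynalogParseError(f"{path}: header lacks a 'bank' line")
    bank = DynalogBankFile(bank_id, linac_type, header, records)
    bank.validate()

    tick = bank.tick_ms
    times = np.array([r.time_ms for r in records])
    gaps = np.diff(times)
    if np.any(gaps != tick):
        bad = int(np.argmax(gaps != tick))
        logger.warning(
            "%s: record spacing %d ms (expected %d ms) after record %d; "
            "gap preserved", path.name, int(gaps[bad]), tick, bad
        )
    return bank


def write_bank_file(bank: DynalogBankFile, path,
                    dialect: DynalogDialect = CLINAC_DIALECT) -> None:
    """Write a bank file; ``parse_bank_file`` of the result re-creates the bank.

    The round trip is exact provided every value is representable at the
    dialect's file resolution (see :meth:`DynalogBankFile.quantized`);
    the float ``native`` dialect round-trips any value. Two writes of the
    same bank are byte-identical.
    """
    bank.validate()
    d = dialect.delimiter
    lines = [
        f"# dynaverify dynalog bank file ({dialect.name} dialect)",
        f"bank{d}{bank.bank_id}",
        f"linac{d}{bank.linac_type}",
        f"leaves{d}{bank.leaf_count}",
    ]
    for key in sorted(bank.header):
        lines.append(f"{key}{d}{bank.header[key]}")
    lines.append(_HEADER_SENTINEL)
    for r in bank.records:
        parts = [
            str(r.time_ms),
            str(int(r.beam_on)),
            str(int(r.beam_hold)),
            str(r.segment),
            dialect.encode_gantry(r.gantry_deg),
            *[dialect.encode_position(j) for j in r.jaws_cm],
            dialect.encode_dose(r.dose_fraction),
            *[dialect.encode_position(p) for p in r.expected_cm],
            *[dialect.encode_position(p) for p in r.actual_cm],
        ]
        lines.append(d.join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# merging and error statistics
# ----------------------------------------------------------------------

#: Agreement tolerances for the shared scalars of the two banks.
MERGE_TOL = {"gantry_deg": 0.2, "jaws_cm": 0.005, "dose_fraction": 1e-3}


def merge_banks(a: DynalogBankFile, b: DynalogBankFile) -> DynalogField:
    """Merge the A and B carriage files of one field into a single stream.

    Shared scalars (gantry, segment, dose fraction, jaws, flags) are taken
    from bank A after checking that bank B agrees within tolerance.
    """
    if a.bank_id != "A" or b.bank_id != "B":
        raise MergeError(f"expected banks A and B, got {a.bank_id!r}/{b.bank_id!r}")
    if a.linac_type != b.linac_type:
        raise MergeError("banks disagree on linac type")
    if len(a.records) != len(b.records):
        raise MergeError(
            f"record count mismatch: bank A has {len(a.records)}, bank B has "
            f"{len(b.records)} (truncated acquisition?)"
        )
    a.validate()
    b.validate()
    if a.leaf_count != b.leaf_count:
        raise MergeError("banks disagree on leaf count")

    merged = []
    for i, (ra, rb) in enumerate(zip(a.records, b.records)):
        if ra.time_ms != rb.time_ms:
            raise ConsistencyError(f"record {i}: time stamps differ")
        if ra.segment != rb.segment:
            raise ConsistencyError(f"record {i}: segment numbers differ")
        if abs(ra.gantry_deg - rb.gantry_deg) > MERGE_TOL["gantry_deg"]:
            raise ConsistencyError(f"record {i}: gantry angles differ")
        if abs(ra.dose_fraction - rb.dose_fraction) > MERGE_TOL["dose_fraction"]:
            raise ConsistencyError(f"record {i}: dose fractions differ")
        if np.max(np.abs(ra.jaws_cm - rb.jaws_cm)) > MERGE_TOL["jaws_cm"]:
            raise ConsistencyError(f"record {i}: jaw positions differ")
        merged.append(
            DynalogRecord(
                ra.time_ms, ra.beam_on, ra.beam_hold, ra.segment, ra.gantry_deg,
                ra.jaws_cm.copy(), ra.dose_fraction,
                np.concatenate([ra.expected_cm, rb.expected_cm]),
                np.concatenate([ra.actual_cm, rb.actual_cm]),
            )
        )
    return DynalogField(merged, a.leaf_count, a.tick_ms)


def leaf_errors(field: DynalogField) -> np.ndarray:
    """Per-record, per-leaf position error, cm: eps = expected - actual."""
    return field.expected - field.actual


def _eligible(field: DynalogField, beam_on_only: bool) -> np.ndarray:
    if not beam_on_only:
        return np.ones(len(field.records), dtype=bool)
    return field.beam_on & ~field.beam_hold


def rms_error(field: DynalogField, beam_on_only: bool = False) -> float:
    """Root-mean-square of all leaf-position errors, millimetres.

    The mean runs over every leaf-position pair of every selected record
    (all records by default; with ``beam_on_only`` only records with beam
    on and no hold-off contribute).
    """
    sel = _eligible(field, beam_on_only)
    if not np.any(sel):
        raise DynalogStructureError("no eligible records for RMS")
    eps_mm = leaf_errors(field)[sel] * MM_PER_CM
    return float(np.sqrt(np.mean(eps_mm ** 2)))


def max_leaf_error(field: DynalogField) -> float:
    """Maximum absolute leaf-position error (MLE) over the field, mm."""
    eps = leaf_errors(field)
    return float(np.max(np.abs(eps)) * MM_PER_CM)
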