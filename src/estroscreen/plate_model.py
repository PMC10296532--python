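"""Data model and CSV I/O for 384-well screening plates.

A screen is organised around three objects: a :class:`PlateLayout` mapping
each well of a 384-well plate to its role (library compound, DMSO vehicle
control, media control, QC compound, or empty), a :class:`RawPlate` holding
the per-well nuclei counts measured by high-content imaging for one plate
under one condition (vehicle or estrogen), and a :class:`ScreenDataset`
pairing the vehicle- and estrogen-condition plates that share a layout.

Wells are addressed the way plate vendors print them: row letters A–P and
1-based column numbers 1–24 ("A1" .. "P24"). Columns 1–22 carry library
compounds; columns 23–24 are reserved for controls (8 DMSO wells, 4 media
wells, and 4 wells per QC compound).

The interchange format is long-form CSV, one row per well; plate-matrix
layouts are deliberately not supported to avoid row/column orientation
ambiguity.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import pandas as pd

ROWS = "ABCDEFGHIJKLMNOP"
N_COLUMNS = 24
N_WELLS = len(ROWS) * N_COLUMNS  # 384
CONTROL_COLUMNS = (23, 24)

#: Conditions a plate can be run under: the whole plate receives either
#: vehicle (0.3% DMSO) or estrogen (10 µM estradiol-17β) medium.
CONDITIONS = ("vehicle", "estrogen")

_ADDRESS_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


class PlateModelError(ValueError):
    """Malformed address, layout, or count table."""


class WellAddress(NamedTuple):
    """A well position: row letter A–P, 1-based column 1–24."""

    row: str
    column: int

    def __str__(self) -> str:
        return f"{self.row}{self.column}"

    @property
    def in_control_columns(self) -> bool:
        return self.column in CONTROL_COLUMNS


def parse_well_address(text: str) -> WellAddress:
    """Parse a printed well address like ``"A1"`` or ``"P24"``.

    Raises :class:`PlateModelError` naming the offending token for anything
    outside the 16 x 24 grid.
    """
    if not isinstance(text, str) or not text.strip():
        raise PlateModelError(f"empty or non-text well address: {text!r}")
    token = text.strip()
    m = _ADDRESS_RE.match(token)
    if m is None:
        raise PlateModelError(f"malformed well address {token!r}")
    row = m.group(1).upper()
    column = int(m.group(2))
    if row not in ROWS:
        raise PlateModelError(f"row {row!r} out of range A-P in address {token!r}")
    if not 1 <= column <= N_COLUMNS:
        raise PlateModelError(
            f"column {column} out of range 1-{N_COLUMNS} in address {token!r}"
        )
    return WellAddress(row, column)


def all_well_addresses() -> list[WellAddress]:
    """The 384 addresses in row-major order (A1..A24, B1..)."""
    return [WellAddress(r, c) for r in ROWS for c in range(1, N_COLUMNS + 1)]


class WellRole(str, enum.Enum):
    """What a well holds. Control roles occur only in columns 23-24."""

    LIBRARY = "library_compound"
    VEHICLE = "vehicle_control"
    MEDIA = "media_control"
    QC_POSITIVE = "qc_positive"
    QC_NEGATIVE = "qc_negative"
    EMPTY = "empty"


#: Roles that must sit in the reserved control columns of a library plate.
CONTROL_ROLES = frozenset(
    {WellRole.VEHICLE, WellRole.MEDIA, WellRole.QC_POSITIVE, WellRole.QC_NEGATIVE}
)


class WellEntry(NamedTuple):
    role: WellRole
    compound_id: Optional[str]
    concentration_uM: Optional[float]


@dataclass
class PlateLayout:
    """Role/compound/concentration map of one 384-well plate.

    ``wells`` always contains exactly 384 entries; addresses not given at
    construction default to empty wells.
    """

    plate_id: str
    wells: dict[WellAddress, WellEntry]

    def __post_init__(self) -> None:
        full: dict[WellAddress, WellEntry] = {
            addr: WellEntry(WellRole.EMPTY, None, None) for addr in all_well_addresses()
        }
        for addr, entry in self.wells.items():
            if not isinstance(addr, WellAddress):
                addr = parse_well_address(str(addr))
            full[addr] = entry
        if len(full) != N_WELLS:
            raise PlateModelError(
                f"layout {self.plate_id!r} has {len(full)} wells, expected {N_WELLS}"
            )
        self.wells = full
        self._validate()

    def _validate(self) -> None:
        for addr, entry in self.wells.items():
            if entry.role is WellRole.LIBRARY:
                if not entry.compound_id:
                    raise PlateModelError(
                        f"{self.plate_id}:{addr}: library well without compound_id"
                    )
                if entry.concentration_uM is None or entry.concentration_uM <= 0:
                    raise PlateModelError(
                        f"{self.plate_id}:{addr}: library well needs a positive "
                        f"concentration, got {entry.concentration_uM!r}"
                    )
            if entry.role in CONTROL_ROLES and not addr.in_control_columns:
                raise PlateModelError(
                    f"{self.plate_id}:{addr}: control role {entry.role.value!r} "
                    f"outside reserved columns {CONTROL_COLUMNS}"
                )

    def wells_with_role(self, role: WellRole) -> list[WellAddress]:
        return [a for a, e in self.wells.items() if e.role is role]

    def role_counts(self) -> dict[WellRole, int]:
        counts = {role: 0 for role in WellRole}
        for entry in self.wells.values():
            counts[entry.role] += 1
        return counts

    def qc_compounds(self) -> dict[str, WellRole]:
        """Declared QC compounds and whether each is positive or negative."""
        out: dict[str, WellRole] = {}
        for entry in self.wells.values():
            if entry.role in (WellRole.QC_POSITIVE, WellRole.QC_NEGATIVE):
                out[entry.compound_id or entry.role.value] = entry.role
        return out

    def compound_wells(self) -> dict[WellAddress, str]:
        """Library wells mapped to their compound ids."""
        return {
            a: e.compound_id  # type: ignore[misc]
            for a, e in self.wells.items()
            if e.role is WellRole.LIBRARY
        }

    def non_empty_wells(self) -> list[WellAddress]:
        return [a for a, e in self.wells.items() if e.role is not WellRole.EMPTY]


@dataclass
class RawPlate:
    """Per-well nuclei counts for one plate, cell line, and condition.

    ``flags`` records image-QC failure tokens per well (an open set, e.g.
    ``acquisition_error``, ``artefact``, ``low_control``); flagged wells are
    excluded from every downstream computation.
    """

    plate_id: str
    cell_line_id: str
    condition: str
    counts: dict[WellAddress, int]
    flags: dict[WellAddress, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise PlateModelError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        for addr, count in self.counts.items():
            if count < 0:
                raise PlateModelError(
                    f"{self.plate_id}:{addr}: negative count {count}"
                )
        self.flags = {a: frozenset(f) for a, f in self.flags.items() if f}

    def flagged_wells(self) -> set[WellAddress]:
        return set(self.flags)

    def unflagged_counts(self) -> dict[WellAddress, int]:
        return {a: c for a, c in self.counts.items() if a not in self.flags}

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.plate_id, self.cell_line_id, self.condition)


@dataclass
class ScreenDataset:
    """Layouts, raw plates, and vehicle/estrogen pairings of a screen.

    ``pairing`` maps (layout plate id, cell line id) to the matched
    (vehicle-condition, estrogen-condition) RawPlate pair sharing that
    layout. ``truth`` optionally carries the synthetic generator's ledger
    of programmed per-compound effects for parameter-recovery tests.
    """

    layouts: dict[str, PlateLayout]
    plates: list[RawPlate]
    pairing: dict[tuple[str, str], tuple[RawPlate, RawPlate]]
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for (layout_id, line), (veh, est) in self.pairing.items():
            if layout_id not in self.layouts:
                raise PlateModelError(f"pairing references unknown layout {layout_id!r}")
            if veh.condition == est.condition:
                raise PlateModelError(
                    f"pairing for ({layout_id}, {line}) has two "
                    f"{veh.condition!r}-condition plates"
                )
            if {veh.condition, est.condition} != set(CONDITIONS):
                raise PlateModelError("pair must hold one vehicle and one estrogen plate")


# ---------------------------------------------------------------------------
# CSV I/O — long format, one row per well.
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = ["well", "role", "compound_id", "concentration_uM"]
COUNT_COLUMNS = ["plate_id", "cell_line", "condition", "well", "count", "flags"]


def read_plate_layout(path, plate_id: Optional[str] = None) -> PlateLayout:
    """Read a layout CSV (columns well, role, compound_id, concentration_uM).

    Missing wells default to empty. Duplicate wells, unknown role tokens,
    and control roles outside columns 23-24 raise :class:`PlateModelError`.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise PlateModelError(f"layout file missing columns {missing}")
    wells: dict[WellAddress, WellEntry] = {}
    for i, rec in enumerate(df.itertuples(index=False)):
        addr = parse_well_address(rec.well)
        if addr in wells:
            raise PlateModelError(f"duplicate well {addr} at row {i + 2}")
        try:
            role = WellRole(rec.role)
        except ValueError:
            raise PlateModelError(
                f"unknown role token {rec.role!r} at row {i + 2}"
            ) from None
        compound = None if pd.isna(rec.compound_id) or rec.compound_id == "" else str(rec.compound_id)
        conc = None if pd.isna(rec.concentration_uM) or rec.concentration_uM == "" else float(rec.concentration_uM)
        wells[addr] = WellEntry(role, compound, conc)
    return PlateLayout(plate_id=plate_id or "layout", wells=wells)


def write_plate_layout(layout: PlateLayout, path) -> None:
    rows = []
    for addr in all_well_addresses():
        entry = layout.wells[addr]
        if entry.role is WellRole.EMPTY:
            continue
        rows.append(
            {
                "well": str(addr),
                "role": entry.role.value,
                "compound_id": entry.compound_id or "",
                "concentration_uM": "" if entry.concentration_uM is None else entry.concentration_uM,
            }
        )
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, index=False)


def read_count_table(path) -> list[RawPlate]:
    """Read a counts CSV into one :class:`RawPlate` per (plate, line, condition).

    Flags are parsed as a semicolon-separated token set. Negative counts,
    unknown condition tokens, and wells repeated within a plate raise
    :class:`PlateModelError` with the offending row number.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise PlateModelError(f"count table missing columns {missing}")
    grouped: dict[tuple[str, str, str], dict] = {}
    for i, rec in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # 1-based plus header
        condition = str(rec.condition)
        if condition not in CONDITIONS:
            raise PlateModelError(f"row {rownum}: unknown condition {condition!r}")
        addr = parse_well_address(rec.well)
        count = float(rec.count)
        if count < 0:
            raise PlateModelError(f"row {rownum}: negative count {count}")
        key = (str(rec.plate_id), str(rec.cell_line), condition)
        bucket = grouped.setdefault(key, {"counts": {}, "flags": {}})
        if addr in bucket["counts"]:
            raise PlateModelError(
                f"row {rownum}: well {addr} repeated within plate {key[0]!r}"
            )
        bucket["counts"][addr] = int(round(count))
        if not pd.isna(rec.flags) and str(rec.flags).strip():
            tokens = frozenset(t.strip() for t in str(rec.flags).split(";") if t.strip())
            if tokens:
                bucket["flags"][addr] = tokens
    return [
        RawPlate(plate_id=pid, cell_line_id=line, condition=cond,
                 counts=b["counts"], flags=b["flags"])
        for (pid, line, cond), b in grouped.items()
    ]


def write_count_table(plates: Iterable[RawPlate], path) -> None:
    rows = []
    for plate in plates:
        for addr in sorted(plate.counts, key=lambda a: (a.row, a.column)):
            rows.append(
                {
                    "plate_id": plate.plate_id,
                    "cell_line": plate.cell_line_id,
                    "condition": plate.condition,
                    "well": str(addr),
                    "count": plate.counts[addr],
                    "flags": ";".join(sorted(plate.flags.get(addr, ()))),
                }
            )
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Control-layout validation
# ---------------------------------------------------------------------------

#: Canonical control complement per library plate: 8 DMSO vehicle wells,
#: 4 media wells, and 4 wells per declared QC compound, all in columns 23-24.
EXPECTED_VEHICLE_WELLS = 8
EXPECTED_MEDIA_WELLS = 4
EXPECTED_WELLS_PER_QC = 4


@dataclass
class ControlLayoutReport:
    plate_id: str
    n_vehicle: int
    n_media: int
    qc_well_counts: dict[str, int]
    problems: list[str]

    @property
    def passed(self) -> bool:
        return not self.problems


def validate_control_layout(layout: PlateLayout) -> ControlLayoutReport:
    """Check a layout carries the canonical control complement.

    Report-only: never raises. Pass requires 8 DMSO, 4 media, and 4 wells
    for each declared QC compound, with at least one QC compound present.
    """
    n_vehicle = len(layout.wells_with_role(WellRole.VEHICLE))
    n_media = len(layout.wells_with_role(WellRole.MEDIA))
    qc_counts: dict[str, int] = {}
    for entry in layout.wells.values():
        if entry.role in (WellRole.QC_POSITIVE, WellRole.QC_NEGATIVE):
            name = entry.compound_id or entry.role.value
            qc_counts[name] = qc_counts.get(name, 0) + 1
    problems: list[str] = []
    if n_vehicle != EXPECTED_VEHICLE_WELLS:
        problems.append(
            f"expected {EXPECTED_VEHICLE_WELLS} DMSO vehicle wells, found {n_vehicle}"
        )
    if n_media != EXPECTED_MEDIA_WELLS:
        problems.append(f"expected {EXPECTED_MEDIA_WELLS} media wells, found {n_media}")
    if not qc_counts:
        problems.append("no QC compounds declared")
    for name, n in sorted(qc_counts.items()):
        if n != EXPECTED_WELLS_PER_QC:
            problems.append(
                f"QC compound {name!r}: expected {EXPECTED_WELLS_PER_QC} wells, found {n}"
            )
    return ControlLayoutReport(
        plate_id=layout.plate_id,
        n_vehicle=n_vehicle,
        n_media=n_media,
        qc_well_counts=qc_counts,
        problems=problems,
    )
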