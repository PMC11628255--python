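"""Data model and I/O for 384-well plates, platemaps and assay configurations.

A plate-reader export is modelled as a 16x24 grid of raw luminescence counts
(rows A-P, columns 1-24).  A platemap assigns each well a role — negative
control (vehicle only, maximal signal), positive control (reference
inhibitor, minimal signal), sample, or empty — plus compound identity and
concentration for sample wells.  Concentrations are stored in µM everywhere
downstream; mM/nM/M inputs are converted on parse.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    DuplicateWell,
    MalformedPlate,
    MissingConcentration,
    UnknownRole,
)

logger = logging.getLogger(__name__)

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
N_WELLS = len(ROWS) * N_COLS

ROLES = ("negative_control", "positive_control", "sample", "empty")

#: multiplicative factors to canonical µM
_UNIT_TO_UM = {
    "nm": 1e-3,
    "um": 1.0,
    "µm": 1.0,
    "μm": 1.0,  # greek mu, as pasted from documents
    "mm": 1e3,
    "m": 1e6,
}


@dataclass(frozen=True, order=True)
class WellAddress:
    """Position on a 384-well plate: row letter A-P, column 1-24."""

    row: str
    col: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise MalformedPlate(f"row {self.row!r} outside A-P")
        if not 1 <= self.col <= N_COLS:
            raise MalformedPlate(f"column {self.col} outside 1-{N_COLS}")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        """Parse 'B7' or 'B07' (case-insensitive) into an address."""
        s = text.strip().upper()
        if len(s) < 2 or not s[1:].isdigit():
            raise MalformedPlate(f"cannot parse well address {text!r}")
        return cls(row=s[0], col=int(s[1:]))

    def __str__(self) -> str:
        return f"{self.row}{self.col:02d}"


def all_addresses() -> list[WellAddress]:
    """All 384 addresses in row-major (A01..A24, B01..) order."""
    return [WellAddress(r, c) for r in ROWS for c in range(1, N_COLS + 1)]


@dataclass
class Plate:
    """One raw luminescence readout: 384 wells of non-negative counts."""

    plate_id: str
    wells: dict[WellAddress, float]
    assay_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.wells) != N_WELLS:
            raise MalformedPlate(
                f"plate {self.plate_id}: {len(self.wells)} wells, expected {N_WELLS}"
            )
        for addr, value in self.wells.items():
            if not math.isfinite(value) or value < 0:
                raise MalformedPlate(
                    f"plate {self.plate_id}: well {addr} has invalid value {value!r}"
                )

    def __getitem__(self, key: WellAddress | str) -> float:
        if isinstance(key, str):
            key = WellAddress.parse(key)
        return self.wells[key]


@dataclass(frozen=True)
class WellRole:
    """Annotation for one well: role kind plus compound/concentration."""

    kind: str
    compound_id: str = ""
    concentration_um: float | None = None
    replicate_group: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ROLES:
            raise UnknownRole(f"unknown well role {self.kind!r}")
        if self.kind == "sample":
            if not self.compound_id:
                raise MissingConcentration("sample well lacks compound_id")
            if self.concentration_um is None:
                raise MissingConcentration(
                    f"sample well for {self.compound_id!r} lacks concentration"
                )
            if self.concentration_um < 0:
                raise MissingConcentration("negative concentration")


@dataclass
class PlateMap:
    """Well → role mapping for one plate layout."""

    entries: dict[WellAddress, WellRole]

    def wells_with_kind(self, kind: str) -> list[WellAddress]:
        return sorted(a for a, r in self.entries.items() if r.kind == kind)


@dataclass
class AssayConfig:
    """Assay conditions: enzyme/buffer pair, positive control, QC gates.

    ``zprime_threshold`` is the minimal acceptable Z' factor (0.5 is the
    conventional floor for biochemical assays); ``max_outliers`` caps how many
    control wells the automatic outlier removal may discard before a plate is
    sent to retest.
    """

    luciferase: str = "FLuc"
    buffer: str = "SC"
    positive_control_name: str = "PTC-124"
    positive_control_um: float = 1.0
    dmso_fraction_pct: float = 0.04
    zprime_threshold: float = 0.5
    max_outliers: int = 2

    def __post_init__(self) -> None:
        if self.luciferase not in ("FLuc", "NLuc", "RLuc"):
            raise ValueError(f"unknown luciferase {self.luciferase!r}")
        if self.buffer not in ("SC", "H"):
            raise ValueError(f"unknown buffer system {self.buffer!r}")
        if not 0 < self.zprime_threshold <= 1:
            raise ValueError("zprime_threshold must lie in (0, 1]")
        if self.max_outliers < 0:
            raise ValueError("max_outliers must be >= 0")

    @property
    def assay_id(self) -> str:
        return f"{self.luciferase}_{self.buffer}"


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def parse_plate_matrix(text: str, plate_id: str, assay_id: str = "") -> Plate:
    """Parse a 16x24 matrix export (rows A-P, header 1-24, comma or tab).

    The first header cell (above the row labels) may be blank or carry any
    label.  Raises :class:`MalformedPlate` on wrong dimensions, duplicate row
    labels or non-numeric cells.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) != len(ROWS) + 1:
        raise MalformedPlate(
            f"plate {plate_id}: expected {len(ROWS) + 1} lines (header + 16 rows), "
            f"got {len(lines)}"
        )
    delim = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    expected = [str(i) for i in range(1, N_COLS + 1)]
    if header[1:] != expected:
        raise MalformedPlate(f"plate {plate_id}: header is not 1..{N_COLS}")

    wells: dict[WellAddress, float] = {}
    seen_rows: set[str] = set()
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(delim)]
        label = cells[0].upper()
        if label in seen_rows:
            raise MalformedPlate(f"plate {plate_id}: duplicate row label {label!r}")
        if label not in ROWS:
            raise MalformedPlate(f"plate {plate_id}: unexpected row label {label!r}")
        seen_rows.add(label)
        if len(cells) != N_COLS + 1:
            raise MalformedPlate(
                f"plate {plate_id}: row {label} has {len(cells) - 1} columns"
            )
        for col, cell in enumerate(cells[1:], start=1):
            try:
                value = float(cell)
            except ValueError as exc:
                raise MalformedPlate(
                    f"plate {plate_id}: non-numeric cell {cell!r} at {label}{col}"
                ) from exc
            wells[WellAddress(label, col)] = value
    return Plate(plate_id=plate_id, wells=wells, assay_id=assay_id)


def plate_to_matrix_text(plate: Plate, delimiter: str = "\t") -> str:
    """Serialize a plate back to the 16x24 matrix dialect."""
    out = [delimiter.join([""] + [str(i) for i in range(1, N_COLS + 1)])]
    for r in ROWS:
        row = [r] + [repr(plate.wells[WellAddress(r, c)]) for c in range(1, N_COLS + 1)]
        out.append(delimiter.join(row))
    return "\n".join(out) + "\n"


def parse_plate_long(text: str) -> list[Plate]:
    """Parse a long-format export: CSV with columns plate_id, well, raw_signal.

    Returns one :class:`Plate` per distinct plate_id (wells missing from the
    file are an error — a plate must be complete).
    """
    df = pd.read_csv(io.StringIO(text), float_precision="round_trip")
    required = {"plate_id", "well", "raw_signal"}
    if not required.issubset(df.columns):
        raise MalformedPlate(f"long format needs columns {sorted(required)}")
    plates = []
    for pid, grp in df.groupby("plate_id", sort=True):
        wells = {
            WellAddress.parse(w): float(v)
            for w, v in zip(grp["well"], grp["raw_signal"])
        }
        if len(wells) != len(grp):
            raise MalformedPlate(f"plate {pid}: duplicate well rows")
        plates.append(Plate(plate_id=str(pid), wells=wells))
    return plates


def convert_to_um(value: float, unit: str) -> float:
    """Convert a concentration in nM/µM/mM/M to canonical µM."""
    key = unit.strip().lower()
    if key not in _UNIT_TO_UM:
        raise MissingConcentration(f"unknown concentration unit {unit!r}")
    return value * _UNIT_TO_UM[key]


def parse_platemap(text: str) -> PlateMap:
    """Parse a platemap CSV (columns well, role, compound_id, concentration,
    conc_unit) into a :class:`PlateMap` with concentrations in µM."""
    reader = csv.DictReader(io.StringIO(text))
    required = {"well", "role", "compound_id", "concentration", "conc_unit"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise MalformedPlate(f"platemap needs columns {sorted(required)}")
    entries: dict[WellAddress, WellRole] = {}
    for row in reader:
        addr = WellAddress.parse(row["well"])
        if addr in entries:
            raise DuplicateWell(f"well {addr} listed twice in platemap")
        kind = row["role"].strip()
        conc_raw = (row["concentration"] or "").strip()
        conc_um: float | None = None
        if conc_raw:
            unit = (row["conc_unit"] or "uM").strip() or "uM"
            conc_um = convert_to_um(float(conc_raw), unit)
        elif kind == "sample":
            raise MissingConcentration(f"sample well {addr} has no concentration")
        entries[addr] = WellRole(
            kind=kind,
            compound_id=(row["compound_id"] or "").strip(),
            concentration_um=conc_um,
            replicate_group=(row.get("replicate_group") or "").strip(),
        )
    return PlateMap(entries=entries)


def platemap_to_csv(platemap: PlateMap) -> str:
    """Serialize a platemap to its CSV dialect (concentrations in µM)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["well", "role", "compound_id", "concentration", "conc_unit", "replicate_group"])
    for addr in sorted(platemap.entries):
        role = platemap.entries[addr]
        conc = "" if role.concentration_um is None else repr(role.concentration_um)
        unit = "" if role.concentration_um is None else "uM"
        writer.writerow([str(addr), role.kind, role.compound_id, conc, unit, role.replicate_group])
    return buf.getvalue()


def join_plate(plate: Plate, platemap: PlateMap) -> pd.DataFrame:
    """Match raw wells with their platemap annotation.

    Returns a tidy frame (plate_id, assay_id, well, role, compound_id,
    concentration_um, replicate_group, raw_signal) containing only mapped,
    non-empty wells.  Wells present on the plate but absent from the platemap
    are excluded with a logged warning, as are empty wells.
    """
    records = []
    unmapped = 0
    for addr in all_addresses():
        role = platemap.entries.get(addr)
        if role is None:
            unmapped += 1
            continue
        if role.kind == "empty":
            continue
        records.append(
            {
                "plate_id": plate.plate_id,
                "assay_id": plate.assay_id,
                "well": str(addr),
                "role": role.kind,
                "compound_id": role.compound_id,
                "concentration_um": role.concentration_um,
                "replicate_group": role.replicate_group,
                "raw_signal": plate.wells[addr],
            }
        )
    if unmapped:
        logger.warning(
            "plate %s: %d wells not covered by the platemap were excluded",
            plate.plate_id,
            unmapped,
        )
    if not records:
        logger.warning("plate %s: platemap maps no analysable wells", plate.plate_id)
        return pd.DataFrame(
            columns=[
                "plate_id", "assay_id", "well", "role", "compound_id",
                "concentration_um", "replicate_group", "raw_signal",
            ]
        )
    return pd.DataFrame.from_records(records)
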