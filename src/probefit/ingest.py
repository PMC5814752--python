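"""Parsing, validation and aggregation of raw bioactivity measurements.

Raw records are qualified ('=' or '>') activity values for a compound against
either a protein target (biochemical assay) or a cell line (cell assay).
Values are normalized to nM, converted to pActivity (-log10 of the molar
concentration) and aggregated per compound-target (or compound-cell-line)
pair into a median pActivity with its median absolute deviation.

Aggregation policy:

* the median runs over *all* measurements, '=' and '>' alike ('>' values are
  upper bounds on potency, so taking them at face value is conservative);
* a pair is *conflicting* when its '='-only median classifies it active
  (pActivity > 5) while at least one '>' record sits at >= 10,000 nM, an
  explicit claim of inactivity; conflicting pairs are inactive;
* the aggregated median is capped at pActivity 10 *after* aggregation, so
  the MAD reflects raw dispersion;
* a pair is *active* iff its capped median pActivity is strictly above 5 and
  it is not conflicting.
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ACTIVITY_PACTIVITY_CAP",
    "ACTIVITY_THRESHOLD_PACTIVITY",
    "CONFLICT_INACTIVE_NM",
    "UNIT_TO_NM",
    "AggregatedPairActivity",
    "ConfigError",
    "Measurement",
    "ParseResult",
    "RejectedRow",
    "TableDialect",
    "aggregate_pair",
    "compute_mad",
    "compute_pactivity",
    "parse_bioactivity_table",
    "read_sdf_structures",
    "read_smiles_file",
    "to_nanomolar",
    "write_aggregate_table",
]

#: Multiplicative factors taking a value in the given unit to nM.
UNIT_TO_NM: Mapping[str, float] = {
    "pM": 1e-3,
    "nM": 1.0,
    "uM": 1e3,
    "µM": 1e3,
    "μM": 1e3,
    "mM": 1e6,
    "M": 1e9,
}

#: Median pActivities above this value are capped to it after aggregation.
ACTIVITY_PACTIVITY_CAP = 10.0

#: A pair is active when its capped median pActivity strictly exceeds this.
ACTIVITY_THRESHOLD_PACTIVITY = 5.0

#: A '>' record at or above this concentration (nM) is an explicit claim of
#: inactivity and vetoes an otherwise-active '=' median.
CONFLICT_INACTIVE_NM = 10_000.0

BIOCHEMICAL = "biochemical"
CELL = "cell"

_QUALIFIERS = ("=", ">")


class ConfigError(ValueError):
    """Fatal configuration problem (e.g. a missing mandatory column)."""


@dataclass(frozen=True)
class Measurement:
    """One raw assay record linking a compound to a target or cell line."""

    compound_id: str
    target_accession: str
    assay_kind: str
    qualifier: str
    value: float
    units: str
    cell_line_id: str = ""
    activity_type: str = ""
    pubmed_id: str = ""
    smiles: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"activity value must be positive, got {self.value}")
        if self.units not in UNIT_TO_NM:
            raise ValueError(f"non-convertible units: {self.units!r}")
        if self.qualifier not in _QUALIFIERS:
            raise ValueError(f"unknown qualifier: {self.qualifier!r}")
        if self.assay_kind == CELL:
            if not self.cell_line_id:
                raise ValueError("cell assay record requires cell_line_id")
        elif self.assay_kind == BIOCHEMICAL:
            if not self.target_accession:
                raise ValueError("biochemical assay record requires target_accession")
        else:
            raise ValueError(f"unknown assay_kind: {self.assay_kind!r}")

    @property
    def value_nm(self) -> float:
        return to_nanomolar(self.value, self.units)

    @property
    def pactivity(self) -> float:
        return compute_pactivity(self.value_nm)

    @property
    def pair_key(self) -> tuple[str, str]:
        """(compound_id, target-or-cell-line) aggregation key."""
        second = self.target_accession if self.assay_kind == BIOCHEMICAL else self.cell_line_id
        return (self.compound_id, second)


@dataclass(frozen=True)
class AggregatedPairActivity:
    """Aggregated activity of one compound against one target or cell line."""

    compound_id: str
    target_accession: str
    median_pactivity: float
    mad: float
    n_measurements: int
    has_equal: bool
    has_greater: bool
    conflicting: bool
    active: bool

    def __post_init__(self) -> None:
        if self.median_pactivity > ACTIVITY_PACTIVITY_CAP:
            raise ValueError("median pActivity exceeds the cap")
        if self.conflicting and self.active:
            raise ValueError("conflicting pairs cannot be active")
        if self.mad < 0:
            raise ValueError("MAD must be non-negative")


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    reason: str


@dataclass
class ParseResult:
    """Outcome of parsing a bioactivity table: accepted records and rejects."""

    measurements: list[Measurement]
    rejects: list[RejectedRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.measurements)

    def __len__(self) -> int:
        return len(self.measurements)


@dataclass(frozen=True)
class TableDialect:
    """Delimiter and header-name mapping for a bioactivity table.

    ``columns`` maps logical field names (the :class:`Measurement` fields) to
    the header names used in the file; identity by default.
    """

    sep: str = "\t"
    columns: Mapping[str, str] = field(default_factory=dict)

    def header(self, logical: str) -> str:
        return self.columns.get(logical, logical)


_MANDATORY_FIELDS = ("compound_id", "assay_kind", "qualifier", "value", "units")
_OPTIONAL_FIELDS = ("target_accession", "cell_line_id", "activity_type", "pubmed_id", "smiles")


def to_nanomolar(value: float, units: str) -> float:
    """Convert an activity value to nM. Raises on unknown units."""
    try:
        factor = UNIT_TO_NM[units]
    except KeyError:
        raise ValueError(f"non-convertible units: {units!r}") from None
    if value <= 0:
        raise ValueError(f"activity value must be positive, got {value}")
    return value * factor


def compute_pactivity(conc_nm: float) -> float:
    """pActivity = -log10 of the concentration in molar units.

    Not capped here; capping is an aggregation-stage policy.
    """
    if conc_nm <= 0:
        raise ValueError(f"concentration must be positive, got {conc_nm}")
    return -math.log10(conc_nm * 1e-9)


def compute_mad(pactivities: Sequence[float]) -> float:
    """Median absolute deviation: median(|x_i - median(x)|)."""
    if len(pactivities) == 0:
        raise ValueError("MAD of an empty collection is undefined")
    center = statistics.median(pactivities)
    return statistics.median(abs(x - center) for x in pactivities)


def aggregate_pair(measurements: Sequence[Measurement]) -> AggregatedPairActivity:
    """Aggregate all measurements of one compound-target (or cell-line) pair."""
    if not measurements:
        raise ValueError("cannot aggregate an empty measurement collection")
    keys = {m.pair_key for m in measurements}
    if len(keys) != 1:
        raise ValueError(f"measurements span multiple compound-target pairs: {sorted(keys)}")
    compound_id, second_key = next(iter(keys))

    pacts = [m.pactivity for m in measurements]
    median = statistics.median(pacts)
    mad = compute_mad(pacts)

    eq = [m for m in measurements if m.qualifier == "="]
    gt = [m for m in measurements if m.qualifier == ">"]
    conflicting = False
    if eq and gt:
        eq_median = statistics.median(m.pactivity for m in eq)
        if eq_median > ACTIVITY_THRESHOLD_PACTIVITY and any(
            m.value_nm >= CONFLICT_INACTIVE_NM for m in gt
        ):
            conflicting = True

    capped = min(median, ACTIVITY_PACTIVITY_CAP)
    active = capped > ACTIVITY_THRESHOLD_PACTIVITY and not conflicting
    return AggregatedPairActivity(
        compound_id=compound_id,
        target_accession=second_key,
        median_pactivity=capped,
        mad=mad,
        n_measurements=len(measurements),
        has_equal=bool(eq),
        has_greater=bool(gt),
        conflicting=conflicting,
        active=active,
    )


def _parse_row(row: Mapping[str, str], dialect: TableDialect) -> Measurement:
    def get(logical: str, default: str = "") -> str:
        raw = row.get(dialect.header(logical), default)
        return (raw or default).strip()

    value_text = get("value")
    try:
        value = float(value_text)
    except ValueError:
        raise ValueError(f"unparseable value: {value_text!r}") from None
    return Measurement(
        compound_id=get("compound_id"),
        target_accession=get("target_accession"),
        assay_kind=get("assay_kind"),
        qualifier=get("qualifier"),
        value=value,
        units=get("units"),
        cell_line_id=get("cell_line_id"),
        activity_type=get("activity_type"),
        pubmed_id=get("pubmed_id"),
        smiles=get("smiles"),
    )


def parse_bioactivity_table(path: str | Path, dialect: TableDialect | None = None) -> ParseResult:
    """Parse a delimited bioactivity table into measurements plus a rejects list.

    Malformed rows are collected as :class:`RejectedRow` with a reason; they
    are never silently dropped. A missing mandatory column is fatal.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter=dialect.sep)
        header = reader.fieldnames or []
        missing = [f for f in _MANDATORY_FIELDS if dialect.header(f) not in header]
        if missing:
            raise ConfigError(
                f"missing mandatory column(s) {missing} in {path} (header: {header})"
            )
        measurements: list[Measurement] = []
        rejects: list[RejectedRow] = []
        for index, row in enumerate(reader):
            try:
                measurements.append(_parse_row(row, dialect))
            except ValueError as exc:
                rejects.append(RejectedRow(row_index=index, reason=str(exc)))
    return ParseResult(measurements=measurements, rejects=rejects)


def read_smiles_file(path: str | Path) -> dict[str, str]:
    """Read a ``.smi`` file (``SMILES<whitespace>compound_id`` per line)."""
    structures: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"malformed SMILES line: {line!r}")
        smiles, compound_id = parts
        structures[compound_id.strip()] = smiles
    return structures


def read_sdf_structures(path: str | Path) -> dict[str, str]:
    """Read an SDF file, mapping molecule title -> SMILES."""
    from rdkit import Chem

    structures: dict[str, str] = {}
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if name:
            structures[name] = Chem.MolToSmiles(mol)
    return structures


def attach_structures(
    measurements: Iterable[Measurement], structures: Mapping[str, str]
) -> dict[str, str]:
    """Collect compound -> SMILES from in-table columns plus an external map.

    The external map wins over in-table SMILES when both are present.
    """
    collected: dict[str, str] = {}
    for m in measurements:
        if m.smiles and m.compound_id not in collected:
            collected[m.compound_id] = m.smiles
    collected.update({k: v for k, v in structures.items() if v})
    return collected


def write_aggregate_table(pairs: Sequence[AggregatedPairActivity], path: str | Path) -> None:
    """Write the normalized aggregate table as TSV."""
    cols = [
        "compound_id",
        "target_accession",
        "median_pactivity",
        "mad",
        "n",
        "has_equal",
        "has_greater",
        "conflicting",
        "active",
    ]
    with Path(path).open("w") as out:
        out.write("\t".join(cols) + "\n")
        for p in pairs:
            out.write(
                "\t".join(
                    [
                        p.compound_id,
                        p.target_accession,
                        f"{p.median_pactivity:.6g}",
                        f"{p.mad:.6g}",
                        str(p.n_measurements),
                        str(int(p.has_equal)),
                        str(int(p.has_greater)),
                        str(int(p.conflicting)),
                        str(int(p.active)),
                    ]
                )
                + "\n"
            )
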