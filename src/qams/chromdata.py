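"""Core domain types and peak-table / configuration I/O.

A *peak table* is the ingestion boundary of the pipeline: one row per
integrated chromatographic peak, in a fixed CSV dialect (comma-separated,
UTF-8, ``.`` decimal separator, one header row).  Retention times are in
minutes, injection volumes in microlitres, injected masses in micrograms;
peak areas are arbitrary detector counts.

An absent ``injected_mass_ug`` cell means "unknown" (a real sample); a
``0`` means a blank injection — the two are distinct.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from qams.errors import ConfigError, FormatError, PanelError, RowParseError

__all__ = [
    "Component",
    "GradientStep",
    "ChromSystem",
    "PeakRecord",
    "PeakTable",
    "read_peak_table",
    "write_peak_table",
    "validate_panel",
    "internal_reference",
    "load_config",
    "save_config",
    "PEAK_TABLE_COLUMNS",
]

PEAK_TABLE_COLUMNS = (
    "sample_id",
    "system_id",
    "component_code",
    "retention_time_min",
    "area",
    "injection_volume_uL",
    "injected_mass_ug",
)


@dataclass(frozen=True)
class Component:
    """One analyte of the panel.

    The panel must contain exactly one component flagged as the internal
    reference: the single analyte for which a standard is actually run,
    against which all others are quantified.
    """

    code: str
    name: str = ""
    is_internal_reference: bool = False


@dataclass(frozen=True)
class GradientStep:
    """One linear segment of a mobile-phase gradient (%A over time, min)."""

    t_start: float
    t_end: float
    percent_A_start: float
    percent_A_end: float

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValueError(f"gradient step must have t_end > t_start, got {self.t_start}..{self.t_end}")
        for p in (self.percent_A_start, self.percent_A_end):
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"%A must lie in [0, 100], got {p}")


@dataclass(frozen=True)
class ChromSystem:
    """A chromatographic system: instrument, column geometry and program.

    ``flow_rate`` is in mL/min, ``injection_volume`` in µL, column
    dimensions in mm, temperature in °C.  The wavelength program is
    carried as metadata only (detector response differences are absorbed
    into per-component calibration slopes).
    """

    system_id: str
    instrument_class: str  # "UPLC" | "HPLC"
    column_id: str = ""
    column_inner_diameter: float = 2.1
    column_length: float = 100.0
    flow_rate: float = 0.2
    column_temperature: float = 30.0
    injection_volume: float = 0.5
    gradient: tuple[GradientStep, ...] = ()
    wavelength_program: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.instrument_class not in ("UPLC", "HPLC"):
            raise ValueError(f"instrument_class must be 'UPLC' or 'HPLC', got {self.instrument_class!r}")
        for name in ("flow_rate", "injection_volume", "column_inner_diameter", "column_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        prev_end = 0.0
        for i, step in enumerate(self.gradient):
            if i == 0 and step.t_start != 0.0:
                raise ValueError("gradient must start at t = 0")
            if i > 0 and step.t_start != prev_end:
                raise ValueError("gradient breakpoints must be contiguous and strictly increasing")
            prev_end = step.t_end

    @property
    def run_time(self) -> float:
        """End of the gradient program in minutes (0 if no gradient)."""
        return self.gradient[-1].t_end if self.gradient else 0.0


@dataclass(frozen=True)
class PeakRecord:
    """One integrated chromatographic peak.

    ``injected_mass`` (µg) is set for standard injections and ``None``
    for unknowns; it is the quantity calibration curves are fitted
    against.
    """

    sample_id: str
    system_id: str
    retention_time: float
    area: float
    injection_volume: float
    component_code: Optional[str] = None
    injected_mass: Optional[float] = None

    def __post_init__(self):
        if not self.retention_time > 0:
            raise ValueError(f"retention_time must be positive, got {self.retention_time}")
        if self.area < 0:
            raise ValueError(f"area must be non-negative, got {self.area}")
        if not self.injection_volume > 0:
            raise ValueError(f"injection_volume must be positive, got {self.injection_volume}")


@dataclass
class PeakTable:
    """A collection of peak records with free-text provenance."""

    records: list[PeakRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            key = (rec.sample_id, rec.system_id, rec.retention_time)
            if key in seen:
                raise ValueError(f"duplicate peak key {key}: (sample_id, system_id, retention_time) must be unique")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, **fields) -> "PeakTable":
        """Sub-table of records whose attributes equal the given values."""
        recs = [
            r for r in self.records
            if all(getattr(r, k) == v for k, v in fields.items())
        ]
        return PeakTable(records=recs, provenance=self.provenance)

    def with_assignments(self, codes: dict[tuple[str, str, float], Optional[str]]) -> "PeakTable":
        """Copy of the table with component codes replaced from a key map."""
        recs = []
        for r in self.records:
            key = (r.sample_id, r.system_id, r.retention_time)
            recs.append(replace(r, component_code=codes.get(key, r.component_code)))
        return PeakTable(records=recs, provenance=self.provenance)


def _parse_float(text: str, column: str, line: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise RowParseError(line, f"column {column!r}: cannot parse {text!r} as a number "
                                  "(decimal separator must be '.')") from None


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peak-table CSV.

    Raises :class:`FormatError` if a mandatory column is missing and
    :class:`RowParseError` (with 1-based line number) for non-numeric
    numeric fields.  Parsing uses ``float()`` on the raw text and is
    therefore locale-independent.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        lines = fh.readlines()
    # leading '#' lines carry provenance (generator, seed) — not data
    provenance = " ".join(l[1:].strip() for l in lines if l.startswith("#"))
    numbered = [(i + 1, l) for i, l in enumerate(lines) if not l.startswith("#") and l.strip()]
    if not numbered:
        raise FormatError(f"{path}: empty file, expected a header row")
    header = next(csv.reader([numbered[0][1]]))
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    col = {name: header.index(name) for name in PEAK_TABLE_COLUMNS}
    records = []
    for line, text in numbered[1:]:
        cells = next(csv.reader([text]))
        if len(cells) != len(header):
            raise RowParseError(line, f"expected {len(header)} cells, found {len(cells)}")
        mass_text = cells[col["injected_mass_ug"]].strip()
        records.append(PeakRecord(
            sample_id=cells[col["sample_id"]],
            system_id=cells[col["system_id"]],
            component_code=cells[col["component_code"]].strip() or None,
            retention_time=_parse_float(cells[col["retention_time_min"]], "retention_time_min", line),
            area=_parse_float(cells[col["area"]], "area", line),
            injection_volume=_parse_float(cells[col["injection_volume_uL"]], "injection_volume_uL", line),
            injected_mass=None if mass_text == "" else _parse_float(mass_text, "injected_mass_ug", line),
        ))
    return PeakTable(records=records, provenance=provenance or f"read from {path.name}")


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write a peak table in the package CSV dialect.

    ``read_peak_table(write_peak_table(t))`` is the identity on all
    record fields.  Floats are written with ``repr`` so the round trip is
    bit-exact; an absent injected mass becomes an empty cell.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if table.provenance:
            fh.write(f"# {table.provenance}\n")
        writer = csv.writer(fh)
        writer.writerow(PEAK_TABLE_COLUMNS)
        for r in table.records:
            writer.writerow([
                r.sample_id,
                r.system_id,
                r.component_code or "",
                repr(r.retention_time),
                repr(r.area),
                repr(r.injection_volume),
                "" if r.injected_mass is None else repr(r.injected_mass),
            ])


def validate_panel(components: Sequence[Component]) -> None:
    """Check panel invariants: unique codes, exactly one internal reference."""
    if not components:
        raise PanelError("empty component panel")
    codes = [c.code for c in components]
    dupes = {c for c in codes if codes.count(c) > 1}
    if dupes:
        raise PanelError(f"duplicate component code(s): {', '.join(sorted(dupes))}")
    n_ref = sum(c.is_internal_reference for c in components)
    if n_ref != 1:
        raise PanelError(f"panel must contain exactly one internal reference, found {n_ref}")


def internal_reference(components: Sequence[Component]) -> Component:
    """The panel's single internal-reference component (panel validated)."""
    validate_panel(components)
    return next(c for c in components if c.is_internal_reference)


# ---------------------------------------------------------------------------
# Configuration documents (YAML): panel + systems
# ---------------------------------------------------------------------------

def _system_to_dict(s: ChromSystem) -> dict:
    return {
        "system_id": s.system_id,
        "instrument_class": s.instrument_class,
        "column_id": s.column_id,
        "column_inner_diameter_mm": s.column_inner_diameter,
        "column_length_mm": s.column_length,
        "flow_rate_mL_min": s.flow_rate,
        "column_temperature_C": s.column_temperature,
        "injection_volume_uL": s.injection_volume,
        "gradient": [
            [st.t_start, st.t_end, st.percent_A_start, st.percent_A_end] for st in s.gradient
        ],
        "wavelength_program": [list(w) for w in s.wavelength_program],
    }


def _system_from_dict(d: dict) -> ChromSystem:
    try:
        return ChromSystem(
            system_id=d["system_id"],
            instrument_class=d["instrument_class"],
            column_id=d.get("column_id", ""),
            column_inner_diameter=d["column_inner_diameter_mm"],
            column_length=d["column_length_mm"],
            flow_rate=d["flow_rate_mL_min"],
            column_temperature=d.get("column_temperature_C", 30.0),
            injection_volume=d["injection_volume_uL"],
            gradient=tuple(GradientStep(*st) for st in d.get("gradient", [])),
            wavelength_program=tuple(tuple(w) for w in d.get("wavelength_program", [])),
        )
    except KeyError as exc:
        raise ConfigError(f"system definition missing key {exc}") from None


def save_config(panel: Sequence[Component], systems: Iterable[ChromSystem], path: str | Path) -> None:
    """Write a panel + systems configuration document (YAML)."""
    doc = {
        "panel": [
            {"code": c.code, "name": c.name, "is_internal_reference": c.is_internal_reference}
            for c in panel
        ],
        "systems": [_system_to_dict(s) for s in systems],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_config(path: str | Path) -> tuple[list[Component], list[ChromSystem]]:
    """Read a panel + systems configuration document (YAML)."""
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from None
    if not isinstance(doc, dict) or "panel" not in doc or "systems" not in doc:
        raise ConfigError(f"{path}: document must contain 'panel' and 'systems' sections")
    panel = [
        Component(
            code=c["code"],
            name=c.get("name", ""),
            is_internal_reference=bool(c.get("is_internal_reference", False)),
        )
        for c in doc["panel"]
    ]
    validate_panel(panel)
    systems = [_system_from_dict(d) for d in doc["systems"]]
    return panel, systems
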