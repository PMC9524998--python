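"""MIxS MIMARKS-SURVEY table building, validation and writing.

MIMARKS-SURVEY is the Genomic Standards Consortium checklist for marker-gene
survey data. Fields are classed mandatory (M), conditionally mandatory (C —
required only when a declared sibling value is present) or environmentally
dependent (E — reported when measured, never invalidating). The field list
itself is deployment configuration (a YAML checklist per water and sediment
package), because submission portals evolve faster than code.

One export row is produced per extraction that has a run-attached FASTQ
record and whose field sample matches the package's material (water →
filter samples, sediment → sub-cores). Values are resolved by walking the
stored provenance chain, so every cell is traceable back to the record it
came from. Building never aborts on a missing mandatory value — the gap is
surfaced by :func:`validate_rows` instead, mirroring how submission
checkers report problems.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigError, LineageError, ValidationError
from .wetlab import lineage

PACKAGES = ("water", "sediment")
_PACKAGE_SAMPLE_KIND = {"water": "filter", "sediment": "subcore"}


@dataclass(frozen=True)
class ChecklistField:
    name: str
    requirement: str  # M | C | E
    source_path: str
    formatter: str = "identity"
    required_if: str = ""


@dataclass
class Checklist:
    package: str
    fields: tuple[ChecklistField, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            raise ConfigError(f"checklist {self.package}: duplicate field names")
        mandatory = {f.name for f in self.fields if f.requirement == "M"}
        for required in ("env_broad_scale", "env_local_scale"):
            if required not in mandatory:
                raise ConfigError(
                    f"checklist {self.package}: {required} must be a mandatory field"
                )

    @property
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]


@dataclass
class MixsRow:
    samp_name: str
    values: dict[str, str] = field(default_factory=dict)  # field name -> formatted value
    fastq_filename: str = ""


@dataclass
class ValidationReport:
    valid_rows: list[MixsRow]
    violations: list[tuple[str, str, str]]  # (samp_name, field, requirement)


def default_checklist_path() -> Path:
    return Path(str(resources.files("medna").joinpath("data/mixs_checklist.yaml")))


def load_checklist(package: str, config_path: str | Path | None = None) -> Checklist:
    if package not in PACKAGES:
        raise ValidationError(f"unknown MIxS package {package!r}; use water or sediment")
    path = Path(config_path) if config_path is not None else default_checklist_path()
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    try:
        entries = raw["packages"][package]
    except (TypeError, KeyError) as exc:
        raise ConfigError(f"checklist config {path} lacks package {package!r}") from exc
    fields = []
    for item in entries:
        if item.get("requirement") not in ("M", "C", "E"):
            raise ConfigError(
                f"checklist field {item.get('name')!r}: requirement must be M, C or E"
            )
        fields.append(
            ChecklistField(
                name=str(item["name"]),
                requirement=item["requirement"],
                source_path=str(item["source_path"]),
                formatter=str(item.get("formatter", "identity")),
                required_if=str(item.get("required_if", "")),
            )
        )
    return Checklist(package=package, fields=tuple(fields))


# ---------------------------------------------------------------------------
# value resolution and formatting


def _resolve(context: dict, dotted: str):
    obj = context
    for part in dotted.split("."):
        if obj is None:
            return None
        if isinstance(obj, dict):
            obj = obj.get(part)
        else:
            obj = getattr(obj, part, None)
    return obj


def _format(value, formatter: str) -> str:
    if value is None:
        return ""
    if formatter == "identity":
        return str(value)
    if formatter == "date_iso":
        return str(value)  # stored timestamps are already ISO 8601 with zone
    if formatter == "join_semicolon":
        return ";".join(str(v) for v in value)
    if formatter == "lat_lon":
        # MIxS convention: signed decimal degrees, latitude first
        return f"{value.lat:.4f} {value.lon:.4f}"
    if formatter == "pcr_primers":
        return f"FWD:{value.forward_seq};REV:{value.reverse_seq}"
    raise ConfigError(f"unknown formatter {formatter!r}")


def _context_for_extraction(store, ext_id: str, fastq) -> Optional[dict]:
    try:
        chain = lineage(store, fastq.file_id)
    except LineageError:
        return None
    fq, run, prep, pool, lib, ext, sample, coll, survey = chain[:9]
    site = chain[9] if len(chain) > 9 else None
    primer = store.tables["primer_pairs"].get(lib.primer_pair_id) if lib else None
    measurements = sorted(
        (
            m
            for m in store.tables["measurements"].values()
            if m.survey_id == survey.survey_id
        ),
        key=lambda m: (m.depth_m, m.measurement_id),
    )
    return {
        "fastq": fq,
        "run": run,
        "prep": prep,
        "pool": pool,
        "library": lib,
        "extraction": ext,
        "sample": sample,
        "collection": coll,
        "survey": survey,
        "site": site,
        "primer_pair": primer,
        "measurement": measurements[0] if measurements else None,
    }


# ---------------------------------------------------------------------------
# operations


def build_mixs_rows(
    store, package: str, checklist: Optional[Checklist] = None
) -> list[MixsRow]:
    """One row per sequenced extraction of the package's material kind.

    Rows come back ordered by sample barcode; unresolvable values are left
    empty (``validate_rows`` reports gaps in M/C fields). Rebuilding from
    an unchanged store is byte-deterministic.
    """
    checklist = checklist or load_checklist(package)
    want_kind = _PACKAGE_SAMPLE_KIND[package]
    rows: list[MixsRow] = []
    seen_extractions: set[str] = set()
    for fq_id in sorted(store.tables["fastq_files"]):
        fastq = store.tables["fastq_files"][fq_id]
        ctx = _context_for_extraction(store, fastq.extraction_id, fastq)
        if ctx is None or ctx["sample"].kind != want_kind:
            continue
        ext_id = ctx["extraction"].extraction_id
        if ext_id in seen_extractions:
            continue
        seen_extractions.add(ext_id)
        values = {}
        for f in checklist.fields:
            values[f.name] = _format(_resolve(ctx, f.source_path), f.formatter)
        rows.append(
            MixsRow(
                samp_name=ctx["sample"].barcode,
                values=values,
                fastq_filename=fastq.filename,
            )
        )
    rows.sort(key=lambda r: r.samp_name)
    return rows


def validate_rows(rows: Sequence[MixsRow], checklist: Checklist) -> ValidationReport:
    """Checklist conformance report; E fields never invalidate a row."""
    valid, violations = [], []
    for row in rows:
        row_ok = True
        for f in checklist.fields:
            value = row.values.get(f.name, "")
            if f.requirement == "M" and not value:
                violations.append((row.samp_name, f.name, "M"))
                row_ok = False
            elif f.requirement == "C" and not value:
                sibling = row.values.get(f.required_if, "") if f.required_if else ""
                if sibling:
                    violations.append((row.samp_name, f.name, "C"))
                    row_ok = False
        if row_ok:
            valid.append(row)
    return ValidationReport(valid_rows=valid, violations=violations)


def write_table(rows: Sequence[MixsRow], path, checklist: Checklist, format: str = "csv") -> None:
    """Write rows as RFC 4180 CSV or TSV, UTF-8, trailing newline."""
    if format not in ("csv", "tsv"):
        raise ValidationError(f"unknown format {format!r}")
    dialect_kwargs = {"delimiter": "\t"} if format == "tsv" else {}
    handle: io.TextIOBase
    close = False
    if hasattr(path, "write"):
        handle = path
    else:
        handle = open(path, "w", encoding="utf-8", newline="")
        close = True
    try:
        writer = csv.writer(handle, lineterminator="\n", **dialect_kwargs)
        writer.writerow(checklist.field_names)
        for row in rows:
            writer.writerow([row.values.get(name, "") for name in checklist.field_names])
    finally:
        if close:
            handle.close()


def read_table(path, checklist: Checklist, format: str = "csv") -> list[MixsRow]:
    dialect_kwargs = {"delimiter": "\t"} if format == "tsv" else {}
    close = False
    if hasattr(path, "read"):
        handle = path
    else:
        handle = open(path, "r", encoding="utf-8", newline="")
        close = True
    try:
        reader = csv.reader(handle, **dialect_kwargs)
        header = next(reader, None)
        if header != checklist.field_names:
            raise ValidationError("table header does not match the checklist field order")
        rows = []
        for record in reader:
            values = dict(zip(header, record))
            rows.append(
                MixsRow(
                    samp_name=values.get("samp_name", ""),
                    values=values,
                    fastq_filename=values.get("fastq_filename", ""),
                )
            )
        return rows
    finally:
        if close:
            handle.close()
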