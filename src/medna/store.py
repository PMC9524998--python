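"""Embedded data store: tables, permissions, views, ETL and round-trip I/O.

The :class:`Store` is a single in-process object holding one table per
domain type, the vocabulary registry, the region set, the site-ID registry
and the barcode label store. It persists to a single JSON file and round-
trips any table through RFC 4180 CSV. Every public operation validates
before it mutates, so a failed call leaves the store unchanged.

Permission gating mirrors a field-station staffing model: project admins
may create, update and read everything; graduate students the same on a
configured subset of tables; interns may read and create on a subset.
Authenticated-but-ungranted users hold no table permissions at all, and
deletion is never part of a preset — it must be granted per user, and even
then referential integrity refuses cascades. A handful of public summary
views are readable without any grant.

ETL ingestion accepts denormalized flat field records (one CSV row per
sample, the shape a tablet survey app exports) and normalizes them into
surveys, measurements, collections and samples. Upserts key on natural
identifiers, so re-ingesting the same file is a no-op; rows with unknown
barcodes or vocabulary codes are rejected individually with reasons while
the rest of the file loads.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

from . import bioinfo, fieldcore, freezer, wetlab
from .errors import IntegrityError, NotFoundError, ValidationError
from .ident import LabelRecord, LabelStore, SiteRegistry, parse_barcode, parse_site_id
from .regions import RegionSet, region_set_from_geojson, region_set_to_geojson
from .vocab import VocabularyRegistry, load_defaults

#: table name -> record dataclass
RECORD_TYPES: dict[str, type] = {
    "sites": fieldcore.FieldSite,
    "surveys": fieldcore.FieldSurvey,
    "measurements": fieldcore.EnvironmentalMeasurement,
    "collections": fieldcore.FieldCollection,
    "samples": fieldcore.FieldSample,
    "extractions": wetlab.Extraction,
    "primer_pairs": wetlab.PrimerPair,
    "pcrs": wetlab.Pcr,
    "index_pairs": wetlab.IndexPair,
    "libraries": wetlab.LibraryPrep,
    "pools": wetlab.PooledLibrary,
    "run_preps": wetlab.RunPrep,
    "runs": wetlab.RunResult,
    "fastq_files": wetlab.FastqFile,
    "quality_meta": bioinfo.QualityMetadata,
    "denoise_meta": bioinfo.DenoiseClusterMetadata,
    "features": bioinfo.FeatureOutput,
    "feature_reads": bioinfo.FeatureRead,
    "taxon_nodes": bioinfo.TaxonNode,
    "annotations": bioinfo.TaxonomicAnnotation,
    "inventory_items": freezer.InventoryItem,
    "inventory_log": freezer.InventoryLogEntry,
    "grants": None,  # PermissionGrant, defined below
}

#: key field per table (feature_reads uses a composite tuple key)
KEY_FIELDS: dict[str, str] = {
    "sites": "site_id",
    "surveys": "survey_id",
    "measurements": "measurement_id",
    "collections": "collection_id",
    "samples": "sample_id",
    "extractions": "extraction_id",
    "primer_pairs": "primer_pair_id",
    "pcrs": "pcr_id",
    "index_pairs": "index_pair_id",
    "libraries": "lib_id",
    "pools": "pool_id",
    "run_preps": "prep_id",
    "runs": "run_id",
    "fastq_files": "file_id",
    "quality_meta": "qm_id",
    "denoise_meta": "dc_id",
    "features": "feature_id",
    "annotations": "annotation_id",
    "inventory_items": "barcode",
    "taxon_nodes": "node_id",
    "grants": "principal",
}

PUBLIC_READ_VIEWS = {"project_summary", "site_list"}

#: table subsets for the graduate and intern presets (deployment config)
GRADUATE_TABLES = (
    "sites",
    "surveys",
    "measurements",
    "collections",
    "samples",
    "extractions",
    "primer_pairs",
    "pcrs",
    "index_pairs",
    "libraries",
    "pools",
    "run_preps",
    "runs",
    "fastq_files",
    "quality_meta",
    "denoise_meta",
    "features",
    "feature_reads",
    "annotations",
    "inventory_items",
    "inventory_log",
)
INTERN_TABLES = ("surveys", "measurements", "collections", "samples", "inventory_log")

ROLE_PRESETS: dict[str, dict[str, tuple[str, ...]]] = {
    "admin": {t: ("create", "read", "update") for t in RECORD_TYPES},
    "graduate": {t: ("create", "read", "update") for t in GRADUATE_TABLES},
    "intern": {t: ("read", "create") for t in INTERN_TABLES},
}


@dataclass
class PermissionGrant:
    principal: str
    role: str  # admin | graduate | intern | custom
    table_ops: dict = field(default_factory=dict)  # table -> list of operations


RECORD_TYPES["grants"] = PermissionGrant


class Store:
    """All tables plus the registries the identifier grammars depend on."""

    def __init__(
        self,
        registry: Optional[VocabularyRegistry] = None,
        regions: Optional[RegionSet] = None,
    ) -> None:
        self.registry = registry if registry is not None else load_defaults()
        self.regions = regions
        # injectable so fixtures and tests can be byte-deterministic
        self.clock = lambda: datetime.now(timezone.utc).isoformat()
        self.sites = SiteRegistry()
        self.labels = LabelStore()
        self.tables: dict[str, dict] = {name: {} for name in RECORD_TYPES}
        self.taxon_index: dict[tuple, str] = {}
        self._counters: dict[str, int] = {}

    # -- ids -------------------------------------------------------------

    def next_id(self, table: str, prefix: str) -> str:
        n = self._counters.get(table, 0) + 1
        self._counters[table] = n
        return f"{prefix}{n:06d}"

    # -- permissions (§ role model in the module docstring) ---------------

    def grant_role(self, principal: str, role: str) -> PermissionGrant:
        if role not in ROLE_PRESETS:
            raise ValidationError(f"unknown role preset {role!r}")
        grant = PermissionGrant(
            principal=principal,
            role=role,
            table_ops={t: list(ops) for t, ops in ROLE_PRESETS[role].items()},
        )
        self.tables["grants"][principal] = grant
        return grant

    def grant_custom(self, principal: str, table: str, operations: Sequence[str]) -> PermissionGrant:
        if table not in RECORD_TYPES:
            raise NotFoundError(f"unknown table {table!r}")
        bad = set(operations) - {"create", "read", "update", "delete"}
        if bad:
            raise ValidationError(f"unknown operation(s) {sorted(bad)}")
        grant = self.tables["grants"].get(principal)
        if grant is None:
            grant = PermissionGrant(principal=principal, role="custom", table_ops={})
            self.tables["grants"][principal] = grant
        ops = set(grant.table_ops.get(table, [])) | set(operations)
        grant.table_ops[table] = sorted(ops)
        return grant

    def gate(self, principal: Optional[str], table: str, operation: str) -> bool:
        """Allow/deny decision; never raises."""
        if operation == "read" and table in PUBLIC_READ_VIEWS:
            return True
        if principal is None:
            return False
        grant = self.tables["grants"].get(principal)
        if grant is None:
            return False
        return operation in grant.table_ops.get(table, ())

    # -- join views mirroring the query endpoints -------------------------

    def _sample_rows(self, collection_kind: str, sample_kind: str) -> list[dict]:
        rows = []
        for sample in self.tables["samples"].values():
            if sample.kind != sample_kind:
                continue
            coll = self.tables["collections"][sample.collection_id]
            if coll.kind != collection_kind:
                continue
            survey = self.tables["surveys"][coll.survey_id]
            row = {
                "survey_id": survey.survey_id,
                "survey_datetime": survey.datetime,
                "site_id": survey.site_id,
                "other_site_text": survey.other_site_text,
                "collection_id": coll.collection_id,
                "control_type": coll.control_type,
                "sample_id": sample.sample_id,
                "barcode": sample.barcode,
            }
            row.update({f"sample_{k}": v for k, v in sorted(sample.payload.items())})
            rows.append(row)
        rows.sort(key=lambda r: (r["survey_datetime"], r["barcode"]))
        return rows

    def view_survey_filters(self) -> list[dict]:
        """One row per filter sample with its survey context."""
        return self._sample_rows("water", "filter")

    def view_survey_subcores(self) -> list[dict]:
        """One row per sub-core sample with its survey context."""
        return self._sample_rows("sediment", "subcore")

    def view_survey_envs(self) -> list[dict]:
        """One row per environmental measurement with its survey context."""
        rows = []
        for m in self.tables["measurements"].values():
            survey = self.tables["surveys"][m.survey_id]
            rows.append(
                {
                    "survey_id": survey.survey_id,
                    "survey_datetime": survey.datetime,
                    "site_id": survey.site_id,
                    "depth_m": m.depth_m,
                    "measure_type": m.measure_type,
                    "value": m.value,
                    "unit": m.unit,
                    "measurement_id": m.measurement_id,
                }
            )
        rows.sort(key=lambda r: (r["survey_datetime"], r["measurement_id"]))
        return rows

    # -- serialization -----------------------------------------------------

    def _table_rows(self, table: str) -> list[dict]:
        rows = []
        if table == "feature_reads":
            for key in sorted(self.tables[table]):
                rows.append(dataclasses.asdict(self.tables[table][key]))
        else:
            for key in sorted(self.tables[table]):
                rows.append(dataclasses.asdict(self.tables[table][key]))
        return rows

    def to_document(self) -> dict:
        """Deterministic plain-JSON representation of the whole store."""
        return {
            "format": "medna-store",
            "version": 1,
            "vocabulary": self.registry.snapshot(),
            "material_sample_kind": dict(sorted(self.registry.material_sample_kind.items())),
            "derived_material_codes": dict(
                sorted(self.registry.derived_material_codes.items())
            ),
            "regions": region_set_to_geojson(self.regions) if self.regions else None,
            "site_ids": self.sites.all_ids(),
            "labels": [
                {
                    "text": r.text,
                    "requester": r.requester,
                    "created_at": r.created_at,
                    "assigned": r.assigned,
                    "assigned_to": r.assigned_to,
                }
                for r in self.labels.all_labels()
            ],
            "counters": dict(sorted(self._counters.items())),
            "tables": {t: self._table_rows(t) for t in sorted(self.tables)},
        }

    def digest(self) -> str:
        """SHA-256 of the canonical JSON document."""
        blob = json.dumps(self.to_document(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_document(), sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_document(cls, doc: dict) -> "Store":
        if doc.get("format") != "medna-store":
            raise ValidationError("not a medna store document")
        store = cls(registry=load_defaults())
        # rebuild model-based vocabulary exactly as snapshotted
        store.registry = _registry_from_snapshot(doc["vocabulary"])
        store.registry.material_sample_kind = dict(doc.get("material_sample_kind", {}))
        store.registry.derived_material_codes = dict(doc.get("derived_material_codes", {}))
        if doc.get("regions"):
            store.regions = region_set_from_geojson(doc["regions"])
        for text in doc.get("site_ids", []):
            store.sites.add_existing(parse_site_id(text))
        for row in doc.get("labels", []):
            rec = LabelRecord(
                parts=parse_barcode(row["text"]),
                text=row["text"],
                requester=row.get("requester", ""),
                created_at=row.get("created_at", ""),
                assigned=bool(row.get("assigned", False)),
                assigned_to=row.get("assigned_to", ""),
            )
            store.labels._by_text[rec.text] = rec
        store._counters = dict(doc.get("counters", {}))
        for table, rows in doc.get("tables", {}).items():
            if table not in RECORD_TYPES:
                raise ValidationError(f"unknown table {table!r} in document")
            for row in rows:
                record = _record_from_dict(table, row)
                store.tables[table][_key_of(table, record)] = record
        _rebuild_taxon_index(store)
        return store

    @classmethod
    def load(cls, path: str | Path) -> "Store":
        return cls.from_document(json.loads(Path(path).read_text(encoding="utf-8")))

    # -- CSV round-trip ----------------------------------------------------

    def export_table_csv(self, table: str, path: str | Path) -> None:
        """Write one table as CSV; every cell is JSON-encoded for losslessness."""
        if table not in RECORD_TYPES:
            raise NotFoundError(f"unknown table {table!r}")
        fields = [f.name for f in dataclasses.fields(RECORD_TYPES[table])]
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(fields)
            for row in self._table_rows(table):
                writer.writerow([json.dumps(row[f], sort_keys=True) for f in fields])

    def import_table_csv(self, table: str, path: str | Path) -> int:
        """Replace one table from CSV; aborts (unchanged) on dangling references."""
        if table not in RECORD_TYPES:
            raise NotFoundError(f"unknown table {table!r}")
        expected = [f.name for f in dataclasses.fields(RECORD_TYPES[table])]
        staged: dict = {}
        with open(path, "r", encoding="utf-8", newline="") as handle:
            reader = csv.reader(handle)
            header = next(reader, None)
            if header != expected:
                raise IntegrityError(
                    f"table {table!r}: header {header} does not match schema {expected}"
                )
            for record_cells in reader:
                row = {f: json.loads(cell) for f, cell in zip(expected, record_cells)}
                record = _record_from_dict(table, row)
                staged[_key_of(table, record)] = record
        previous = self.tables[table]
        self.tables[table] = staged
        problems = self.integrity_scan()
        if problems:
            self.tables[table] = previous
            raise IntegrityError(
                f"import of {table!r} aborted; violations: " + "; ".join(problems[:10])
            )
        if table == "taxon_nodes":
            _rebuild_taxon_index(self)
        return len(staged)

    # -- ETL ---------------------------------------------------------------

    def ingest_flat_records(self, records: Sequence[dict]) -> "IngestReport":
        return _ingest_flat_records(self, records)

    # -- integrity ---------------------------------------------------------

    def integrity_scan(self) -> list[str]:
        return integrity_scan(self)


def _registry_from_snapshot(snapshot: list[dict]) -> VocabularyRegistry:
    from .vocab import VocabularyEntry, VocabularyRegistry

    registry = VocabularyRegistry()
    for row in snapshot:
        key = (row["vocabulary_name"], row["code"])
        if key in registry._entries:
            entry = registry._entries[key]
            entry.active = row["active"]
            continue
        registry._entries[key] = VocabularyEntry(
            vocabulary_name=row["vocabulary_name"],
            code=row["code"],
            label=row["label"],
            kind=row["kind"],
            active=row["active"],
            extra=dict(row.get("extra", {})),
        )
    return registry


def _key_of(table: str, record) -> Any:
    if table == "feature_reads":
        return (record.feature_id, record.extraction_id)
    if table == "inventory_log":
        return f"log{record.seq_no:06d}"
    return getattr(record, KEY_FIELDS[table])


def _record_from_dict(table: str, row: dict):
    cls = RECORD_TYPES[table]
    row = dict(row)
    if table in ("inventory_items", "inventory_log") and row.get("location") is not None:
        row["location"] = freezer.StorageLocation(**row["location"])
    return cls(**row)


def _rebuild_taxon_index(store: Store) -> None:
    store.taxon_index = {
        (n.parent_id, n.rank, n.name): n.node_id
        for n in store.tables["taxon_nodes"].values()
    }


# ---------------------------------------------------------------------------
# integrity scan


def integrity_scan(store: Store) -> list[str]:
    """Referential and structural integrity across all tables.

    Returns a list of human-readable violations; empty means clean.
    """
    bad: list[str] = []

    def ref(table: str, key, owner: str) -> None:
        if key and key not in store.tables[table]:
            bad.append(f"{owner}: dangling reference to {table}/{key}")

    for site in store.tables["sites"].values():
        if site.site_id not in store.sites:
            bad.append(f"site {site.site_id}: not present in the site-ID registry")
    for s in store.tables["surveys"].values():
        if s.site_id:
            ref("sites", s.site_id, f"survey {s.survey_id}")
        elif not s.other_site_text:
            bad.append(f"survey {s.survey_id}: neither site nor 'other' text")
        if not s.projects:
            bad.append(f"survey {s.survey_id}: no projects")
    for m in store.tables["measurements"].values():
        ref("surveys", m.survey_id, f"measurement {m.measurement_id}")
        if m.depth_m < 0:
            bad.append(f"measurement {m.measurement_id}: negative depth")
    for c in store.tables["collections"].values():
        ref("surveys", c.survey_id, f"collection {c.collection_id}")
        allowed = (
            fieldcore.WATER_PAYLOAD_FIELDS
            if c.kind == "water"
            else fieldcore.SEDIMENT_PAYLOAD_FIELDS
        )
        if set(c.payload) - allowed:
            bad.append(f"collection {c.collection_id}: payload does not match kind {c.kind}")
    assigned_samples = 0
    for s in store.tables["samples"].values():
        ref("collections", s.collection_id, f"sample {s.sample_id}")
        label = store.labels.get(s.barcode)
        if label is None or not label.assigned or label.assigned_to != s.sample_id:
            bad.append(f"sample {s.sample_id}: barcode {s.barcode} not bound to it")
        else:
            assigned_samples += 1
        allowed = (
            fieldcore.FILTER_PAYLOAD_FIELDS
            if s.kind == "filter"
            else fieldcore.SUBCORE_PAYLOAD_FIELDS
        )
        if set(s.payload) - allowed:
            bad.append(f"sample {s.sample_id}: payload does not match kind {s.kind}")
        coll = store.tables["collections"].get(s.collection_id)
        if coll and fieldcore.SAMPLE_KIND_TO_COLLECTION_KIND[s.kind] != coll.kind:
            bad.append(f"sample {s.sample_id}: {s.kind} sample on {coll.kind} collection")
    # barcode assignment injectivity
    owners: dict[str, str] = {}
    for label in store.labels.all_labels():
        if label.assigned:
            if label.assigned_to in owners.values():
                pass
            owners[label.text] = label.assigned_to
    by_owner: dict[str, list[str]] = {}
    for text, owner in owners.items():
        by_owner.setdefault(owner, []).append(text)
    for owner, texts in by_owner.items():
        if len(texts) > 1:
            bad.append(f"record {owner} bound to multiple barcodes {sorted(texts)}")
    for e in store.tables["extractions"].values():
        ref("samples", e.field_sample_id, f"extraction {e.extraction_id}")
        if e.final_volume_ul <= 0:
            bad.append(f"extraction {e.extraction_id}: non-positive volume")
        if e.concentration_ng_per_ul < 0:
            bad.append(f"extraction {e.extraction_id}: negative concentration")
    for p in store.tables["pcrs"].values():
        ref("extractions", p.extraction_id, f"pcr {p.pcr_id}")
        ref("primer_pairs", p.primer_pair_id, f"pcr {p.pcr_id}")
        if not p.replicates:
            bad.append(f"pcr {p.pcr_id}: no replicates")
    for lib in store.tables["libraries"].values():
        ref("extractions", lib.extraction_id, f"library {lib.lib_id}")
        ref("primer_pairs", lib.primer_pair_id, f"library {lib.lib_id}")
        ref("index_pairs", lib.index_pair_id, f"library {lib.lib_id}")
    for pool in store.tables["pools"].values():
        if not pool.member_lib_ids:
            bad.append(f"pool {pool.pool_id}: no members")
        pairs = set()
        for lid in pool.member_lib_ids:
            ref("libraries", lid, f"pool {pool.pool_id}")
            lib = store.tables["libraries"].get(lid)
            if lib is None:
                continue
            ip = store.tables["index_pairs"].get(lib.index_pair_id)
            if ip is None:
                continue
            key = (ip.i7_seq, ip.i5_seq)
            if key in pairs:
                bad.append(f"pool {pool.pool_id}: duplicate index pair {key}")
            pairs.add(key)
    for prep in store.tables["run_preps"].values():
        for pid in prep.pool_ids:
            ref("pools", pid, f"run prep {prep.prep_id}")
    for run in store.tables["runs"].values():
        ref("run_preps", run.prep_id, f"run {run.run_id}")
    seen_files = set()
    for fq in store.tables["fastq_files"].values():
        ref("runs", fq.run_id, f"fastq {fq.file_id}")
        if fq.extraction_id:
            ref("extractions", fq.extraction_id, f"fastq {fq.file_id}")
        key = (fq.run_id, fq.filename)
        if key in seen_files:
            bad.append(f"fastq {fq.file_id}: duplicate filename in run {fq.run_id}")
        seen_files.add(key)
    for qm in store.tables["quality_meta"].values():
        for fid in qm.fastq_file_ids:
            ref("fastq_files", fid, f"quality metadata {qm.qm_id}")
        if not 0 < qm.min_read_length <= qm.max_read_length:
            bad.append(f"quality metadata {qm.qm_id}: bad read-length window")
    for dc in store.tables["denoise_meta"].values():
        ref("quality_meta", dc.qm_id, f"denoise metadata {dc.dc_id}")
    for feat in store.tables["features"].values():
        ref("denoise_meta", feat.dc_id, f"feature {feat.feature_id}")
        if set(feat.sequence) - wetlab.IUPAC_DNA:
            bad.append(f"feature {feat.feature_id}: non-IUPAC sequence")
    for (fid, eid), fr in store.tables["feature_reads"].items():
        ref("features", fid, f"feature read ({fid}, {eid})")
        ref("extractions", eid, f"feature read ({fid}, {eid})")
        if fr.read_count < 0:
            bad.append(f"feature read ({fid}, {eid}): negative count")
    # taxonomy: parents exist, rank order contiguous
    rank_pos = {r: i for i, r in enumerate(bioinfo.RANKS)}
    for node in store.tables["taxon_nodes"].values():
        if node.rank not in rank_pos:
            bad.append(f"taxon {node.node_id}: unknown rank {node.rank}")
            continue
        if node.parent_id:
            parent = store.tables["taxon_nodes"].get(node.parent_id)
            if parent is None:
                bad.append(f"taxon {node.node_id}: dangling parent {node.parent_id}")
            elif rank_pos[parent.rank] != rank_pos[node.rank] - 1:
                bad.append(f"taxon {node.node_id}: rank gap above {node.rank}")
        elif rank_pos[node.rank] != 0:
            bad.append(f"taxon {node.node_id}: rootless {node.rank} node")
    for ann in store.tables["annotations"].values():
        ref("features", ann.feature_id, f"annotation {ann.annotation_id}")
        if ann.verified_node_id:
            ref("taxon_nodes", ann.verified_node_id, f"annotation {ann.annotation_id}")
    # inventory invariants
    locations: dict = {}
    for item in store.tables["inventory_items"].values():
        if item.volume_ul < 0:
            bad.append(f"inventory {item.barcode}: negative volume")
        if item.status in ("in_storage", "checked_out"):
            if item.location is None:
                bad.append(f"inventory {item.barcode}: active item without a location")
            elif item.location in locations:
                bad.append(
                    f"location {item.location} shared by {locations[item.location]} "
                    f"and {item.barcode}"
                )
            else:
                locations[item.location] = item.barcode
    try:
        replayed = freezer.replay_ledger(
            [
                store.tables["inventory_log"][k]
                for k in sorted(store.tables["inventory_log"])
            ]
        )
    except Exception as exc:  # replay failure is itself a violation
        bad.append(f"inventory ledger does not replay: {exc}")
    else:
        if {b: (i.status, i.volume_ul, i.location) for b, i in replayed.items()} != {
            b: (i.status, i.volume_ul, i.location)
            for b, i in store.tables["inventory_items"].items()
        }:
            bad.append("inventory ledger replay disagrees with live item state")
    return bad


# ---------------------------------------------------------------------------
# ETL


@dataclass
class IngestReport:
    surveys_created: int = 0
    measurements_created: int = 0
    collections_created: int = 0
    samples_created: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    @property
    def total_created(self) -> int:
        return (
            self.surveys_created
            + self.measurements_created
            + self.collections_created
            + self.samples_created
        )


FLAT_COLUMNS = (
    "site_id",
    "other_site_text",
    "survey_datetime",
    "recorders",
    "projects",
    "collection_kind",
    "control_type",
    "sample_barcode",
    "sample_kind",
)


def read_flat_csv(path: str | Path) -> list[dict]:
    """Read a denormalized flat field-record CSV into raw row dicts."""
    with open(path, "r", encoding="utf-8", newline="") as handle:
        return [dict(row) for row in csv.DictReader(handle)]


def _survey_key(record: dict) -> tuple:
    recorders = frozenset(x for x in (record.get("recorders") or "").split(";") if x)
    return (
        record.get("site_id") or record.get("other_site_text") or "",
        record.get("survey_datetime") or "",
        recorders,
    )


def _find_survey(store: Store, key: tuple):
    for s in store.tables["surveys"].values():
        if _survey_key(
            {
                "site_id": s.site_id,
                "other_site_text": s.other_site_text,
                "survey_datetime": s.datetime,
                "recorders": ";".join(s.recorders),
            }
        ) == key:
            return s
    return None


def _ingest_flat_records(store: Store, records: Sequence[dict]) -> IngestReport:
    report = IngestReport()
    for idx, rec in enumerate(records):
        try:
            _ingest_one(store, rec, report)
        except Exception as exc:
            report.rejects.append((idx, str(exc)))
    return report


def _ingest_one(store: Store, rec: dict, report: IngestReport) -> None:
    site_id = (rec.get("site_id") or "").strip()
    other = (rec.get("other_site_text") or "").strip()
    dt = (rec.get("survey_datetime") or "").strip()
    if not dt:
        raise ValidationError("missing survey_datetime")
    recorders = [x for x in (rec.get("recorders") or "").split(";") if x]
    projects = [x for x in (rec.get("projects") or "").split(";") if x]

    # validate everything up front so a bad row changes nothing
    if site_id and site_id not in store.tables["sites"]:
        raise NotFoundError(f"unknown site {site_id!r}")
    barcode = (rec.get("sample_barcode") or "").strip()
    sample_kind = (rec.get("sample_kind") or "").strip()
    coll_kind = (rec.get("collection_kind") or "").strip()
    control_type = (rec.get("control_type") or "true_sample").strip()
    if coll_kind and coll_kind not in ("water", "sediment"):
        raise ValidationError(f"unknown collection kind {coll_kind!r}")
    if control_type and not store.registry.has("control_type", control_type):
        raise ValidationError(f"unknown control type {control_type!r}")
    measurements = []
    i = 1
    while f"meas{i}_type" in rec:
        mtype = (rec.get(f"meas{i}_type") or "").strip()
        if mtype:
            if not store.registry.has("env_measure_type", mtype):
                raise ValidationError(f"unknown measure type {mtype!r}")
            measurements.append(
                (
                    float(rec.get(f"meas{i}_depth") or 0.0),
                    mtype,
                    float(rec.get(f"meas{i}_value") or 0.0),
                )
            )
        i += 1
    if barcode:
        label = store.labels.get(barcode)
        if label is None:
            raise NotFoundError(f"unknown barcode {barcode!r}")
        if not sample_kind:
            sample_kind = store.registry.material_sample_kind.get(
                parse_barcode(barcode).material_code, ""
            )
        if sample_kind not in ("filter", "subcore"):
            raise ValidationError(f"unknown sample kind {sample_kind!r}")
        expected_kind = store.registry.material_sample_kind.get(
            parse_barcode(barcode).material_code, ""
        )
        if expected_kind != sample_kind:
            raise ValidationError(
                f"barcode {barcode!r} material labels {expected_kind!r} samples, "
                f"not {sample_kind!r}"
            )
        if not coll_kind:
            coll_kind = fieldcore.SAMPLE_KIND_TO_COLLECTION_KIND[sample_kind]

    # upsert survey
    key = _survey_key(rec)
    survey = _find_survey(store, key)
    if survey is None:
        survey = fieldcore.create_survey(
            store,
            site_id=site_id,
            other_site_text=other,
            datetime_iso=dt,
            recorders=recorders,
            projects=projects or ["default"],
        )
        report.surveys_created += 1

    # upsert measurements by (survey, depth, type)
    existing = {
        (m.survey_id, m.depth_m, m.measure_type)
        for m in store.tables["measurements"].values()
    }
    for depth, mtype, value in measurements:
        if (survey.survey_id, depth, mtype) in existing:
            continue
        fieldcore.attach_measurement(store, survey.survey_id, depth, mtype, value)
        report.measurements_created += 1

    if not barcode:
        return
    label = store.labels.get(barcode)
    if label.assigned:
        return  # sample already ingested; idempotent no-op
    payload_prefix = "sample_"
    payload = {
        k[len(payload_prefix):]: v
        for k, v in rec.items()
        if k.startswith(payload_prefix)
        and k not in ("sample_barcode", "sample_kind")
        and (v or "").strip()
    }
    coll_payload = {
        k[len("collection_"):]: v
        for k, v in rec.items()
        if k.startswith("collection_") and k != "collection_kind" and (v or "").strip()
    }
    # one collection per (survey, kind, control_type) natural key
    coll = next(
        (
            c
            for c in store.tables["collections"].values()
            if c.survey_id == survey.survey_id
            and c.kind == coll_kind
            and c.control_type == control_type
        ),
        None,
    )
    if coll is None:
        coll = fieldcore.create_collection(
            store, survey.survey_id, coll_kind, control_type, coll_payload
        )
        report.collections_created += 1
    fieldcore.register_sample(store, coll.collection_id, barcode, sample_kind, payload)
    report.samples_created += 1
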