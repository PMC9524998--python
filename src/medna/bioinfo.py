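"""Bioinformatics metadata: processing parameters, features and taxonomy.

No sequence processing happens here — denoising, clustering and annotation
run elsewhere; this module captures their parameters and results so a read
count or a taxon name can always be traced back to the exact software,
reference database and trimming settings that produced it.

The taxonomy is a forest of parent-linked nodes over nine fixed ranks
(domain, kingdom, supergroup, phylum/division, class, order, family, genus,
species — the supergroup and phylum/division ranks accommodate protist
classifications alongside the Linnaean ranks). Lineages must fill ranks
contiguously from domain downward; inserting a lineage re-uses any already
present prefix, so curated species lists deduplicate hierarchically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import DuplicateError, NotFoundError, ValidationError
from .wetlab import IUPAC_DNA, _check_dna

RANKS = (
    "domain",
    "kingdom",
    "supergroup",
    "phylum_division",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


@dataclass
class QualityMetadata:
    qm_id: str
    fastq_file_ids: list[str]
    min_read_length: int
    max_read_length: int
    trim_fwd: int
    trim_rev: int
    min_quality: float
    analysis_location: str = ""
    sop: str = ""
    env_file: str = ""  # verbatim installed-package listing
    analyst: str = ""
    analysis_datetime: str = ""


@dataclass
class DenoiseClusterMetadata:
    dc_id: str
    qm_id: str
    method_name: str
    software_and_version: str = ""
    parameters: str = ""
    chimera_method: str = ""
    chimera_parameters: str = ""


@dataclass
class FeatureOutput:
    feature_id: str
    dc_id: str
    sequence: str


@dataclass
class FeatureRead:
    feature_id: str
    extraction_id: str
    read_count: int


@dataclass
class TaxonNode:
    node_id: str
    rank: str
    name: str
    parent_id: str  # "" at domain level


@dataclass
class TaxonomicAnnotation:
    annotation_id: str
    feature_id: str
    reference_db_name: str
    reference_db_version: str
    method: str
    confidence: float
    assigned: dict = field(default_factory=dict)  # rank -> free-text name
    verified_node_id: str = ""


# ---------------------------------------------------------------------------
# processing metadata


def record_quality_step(
    store,
    fastq_file_ids: Sequence[str],
    *,
    min_read_length: int,
    max_read_length: int,
    trim_fwd: int = 0,
    trim_rev: int = 0,
    min_quality: float = 0.0,
    **attrs,
) -> QualityMetadata:
    for fid in fastq_file_ids:
        if fid not in store.tables["fastq_files"]:
            raise NotFoundError(f"unknown fastq record {fid!r}")
    if not 0 < min_read_length <= max_read_length:
        raise ValidationError(
            f"read-length window {min_read_length}-{max_read_length} invalid"
        )
    if trim_fwd < 0 or trim_rev < 0:
        raise ValidationError("trim lengths cannot be negative")
    qm = QualityMetadata(
        qm_id=store.next_id("quality_meta", "qm"),
        fastq_file_ids=sorted(fastq_file_ids),
        min_read_length=int(min_read_length),
        max_read_length=int(max_read_length),
        trim_fwd=int(trim_fwd),
        trim_rev=int(trim_rev),
        min_quality=float(min_quality),
        **attrs,
    )
    store.tables["quality_meta"][qm.qm_id] = qm
    return qm


def record_denoise_step(store, qm_id: str, method_name: str, **attrs) -> DenoiseClusterMetadata:
    if qm_id not in store.tables["quality_meta"]:
        raise NotFoundError(f"unknown quality-metadata record {qm_id!r}")
    if not store.registry.has("denoise_cluster_method", method_name):
        raise ValidationError(f"unknown denoise/cluster method {method_name!r}")
    dc = DenoiseClusterMetadata(
        dc_id=store.next_id("denoise_meta", "dc"), qm_id=qm_id, method_name=method_name, **attrs
    )
    store.tables["denoise_meta"][dc.dc_id] = dc
    return dc


def register_features(store, dc_id: str, features: Sequence[tuple[str, str]]) -> int:
    """Register (feature_id, sequence) pairs under one denoise/cluster step."""
    if dc_id not in store.tables["denoise_meta"]:
        raise NotFoundError(f"unknown denoise/cluster record {dc_id!r}")
    for fid, seq in features:
        if fid in store.tables["features"]:
            raise DuplicateError(f"feature {fid!r} already registered")
        _check_dna(seq, IUPAC_DNA, f"feature {fid}")
    for fid, seq in features:
        store.tables["features"][fid] = FeatureOutput(fid, dc_id, seq.upper())
    return len(features)


def add_feature_reads(store, reads: Sequence[tuple[str, str, int]]) -> int:
    """Add (feature_id, extraction_id, read_count) cells; duplicates rejected."""
    for fid, eid, count in reads:
        if fid not in store.tables["features"]:
            raise NotFoundError(f"unknown feature {fid!r}")
        if eid not in store.tables["extractions"]:
            raise NotFoundError(f"unknown extraction {eid!r}")
        if count < 0:
            raise ValidationError(f"read count {count} for ({fid}, {eid}) is negative")
        if (fid, eid) in store.tables["feature_reads"]:
            raise DuplicateError(f"feature read ({fid!r}, {eid!r}) already stored")
    new = {}
    for fid, eid, count in reads:
        if (fid, eid) in new:
            raise DuplicateError(f"feature read ({fid!r}, {eid!r}) repeated in batch")
        new[(fid, eid)] = FeatureRead(fid, eid, int(count))
    store.tables["feature_reads"].update(new)
    return len(new)


def export_feature_table(store, dc_id: str) -> pd.DataFrame:
    """Features × extractions read-count matrix for one denoise/cluster step.

    Rows are this step's features, columns all extractions in the store,
    both in lexicographic id order; absent cells are 0. An empty step
    yields a 0×0 frame. The cell total equals the stored read-count total.
    """
    if dc_id not in store.tables["denoise_meta"]:
        raise NotFoundError(f"unknown denoise/cluster record {dc_id!r}")
    feature_ids = sorted(
        f.feature_id for f in store.tables["features"].values() if f.dc_id == dc_id
    )
    if not feature_ids:
        return pd.DataFrame()
    extraction_ids = sorted(store.tables["extractions"])
    df = pd.DataFrame(0, index=feature_ids, columns=extraction_ids, dtype=int)
    for (fid, eid), fr in store.tables["feature_reads"].items():
        if fid in df.index:
            df.at[fid, eid] = fr.read_count
    df.index.name = "feature_id"
    return df


def write_feature_table_tsv(store, dc_id: str, path) -> None:
    df = export_feature_table(store, dc_id)
    if not df.empty:
        # header shows extraction barcodes; first column feature_id
        df = df.rename(
            columns={eid: store.tables["extractions"][eid].barcode for eid in df.columns}
        )
    df.to_csv(path, sep="\t")


def write_features_fasta(store, dc_id: str, handle) -> int:
    """Plain FASTA (60-column wrap) of one step's feature sequences."""
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w", encoding="utf-8")
        close = True
    try:
        n = 0
        for fid in sorted(
            f.feature_id for f in store.tables["features"].values() if f.dc_id == dc_id
        ):
            seq = store.tables["features"][fid].sequence
            handle.write(f">{fid}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")
            n += 1
        return n
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# taxonomy


def _lineage_names(lineage: dict | Sequence[Optional[str]]) -> list[Optional[str]]:
    if isinstance(lineage, dict):
        unknown = set(lineage) - set(RANKS)
        if unknown:
            raise ValidationError(f"unknown taxonomic rank(s) {sorted(unknown)}")
        names = [lineage.get(r) or None for r in RANKS]
    else:
        names = list(lineage) + [None] * (len(RANKS) - len(lineage))
    deepest = max((i for i, n in enumerate(names) if n), default=-1)
    for i in range(deepest + 1):
        if not names[i]:
            raise ValidationError(
                f"lineage has a gap at rank {RANKS[i]!r} below an assigned "
                f"{RANKS[deepest]!r}; ranks must fill contiguously from domain down"
            )
    if deepest < 0:
        raise ValidationError("empty lineage")
    return names[: deepest + 1]


def upsert_lineage(store, lineage) -> str:
    """Insert a lineage, sharing nodes on common prefixes; returns the deepest node id.

    ``lineage`` is a dict rank→name or an ordered sequence of names from
    domain downward. Ranks below the deepest assigned one stay empty;
    a gap (e.g. a genus without a family) is rejected.
    """
    names = _lineage_names(lineage)
    parent_id = ""
    node_id = ""
    for rank, name in zip(RANKS, names):
        key = (parent_id, rank, name)
        existing = store.taxon_index.get(key)
        if existing is None:
            node_id = store.next_id("taxon_nodes", "tax")
            store.tables["taxon_nodes"][node_id] = TaxonNode(node_id, rank, name, parent_id)
            store.taxon_index[key] = node_id
        else:
            node_id = existing
        parent_id = node_id
    return node_id


def lineage_of_node(store, node_id: str) -> dict:
    """Rank→name path from the root down to ``node_id``."""
    node = store.tables["taxon_nodes"].get(node_id)
    if node is None:
        raise NotFoundError(f"unknown taxonomy node {node_id!r}")
    path = {}
    while node is not None:
        path[node.rank] = node.name
        node = store.tables["taxon_nodes"].get(node.parent_id)
    return {r: path[r] for r in RANKS if r in path}


def all_leaf_lineages(store) -> list[dict]:
    """Root-to-leaf paths of the whole curated taxonomy."""
    parents = {n.parent_id for n in store.tables["taxon_nodes"].values()}
    leaves = [nid for nid in store.tables["taxon_nodes"] if nid not in parents]
    return sorted(
        (lineage_of_node(store, nid) for nid in leaves),
        key=lambda d: tuple(d.get(r, "") for r in RANKS),
    )


def annotate_feature(
    store,
    feature_id: str,
    *,
    reference_db_name: str,
    reference_db_version: str,
    method: str,
    confidence: float,
    assigned: dict,
) -> TaxonomicAnnotation:
    if feature_id not in store.tables["features"]:
        raise NotFoundError(f"unknown feature {feature_id!r}")
    entry = store.registry.lookup("annotation_method", method)
    scale = entry.extra.get("confidence_scale", "unit-interval")
    if scale == "unit-interval" and not 0.0 <= confidence <= 1.0:
        raise ValidationError(
            f"confidence {confidence} outside [0, 1] for method {method!r}"
        )
    if scale == "bitscore" and confidence < 0:
        raise ValidationError(f"bitscore {confidence} cannot be negative")
    unknown = set(assigned) - set(RANKS)
    if unknown:
        raise ValidationError(f"assigned lineage has unknown rank(s) {sorted(unknown)}")
    ann = TaxonomicAnnotation(
        annotation_id=store.next_id("annotations", "ann"),
        feature_id=feature_id,
        reference_db_name=reference_db_name,
        reference_db_version=reference_db_version,
        method=method,
        confidence=float(confidence),
        assigned=dict(assigned),
    )
    store.tables["annotations"][ann.annotation_id] = ann
    return ann


def verify_annotation(store, annotation_id: str, node_id: str) -> TaxonomicAnnotation:
    ann = store.tables["annotations"].get(annotation_id)
    if ann is None:
        raise NotFoundError(f"unknown annotation {annotation_id!r}")
    if node_id not in store.tables["taxon_nodes"]:
        raise NotFoundError(f"unknown taxonomy node {node_id!r}")
    ann.verified_node_id = node_id
    return ann
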