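"""Wet-lab processing chain.

extraction → (qPCR/ddPCR with replicates | library prep with a primer pair
and an i7/i5 index pair) → pooled library → run prep → run result → FASTQ
file records.

Extractions and pooled libraries are barcoded things in their own right:
recording one mints a fresh label in the parent sample's (site, year) scope
using a configured derived-material letter (``e`` / ``p`` by default).

FASTQ files are opaque here — only filename, SHA-256 checksum and size are
captured; the provenance chain, not the reads, is the data. ``lineage``
walks a FASTQ record back hop by hop to the field site (or to an "other"
site survey) and names the first missing hop when the chain is broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_letters

from .errors import (
    AmbiguityError,
    DemultiplexConflictError,
    DuplicateError,
    LineageError,
    NotFoundError,
    ValidationError,
)
from .ident import LabelRequest, format_barcode, parse_barcode

IUPAC_DNA = set(ambiguous_dna_letters)  # ACGT plus ambiguity codes
STRICT_DNA = set("ACGT")


def _check_dna(seq: str, alphabet: set, what: str) -> None:
    bad = set(seq.upper()) - alphabet
    if not seq or bad:
        raise ValidationError(f"{what} {seq!r} is not DNA over {''.join(sorted(alphabet))}")


@dataclass
class Extraction:
    extraction_id: str
    barcode: str  # the extraction's own minted label
    field_sample_id: str
    method: str
    process_location: str
    sop: str
    final_volume_ul: float
    concentration_ng_per_ul: float
    is_negative_control: bool = False


@dataclass
class PrimerPair:
    primer_pair_id: str
    name: str
    target_gene: str
    forward_seq: str
    reverse_seq: str
    amplicon_min_bp: int
    amplicon_max_bp: int

    def __post_init__(self) -> None:
        _check_dna(self.forward_seq, IUPAC_DNA, "forward primer")
        _check_dna(self.reverse_seq, IUPAC_DNA, "reverse primer")
        if not 0 < self.amplicon_min_bp <= self.amplicon_max_bp:
            raise ValidationError(
                f"amplicon range {self.amplicon_min_bp}-{self.amplicon_max_bp} invalid"
            )


@dataclass
class Pcr:
    pcr_id: str
    extraction_id: str
    pcr_type: str  # qpcr | ddpcr
    primer_pair_id: str
    replicates: list[dict] = field(default_factory=list)  # {replicate_no, value, unit}
    process_location: str = ""
    sop: str = ""


@dataclass
class IndexPair:
    index_pair_id: str
    i7_seq: str
    i5_seq: str
    adapter: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.i7_seq, STRICT_DNA, "i7 index")
        _check_dna(self.i5_seq, STRICT_DNA, "i5 index")


@dataclass
class LibraryPrep:
    lib_id: str
    extraction_id: str
    primer_pair_id: str
    index_pair_id: str
    amplification_method: str = ""
    quantification_method: str = ""
    size_selection_method: str = ""
    index_removal_method: str = ""
    concentration_ng_per_ul: float = 0.0
    lib_layout: str = "paired"


@dataclass
class PooledLibrary:
    pool_id: str
    barcode: str
    member_lib_ids: list[str] = field(default_factory=list)


@dataclass
class RunPrep:
    prep_id: str
    pool_ids: list[str] = field(default_factory=list)
    library_conc_pm: float = 0.0
    standard_conc_pm: float = 0.0
    kit: str = ""


@dataclass
class RunResult:
    run_id: str
    prep_id: str
    run_date: str
    completion_date: str = ""


@dataclass
class FastqFile:
    file_id: str
    run_id: str
    filename: str
    checksum_sha256: str
    size_bytes: int = 0
    extraction_id: str = ""  # optional attribution


# ---------------------------------------------------------------------------
# operations


def _mint_derived_barcode(store, sample_barcode: str, entity: str) -> str:
    """Mint a label for an extraction or pooled library in the sample's scope."""
    parts = parse_barcode(sample_barcode)
    material = store.registry.derived_material_codes.get(entity)
    if material is None:
        raise ValidationError(f"no derived material code configured for {entity!r}")
    req = LabelRequest(
        site=parts.site,
        year=parts.year,
        material_code=material,
        count=1,
        created_at=store.clock() if hasattr(store, "clock") else "",
    )
    [minted] = store.labels.fulfill_label_request(req)
    return format_barcode(minted)


def record_extraction(
    store,
    field_sample_barcode: str,
    *,
    method: str = "",
    process_location: str = "",
    sop: str = "",
    final_volume_ul: float,
    concentration_ng_per_ul: float = 0.0,
    is_negative_control: bool = False,
) -> Extraction:
    label = store.labels.get(field_sample_barcode)
    if label is None or not label.assigned:
        raise NotFoundError(
            f"{field_sample_barcode!r} is not an assigned field-sample barcode"
        )
    sample = store.tables["samples"].get(label.assigned_to)
    if sample is None:
        raise NotFoundError(f"barcode {field_sample_barcode!r} binds no field sample")
    if final_volume_ul <= 0:
        raise ValidationError("final solution volume must be positive")
    if concentration_ng_per_ul < 0:
        raise ValidationError("DNA concentration cannot be negative")
    ext = Extraction(
        extraction_id=store.next_id("extractions", "ext"),
        barcode=_mint_derived_barcode(store, field_sample_barcode, "extraction"),
        field_sample_id=sample.sample_id,
        method=method,
        process_location=process_location,
        sop=sop,
        final_volume_ul=float(final_volume_ul),
        concentration_ng_per_ul=float(concentration_ng_per_ul),
        is_negative_control=is_negative_control,
    )
    store.tables["extractions"][ext.extraction_id] = ext
    store.labels.assign(ext.barcode, ext.extraction_id)
    return ext


def add_primer_pair(store, **attrs) -> PrimerPair:
    pp = PrimerPair(primer_pair_id=store.next_id("primer_pairs", "prm"), **attrs)
    store.tables["primer_pairs"][pp.primer_pair_id] = pp
    return pp


def add_index_pair(store, i7_seq: str, i5_seq: str, adapter: str = "") -> IndexPair:
    ip = IndexPair(
        index_pair_id=store.next_id("index_pairs", "idx"),
        i7_seq=i7_seq.upper(),
        i5_seq=i5_seq.upper(),
        adapter=adapter,
    )
    store.tables["index_pairs"][ip.index_pair_id] = ip
    return ip


def record_pcr(
    store,
    extraction_id: str,
    pcr_type: str,
    primer_pair_id: str,
    replicates: list[dict],
    process_location: str = "",
    sop: str = "",
) -> Pcr:
    if extraction_id not in store.tables["extractions"]:
        raise NotFoundError(f"unknown extraction {extraction_id!r}")
    if not store.registry.has("pcr_type", pcr_type):
        raise ValidationError(f"unknown PCR type {pcr_type!r}")
    if primer_pair_id not in store.tables["primer_pairs"]:
        raise NotFoundError(f"unknown primer pair {primer_pair_id!r}")
    if not replicates:
        raise ValidationError("a PCR needs at least one replicate")
    nos = [r["replicate_no"] for r in replicates]
    if len(nos) != len(set(nos)):
        raise ValidationError("replicate numbers must be unique")
    pcr = Pcr(
        pcr_id=store.next_id("pcrs", "pcr"),
        extraction_id=extraction_id,
        pcr_type=pcr_type,
        primer_pair_id=primer_pair_id,
        replicates=[dict(r) for r in replicates],
        process_location=process_location,
        sop=sop,
    )
    store.tables["pcrs"][pcr.pcr_id] = pcr
    return pcr


def build_library(
    store,
    extraction_id: str,
    primer_pair_id: str,
    index_pair_id: str,
    *,
    lib_layout: str = "paired",
    concentration_ng_per_ul: float = 0.0,
    **methods,
) -> LibraryPrep:
    for table, key in (
        ("extractions", extraction_id),
        ("primer_pairs", primer_pair_id),
        ("index_pairs", index_pair_id),
    ):
        if key not in store.tables[table]:
            raise NotFoundError(f"unknown {table[:-1]} {key!r}")
    if not store.registry.has("lib_layout", lib_layout):
        raise ValidationError(f"unknown library layout {lib_layout!r}")
    if concentration_ng_per_ul < 0:
        raise ValidationError("library concentration cannot be negative")
    lib = LibraryPrep(
        lib_id=store.next_id("libraries", "lib"),
        extraction_id=extraction_id,
        primer_pair_id=primer_pair_id,
        index_pair_id=index_pair_id,
        lib_layout=lib_layout,
        concentration_ng_per_ul=float(concentration_ng_per_ul),
        **methods,
    )
    store.tables["libraries"][lib.lib_id] = lib
    return lib


def pool_libraries(store, lib_ids: list[str]) -> PooledLibrary:
    if not lib_ids:
        raise ValidationError("a pooled library needs at least one member")
    libs = []
    for lid in lib_ids:
        lib = store.tables["libraries"].get(lid)
        if lib is None:
            raise NotFoundError(f"unknown library {lid!r}")
        libs.append(lib)
    seen: dict[tuple[str, str], str] = {}
    for lib in libs:
        ip = store.tables["index_pairs"][lib.index_pair_id]
        key = (ip.i7_seq, ip.i5_seq)
        if key in seen:
            raise DemultiplexConflictError(
                f"libraries {seen[key]} and {lib.lib_id} share index pair "
                f"i7={ip.i7_seq} i5={ip.i5_seq}; the pool could not be demultiplexed"
            )
        seen[key] = lib.lib_id
    # derive the pool's barcode scope from its first member's field sample
    first_ext = store.tables["extractions"][libs[0].extraction_id]
    pool = PooledLibrary(
        pool_id=store.next_id("pools", "pol"),
        barcode=_mint_derived_barcode(
            store, store.tables["samples"][first_ext.field_sample_id].barcode, "pooled_library"
        ),
        member_lib_ids=sorted(lib_ids),
    )
    store.tables["pools"][pool.pool_id] = pool
    store.labels.assign(pool.barcode, pool.pool_id)
    return pool


def record_run(
    store,
    pool_ids: list[str],
    *,
    run_date: str,
    completion_date: str = "",
    library_conc_pm: float = 0.0,
    standard_conc_pm: float = 0.0,
    kit: str = "",
) -> RunResult:
    if not pool_ids:
        raise ValidationError("a run prep needs at least one pooled library")
    for pid in pool_ids:
        if pid not in store.tables["pools"]:
            raise NotFoundError(f"unknown pooled library {pid!r}")
    prep = RunPrep(
        prep_id=store.next_id("run_preps", "prp"),
        pool_ids=sorted(pool_ids),
        library_conc_pm=float(library_conc_pm),
        standard_conc_pm=float(standard_conc_pm),
        kit=kit,
    )
    store.tables["run_preps"][prep.prep_id] = prep
    run = RunResult(
        run_id=store.next_id("runs", "run"),
        prep_id=prep.prep_id,
        run_date=run_date,
        completion_date=completion_date,
    )
    store.tables["runs"][run.run_id] = run
    return run


def attach_fastq(
    store,
    run_id: str,
    filename: str,
    checksum_sha256: str,
    size_bytes: int = 0,
    extraction_id: str = "",
) -> FastqFile:
    if run_id not in store.tables["runs"]:
        raise NotFoundError(f"unknown run {run_id!r}")
    if extraction_id and extraction_id not in store.tables["extractions"]:
        raise NotFoundError(f"unknown extraction {extraction_id!r}")
    for other in store.tables["fastq_files"].values():
        if other.run_id == run_id and other.filename == filename:
            raise DuplicateError(f"run {run_id} already has a file named {filename!r}")
    fq = FastqFile(
        file_id=store.next_id("fastq_files", "fq"),
        run_id=run_id,
        filename=filename,
        checksum_sha256=checksum_sha256,
        size_bytes=int(size_bytes),
        extraction_id=extraction_id,
    )
    store.tables["fastq_files"][fq.file_id] = fq
    return fq


# ---------------------------------------------------------------------------
# lineage


def _resolve_extraction_for_fastq(store, fastq: FastqFile, prep: RunPrep):
    """The single extraction a FASTQ attributes to, or raise."""
    if fastq.extraction_id:
        ext = store.tables["extractions"].get(fastq.extraction_id)
        if ext is None:
            raise LineageError(
                f"fastq {fastq.file_id}: extraction {fastq.extraction_id} missing",
                missing_hop="extraction",
            )
        return ext
    member_libs: list[str] = []
    for pid in prep.pool_ids:
        pool = store.tables["pools"].get(pid)
        if pool is not None:
            member_libs.extend(pool.member_lib_ids)
    if len(member_libs) != 1:
        raise AmbiguityError(
            f"fastq {fastq.file_id} names no extraction and its run pools "
            f"{len(member_libs)} libraries; attribution is ambiguous"
        )
    lib = store.tables["libraries"].get(member_libs[0])
    if lib is None:
        raise LineageError(
            f"fastq {fastq.file_id}: library {member_libs[0]} missing", missing_hop="library"
        )
    ext = store.tables["extractions"].get(lib.extraction_id)
    if ext is None:
        raise LineageError(
            f"fastq {fastq.file_id}: extraction {lib.extraction_id} missing",
            missing_hop="extraction",
        )
    return ext


def lineage(store, fastq_file_id: str) -> list:
    """Full provenance chain for one FASTQ record.

    Returns ``[FastqFile, RunResult, RunPrep, PooledLibrary, LibraryPrep,
    Extraction, FieldSample, FieldCollection, FieldSurvey]`` plus the
    :class:`~medna.fieldcore.FieldSite` when the survey references one.
    """
    fastq = store.tables["fastq_files"].get(fastq_file_id)
    if fastq is None:
        raise NotFoundError(f"unknown fastq record {fastq_file_id!r}")
    run = store.tables["runs"].get(fastq.run_id)
    if run is None:
        raise LineageError(f"fastq {fastq_file_id}: run missing", missing_hop="run")
    prep = store.tables["run_preps"].get(run.prep_id)
    if prep is None:
        raise LineageError(f"run {run.run_id}: run prep missing", missing_hop="run_prep")
    ext = _resolve_extraction_for_fastq(store, fastq, prep)
    # the pool and library on the path to this extraction
    lib = None
    pool = None
    for pid in prep.pool_ids:
        p = store.tables["pools"].get(pid)
        if p is None:
            continue
        for lid in p.member_lib_ids:
            cand = store.tables["libraries"].get(lid)
            if cand is not None and cand.extraction_id == ext.extraction_id:
                pool, lib = p, cand
                break
        if lib is not None:
            break
    if pool is None:
        raise LineageError(
            f"fastq {fastq_file_id}: no pooled library on this run contains a library "
            f"of extraction {ext.extraction_id}",
            missing_hop="pooled_library",
        )
    sample = store.tables["samples"].get(ext.field_sample_id)
    if sample is None:
        raise LineageError(
            f"extraction {ext.extraction_id}: field sample missing", missing_hop="field_sample"
        )
    coll = store.tables["collections"].get(sample.collection_id)
    if coll is None:
        raise LineageError(
            f"sample {sample.sample_id}: collection missing", missing_hop="field_collection"
        )
    survey = store.tables["surveys"].get(coll.survey_id)
    if survey is None:
        raise LineageError(
            f"collection {coll.collection_id}: survey missing", missing_hop="field_survey"
        )
    chain = [fastq, run, prep, pool, lib, ext, sample, coll, survey]
    if survey.site_id:
        site = store.tables["sites"].get(survey.site_id)
        if site is None:
            raise LineageError(
                f"survey {survey.survey_id}: site {survey.site_id} missing",
                missing_hop="field_site",
            )
        chain.append(site)
    return chain
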