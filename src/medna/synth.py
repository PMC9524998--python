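"""Deterministic synthetic fixtures spanning every module.

The generator builds a fully populated store — toy region polygons, minted
sites, surveys with multi-depth measurements, water/sediment collections
(one negative field control per site), barcoded samples, complete wet-lab
chains down to FASTQ records, processing metadata with features and read
counts, curated taxonomy with annotations, and a freezer ledger with one
check-out/return cycle per extraction — without touching the network or any
real data source.

Determinism contract: the same :class:`FixtureSpec` always produces a store
with an identical digest. Each entity family draws from its own pseudo-
random stream seeded as ``"{seed}:{family}"``, so adding a new family later
never perturbs the values an existing family generates.

``defect_rate`` seeds *validation* defects for negative tests: the chosen
fraction of sites (at least one) lose their EnvO terms, which surfaces as
mandatory-field violations in the MIxS checklist report. With
``defect_rate=0`` every module invariant holds and the store passes the
full integrity scan.

Measurement values are plain uniform draws over plausible instrument
ranges; the fixtures emulate structure and referential topology, not the
statistics of real water chemistry.
"""

from __future__ import annotations

import hashlib
import math
import random
from dataclasses import dataclass

from . import bioinfo, fieldcore, freezer, wetlab
from .errors import ValidationError
from .ident import BARCODE_SEQ_MAX, LabelRequest, SITE_SEQ_MAX, format_site_id
from .regions import RegionPolygon, RegionSet, assign_region
from .store import Store
from .vocab import load_defaults

FIXTURE_YEAR = 21  # two-digit collection year used throughout
N_FEATURES = 5
CREW = ("avery", "blake", "casey", "devon", "emerson", "finley")
MEASURE_TYPES = ("water-temp", "salinity", "ph", "do")
RETURN_ACTIONS = ("extraction", "pcr", "library-prep", "none")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 7
    n_sites: int = 2
    n_surveys_per_site: int = 2
    n_samples_per_survey: int = 3
    n_runs: int = 1
    water_fraction: float = 0.5
    defect_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_surveys_per_site", "n_samples_per_survey", "n_runs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValidationError("water_fraction must lie in [0, 1]")
        if not 0.0 <= self.defect_rate <= 1.0:
            raise ValidationError("defect_rate must lie in [0, 1]")

    def n_water_per_survey(self) -> int:
        return round(self.water_fraction * self.n_samples_per_survey)


def _stream(spec: FixtureSpec, family: str) -> random.Random:
    return random.Random(f"{spec.seed}:{family}")


def toy_region_set() -> RegionSet:
    """Four rectangular watersheds (one legacy 2-char) plus one marine area."""

    def rect(code, name, kind, lon0, lat0, dlon=1.0, dlat=1.0, legacy=False):
        ring = [
            (lon0, lat0),
            (lon0 + dlon, lat0),
            (lon0 + dlon, lat0 + dlat),
            (lon0, lat0 + dlat),
            (lon0, lat0),
        ]
        return RegionPolygon(code, name, kind, [ring], legacy=legacy)

    return RegionSet(
        [
            rect("ME", "Legacy Maine watershed", "watershed", -70.0, 44.0, legacy=True),
            rect("AND", "Androscoggin-like watershed", "watershed", -69.0, 44.0),
            rect("KEN", "Kennebec-like watershed", "watershed", -70.0, 45.0),
            rect("PEN", "Penobscot-like watershed", "watershed", -69.0, 45.0),
            rect("GOM", "Gulf-of-Maine-like marine area", "marine", -70.0, 42.0, 2.0, 1.5),
        ]
    )


def expected_counts(spec: FixtureSpec) -> dict[str, int]:
    """Closed-form entity counts the generated store must match exactly."""
    surveys = spec.n_sites * spec.n_surveys_per_site
    samples = surveys * spec.n_samples_per_survey
    n_water = spec.n_water_per_survey()
    n_sed = spec.n_samples_per_survey - n_water
    kinds_per_survey = (1 if n_water else 0) + (1 if n_sed else 0)
    runs = min(spec.n_runs, surveys)
    return {
        "sites": spec.n_sites,
        "surveys": surveys,
        "measurements": surveys * 2 * len(MEASURE_TYPES),
        "collections": surveys * kinds_per_survey + spec.n_sites,  # + negative controls
        "samples": samples,
        "extractions": samples,
        "libraries": samples,
        "pools": surveys,
        "run_preps": runs,
        "runs": runs,
        "fastq_files": samples,
        "features": N_FEATURES,
        "feature_reads": N_FEATURES * samples,
        "labels": samples + samples + surveys,  # sample + extraction + pool labels
        "inventory_log": samples * 3,  # add, check_out, return per extraction
    }


def _check_capacity(spec: FixtureSpec) -> None:
    regions = toy_region_set()
    per_scope_sites = math.ceil(spec.n_sites / len(regions.codes))
    if per_scope_sites > SITE_SEQ_MAX:
        raise ValidationError("spec exceeds the two-digit site sequence capacity")
    per_scope_labels = spec.n_surveys_per_site * spec.n_samples_per_survey * 2
    if per_scope_labels > BARCODE_SEQ_MAX:
        raise ValidationError("spec exceeds the four-digit barcode sequence capacity")


def _index_seq(n: int) -> str:
    # unique deterministic 8-mer per integer (base-4 encoding)
    letters = "ACGT"
    return "".join(letters[(n >> (2 * k)) & 3] for k in range(8))


def generate_fixture(spec: FixtureSpec) -> Store:
    _check_capacity(spec)
    regions = toy_region_set()
    store = Store(registry=load_defaults(), regions=regions)
    tick = [0]

    def clock() -> str:
        tick[0] += 1
        return f"20{FIXTURE_YEAR}-06-01T{tick[0] // 3600:02d}:{(tick[0] // 60) % 60:02d}:{tick[0] % 60:02d}+00:00"

    store.clock = clock
    store.grant_role("alice", "admin")
    store.grant_role("gina", "graduate")
    store.grant_role("ivan", "intern")

    site_rng = _stream(spec, "sites")
    survey_rng = _stream(spec, "surveys")
    meas_rng = _stream(spec, "measurements")
    reads_rng = _stream(spec, "feature_reads")
    seq_rng = _stream(spec, "sequences")
    inv_rng = _stream(spec, "inventory")

    n_defect_sites = 0
    if spec.defect_rate > 0:
        n_defect_sites = max(1, round(spec.defect_rate * spec.n_sites))

    # -- sites ----------------------------------------------------------
    region_codes = regions.codes
    site_records = []
    for i in range(spec.n_sites):
        code = region_codes[i % len(region_codes)]
        poly = regions.get(code)
        ring = poly.rings[0]
        lon = site_rng.uniform(min(p[0] for p in ring) + 0.1, max(p[0] for p in ring) - 0.1)
        lat = site_rng.uniform(min(p[1] for p in ring) + 0.1, max(p[1] for p in ring) - 0.1)
        assigned_code = assign_region((lon, lat), regions)
        system = "C" if poly.kind == "marine" else "L"
        parts = store.sites.mint("p", assigned_code, system, registry=store.registry)
        defective = i < n_defect_sites
        site = fieldcore.FieldSite(
            site_id=format_site_id(parts),
            lon=round(lon, 5),
            lat=round(lat, 5),
            envo_biome="" if defective else "freshwater lake biome [ENVO:01000252]",
            envo_feature="" if defective else "lake [ENVO:00000020]",
            general_location_name=f"{poly.name} station {i + 1}",
        )
        store.tables["sites"][site.site_id] = site
        site_records.append(site)

    # -- shared wet-lab reference records --------------------------------
    primer = wetlab.add_primer_pair(
        store,
        name="18S-V9",
        target_gene="18S rRNA V9",
        forward_seq="TTGTACACACCGCCC",
        reverse_seq="CCTTCYGCAGGTTCACCTAC",
        amplicon_min_bp=120,
        amplicon_max_bp=160,
    )

    # -- surveys, collections, samples, wet lab --------------------------
    n_water = spec.n_water_per_survey()
    pools = []
    extraction_of_sample: dict[str, str] = {}
    for si, site in enumerate(site_records):
        for vi in range(spec.n_surveys_per_site):
            day = 1 + (si * spec.n_surveys_per_site + vi) % 28
            survey = fieldcore.create_survey(
                store,
                site_id=site.site_id,
                datetime_iso=f"20{FIXTURE_YEAR}-06-{day:02d}T09:00:00+00:00",
                recorders=sorted(survey_rng.sample(CREW, 2)),
                projects=["maine-edna"],
            )
            for depth in (0.0, 10.0):
                for mtype in MEASURE_TYPES:
                    fieldcore.attach_measurement(
                        store,
                        survey.survey_id,
                        depth,
                        mtype,
                        round(meas_rng.uniform(0.0, 30.0), 2),
                    )
            if vi == 0:  # one negative field control collection per site
                fieldcore.create_collection(
                    store,
                    survey.survey_id,
                    "water",
                    "negative_control",
                    {"volume_filtered_ml": 0.0},
                )
            colls = {}
            if n_water:
                colls["filter"] = fieldcore.create_collection(
                    store,
                    survey.survey_id,
                    "water",
                    "true_sample",
                    {"volume_filtered_ml": 1000.0, "storage_duration_h": 2.0},
                )
            if spec.n_samples_per_survey - n_water:
                colls["subcore"] = fieldcore.create_collection(
                    store,
                    survey.survey_id,
                    "sediment",
                    "true_sample",
                    {"core_method": "gravity", "subdivision_method": "slice"},
                )
            # mint this survey's labels in one batch request per material
            site_parts = store.sites.get(site.site_id)
            kinds = ["filter"] * n_water + ["subcore"] * (
                spec.n_samples_per_survey - n_water
            )
            labels = {}
            for material, count in (("w", n_water), ("s", len(kinds) - n_water)):
                if count:
                    minted = store.labels.fulfill_label_request(
                        LabelRequest(
                            site=site_parts,
                            year=FIXTURE_YEAR,
                            material_code=material,
                            count=count,
                            requester="alice",
                            created_at=store.clock(),
                        )
                    )
                    labels[material] = [wetlab.format_barcode(p) for p in minted]
            lib_ids = []
            for kind in kinds:
                material = "w" if kind == "filter" else "s"
                barcode = labels[material].pop(0)
                payload = (
                    {"filter_material": "cellulose nitrate", "pore_size_um": 0.45}
                    if kind == "filter"
                    else {"method": "slice", "length_cm": 5.0, "diameter_cm": 6.0, "number": 1}
                )
                sample = fieldcore.register_sample(
                    store, colls[kind].collection_id, barcode, kind, payload
                )
                ext = wetlab.record_extraction(
                    store,
                    barcode,
                    method="spin-column",
                    process_location="UMAINE",
                    final_volume_ul=100.0,
                    concentration_ng_per_ul=round(seq_rng.uniform(0.5, 20.0), 2),
                )
                extraction_of_sample[sample.sample_id] = ext.extraction_id
                ip = wetlab.add_index_pair(
                    store,
                    i7_seq=_index_seq(2 * len(store.tables["libraries"])),
                    i5_seq=_index_seq(2 * len(store.tables["libraries"]) + 1),
                    adapter="CTGTCTCTTATACACATCT",
                )
                lib = wetlab.build_library(
                    store,
                    ext.extraction_id,
                    primer.primer_pair_id,
                    ip.index_pair_id,
                    lib_layout="paired",
                    concentration_ng_per_ul=round(seq_rng.uniform(1.0, 10.0), 2),
                    amplification_method="pcr-35cyc",
                    quantification_method="fluorometry",
                )
                lib_ids.append(lib.lib_id)
            pools.append(wetlab.pool_libraries(store, lib_ids))

    # -- runs and FASTQ records ------------------------------------------
    n_runs = min(spec.n_runs, len(pools))
    run_of_pool: dict[str, str] = {}
    for ri in range(n_runs):
        member_pools = [p for pi, p in enumerate(pools) if pi % n_runs == ri]
        run = wetlab.record_run(
            store,
            [p.pool_id for p in member_pools],
            run_date=f"20{FIXTURE_YEAR}-07-{ri + 1:02d}T00:00:00+00:00",
            completion_date=f"20{FIXTURE_YEAR}-07-{ri + 2:02d}T00:00:00+00:00",
            library_conc_pm=4.0,
            standard_conc_pm=12.5,
            kit="MiSeq Reagent Kit v3",
        )
        for pool in member_pools:
            run_of_pool[pool.pool_id] = run.run_id
    fastq_ids = []
    for pool in pools:
        for lid in pool.member_lib_ids:
            lib = store.tables["libraries"][lid]
            ext = store.tables["extractions"][lib.extraction_id]
            sample = store.tables["samples"][ext.field_sample_id]
            filename = f"{sample.barcode}_R1.fastq.gz"
            checksum = hashlib.sha256(filename.encode()).hexdigest()
            fq = wetlab.attach_fastq(
                store,
                run_of_pool[pool.pool_id],
                filename,
                checksum,
                size_bytes=1_000_000 + 1000 * len(fastq_ids),
                extraction_id=ext.extraction_id,
            )
            fastq_ids.append(fq.file_id)

    # -- bioinformatics metadata -----------------------------------------
    qm = bioinfo.record_quality_step(
        store,
        fastq_ids,
        min_read_length=100,
        max_read_length=150,
        trim_fwd=15,
        trim_rev=20,
        min_quality=30,
        analyst="gina",
        analysis_datetime=store.clock(),
    )
    dc = bioinfo.record_denoise_step(
        store,
        qm.qm_id,
        "denoise-asv",
        software_and_version="dada2 1.30",
        parameters="pooled=FALSE",
        chimera_method="consensus",
    )
    features = [
        (f"asv{k + 1:03d}", "".join(seq_rng.choice("ACGT") for _ in range(120)))
        for k in range(N_FEATURES)
    ]
    bioinfo.register_features(store, dc.dc_id, features)
    reads = []
    for fid, _ in features:
        for eid in sorted(store.tables["extractions"]):
            reads.append((fid, eid, reads_rng.randrange(0, 5000)))
    bioinfo.add_feature_reads(store, reads)

    lineages = [
        {
            "domain": "Eukaryota",
            "kingdom": "Chromista",
            "supergroup": "Stramenopiles",
            "phylum_division": "Bacillariophyta",
            "class": "Bacillariophyceae",
            "order": "Naviculales",
            "family": "Naviculaceae",
            "genus": "Navicula",
            "species": "Navicula cryptocephala",
        },
        {
            "domain": "Eukaryota",
            "kingdom": "Chromista",
            "supergroup": "Stramenopiles",
            "phylum_division": "Bacillariophyta",
            "class": "Bacillariophyceae",
            "order": "Naviculales",
            "family": "Naviculaceae",
            "genus": "Navicula",
            "species": "Navicula radiosa",
        },
    ]
    nodes = [bioinfo.upsert_lineage(store, lin) for lin in lineages]
    ann = bioinfo.annotate_feature(
        store,
        features[0][0],
        reference_db_name="PR2",
        reference_db_version="4.14",
        method="naive-bayes",
        confidence=0.93,
        assigned=lineages[0],
    )
    bioinfo.verify_annotation(store, ann.annotation_id, nodes[0])

    # -- freezer ledger ---------------------------------------------------
    positions_per_box = 81  # 9 x 9 tube box
    for i, ext_id in enumerate(sorted(store.tables["extractions"])):
        ext = store.tables["extractions"][ext_id]
        loc = freezer.StorageLocation(
            freezer_id="F1",
            rack=1 + i // (positions_per_box * 5),
            box=1 + (i // positions_per_box) % 5,
            position=f"{chr(ord('A') + (i % positions_per_box) // 9)}{1 + i % 9}",
        )
        freezer.add_item(store, ext.barcode, loc, volume_ul=100.0, actor="gina")
        freezer.check_out(store, ext.barcode, actor="gina")
        freezer.return_item(
            store,
            ext.barcode,
            actions=[inv_rng.choice(RETURN_ACTIONS)],
            aliquot_volume_ul=float(inv_rng.randrange(0, 21)),
            actor="gina",
        )
    return store


# ---------------------------------------------------------------------------
# flat-record fixtures for ETL tests


def flat_records_fixture(
    seed: int = 7, n_rows: int = 5, defect_rate: float = 0.0
) -> tuple[Store, list[dict]]:
    """A small store plus denormalized field rows referencing its labels.

    The store holds minted sites and unassigned barcodes; the rows emulate a
    tablet export (two surveys' worth). ``defect_rate`` turns that fraction
    of rows (at least one) into bad-vocabulary rows for rejection tests.
    """
    rng = random.Random(f"{seed}:flat")
    regions = toy_region_set()
    store = Store(registry=load_defaults(), regions=regions)
    parts = store.sites.mint("p", "ME", "L", registry=store.registry)
    site = fieldcore.FieldSite(
        site_id=format_site_id(parts),
        lon=-69.5,
        lat=44.5,
        envo_biome="freshwater lake biome [ENVO:01000252]",
        envo_feature="lake [ENVO:00000020]",
        general_location_name="Toy lake",
    )
    store.tables["sites"][site.site_id] = site
    minted = store.labels.fulfill_label_request(
        LabelRequest(
            site=parts,
            year=FIXTURE_YEAR,
            material_code="w",
            count=n_rows,
            requester="alice",
            created_at="2021-06-01T00:00:00+00:00",
        )
    )
    n_bad = max(1, round(defect_rate * n_rows)) if defect_rate > 0 else 0
    rows = []
    for i, label in enumerate(minted):
        survey_no = i % 2  # rows interleave two surveys
        rows.append(
            {
                "site_id": site.site_id,
                "other_site_text": "",
                "survey_datetime": f"2021-06-{10 + survey_no:02d}T09:00:00+00:00",
                "recorders": "avery;blake",
                "projects": "maine-edna",
                "meas1_depth": "0",
                "meas1_type": "sparkle" if i < n_bad else "salinity",
                "meas1_value": str(round(rng.uniform(28.0, 33.0), 2)),
                "collection_kind": "water",
                "control_type": "true_sample",
                "collection_volume_filtered_ml": "1000",
                "sample_barcode": wetlab.format_barcode(label),
                "sample_kind": "filter",
                "sample_filter_material": "cellulose nitrate",
                "sample_pore_size_um": "0.45",
            }
        )
    return store, rows
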