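"""Processing metadata, feature table export, hierarchical taxonomy."""

import io

import pytest

from medna import bioinfo, errors
from medna.bioinfo import RANKS

LINEAGE = {
    "domain": "Eukaryota",
    "kingdom": "Chromista",
    "supergroup": "Stramenopiles",
    "phylum_division": "Bacillariophyta",
    "class": "Bacillariophyceae",
    "order": "Naviculales",
    "family": "Naviculaceae",
    "genus": "Navicula",
    "species": "Navicula cryptocephala",
}


def test_rank_list_is_the_nine_rank_hierarchy():
    assert RANKS == (
        "domain", "kingdom", "supergroup", "phylum_division", "class",
        "order", "family", "genus", "species",
    )


def test_quality_step_validation(fixture_store):
    with pytest.raises(errors.ValidationError):
        bioinfo.record_quality_step(
            fixture_store, [], min_read_length=200, max_read_length=100
        )
    with pytest.raises(errors.NotFoundError):
        bioinfo.record_quality_step(
            fixture_store, ["nope"], min_read_length=100, max_read_length=150
        )


def test_feature_registration_and_read_counts(fixture_store):
    dc_id = sorted(fixture_store.tables["denoise_meta"])[0]
    with pytest.raises(errors.ValidationError):
        bioinfo.register_features(fixture_store, dc_id, [("fX", "ACGQ")])
    eid = sorted(fixture_store.tables["extractions"])[0]
    fid = sorted(
        f.feature_id for f in fixture_store.tables["features"].values()
    )[0]
    with pytest.raises(errors.DuplicateError):
        bioinfo.add_feature_reads(fixture_store, [(fid, eid, 5)])
    with pytest.raises(errors.NotFoundError):
        bioinfo.add_feature_reads(fixture_store, [(fid, "extXXXXXX", 1)])
    other_eid = sorted(fixture_store.tables["extractions"])[1]
    dc_id = sorted(fixture_store.tables["denoise_meta"])[0]
    bioinfo.register_features(fixture_store, dc_id, [("negcount", "ACGT")])
    with pytest.raises(errors.ValidationError):
        bioinfo.add_feature_reads(fixture_store, [("negcount", other_eid, -1)])


def test_feature_table_matches_summation_oracle(store):
    """Matrix cells and totals equal a hand-built dict of stored counts."""
    from medna.synth import FixtureSpec, generate_fixture

    s = generate_fixture(FixtureSpec(seed=5, n_sites=1, n_surveys_per_site=1))
    dc_id = sorted(s.tables["denoise_meta"])[0]
    df = export = bioinfo.export_feature_table(s, dc_id)
    stored = {(fr.feature_id, fr.extraction_id): fr.read_count
              for fr in s.tables["feature_reads"].values()}
    assert int(df.to_numpy().sum()) == sum(stored.values())
    for (fid, eid), count in stored.items():
        assert df.at[fid, eid] == count
    assert list(df.index) == sorted(df.index)
    assert list(df.columns) == sorted(df.columns)
    # deterministic re-export
    buf1, buf2 = io.StringIO(), io.StringIO()
    bioinfo.export_feature_table(s, dc_id).to_csv(buf1, sep="\t")
    bioinfo.export_feature_table(s, dc_id).to_csv(buf2, sep="\t")
    assert buf1.getvalue() == buf2.getvalue()


def test_empty_denoise_step_gives_empty_matrix(fixture_store):
    qm_id = sorted(fixture_store.tables["quality_meta"])[0]
    dc = bioinfo.record_denoise_step(fixture_store, qm_id, "dereplicate")
    assert bioinfo.export_feature_table(fixture_store, dc.dc_id).shape == (0, 0)


def test_full_lineage_creates_one_node_per_rank(store):
    assert len(store.tables["taxon_nodes"]) == 0
    node = bioinfo.upsert_lineage(store, LINEAGE)
    assert len(store.tables["taxon_nodes"]) == 9
    assert store.tables["taxon_nodes"][node].rank == "species"


def test_sibling_species_adds_exactly_one_node(store):
    bioinfo.upsert_lineage(store, LINEAGE)
    sibling = dict(LINEAGE, species="Navicula radiosa")
    before = len(store.tables["taxon_nodes"])
    bioinfo.upsert_lineage(store, sibling)
    assert len(store.tables["taxon_nodes"]) == before + 1
    # idempotent re-insert
    bioinfo.upsert_lineage(store, sibling)
    assert len(store.tables["taxon_nodes"]) == before + 1


def test_rank_gap_is_rejected(store):
    gapped = dict(LINEAGE)
    gapped["family"] = ""
    with pytest.raises(errors.ValidationError, match="family"):
        bioinfo.upsert_lineage(store, gapped)


def test_partial_lineage_to_genus_is_accepted(store):
    partial = {k: v for k, v in LINEAGE.items() if k != "species"}
    node = bioinfo.upsert_lineage(store, partial)
    assert store.tables["taxon_nodes"][node].rank == "genus"


def test_root_to_leaf_roundtrip_recovers_input_set(store):
    lineages = [
        LINEAGE,
        dict(LINEAGE, species="Navicula radiosa"),
        dict(LINEAGE, genus="Pinnularia", species="Pinnularia viridis"),
        {
            "domain": "Bacteria",
            "kingdom": "Pseudomonadati",
            "supergroup": "-",
            "phylum_division": "Pseudomonadota",
            "class": "Gammaproteobacteria",
            "order": "Vibrionales",
            "family": "Vibrionaceae",
            "genus": "Vibrio",
            "species": "Vibrio splendidus",
        },
    ]
    for lin in lineages:
        bioinfo.upsert_lineage(store, lin)
    recovered = bioinfo.all_leaf_lineages(store)
    key = lambda d: tuple(d.get(r, "") for r in RANKS)
    assert sorted(map(key, recovered)) == sorted(map(key, lineages))


def test_annotation_confidence_scales_and_verification(fixture_store):
    fid = sorted(f.feature_id for f in fixture_store.tables["features"].values())[1]
    with pytest.raises(errors.ValidationError):
        bioinfo.annotate_feature(
            fixture_store, fid, reference_db_name="PR2", reference_db_version="4",
            method="naive-bayes", confidence=1.7, assigned={},
        )
    # bitscore methods accept values above 1
    ann = bioinfo.annotate_feature(
        fixture_store, fid, reference_db_name="nt", reference_db_version="2021",
        method="blast", confidence=250.0, assigned={"domain": "Eukaryota"},
    )
    node = bioinfo.upsert_lineage(fixture_store, LINEAGE)
    bioinfo.verify_annotation(fixture_store, ann.annotation_id, node)
    assert fixture_store.tables["annotations"][ann.annotation_id].verified_node_id == node
    # several annotations per feature coexist
    anns = [a for a in fixture_store.tables["annotations"].values() if a.feature_id == fid]
    assert len(anns) >= 1


def test_fasta_writer_wraps_at_60_columns(fixture_store):
    dc_id = sorted(fixture_store.tables["denoise_meta"])[0]
    buf = io.StringIO()
    n = bioinfo.write_features_fasta(fixture_store, dc_id, buf)
    assert n == len([f for f in fixture_store.tables["features"].values() if f.dc_id == dc_id])
    lines = buf.getvalue().splitlines()
    assert all(len(line) <= 60 for line in lines if not line.startswith(">"))
    from Bio import SeqIO

    records = list(SeqIO.parse(io.StringIO(buf.getvalue()), "fasta"))
    assert len(records) == n
    assert str(records[0].seq) == fixture_store.tables["features"][records[0].id].sequence
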