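"""Persistence, permissions, join views, ETL ingestion, CSV round-trip."""

import pytest

from medna import errors
from medna.store import Store, read_flat_csv
from medna.synth import FixtureSpec, flat_records_fixture, generate_fixture


# -- permissions -----------------------------------------------------------


def test_ungranted_principal_is_denied_everything(fixture_store):
    assert not fixture_store.gate("stranger", "surveys", "create")
    assert not fixture_store.gate("stranger", "surveys", "read")
    assert not fixture_store.gate(None, "surveys", "read")


def test_public_summary_views_readable_without_authentication(fixture_store):
    assert fixture_store.gate(None, "project_summary", "read")
    assert fixture_store.gate(None, "site_list", "read")
    assert not fixture_store.gate(None, "site_list", "create")


def test_role_presets(fixture_store):
    # admin: create/update/read everywhere, but no delete without explicit grant
    assert fixture_store.gate("alice", "extractions", "create")
    assert fixture_store.gate("alice", "extractions", "update")
    assert not fixture_store.gate("alice", "extractions", "delete")
    # graduate: subset only
    assert fixture_store.gate("gina", "extractions", "update")
    assert not fixture_store.gate("gina", "grants", "create")
    # intern: read/create on subset, never update
    assert fixture_store.gate("ivan", "surveys", "create")
    assert not fixture_store.gate("ivan", "surveys", "update")
    assert not fixture_store.gate("ivan", "extractions", "read")


def test_gate_is_monotone_in_grants(store):
    store.grant_role("u", "intern")
    allowed_before = {
        (t, op)
        for t in store.tables
        for op in ("create", "read", "update", "delete")
        if store.gate("u", t, op)
    }
    store.grant_custom("u", "extractions", ["delete"])
    allowed_after = {
        (t, op)
        for t in store.tables
        for op in ("create", "read", "update", "delete")
        if store.gate("u", t, op)
    }
    assert allowed_before <= allowed_after
    assert ("extractions", "delete") in allowed_after


# -- join views ------------------------------------------------------------


def test_view_counts_match_fixture_topology(fixture_store):
    n_filters = sum(1 for s in fixture_store.tables["samples"].values() if s.kind == "filter")
    n_subcores = sum(1 for s in fixture_store.tables["samples"].values() if s.kind == "subcore")
    assert len(fixture_store.view_survey_filters()) == n_filters
    assert len(fixture_store.view_survey_subcores()) == n_subcores
    assert len(fixture_store.view_survey_envs()) == len(fixture_store.tables["measurements"])


def test_views_are_deterministically_ordered(fixture_store):
    rows = fixture_store.view_survey_filters()
    keys = [(r["survey_datetime"], r["barcode"]) for r in rows]
    assert keys == sorted(keys)
    assert rows == fixture_store.view_survey_filters()


def test_survey_without_collections_appears_in_no_sample_view(store):
    from medna import fieldcore

    store.sites.mint("p", "ME", "L", registry=store.registry)
    store.tables["sites"]["pME_L01"] = fieldcore.FieldSite(
        "pME_L01", -69.5, 44.5, "b", "f"
    )
    fieldcore.create_survey(
        store, site_id="pME_L01", datetime_iso="2021-06-01T09:00:00+00:00",
        recorders=["a"], projects=["p"],
    )
    assert store.view_survey_filters() == []
    assert store.view_survey_subcores() == []


# -- persistence and CSV ----------------------------------------------------


def test_save_load_roundtrip_preserves_digest(fixture_store, tmp_path):
    path = tmp_path / "store.json"
    fixture_store.save(path)
    loaded = Store.load(path)
    assert loaded.digest() == fixture_store.digest()
    # loaded store remains fully usable
    assert loaded.integrity_scan() == []


def test_table_csv_roundtrip_is_lossless(fixture_store, tmp_path):
    for table in ("samples", "inventory_log", "feature_reads", "surveys"):
        p1 = tmp_path / f"{table}.csv"
        fixture_store.export_table_csv(table, p1)
        before = fixture_store.digest()
        n = fixture_store.import_table_csv(table, p1)
        assert n == len(fixture_store.tables[table])
        assert fixture_store.digest() == before
        p2 = tmp_path / f"{table}2.csv"
        fixture_store.export_table_csv(table, p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_empty_table_exports_header_only(store, tmp_path):
    p = tmp_path / "runs.csv"
    store.export_table_csv("runs", p)
    lines = p.read_text().splitlines()
    assert len(lines) == 1
    assert lines[0].startswith("run_id")


def test_import_with_dangling_reference_aborts_unchanged(fixture_store, tmp_path):
    p = tmp_path / "samples.csv"
    fixture_store.export_table_csv("samples", p)
    text = p.read_text()
    # a collection that actually has samples referencing it
    key = next(iter(fixture_store.tables["samples"].values())).collection_id
    assert key in text
    p.write_text(text.replace(key, "colXXXXXX"))
    before = fixture_store.digest()
    with pytest.raises(errors.IntegrityError):
        fixture_store.import_table_csv("samples", p)
    assert fixture_store.digest() == before


def test_integrity_scan_clean_on_fixture_and_detects_breakage(tmp_path):
    s = generate_fixture(FixtureSpec(seed=13, n_sites=1, n_surveys_per_site=1))
    assert s.integrity_scan() == []
    victim = next(iter(s.tables["samples"].values())).collection_id
    del s.tables["collections"][victim]
    assert any("dangling" in p for p in s.integrity_scan())


# -- ETL --------------------------------------------------------------------


def test_flat_ingest_normalizes_and_is_idempotent():
    store, records = flat_records_fixture(seed=3, n_rows=5)
    r1 = store.ingest_flat_records(records)
    assert (r1.surveys_created, r1.samples_created) == (2, 5)
    assert r1.rejects == []
    digest = store.digest()
    r2 = store.ingest_flat_records(records)
    assert r2.total_created == 0 and r2.rejects == []
    assert store.digest() == digest
    assert store.integrity_scan() == []


def test_flat_ingest_rejects_bad_vocabulary_rows_with_reason():
    store, records = flat_records_fixture(seed=3, n_rows=5, defect_rate=0.2)
    report = store.ingest_flat_records(records)
    assert len(report.rejects) == 1
    idx, reason = report.rejects[0]
    assert "sparkle" in reason
    assert report.samples_created == 4  # valid rows still ingested


def test_flat_ingest_unknown_barcode_rejected():
    store, records = flat_records_fixture(seed=3, n_rows=2)
    records[0]["sample_barcode"] = "pME_L01_21w_9999"
    report = store.ingest_flat_records(records)
    assert len(report.rejects) == 1 and "9999" in report.rejects[0][1]
    assert report.samples_created == 1


def test_flat_ingest_empty_file_is_noop(store, tmp_path):
    p = tmp_path / "flat.csv"
    p.write_text("site_id,survey_datetime,recorders,projects\n")
    report = store.ingest_flat_records(read_flat_csv(p))
    assert report.total_created == 0 and report.rejects == []


def test_flat_csv_roundtrip_through_disk(tmp_path):
    import csv

    store, records = flat_records_fixture(seed=5, n_rows=4)
    p = tmp_path / "flat.csv"
    with open(p, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(records[0]))
        writer.writeheader()
        writer.writerows(records)
    report = store.ingest_flat_records(read_flat_csv(p))
    assert report.samples_created == 4
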