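"""Inventory state machine and ledger replay."""

import random

import pytest

from medna import errors, fieldcore, freezer
from medna.freezer import InventoryLogEntry, StorageLocation, replay_ledger
from medna.ident import LabelRequest, format_barcode


@pytest.fixture()
def inv_store(store):
    """Store with 20 assigned sample barcodes ready for inventorying."""
    parts = store.sites.mint("p", "ME", "L", registry=store.registry)
    site = fieldcore.FieldSite(
        site_id="pME_L01", lon=-69.5, lat=44.5, envo_biome="b", envo_feature="f"
    )
    store.tables["sites"][site.site_id] = site
    survey = fieldcore.create_survey(
        store, site_id="pME_L01", datetime_iso="2021-06-01T09:00:00+00:00",
        recorders=["a"], projects=["p"],
    )
    coll = fieldcore.create_collection(
        store, survey.survey_id, "water", "true_sample", {"volume_filtered_ml": 100}
    )
    minted = store.labels.fulfill_label_request(LabelRequest(parts, 21, "w", count=20))
    barcodes = []
    for p in minted:
        text = format_barcode(p)
        fieldcore.register_sample(store, coll.collection_id, text, "filter", {})
        barcodes.append(text)
    store._barcodes = barcodes
    return store


def loc(i):
    return StorageLocation("F1", 1, 1 + i // 81, f"A{1 + i % 9}")


def test_worked_ledger_ends_at_volume_90_removed(inv_store):
    b = inv_store._barcodes[0]
    freezer.add_item(inv_store, b, loc(0), 100.0)
    freezer.check_out(inv_store, b)
    freezer.return_item(inv_store, b, ["extraction"], aliquot_volume_ul=10.0)
    freezer.remove_item(inv_store, b)
    item = freezer.item_state(inv_store, b)
    assert (item.status, item.volume_ul, item.location) == ("removed", 90.0, None)
    entries = [inv_store.tables["inventory_log"][k]
               for k in sorted(inv_store.tables["inventory_log"])]
    replayed = replay_ledger(entries)
    assert replayed[b].status == "removed" and replayed[b].volume_ul == 90.0


def test_occupancy_and_state_errors(inv_store):
    b0, b1 = inv_store._barcodes[:2]
    freezer.add_item(inv_store, b0, loc(0), 50.0)
    with pytest.raises(errors.OccupancyError):
        freezer.add_item(inv_store, b1, loc(0), 50.0)
    with pytest.raises(errors.StateError):
        freezer.add_item(inv_store, b0, loc(1), 50.0)  # already active
    freezer.check_out(inv_store, b0)
    with pytest.raises(errors.StateError):
        freezer.check_out(inv_store, b0)
    with pytest.raises(errors.StateError):
        freezer.return_item(inv_store, b1, ["none"])  # never checked out


def test_home_slot_reserved_while_checked_out_and_freed_on_remove(inv_store):
    b0, b1 = inv_store._barcodes[:2]
    freezer.add_item(inv_store, b0, loc(0), 50.0)
    freezer.check_out(inv_store, b0)
    with pytest.raises(errors.OccupancyError):
        freezer.add_item(inv_store, b1, loc(0), 10.0)
    freezer.remove_item(inv_store, b0)  # removal from checked_out is allowed
    freezer.add_item(inv_store, b1, loc(0), 10.0)  # slot reusable
    with pytest.raises(errors.StateError):
        freezer.remove_item(inv_store, b0)  # removed is absorbing


def test_aliquot_cannot_exceed_volume(inv_store):
    b = inv_store._barcodes[0]
    freezer.add_item(inv_store, b, loc(0), 100.0)
    freezer.check_out(inv_store, b)
    with pytest.raises(errors.VolumeError):
        freezer.return_item(inv_store, b, ["pcr"], aliquot_volume_ul=150.0)
    # failed return leaves the item checked out with full volume
    item = freezer.item_state(inv_store, b)
    assert (item.status, item.volume_ul) == ("checked_out", 100.0)
    freezer.return_item(inv_store, b, ["none"], aliquot_volume_ul=0.0)
    assert freezer.item_state(inv_store, b).volume_ul == 100.0


def test_unknown_return_action_rejected(inv_store):
    b = inv_store._barcodes[0]
    freezer.add_item(inv_store, b, loc(0), 100.0)
    freezer.check_out(inv_store, b)
    with pytest.raises(errors.ValidationError, match="sequencing-party"):
        freezer.return_item(inv_store, b, ["sequencing-party"])


def test_replay_rejects_invalid_transition_with_entry_number():
    entries = [
        InventoryLogEntry(1, "x", "add", "", "t", location=loc(0), volume_ul=10.0),
        InventoryLogEntry(2, "x", "return", "", "t", aliquot_volume_ul=0.0),
    ]
    with pytest.raises(errors.ReplayError) as exc:
        replay_ledger(entries)
    assert exc.value.seq_no == 2


def test_replay_of_empty_ledger_is_empty():
    assert replay_ledger([]) == {}


def test_500_random_operations_replay_equals_live_state(inv_store):
    """Oracle equivalence: incremental state vs pure ledger replay."""
    rng = random.Random(99)
    barcodes = inv_store._barcodes
    actions = list(inv_store.registry.codes("return_action"))
    applied = 0
    attempts = 0
    while applied < 500 and attempts < 5000:
        attempts += 1
        b = rng.choice(barcodes)
        op = rng.choice(["add", "check_out", "return", "remove"])
        try:
            if op == "add":
                freezer.add_item(inv_store, b, loc(rng.randrange(40)), float(rng.randrange(10, 200)))
            elif op == "check_out":
                freezer.check_out(inv_store, b)
            elif op == "return":
                freezer.return_item(
                    inv_store, b, [rng.choice(actions)],
                    aliquot_volume_ul=float(rng.randrange(0, 10)),
                )
            else:
                freezer.remove_item(inv_store, b)
        except errors.MednaError:
            continue
        applied += 1
        # state-machine invariants on every reachable state
        locations = [
            i.location for i in inv_store.tables["inventory_items"].values()
            if i.status in ("in_storage", "checked_out")
        ]
        assert len(locations) == len(set(locations))
        assert all(i.volume_ul >= 0 for i in inv_store.tables["inventory_items"].values())
    assert applied == 500
    entries = [inv_store.tables["inventory_log"][k]
               for k in sorted(inv_store.tables["inventory_log"])]
    # checkout/return balance within each storage lifetime (add .. remove)
    for b in barcodes:
        balance = 0
        for e in entries:
            if e.barcode != b:
                continue
            if e.action == "add":
                balance = 0
            elif e.action == "check_out":
                balance += 1
            elif e.action == "return":
                balance -= 1
            assert balance in (0, 1)
    replayed = replay_ledger(entries, set(actions))
    live = inv_store.tables["inventory_items"]
    assert set(replayed) == set(live)
    for b in replayed:
        assert (replayed[b].status, replayed[b].volume_ul, replayed[b].location) == (
            live[b].status, live[b].volume_ul, live[b].location
        )
    # replay is deterministic
    replayed2 = replay_ledger(entries, set(actions))
    assert {b: (i.status, i.volume_ul) for b, i in replayed.items()} == {
        b: (i.status, i.volume_ul) for b, i in replayed2.items()
    }
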