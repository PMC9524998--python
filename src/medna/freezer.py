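"""Freezer inventory: locations, item state machine and append-only ledger.

A storage location is freezer → rack → box → tube position. Any barcoded
thing (field sample, extraction, pooled library) can be inventoried. Item
state follows a small machine::

    (absent) --add--> in_storage --check_out--> checked_out
    in_storage  <----return (actions, optional aliquot)---- checked_out
    in_storage | checked_out --remove--> removed   (terminal)

Every transition appends an :class:`InventoryLogEntry`; the ledger is the
source of truth and :func:`replay_ledger` reconstructs item state from it,
rejecting any sequence the machine would not have allowed. Returns record
what was done while the item was out (codes from the ``return_action``
vocabulary: extraction, PCR, library prep, pooled library, run prep, run
result, or none) and how much volume was withdrawn as aliquots; volumes
never go negative. A checked-out item keeps its home slot reserved so the
return needs no location argument. Removal is terminal and frees the slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Optional

from .errors import (
    NotFoundError,
    OccupancyError,
    ReplayError,
    StateError,
    ValidationError,
    VolumeError,
)

DEFAULT_FREEZER_TEMP_C = -80.0


@dataclass(frozen=True)
class StorageLocation:
    freezer_id: str
    rack: int
    box: int
    position: str  # e.g. "A1"

    def __post_init__(self) -> None:
        if self.rack < 1 or self.box < 1:
            raise ValidationError("rack and box numbers start at 1")


@dataclass
class InventoryItem:
    barcode: str
    volume_ul: float
    status: str  # in_storage | checked_out | removed
    location: Optional[StorageLocation]  # home slot while active; None once removed


@dataclass
class InventoryLogEntry:
    seq_no: int
    barcode: str
    action: str  # add | check_out | return | remove
    actor: str
    timestamp: str
    location: Optional[StorageLocation] = None  # add only
    volume_ul: Optional[float] = None  # add only
    return_actions: list[str] = field(default_factory=list)  # return only
    aliquot_volume_ul: Optional[float] = None  # return only


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


class _LedgerState:
    """Pure state machine over inventory items; shared by live ops and replay."""

    def __init__(self, return_action_codes: Optional[set[str]] = None) -> None:
        self.items: dict[str, InventoryItem] = {}
        self.return_action_codes = return_action_codes

    def _occupied(self, location: StorageLocation) -> Optional[str]:
        for item in self.items.values():
            if item.status in ("in_storage", "checked_out") and item.location == location:
                return item.barcode
        return None

    def apply(self, entry: InventoryLogEntry) -> None:
        item = self.items.get(entry.barcode)
        if entry.action == "add":
            if item is not None and item.status in ("in_storage", "checked_out"):
                raise StateError(f"{entry.barcode} is already active in inventory")
            if entry.location is None:
                raise ValidationError("add entry needs a storage location")
            holder = self._occupied(entry.location)
            if holder is not None:
                raise OccupancyError(
                    f"location {entry.location} already holds {holder}"
                )
            if entry.volume_ul is None or entry.volume_ul < 0:
                raise ValidationError("add entry needs a non-negative volume")
            self.items[entry.barcode] = InventoryItem(
                barcode=entry.barcode,
                volume_ul=float(entry.volume_ul),
                status="in_storage",
                location=entry.location,
            )
        elif entry.action == "check_out":
            if item is None or item.status != "in_storage":
                raise StateError(
                    f"{entry.barcode} is not in storage "
                    f"(status: {item.status if item else 'absent'})"
                )
            item.status = "checked_out"
        elif entry.action == "return":
            if item is None or item.status != "checked_out":
                raise StateError(
                    f"{entry.barcode} is not checked out "
                    f"(status: {item.status if item else 'absent'})"
                )
            aliquot = entry.aliquot_volume_ul or 0.0
            if aliquot < 0:
                raise ValidationError("aliquot volume cannot be negative")
            if aliquot > item.volume_ul:
                raise VolumeError(
                    f"aliquot {aliquot} µL exceeds stored {item.volume_ul} µL "
                    f"of {entry.barcode}"
                )
            if self.return_action_codes is not None:
                unknown = set(entry.return_actions) - self.return_action_codes
                if unknown:
                    raise ValidationError(f"unknown return action(s) {sorted(unknown)}")
            item.volume_ul -= aliquot
            item.status = "in_storage"
        elif entry.action == "remove":
            if item is None or item.status not in ("in_storage", "checked_out"):
                raise StateError(
                    f"{entry.barcode} cannot be removed "
                    f"(status: {item.status if item else 'absent'})"
                )
            item.status = "removed"
            item.location = None
        else:
            raise ValidationError(f"unknown inventory action {entry.action!r}")


# ---------------------------------------------------------------------------
# live operations on a Store


def _live_state(store) -> _LedgerState:
    st = _LedgerState(set(store.registry.codes("return_action")) or None)
    st.items = store.tables["inventory_items"]
    return st


def _append(store, entry_kwargs: dict) -> InventoryLogEntry:
    if not entry_kwargs.get("timestamp"):
        clock = getattr(store, "clock", None)
        entry_kwargs["timestamp"] = clock() if clock else _now()
    log = store.tables["inventory_log"]
    seq_no = (max((e.seq_no for e in log.values()), default=0)) + 1
    entry = InventoryLogEntry(seq_no=seq_no, **entry_kwargs)
    _live_state(store).apply(entry)  # mutates inventory_items; raises before appending
    log[f"log{seq_no:06d}"] = entry
    return entry


def _require_known_barcode(store, barcode: str) -> None:
    label = store.labels.get(barcode)
    if label is None or not label.assigned:
        raise NotFoundError(
            f"{barcode!r} is not an assigned barcode (field sample, extraction or pool)"
        )


def add_item(
    store, barcode: str, location: StorageLocation, volume_ul: float, actor: str = ""
) -> InventoryLogEntry:
    _require_known_barcode(store, barcode)
    return _append(
        store,
        dict(
            barcode=barcode,
            action="add",
            actor=actor,
            timestamp="",
            location=location,
            volume_ul=float(volume_ul),
        ),
    )


def check_out(store, barcode: str, actor: str = "") -> InventoryLogEntry:
    return _append(store, dict(barcode=barcode, action="check_out", actor=actor, timestamp=""))


def return_item(
    store,
    barcode: str,
    actions: Iterable[str],
    aliquot_volume_ul: float = 0.0,
    actor: str = "",
) -> InventoryLogEntry:
    return _append(
        store,
        dict(
            barcode=barcode,
            action="return",
            actor=actor,
            timestamp="",
            return_actions=sorted(actions),
            aliquot_volume_ul=float(aliquot_volume_ul),
        ),
    )


def remove_item(store, barcode: str, actor: str = "") -> InventoryLogEntry:
    return _append(store, dict(barcode=barcode, action="remove", actor=actor, timestamp=""))


def item_state(store, barcode: str) -> InventoryItem:
    item = store.tables["inventory_items"].get(barcode)
    if item is None:
        raise NotFoundError(f"{barcode!r} has never been inventoried")
    return item


# ---------------------------------------------------------------------------
# replay


def replay_ledger(
    entries: Iterable[InventoryLogEntry],
    return_action_codes: Optional[set[str]] = None,
) -> dict[str, InventoryItem]:
    """Reconstruct item states from a ledger (pure function).

    Entries must arrive in strictly increasing ``seq_no`` order; an invalid
    transition raises :class:`~medna.errors.ReplayError` naming the entry.
    """
    state = _LedgerState(return_action_codes)
    last_seq = 0
    for entry in entries:
        if entry.seq_no <= last_seq:
            raise ReplayError(
                f"ledger out of order at seq_no {entry.seq_no}", seq_no=entry.seq_no
            )
        last_seq = entry.seq_no
        try:
            state.apply(replace(entry))
        except (StateError, ValidationError, VolumeError) as exc:
            raise ReplayError(
                f"invalid transition at ledger entry {entry.seq_no}: {exc}",
                seq_no=entry.seq_no,
            ) from exc
    return state.items
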