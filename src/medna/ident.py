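"""Hierarchical human-readable identifiers.

Two grammars cover every physical thing the system tracks:

* **Site ID** — ``pRR_SCC``: one lowercase project/fund letter ``p``, a 2–3
  character uppercase watershed or marine region code ``RR``/``RRR``, an
  underscore, one uppercase system-type letter ``S`` and a zero-padded
  two-digit sequence ``CC`` (01–99). Two-character region codes are reserved
  for legacy Maine watersheds.
* **Sample barcode** — ``pRR_SCC_YYm_CCCC``: the site ID, the last two
  digits of the collection year ``YY``, one lowercase material letter ``m``
  and a zero-padded four-digit sequence ``CCCC`` (0001–9999).

Sequences increment within a scope: ``(project, region, system)`` for sites
and ``(site, year, material)`` for barcodes. When a scope's digits run out a
:class:`~medna.errors.CapacityError` is raised — the grammar deliberately
has no escape hatch, so capacity pressure is visible rather than silent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, Optional

from .errors import CapacityError, DuplicateError, ParseError, RangeError, ValidationError
from .vocab import VocabularyRegistry

SITE_SEQ_MAX = 99
BARCODE_SEQ_MAX = 9999

_SITE_RE = re.compile(r"^([a-z])([A-Z]{2,3})_([A-Z])(\d{2})$")
_BARCODE_TAIL_RE = re.compile(r"^(\d{2})([a-z])_(\d{4})$")


@dataclass(frozen=True, order=True)
class SiteIdParts:
    project_code: str
    region_code: str
    system_code: str
    sequence: int

    def scope(self) -> tuple[str, str, str]:
        return (self.project_code, self.region_code, self.system_code)


@dataclass(frozen=True, order=True)
class BarcodeParts:
    site: SiteIdParts
    year: int  # last two digits of the collection year
    material_code: str
    sequence: int

    def scope(self) -> tuple[SiteIdParts, int, str]:
        return (self.site, self.year, self.material_code)


@dataclass
class LabelRequest:
    """A batch request for ``count`` fresh barcodes in one scope."""

    site: SiteIdParts
    year: int
    material_code: str
    count: int
    requester: str = ""
    created_at: str = ""


# ---------------------------------------------------------------------------
# formatting / parsing


def format_site_id(parts: SiteIdParts) -> str:
    if not 1 <= parts.sequence <= SITE_SEQ_MAX:
        raise RangeError(
            f"site sequence {parts.sequence} outside 1..{SITE_SEQ_MAX}: "
            "the two-digit grammar has no room"
        )
    return f"{parts.project_code}{parts.region_code}_{parts.system_code}{parts.sequence:02d}"


def format_barcode(parts: BarcodeParts) -> str:
    if not 1 <= parts.sequence <= BARCODE_SEQ_MAX:
        raise RangeError(f"barcode sequence {parts.sequence} outside 1..{BARCODE_SEQ_MAX}")
    if not 0 <= parts.year <= 99:
        raise RangeError(f"two-digit year {parts.year} outside 0..99")
    return (
        f"{format_site_id(parts.site)}_{parts.year:02d}{parts.material_code}"
        f"_{parts.sequence:04d}"
    )


def parse_site_id(
    text: str,
    registry: Optional[VocabularyRegistry] = None,
    region_codes: Optional[Iterable[str]] = None,
) -> SiteIdParts:
    """Parse ``pRR_SCC``; optionally validate codes against vocabularies.

    Errors name the failing grammar component so operators can correct
    hand-typed labels.
    """
    if text.count("_") != 1:
        raise ParseError(
            f"site ID {text!r}: expected exactly one '_' separator", component="separator"
        )
    m = _SITE_RE.match(text)
    if m is None:
        head, _, tail = text.partition("_")
        if not re.match(r"^[a-z][A-Z]{2,3}$", head):
            raise ParseError(
                f"site ID {text!r}: prefix {head!r} is not a lowercase project letter "
                "followed by a 2-3 letter uppercase region code",
                component="region",
            )
        if not re.match(r"^[A-Z]\d{2}$", tail):
            raise ParseError(
                f"site ID {text!r}: suffix {tail!r} is not a system letter plus a "
                "two-digit sequence",
                component="sequence" if re.match(r"^[A-Z]", tail) else "system",
            )
        raise ParseError(f"site ID {text!r} does not match pRR_SCC", component="grammar")
    project, region, system, seq_text = m.groups()
    sequence = int(seq_text)
    if sequence == 0:
        raise ParseError(f"site ID {text!r}: sequence 00 is not mintable", component="sequence")
    if registry is not None and not registry.has("system_type", system):
        raise ParseError(
            f"site ID {text!r}: unknown system type {system!r}", component="system"
        )
    if region_codes is not None and region not in set(region_codes):
        raise ParseError(f"site ID {text!r}: unknown region {region!r}", component="region")
    return SiteIdParts(project, region, system, sequence)


def parse_barcode(
    text: str,
    registry: Optional[VocabularyRegistry] = None,
    region_codes: Optional[Iterable[str]] = None,
) -> BarcodeParts:
    """Parse ``pRR_SCC_YYm_CCCC``."""
    if text.count("_") != 3:
        raise ParseError(
            f"barcode {text!r}: expected exactly three '_' separators", component="separator"
        )
    p1, p2, p3, p4 = text.split("_")
    site = parse_site_id(f"{p1}_{p2}", registry=registry, region_codes=region_codes)
    m = _BARCODE_TAIL_RE.match(f"{p3}_{p4}")
    if m is None:
        if not re.match(r"^\d{2}[a-z]$", p3):
            component = "year" if not re.match(r"^\d{2}", p3) else "material"
            raise ParseError(
                f"barcode {text!r}: segment {p3!r} is not YY + material letter",
                component=component,
            )
        raise ParseError(
            f"barcode {text!r}: {p4!r} is not a four-digit sequence", component="sequence"
        )
    year_text, material, seq_text = m.groups()
    sequence = int(seq_text)
    if sequence == 0:
        raise ParseError(f"barcode {text!r}: sequence 0000 is not mintable", component="sequence")
    if registry is not None and not registry.has("sample_material", material):
        raise ParseError(
            f"barcode {text!r}: unknown material code {material!r}", component="material"
        )
    return BarcodeParts(site, int(year_text), material, sequence)


# ---------------------------------------------------------------------------
# minting


class SiteRegistry:
    """Persisted set of minted site IDs with per-scope sequential minting."""

    def __init__(self) -> None:
        self._by_text: dict[str, SiteIdParts] = {}

    def __contains__(self, text: str) -> bool:
        return text in self._by_text

    def __len__(self) -> int:
        return len(self._by_text)

    def all_ids(self) -> list[str]:
        return sorted(self._by_text)

    def get(self, text: str) -> Optional[SiteIdParts]:
        return self._by_text.get(text)

    def add_existing(self, parts: SiteIdParts) -> None:
        """Record an externally minted ID (e.g. loaded from persistence)."""
        text = format_site_id(parts)
        if text in self._by_text:
            raise DuplicateError(f"site ID {text} already registered")
        self._by_text[text] = parts

    def next_sequence(self, project: str, region: str, system: str) -> int:
        scope = (project, region, system)
        used = [p.sequence for p in self._by_text.values() if p.scope() == scope]
        return (max(used) + 1) if used else 1

    def mint(
        self,
        project_code: str,
        region_code: str,
        system_code: str,
        registry: Optional[VocabularyRegistry] = None,
        region_codes: Optional[Iterable[str]] = None,
    ) -> SiteIdParts:
        if registry is not None and not registry.has("system_type", system_code):
            raise ValidationError(f"unknown system type {system_code!r}")
        if region_codes is not None and region_code not in set(region_codes):
            raise ValidationError(f"unknown region code {region_code!r}")
        seq = self.next_sequence(project_code, region_code, system_code)
        if seq > SITE_SEQ_MAX:
            raise CapacityError(
                f"scope {project_code}{region_code}_{system_code} exhausted its "
                f"{SITE_SEQ_MAX} two-digit sequences"
            )
        parts = SiteIdParts(project_code, region_code, system_code, seq)
        self._by_text[format_site_id(parts)] = parts
        return parts


@dataclass
class LabelRecord:
    """One persisted (possibly not yet assigned) sample label."""

    parts: BarcodeParts
    text: str
    requester: str = ""
    created_at: str = ""
    assigned: bool = False
    assigned_to: str = ""  # record id of the sample/extraction/pool, once bound


class LabelStore:
    """Persisted barcodes; fulfils batch label requests atomically."""

    def __init__(self) -> None:
        self._by_text: dict[str, LabelRecord] = {}

    def __contains__(self, text: str) -> bool:
        return text in self._by_text

    def __len__(self) -> int:
        return len(self._by_text)

    def get(self, text: str) -> Optional[LabelRecord]:
        return self._by_text.get(text)

    def all_labels(self) -> list[LabelRecord]:
        return [self._by_text[t] for t in sorted(self._by_text)]

    def next_sequence(self, site: SiteIdParts, year: int, material: str) -> int:
        scope = (site, year, material)
        used = [r.parts.sequence for r in self._by_text.values() if r.parts.scope() == scope]
        return (max(used) + 1) if used else 1

    def fulfill_label_request(self, request: LabelRequest) -> list[BarcodeParts]:
        """Mint ``request.count`` consecutive labels, all-or-nothing."""
        if request.count < 1:
            raise ValidationError("label request count must be >= 1")
        start = self.next_sequence(request.site, request.year, request.material_code)
        end = start + request.count - 1
        if end > BARCODE_SEQ_MAX:
            raise CapacityError(
                f"request for {request.count} labels would pass sequence "
                f"{BARCODE_SEQ_MAX} in scope {format_site_id(request.site)}_"
                f"{request.year:02d}{request.material_code}; nothing persisted"
            )
        created_at = request.created_at or datetime.now(timezone.utc).isoformat()
        minted = []
        for seq in range(start, end + 1):
            parts = BarcodeParts(request.site, request.year, request.material_code, seq)
            minted.append(parts)
        # validation complete; persist (atomic because nothing above mutates)
        for parts in minted:
            text = format_barcode(parts)
            self._by_text[text] = LabelRecord(
                parts=parts, text=text, requester=request.requester, created_at=created_at
            )
        return minted

    def assign(self, text: str, record_id: str) -> LabelRecord:
        rec = self._by_text.get(text)
        if rec is None:
            raise KeyError(text)
        rec.assigned = True
        rec.assigned_to = record_id
        return rec
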