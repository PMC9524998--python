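"""Controlled-vocabulary registry.

Two kinds of vocabulary coexist:

* **enumerated** — hard-coded choice sets that are part of the schema itself
  (control types, PCR chemistry, library layout, coring methods). These are
  frozen: they cannot be added to, edited, or deactivated after load.
* **model_based** — project-specific choice sets (system types, sample
  materials, environmental measure types, return actions, process
  locations). These ship as an editable YAML config and may be extended or
  soft-deleted at run time, but only by an administrator.

Codes double as components of the human-readable identifier grammars, so
they may contain neither whitespace nor underscores.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import (
    ConfigError,
    DuplicateError,
    ImmutableError,
    InactiveError,
    NotFoundError,
    PermissionError_,
    ValidationError,
)

#: Choice sets that are part of the schema, not of any one deployment.
ENUMERATED: dict[str, dict[str, str]] = {
    "control_type": {
        "true_sample": "True sample",
        "mock": "Mock community",
        "positive_control": "Positive field control",
        "negative_control": "Negative field control",
    },
    "collection_kind": {"water": "Water collection", "sediment": "Sediment collection"},
    "sample_kind": {"filter": "Filter", "subcore": "Sub-core"},
    "core_method": {"gravity": "Gravity corer", "piston": "Piston corer", "wedge": "Wedge corer"},
    "subdivision_method": {"scoop": "Scoop", "syringe": "Syringe", "slice": "Slice"},
    "pcr_type": {"qpcr": "Quantitative PCR", "ddpcr": "Droplet digital PCR"},
    "lib_layout": {"paired": "Paired-end", "single": "Single-end"},
    "inventory_action": {
        "add": "Addition",
        "check_out": "Check-out",
        "return": "Return",
        "remove": "Permanent removal",
    },
}

_FORBIDDEN_CODE_CHARS = set(" \t\n\r_")


def _role_of(principal) -> str:
    return principal if isinstance(principal, str) else getattr(principal, "role", "")


@dataclass
class VocabularyEntry:
    """One (vocabulary, code) choice."""

    vocabulary_name: str
    code: str
    label: str
    kind: str = "model_based"  # or "enumerated"
    active: bool = True
    extra: dict = field(default_factory=dict)  # e.g. default unit, confidence scale

    def validate(self) -> None:
        if self.kind not in ("enumerated", "model_based"):
            raise ValidationError(f"unknown vocabulary kind {self.kind!r}")
        if not self.code:
            raise ValidationError("vocabulary code must be nonempty")
        if _FORBIDDEN_CODE_CHARS & set(self.code):
            raise ValidationError(
                f"code {self.code!r} contains whitespace or underscore, which the "
                "identifier grammars reserve as separators"
            )


class VocabularyRegistry:
    """In-memory registry of all vocabularies, keyed (vocabulary_name, code)."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], VocabularyEntry] = {}
        self.material_sample_kind: dict[str, str] = {}
        self.derived_material_codes: dict[str, str] = {}
        for vocab_name, choices in ENUMERATED.items():
            for code, label in choices.items():
                e = VocabularyEntry(vocab_name, code, label, kind="enumerated")
                self._entries[(vocab_name, code)] = e

    # -- queries ---------------------------------------------------------

    def lookup(self, vocabulary_name: str, code: str) -> VocabularyEntry:
        if not any(name == vocabulary_name for name, _ in self._entries):
            raise NotFoundError(f"unknown vocabulary {vocabulary_name!r}")
        entry = self._entries.get((vocabulary_name, code))
        if entry is None:
            raise NotFoundError(f"no code {code!r} in vocabulary {vocabulary_name!r}")
        if not entry.active:
            raise InactiveError(
                f"code {code!r} in vocabulary {vocabulary_name!r} is deactivated"
            )
        return entry

    def has(self, vocabulary_name: str, code: str) -> bool:
        e = self._entries.get((vocabulary_name, code))
        return e is not None and e.active

    def codes(self, vocabulary_name: str, include_inactive: bool = False) -> list[str]:
        return sorted(
            code
            for (name, code), e in self._entries.items()
            if name == vocabulary_name and (include_inactive or e.active)
        )

    def entries(self, vocabulary_name: str | None = None) -> list[VocabularyEntry]:
        out = [
            e
            for (name, _), e in sorted(self._entries.items())
            if vocabulary_name is None or name == vocabulary_name
        ]
        return out

    # -- mutation (admin only, model_based only) -------------------------

    def register_entry(self, entry: VocabularyEntry, principal) -> None:
        if _role_of(principal) != "admin":
            raise PermissionError_("vocabulary customization is restricted to administrators")
        if entry.kind == "enumerated":
            raise ImmutableError("enumerated vocabularies are hard-coded and frozen")
        entry.validate()
        key = (entry.vocabulary_name, entry.code)
        if key in self._entries:
            raise DuplicateError(f"{key} already registered")
        self._entries[key] = entry

    def deactivate(self, vocabulary_name: str, code: str, principal) -> None:
        if _role_of(principal) != "admin":
            raise PermissionError_("vocabulary customization is restricted to administrators")
        entry = self.lookup(vocabulary_name, code)
        if entry.kind == "enumerated":
            raise ImmutableError("enumerated entries cannot be deactivated")
        entry.active = False

    # -- serialization ---------------------------------------------------

    def snapshot(self) -> list[dict]:
        """Deterministic plain representation (for digests and persistence)."""
        rows = []
        for (name, code), e in sorted(self._entries.items()):
            rows.append(
                {
                    "vocabulary_name": name,
                    "code": code,
                    "label": e.label,
                    "kind": e.kind,
                    "active": e.active,
                    "extra": dict(sorted(e.extra.items())),
                }
            )
        return rows

    def enumerated_snapshot(self) -> list[dict]:
        return [r for r in self.snapshot() if r["kind"] == "enumerated"]

    def clone(self) -> "VocabularyRegistry":
        return copy.deepcopy(self)


def default_config_path() -> Path:
    return Path(str(resources.files("medna").joinpath("data/vocab_defaults.yaml")))


def load_defaults(config_path: str | Path | None = None) -> VocabularyRegistry:
    """Build a registry from a YAML config (the shipped defaults if none given).

    Loading is idempotent: the same file always yields an identical registry.
    An empty config yields only the built-in enumerations.
    """
    path = Path(config_path) if config_path is not None else default_config_path()
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"vocabulary config {path} failed to parse: {exc}") from exc
    registry = VocabularyRegistry()
    if raw is None:
        return registry
    if not isinstance(raw, Mapping):
        raise ConfigError(f"vocabulary config {path} must be a mapping at top level")
    seen: set[tuple[str, str]] = set()
    for vocab_name, items in (raw.get("vocabularies") or {}).items():
        if not isinstance(items, Iterable) or isinstance(items, (str, bytes)):
            raise ConfigError(f"vocabulary {vocab_name!r}: expected a list of entries")
        for item in items:
            if not isinstance(item, Mapping) or "code" not in item or "label" not in item:
                raise ConfigError(
                    f"vocabulary {vocab_name!r}: entry {item!r} needs 'code' and 'label'"
                )
            code = str(item["code"])
            key = (vocab_name, code)
            if key in seen:
                raise DuplicateError(f"duplicate entry {key} in config {path}")
            seen.add(key)
            extra = {k: v for k, v in item.items() if k not in ("code", "label")}
            entry = VocabularyEntry(vocab_name, code, str(item["label"]), extra=extra)
            try:
                entry.validate()
            except ValidationError as exc:
                raise ConfigError(f"vocabulary {vocab_name!r} entry {code!r}: {exc}") from exc
            if key in registry._entries:
                raise DuplicateError(f"config entry {key} collides with a built-in enumeration")
            registry._entries[key] = entry
    registry.material_sample_kind = dict(raw.get("material_sample_kind") or {})
    registry.derived_material_codes = dict(raw.get("derived_material_codes") or {})
    return registry
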