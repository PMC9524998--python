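"""Field-survey data model.

The chain runs site → survey → collection → sample:

* a **field site** is a fixed, minted location (site ID, coordinates and
  EnvO broad-scale biome / local-scale feature terms);
* a **field survey** is one visit — it may reference a site or carry free
  "other site" text (the site relationship is optional), names its crew and
  one or more funding projects, and holds environmental measurements taken
  at one or more depths;
* a **field collection** is water or sediment taken during a survey and may
  be a true sample, a mock, or a positive/negative field control;
* a **field sample** is the physical unit that gets a barcode — a filter
  (from water) or a sub-core (from sediment).

Collections and samples are polymorphic supertype/subtype records: the
supertype row declares the kind and carries exactly one matching payload.
Barcodes bind injectively: a persisted label is assigned to at most one
sample, ever. Records at this layer are append/update only — deletion would
orphan provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    ConsistencyError,
    DoubleBindError,
    NotFoundError,
    PolymorphismError,
    ValidationError,
)
from .ident import parse_barcode

WATER_PAYLOAD_FIELDS = {"volume_filtered_ml", "storage_duration_h", "storage_condition"}
SEDIMENT_PAYLOAD_FIELDS = {"core_method", "subdivision_method"}
FILTER_PAYLOAD_FIELDS = {"filter_material", "pore_size_um", "volume_filtered_ml"}
SUBCORE_PAYLOAD_FIELDS = {"method", "length_cm", "diameter_cm", "number"}

_COLLECTION_PAYLOADS = {"water": WATER_PAYLOAD_FIELDS, "sediment": SEDIMENT_PAYLOAD_FIELDS}
_SAMPLE_PAYLOADS = {"filter": FILTER_PAYLOAD_FIELDS, "subcore": SUBCORE_PAYLOAD_FIELDS}
#: which collection kind each sample kind may hang off
SAMPLE_KIND_TO_COLLECTION_KIND = {"filter": "water", "subcore": "sediment"}


@dataclass
class FieldSite:
    site_id: str  # formatted pRR_SCC
    lon: float
    lat: float
    envo_biome: str
    envo_feature: str
    general_location_name: str = ""


@dataclass
class FieldSurvey:
    survey_id: str
    site_id: str  # "" when only other_site_text is used
    other_site_text: str
    datetime: str  # ISO 8601 with zone
    recorders: list[str] = field(default_factory=list)
    projects: list[str] = field(default_factory=list)


@dataclass
class EnvironmentalMeasurement:
    measurement_id: str
    survey_id: str
    depth_m: float
    measure_type: str
    value: float
    unit: str


@dataclass
class FieldCollection:
    collection_id: str
    survey_id: str
    kind: str  # water | sediment
    control_type: str
    payload: dict = field(default_factory=dict)


@dataclass
class FieldSample:
    sample_id: str
    collection_id: str
    barcode: str
    material_code: str
    kind: str  # filter | subcore
    payload: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations (all take the Store duck-type: .tables, .registry, .labels, .next_id)


def create_survey(
    store,
    *,
    site_id: str = "",
    other_site_text: str = "",
    datetime_iso: str,
    recorders: list[str],
    projects: list[str],
) -> FieldSurvey:
    if not projects:
        raise ValidationError("a survey must belong to at least one project")
    if not site_id and not other_site_text:
        raise ValidationError("survey needs a site reference or 'other' site text")
    if site_id and site_id not in store.tables["sites"]:
        raise NotFoundError(f"unknown field site {site_id!r}")
    survey = FieldSurvey(
        survey_id=store.next_id("surveys", "srv"),
        site_id=site_id,
        other_site_text=other_site_text,
        datetime=datetime_iso,
        recorders=list(recorders),
        projects=sorted(set(projects)),
    )
    store.tables["surveys"][survey.survey_id] = survey
    return survey


def attach_measurement(
    store, survey_id: str, depth_m: float, measure_type: str, value: float, unit: str = ""
) -> EnvironmentalMeasurement:
    if survey_id not in store.tables["surveys"]:
        raise NotFoundError(f"unknown survey {survey_id!r}")
    if not store.registry.has("env_measure_type", measure_type):
        raise ValidationError(f"unknown environmental measure type {measure_type!r}")
    if depth_m < 0:
        raise ValidationError(f"depth {depth_m} m is negative")
    if not unit:
        unit = store.registry.lookup("env_measure_type", measure_type).extra.get("unit", "")
    m = EnvironmentalMeasurement(
        measurement_id=store.next_id("measurements", "env"),
        survey_id=survey_id,
        depth_m=float(depth_m),
        measure_type=measure_type,
        value=float(value),
        unit=unit,
    )
    store.tables["measurements"][m.measurement_id] = m
    return m


def _check_payload(kind: str, payload: dict, allowed: dict[str, set], label: str) -> None:
    if kind not in allowed:
        raise ValidationError(f"unknown {label} kind {kind!r}")
    extra = set(payload) - allowed[kind]
    if extra:
        # extra keys mean the payload was built for the other subtype
        other = next(k for k in allowed if k != kind)
        if extra & allowed[other]:
            raise PolymorphismError(
                f"{label} kind {kind!r} received fields {sorted(extra)} belonging to "
                f"the {other!r} payload"
            )
        raise ValidationError(f"{label} payload has unknown fields {sorted(extra)}")


def create_collection(
    store, survey_id: str, kind: str, control_type: str, payload: dict
) -> FieldCollection:
    if survey_id not in store.tables["surveys"]:
        raise NotFoundError(f"unknown survey {survey_id!r}")
    if not store.registry.has("control_type", control_type):
        raise ValidationError(f"unknown control type {control_type!r}")
    _check_payload(kind, payload, _COLLECTION_PAYLOADS, "collection")
    if kind == "sediment":
        for key, vocab_name in (("core_method", "core_method"), ("subdivision_method", "subdivision_method")):
            code = payload.get(key)
            if code is not None and not store.registry.has(vocab_name, code):
                raise ValidationError(f"unknown {key} {code!r}")
    coll = FieldCollection(
        collection_id=store.next_id("collections", "col"),
        survey_id=survey_id,
        kind=kind,
        control_type=control_type,
        payload=dict(payload),
    )
    store.tables["collections"][coll.collection_id] = coll
    return coll


def register_sample(store, collection_id: str, barcode_text: str, kind: str, payload: dict) -> FieldSample:
    coll = store.tables["collections"].get(collection_id)
    if coll is None:
        raise NotFoundError(f"unknown collection {collection_id!r}")
    label = store.labels.get(barcode_text)
    if label is None:
        raise NotFoundError(f"barcode {barcode_text!r} was never minted as a label")
    if label.assigned:
        raise DoubleBindError(
            f"barcode {barcode_text!r} is already bound to {label.assigned_to}"
        )
    _check_payload(kind, payload, _SAMPLE_PAYLOADS, "sample")
    material = parse_barcode(barcode_text).material_code
    expected_kind = store.registry.material_sample_kind.get(material)
    if expected_kind != kind:
        raise ConsistencyError(
            f"barcode material {material!r} labels {expected_kind!r} samples, "
            f"not {kind!r}"
        )
    if SAMPLE_KIND_TO_COLLECTION_KIND[kind] != coll.kind:
        raise ConsistencyError(
            f"a {kind} sample cannot come from a {coll.kind} collection"
        )
    sample = FieldSample(
        sample_id=store.next_id("samples", "smp"),
        collection_id=collection_id,
        barcode=barcode_text,
        material_code=material,
        kind=kind,
        payload=dict(payload),
    )
    store.tables["samples"][sample.sample_id] = sample
    store.labels.assign(barcode_text, sample.sample_id)
    return sample
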