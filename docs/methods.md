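# Methods

This note documents the data model, the procedures and the design choices
behind `medna`, in the order a record travels through the system.

## Identifier grammars

Site IDs are `pRR_SCC`: one lowercase project/fund letter, a 2–3 character
uppercase region code, an underscore, one uppercase system-type letter and
a zero-padded two-digit sequence (01–99). Sample barcodes extend the site
ID: `pRR_SCC_YYm_CCCC`, with the last two digits of the collection year,
one lowercase material letter and a zero-padded four-digit sequence
(0001–9999). Case is canonical (project lowercase, region and system
uppercase, material lowercase) and compared exactly.

Sequences increment within a scope. For sites the scope is
`(project, region, system)` — the project letter is included, so two funds
can both hold an `…ME_L01`. For barcodes it is `(site, year, material)`,
matching the visible prefix structure of the label. Minting is
validate-then-write, so repeated minting can never produce duplicates, and
batch label requests are all-or-nothing: a request that would pass 9999
persists nothing. Exhaustion raises a capacity error by design; the
two/four-digit widths are part of the label contract with field teams, and
a deployment that outgrows them needs a new scheme (e.g. UUID labels), not
a silently wider field.

Parsing is the exact inverse of formatting (property-tested in both
directions) and error messages name the failing grammar component
(separator, region, system, sequence, year, material) because these strings
are hand-typed on boats.

Derived entities that are physically barcoded — DNA extractions and pooled
libraries — mint labels in their parent sample's (site, year) scope using
configured material letters (`e` and `p` by default, shipped in the
vocabulary config alongside `w` water and `s` sediment).

## Vocabularies

Two kinds of controlled vocabulary coexist. *Enumerated* sets are part of
the schema (control types, water/sediment, filter/sub-core, coring and
subdivision methods, qPCR/ddPCR, paired/single library layout, inventory
actions); they are hard-coded and frozen. *Model-based* sets are deployment
choices (system types, materials, environmental measure types, return
actions, process locations, denoise/cluster methods, annotation methods);
they ship as a YAML config, may be extended or soft-deleted at run time,
and mutation is restricted to administrators. Deactivation is a soft delete
so historical records keep resolving. Codes may contain neither whitespace
nor underscores, because underscores delimit the identifier grammars.

The default environmental measure types cover water temperature, salinity,
pH, up- and down-looking PAR, turbidity, conductivity, dissolved oxygen,
nitrate+nitrite, pheophytin and chlorophyll *a*, each with a default unit;
units are stored per measurement rather than implied, so a deployment can
override them without ambiguity. The single-letter system-type codes
(L lake, S stream/river, E estuary, C coast, P pelagic, A aquarium,
M mock) are package defaults shipped as config — deployments rename them
freely.

## Region geometry

Region polygons carry a code (2 characters only for legacy-flagged
watersheds, otherwise 3), a kind (watershed or marine) and closed rings in
WGS84 lon/lat. All geometry is planar on lon/lat. Simplification tolerances
are metres: vertices are projected onto a local equirectangular plane about
the polyline centroid (Earth radius 6 371 008.8 m), which at a 100 m
tolerance over polygons spanning tens of kilometres introduces distortion
orders of magnitude below the tolerance itself.

Douglas–Peucker is implemented directly (iterative, point-to-*segment*
distance) so the published guarantee holds exactly: the output is a
subsequence of the input retaining both endpoints, and every removed vertex
lies within tolerance of the simplified polyline. Using segment rather than
infinite-line distance makes that bound provable without edge cases when a
vertex projects beyond a segment end. Tolerance 0 returns the input
unchanged. Simplification is idempotent and vertex counts are monotone in
the tolerance; a ring that would degenerate below 4 vertices keeps its
original shape. Tests cross-check against shapely's independent
Douglas–Peucker and a brute-force deviation oracle.

Point-in-region assignment uses boundary-inclusive containment
(shapely `covers`). Overlaps are resolved deterministically: watershed
before marine (a shoreline point belongs to its watershed), then smaller
planar area (the more specific region wins), then lexicographic code. A
point in no polygon raises an explicit "unassigned" error — the caller
records the survey against an "other" site instead. The mapping from
source datasets (e.g. 8-digit hydrologic unit codes) to the short region
codes is supplied as data with the region file, not computed.

## Field model

A survey's site relationship is optional: either a minted site or free
"other" text (or both, with the site taking precedence). Surveys belong to
one or more projects (many-to-many) and hold any number of environmental
measurements; the same measure type may appear at several depths.
Timestamps carry explicit zones and export as ISO 8601, because MIxS
collection dates must be unambiguous.

Collections and samples are supertype/subtype polymorphic: the supertype
row declares the kind (water/sediment, filter/sub-core) and carries exactly
one matching payload; mismatched payloads are rejected at write time rather
than by storage-engine machinery. The material letter of a barcode must
agree with the sample kind through a configured map (`w`→filter,
`s`→sub-core), and a persisted label binds to at most one sample ever.
Records at this layer are append/update only — deletion would orphan
provenance.

## Wet lab and lineage

The chain is extraction → (PCR | library prep) → pooled library → run prep
→ run result → FASTQ record. qPCR and ddPCR replicates share one table with
unit-tagged values (Cq vs copies/µL). Pools refuse members whose (i7, i5)
index pairs collide, since such a pool could not be demultiplexed. FASTQ
files are opaque — filename, SHA-256 and size only; the sequence data live
elsewhere.

`lineage()` resolves a FASTQ record's full provenance. Attribution to an
extraction uses the explicit optional reference; without one, it succeeds
only when the run's pools contain exactly one library (a single-member
pool), and otherwise raises an ambiguity error rather than guessing. A
broken chain raises an error naming the first missing hop.

## Bioinformatics metadata

Only parameters and results are stored — the package never runs trimming,
denoising or classifiers. Features (ASVs/OTUs) are IUPAC DNA sequences
keyed per denoise/cluster step; read counts are unique per
(feature, extraction), and the export is a features × extractions matrix
(lexicographic ids, absent cells 0) whose total provably equals the stored
counts. The TSV writer shows extraction barcodes in the header for human
use.

The curated taxonomy is a forest of parent-linked nodes over nine ranks —
domain, kingdom, supergroup, phylum/division, class, order, family, genus,
species — chosen to accommodate protist reference databases (PR2-style
supergroups) alongside Linnaean ranks. Lineages must fill ranks
contiguously from domain down; insertion shares any existing prefix, so a
sibling species adds exactly one node. Annotations record method, reference
database and a confidence whose scale is declared per method in the
vocabulary config (unit interval for classifiers, non-negative bitscore for
alignment methods); manual verification links an annotation to a curated
node and is the only way the verified flag is set.

## Freezer inventory

Storage addresses are freezer → rack → box → position. Item state follows
add → in_storage → checked_out → (return) → in_storage → removed, with
removal allowed from checked_out as well (samples consumed in the lab) and
terminal thereafter. Returns carry the actions performed while out (from
the return-action vocabulary: extraction, PCR, library prep, pooled
library, run prep, run result, or none) and an aliquot volume that is
subtracted, never below zero. A checked-out item keeps its home slot
reserved, so returns need no location argument; there is deliberately no
move operation (model a move as remove + add). Storage temperature is an
attribute of the freezer (default −80 °C), not of items.

The ledger is append-only with strictly increasing sequence numbers and is
the source of truth: live state and `replay_ledger` share one pure state
machine, so replaying any valid ledger reproduces the live state exactly,
and replay rejects invalid transitions naming the entry. This equivalence
is property-tested with 500 random operations over 20 items.

## MIxS export

The MIMARKS-SURVEY field list is deployment configuration (YAML), not code:
each field has a requirement class (M/C/E), a dotted source path into the
joined lineage record, an optional formatter (ISO dates; lat_lon as signed
decimal degrees, latitude first; primer pairs as `FWD:…;REV:…`) and, for C
fields, the sibling field whose presence makes it required. The shipped
default is a minimal 15-field set modeled on the public MIxS 5 water and
sediment survey packages, plus the FASTQ filename/checksum columns (file
"download" is modeled as emitting those stored values, not file transfer).
Both packages require the EnvO broad-scale and local-scale context terms.

One row is built per extraction with a run-attached FASTQ whose sample
matches the package's material, ordered by sample barcode. Building never
aborts: missing mandatory values surface in the validation report, the way
submission checkers behave. E fields never invalidate. Writing is RFC 4180
CSV (or TSV), UTF-8 with trailing newline, and export→parse→export is a
byte-level fixpoint.

## Store, permissions, ETL

The store is an in-process object persisted to a single sorted-JSON file;
its SHA-256 digest over the canonical document defines state equality.
Every public operation validates before mutating, so a failed call leaves
the store unchanged. Per-table CSV round-trips JSON-encode each cell,
making them lossless; imports validate referential integrity against the
rest of the store and abort unchanged on dangling references. A full
integrity scan covers every reference, the polymorphism and barcode
injectivity invariants, taxonomy contiguity, pool demultiplexability and
ledger/live-state agreement.

Permission gating is decision-only (allow/deny, never raising): admins get
create/read/update on all tables, graduates the same on a configured
subset, interns read/create on a smaller subset; ungranted principals get
nothing, and a few public summary views are readable unauthenticated.
Delete appears in no preset — it must be granted per user and cascades are
refused, because provenance outlives convenience.

ETL ingestion takes denormalized flat rows (one per sample, with repeated
`measN_*` measurement triples — the shape tablet survey apps export).
Rows group into surveys by (site-or-other, datetime, recorder set);
surveys, measurements (by survey/depth/type), collections (by
survey/kind/control type) and samples (by barcode) upsert on those natural
keys, so re-ingesting a file is a no-op. Each row is fully validated before
any of it is written; bad rows are rejected individually with reasons while
the rest of the file loads.

## Synthetic fixtures

`generate_fixture(FixtureSpec)` builds a complete store: a toy region set
(four rectangular watersheds, one legacy 2-character code, plus one marine
rectangle — generated, never shipped as data), minted sites placed inside
their polygons, surveys with measurements at 0 m and 10 m across four
measure types, one negative field control collection per site, samples
split water/sediment by `water_fraction` (deterministically, so entity
counts have closed forms), full wet-lab chains with globally unique index
pairs, one quality/denoise step with five 120-bp features and read counts
for every extraction, two curated lineages with one verified annotation,
and an add/check-out/return cycle per extraction in the freezer.

Determinism: every entity family draws from its own stream seeded as
`"{seed}:{family}"`, and the store clock is a logical counter, so identical
specs give identical digests and new families never perturb old values.
`defect_rate` blanks the EnvO terms of that fraction of sites (at least
one) to seed mandatory-field violations for negative tests; a companion
flat-record generator seeds unknown-vocabulary rows for ETL rejection
tests. Defaults (2 sites × 2 surveys × 3 samples, 1 run) keep every suite
run in seconds while exercising both materials, both region kinds and
multi-member pools.

What the fixtures do **not** emulate: realistic measurement statistics
(values are uniform draws over plausible instrument ranges), real watershed
geometry, sequencing error, or operator typos beyond the seeded defect
classes. Passing tests therefore demonstrate structural and procedural
correctness — grammar, state machines, joins, exports — not robustness to
messy real-world field data.

## Known limitations

- Concurrency: the store is single-process; "atomic" means
  validate-then-write within one process, not multi-writer transactions.
- Geometry is planar; polygons spanning the antimeridian or poles are out
  of scope, as are datum transformations.
- The two-digit site and four-digit barcode sequences are hard capacity
  limits, surfaced as errors.
- The MIxS checklist default is minimal; real submissions will extend the
  config with portal-specific fields.
- Century disambiguation of the two-digit label year is not attempted;
  records carry full ISO dates elsewhere.
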