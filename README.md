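# medna

Embeddable metadata management for environmental-DNA (eDNA) metabarcoding
campaigns: a library plus `medna` CLI that tracks samples from field
collection through wet-lab processing to bioinformatic annotation, without
requiring a database server or web stack.

eDNA monitoring programs generate thousands of physical objects — water
filters, sediment sub-cores, DNA extractions, pooled sequencing libraries —
whose scientific value depends entirely on the metadata chain connecting a
FASTQ file back to a dated, geolocated field survey. `medna` models that
chain end to end for field teams, lab managers and bioinformaticians:

- **Identifiers** — hierarchical human-readable site IDs `pRR_SCC`
  (project letter, 2–3 character region code, system-type letter, two-digit
  sequence) and sample barcodes `pRR_SCC_YYm_CCCC` (site ID, two-digit
  year, material letter, four-digit sequence), with strict parsing,
  sequential per-scope minting and batch label requests. Capacity limits
  are enforced, never silently worked around.
- **Region coding** — watershed and marine polygon sets (GeoJSON), merged
  with collision checking; Douglas–Peucker simplification with a
  tolerance in metres (measured on a local equirectangular projection);
  deterministic point-in-region assignment (boundary-inclusive, watershed
  over marine, then smaller area, then lexicographic code).
- **Field model** — surveys (with an optional site reference or free-text
  "other" site), multi-depth environmental measurements from a controlled
  vocabulary (temperature, salinity, pH, PAR, turbidity, conductivity,
  dissolved oxygen, nutrients, pigments), polymorphic water/sediment
  collections and filter/sub-core samples bound injectively to barcodes.
- **Wet lab** — extractions (barcoded themselves), qPCR/ddPCR with
  replicates, library preps with primer and i7/i5 index pairs, pooled
  libraries that refuse index collisions (demultiplexability), run preps,
  run results and opaque FASTQ file records (name, SHA-256, size);
  `lineage()` walks any FASTQ record back to its field site and names the
  first missing hop when the chain is broken.
- **Bioinformatics metadata** — quality-trimming and denoise/cluster
  parameters, ASV/OTU feature sequences with per-extraction read counts,
  and a nine-rank curated taxonomy (domain … species, including
  supergroup and phylum/division) with prefix-sharing insertion and
  manually verified annotations.
- **Freezer inventory** — freezer/rack/box/position addressing and an
  append-only ledger (add, check-out, return with actions and aliquots,
  permanent removal) whose replay provably reconstructs live state.
- **MIxS export** — MIMARKS-SURVEY water and sediment tables with
  mandatory (M) / conditionally mandatory (C) / environmentally dependent
  (E) field classification, driven by an editable checklist config, written
  as RFC 4180 CSV or TSV.
- **Store** — a single-file JSON store with per-table CSV round-trips,
  role-based CRUD gating (admin / graduate / intern presets), join views
  mirroring common queries, ETL ingestion of denormalized flat field CSVs
  (idempotent upserts, per-row rejects with reasons) and a full
  referential-integrity scan.
- **Synthetic fixtures** — a deterministic generator that builds a complete
  valid store (or one with seeded validation defects) from a small spec, so
  everything is testable offline.

## Worked example

```python
from medna import FixtureSpec, generate_fixture
from medna import mixs, wetlab

store = generate_fixture(FixtureSpec(seed=7, n_sites=2, n_surveys_per_site=2,
                                     n_samples_per_survey=3))
print("sites:", store.sites.all_ids())
checklist = mixs.load_checklist("water")
rows = mixs.build_mixs_rows(store, "water", checklist)
report = mixs.validate_rows(rows, checklist)
print(f"water package: {len(rows)} rows, {len(report.violations)} violations")
chain = wetlab.lineage(store, sorted(store.tables["fastq_files"])[0])
print(" -> ".join(type(r).__name__ for r in chain))
```

prints

```
sites: ['pAND_L01', 'pGOM_C01']
water package: 8 rows, 0 violations
FastqFile -> RunResult -> RunPrep -> PooledLibrary -> LibraryPrep -> Extraction -> FieldSample -> FieldCollection -> FieldSurvey -> FieldSite
```

Two sites were minted (`pAND_L01` in a watershed, `pGOM_C01` in the marine
area), the 8 water-filter extractions with sequenced FASTQ records each
became one MIMARKS-SURVEY row with no mandatory field missing, and a FASTQ
record resolves its complete ten-hop provenance chain to the field site.

The same pipelines are available from the shell:

```bash
medna fixtures --seed 7 -o store.json   # synthetic store
medna check --store store.json          # integrity scan
medna export-mixs --package water --format csv -o water.csv --store store.json
medna mint-labels --site pAND_L01 --year 22 --material w --count 3 --store store.json
```

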