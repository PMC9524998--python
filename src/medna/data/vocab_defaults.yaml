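# Default model-based vocabularies. Administrators may extend these at run
# time; enumerated vocabularies are hard-coded in medna.vocab and cannot be
# edited. Codes must contain no whitespace and no underscores (underscores
# are the separator of the identifier grammars).
vocabularies:
  system_type:
    - {code: L, label: Lake}
    - {code: S, label: Stream/River}
    - {code: E, label: Estuary}
    - {code: C, label: Coast}
    - {code: P, label: Pelagic}
    - {code: A, label: Aquarium}
    - {code: M, label: Mock community}
  sample_material:
    - {code: w, label: Water}
    - {code: s, label: Sediment}
    - {code: e, label: DNA extraction}
    - {code: p, label: Pooled library}
  env_measure_type:
    - {code: water-temp, label: Water temperature, unit: "degC"}
    - {code: salinity, label: Salinity, unit: PSU}
    - {code: ph, label: pH, unit: pH}
    - {code: par1, label: "Photosynthetically active radiation, channel 1 (up-looking)", unit: "umol/m2/s"}
    - {code: par2, label: "Photosynthetically active radiation, channel 2 (down-looking)", unit: "umol/m2/s"}
    - {code: turbidity, label: Turbidity, unit: NTU}
    - {code: conductivity, label: Conductivity, unit: "uS/cm"}
    - {code: do, label: Dissolved oxygen, unit: "mg/L"}
    - {code: no3no2, label: Nitrate and nitrite, unit: "uM"}
    - {code: pheophytin, label: Pheophytin, unit: "ug/L"}
    - {code: chla, label: Chlorophyll a, unit: "ug/L"}
  return_action:
    - {code: extraction, label: DNA extraction}
    - {code: pcr, label: PCR}
    - {code: library-prep, label: Library preparation}
    - {code: pooled-library, label: Library pooling}
    - {code: run-prep, label: Sequencing run preparation}
    - {code: run-result, label: Sequencing run result}
    - {code: none, label: No action taken}
  process_location:
    - {code: UMAINE, label: University of Maine core facility}
  denoise_cluster_method:
    - {code: denoise-asv, label: Denoising to amplicon sequence variants}
    - {code: cluster-otu, label: Clustering to operational taxonomic units}
    - {code: dereplicate, label: Dereplication only}
  annotation_method:
    - {code: naive-bayes, label: Naive Bayes classifier, confidence_scale: unit-interval}
    - {code: blast, label: BLAST-family alignment, confidence_scale: bitscore}

# Maps a barcode material code to the field-sample kind it may label.
material_sample_kind:
  w: filter
  s: subcore

# Material codes used when minting barcodes for non-field entities.
derived_material_codes:
  extraction: e
  pooled_library: p
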