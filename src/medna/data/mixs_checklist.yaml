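# MIMARKS-SURVEY checklist configuration.
#
# Each package (water, sediment) lists its fields in export order.
#   requirement: M (mandatory) | C (conditionally mandatory) | E
#                (environmentally dependent; never invalidates a row)
#   source_path: dotted path into the joined lineage record
#                (survey / site / collection / sample / extraction /
#                 library / primer_pair / prep / run / fastq / measurement)
#   formatter:   identity (default) | date_iso | lat_lon | join_semicolon
#                | pcr_primers
#   required_if: for C fields — the field is mandatory when the named
#                sibling checklist field is nonempty in the same row.
#
# This minimal field set follows the public MIxS 5 survey packages; deployments
# extend it by editing this file, not the code.
packages:
  water:
    - {name: samp_name, requirement: M, source_path: sample.barcode}
    - {name: project_name, requirement: M, source_path: survey.projects, formatter: join_semicolon}
    - {name: collection_date, requirement: M, source_path: survey.datetime, formatter: date_iso}
    - {name: geo_loc_name, requirement: M, source_path: site.general_location_name}
    - {name: lat_lon, requirement: M, source_path: site, formatter: lat_lon}
    - {name: env_broad_scale, requirement: M, source_path: site.envo_biome}
    - {name: env_local_scale, requirement: M, source_path: site.envo_feature}
    - {name: env_medium, requirement: M, source_path: collection.kind}
    - {name: depth, requirement: E, source_path: measurement.depth_m}
    - {name: samp_mat_process, requirement: E, source_path: sample.payload.filter_material}
    - {name: nucl_acid_ext, requirement: C, source_path: extraction.method, required_if: samp_name}
    - {name: target_gene, requirement: M, source_path: primer_pair.target_gene}
    - {name: pcr_primers, requirement: C, source_path: primer_pair, formatter: pcr_primers, required_if: target_gene}
    - {name: seq_meth, requirement: C, source_path: prep.kit, required_if: fastq_filename}
    - {name: lib_layout, requirement: C, source_path: library.lib_layout, required_if: target_gene}
    - {name: fastq_filename, requirement: E, source_path: fastq.filename}
    - {name: fastq_checksum_sha256, requirement: E, source_path: fastq.checksum_sha256}
  sediment:
    - {name: samp_name, requirement: M, source_path: sample.barcode}
    - {name: project_name, requirement: M, source_path: survey.projects, formatter: join_semicolon}
    - {name: collection_date, requirement: M, source_path: survey.datetime, formatter: date_iso}
    - {name: geo_loc_name, requirement: M, source_path: site.general_location_name}
    - {name: lat_lon, requirement: M, source_path: site, formatter: lat_lon}
    - {name: env_broad_scale, requirement: M, source_path: site.envo_biome}
    - {name: env_local_scale, requirement: M, source_path: site.envo_feature}
    - {name: env_medium, requirement: M, source_path: collection.kind}
    - {name: depth, requirement: E, source_path: measurement.depth_m}
    - {name: samp_mat_process, requirement: E, source_path: collection.payload.core_method}
    - {name: nucl_acid_ext, requirement: C, source_path: extraction.method, required_if: samp_name}
    - {name: target_gene, requirement: M, source_path: primer_pair.target_gene}
    - {name: pcr_primers, requirement: C, source_path: primer_pair, formatter: pcr_primers, required_if: target_gene}
    - {name: seq_meth, requirement: C, source_path: prep.kit, required_if: fastq_filename}
    - {name: lib_layout, requirement: C, source_path: library.lib_layout, required_if: target_gene}
    - {name: fastq_filename, requirement: E, source_path: fastq.filename}
    - {name: fastq_checksum_sha256, requirement: E, source_path: fastq.checksum_sha256}
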