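# Example metagenome checklist: a small MIxS-style illustration.
# This is NOT the authoritative GSC term list; it exists so the package
# ships a working standard-as-data file that labs can copy and extend.
name: example-metagenome-checklist
version: "1.0"
vocabularies:
  environmental_package: vocab/environmental_package.tsv
  biome: vocab/biome.tsv
  feature: vocab/feature.tsv
  material: vocab/material.tsv
collections:
  - name: project
    fields:
      - key: project_name
        label: Project Name
        type: text
        required: true
        definition: Short name identifying the study.
        example: Lake Ontario time series
      - key: pi_organization
        label: PI Organization
        type: text
        required: true
        definition: Organization of the principal investigator.
        example: University of Example
      - key: pi_email
        label: PI Email
        type: email
        required: true
        example: pi@example.org
      - key: project_description
        label: Project Description
        type: text
        definition: Free-text summary of the study goals.
      - key: project_funding
        label: Funding Source
        type: text
      - key: project_url
        label: Project URL
        type: url
        example: https://example.org/lake-ontario
  - name: sample
    fields:
      - key: collection_date
        label: Collection Date
        type: date
        required: true
        definition: Day the sample was taken (ISO 8601).
        example: "2014-12-08"
      - key: collection_time
        label: Collection Time
        type: time
        example: "14:30:00"
      - key: collection_timestamp
        label: Collection Timestamp
        type: datetime
        definition: Full timestamp if known; overrides date+time.
        example: "2014-12-08T14:30:00Z"
      - key: latitude
        label: Latitude
        type: latitude
        required: true
        units: decimal degrees
        example: "43.6532"
      - key: longitude
        label: Longitude
        type: longitude
        required: true
        units: decimal degrees
        example: "-79.3832"
      - key: depth
        label: Depth
        type: decimal
        units: m
      - key: elevation
        label: Elevation
        type: decimal
        units: m
      - key: biome
        label: Biome
        type: cv_term
        required: true
        vocab: biome
        definition: Broad ecological context of the sample site.
        example: marine biome
      - key: feature
        label: Environmental Feature
        type: cv_term
        required: true
        vocab: feature
        example: coral reef
      - key: material
        label: Environmental Material
        type: cv_term
        required: true
        vocab: material
        example: sea water
      - key: env_package
        label: Environmental Package
        type: cv_term
        required: true
        vocab: environmental_package
        definition: Which environmental package block describes this sample.
        example: water
      - key: sample_code
        label: Sample Code
        type: pattern
        pattern: "[A-Z]{2}[0-9]{4}"
        definition: Internal two-letter, four-digit sample code.
        example: AB1234
      - key: num_replicates
        label: Number of Replicates
        type: integer
      - key: sample_description
        label: Sample Description
        type: text
  - name: library
    subtype: metagenome
    fields:
      - key: sample_name
        label: Sample Name
        type: text
        required: true
        definition: Id of the sample this library was extracted from.
      - key: seq_meth
        label: Sequencing Method
        type: text
        required: true
        example: Illumina NovaSeq
      - key: insert_size
        label: Insert Size
        type: integer
        units: bp
      - key: read_count
        label: Read Count
        type: integer
      - key: run_date
        label: Run Date
        type: date
  - name: ep
    subtype: water
    fields:
      - key: sample_name
        label: Sample Name
        type: text
        required: true
        definition: Id of the sample this block describes.
      - key: temperature
        label: Temperature
        type: decimal
        required: true
        units: "°C"
      - key: salinity
        label: Salinity
        type: decimal
        units: psu
      - key: ph
        label: pH
        type: decimal
      - key: chlorophyll
        label: Chlorophyll
        type: decimal
        units: mg/m3
  - name: ep
    subtype: soil
    fields:
      - key: sample_name
        label: Sample Name
        type: text
        required: true
        definition: Id of the sample this block describes.
      - key: ph
        label: pH
        type: decimal
        required: true
      - key: soil_type
        label: Soil Type
        type: text
        required: true
        example: podzol
      - key: water_content
        label: Water Content
        type: decimal
        units: "%"
      - key: tot_org_carbon
        label: Total Organic Carbon
        type: decimal
        units: g/kg
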