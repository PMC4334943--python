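# Template and vocabulary file formats

Checklists are shipped as data so that standards can be versioned,
diffed and swapped without code changes. Three file kinds exist:
template documents, standalone package documents, and vocabulary term
tables. All are UTF-8 text.

## Template documents (YAML)

One document per template:

```yaml
name: example-metagenome-checklist
version: "1.0"
vocabularies:
  biome: vocab/biome.tsv          # path relative to this file, or inline:
  # biome:
  #   terms:
  #     - {id: "ENVO:00000447", label: marine biome, synonyms: [ocean biome]}
collections:
  - name: project                 # exactly one
    fields:
      - key: project_name         # canonical: lowercase, underscores
        label: Project Name       # display form, free casing
        type: text                # see data types below
        required: true
        definition: Short name identifying the study.
        example: Lake Ontario time series
  - name: sample                  # exactly one
    fields: [...]
  - name: library                 # one or more, distinguished by subtype
    subtype: metagenome
    fields: [...]
  - name: ep                      # one or more environmental packages
    subtype: water                # the package name (mandatory for ep)
    fields: [...]
```

Field attributes: `key` (mandatory), `label`, `type`, `required`,
`definition`, `vocab` (mandatory iff `type: cv_term`), `pattern`
(mandatory iff `type: pattern`; a full-string-anchored regex), `units`,
`example`. Keys must be unique within their collection; every `vocab`
reference must name a registered vocabulary; `pattern` regexes must
compile. Violations are schema errors at load time, naming the offending
key.

Data types: `text`, `integer`, `decimal`, `date`, `time`, `datetime`,
`latitude`, `longitude`, `url`, `email`, `cv_term`, `pattern`. The
validation profile for each is described in `docs/methods.md`.

`write_template` serializes a template (vocabularies inline) to a single
document; `load_template(write_template(t))` reproduces `t`
field-for-field.

## Standalone package documents

An environmental package that can be attached to any template:

```yaml
package:
  name: ep
  subtype: air
  fields: [...]
vocabularies: {}   # optional, for vocabularies the package introduces
```

Loaded with `load_package`, attached with `attach_package` (value
semantics: the input template is never modified).

## Vocabulary term tables (TSV)

Columns: `term_id`, `label`, `synonyms` (pipe-separated), `parents`
(pipe-separated term ids). Term ids and case-folded labels must be
unique; parents must exist. A synonym colliding with a label is shadowed
by the label. `load_obo` imports OBO-format ontology releases into this
form.

The bundled vocabularies (`src/metacap/data/vocab/`) are small curated
ENVO-style subsets for the biome / feature / material triad plus the
package names; they are illustrative, not an authoritative ENVO export.
The bundled template is likewise a working MIxS-style example, not the
authoritative GSC term list.

## Workbook layout

One sheet per collection, named `project`, `sample`,
`library <subtype>`, `ep <package>`. Row 1: canonical keys, with the
reserved entity-id column `id` first. Row 2: human annotation (label,
units in parentheses, `*` marking required keys). Rows 3+: one entity
per row; libraries and ep blocks carry their `sample_name` link as an
ordinary cell. Dialects: `xlsx`, and `tsv-dir` (one TSV per sheet,
spaces in sheet names becoming underscores; byte-deterministic output).
All cells are read back as text; empty cells under known columns read as
empty strings (distinguishable from an absent column). Duplicate-id rows:
first wins, error recorded with its sheet/row/column.
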