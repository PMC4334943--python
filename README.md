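# metacap

Checklist-driven metadata capture and validation for metagenomic
sequencing projects.

Sequence archives are full of datasets whose metadata — where a sample
came from, when and how it was collected, what environment it describes —
is missing, malformed, or recorded in ad-hoc vocabularies, which cripples
downstream comparative analyses. `metacap` is an offline toolkit for labs
and data curators who want project metadata captured early, validated
against a minimum-information checklist (GSC MIxS-style), and exchanged
as ordinary spreadsheets.

## The model

Metadata is stored in a deliberately hybrid schema. Every datum is an
entity–attribute–value row

```
id | collection | key | value
```

so arbitrary key–value pairs can always be captured; organizing rows into
named *collections* is what lets a checklist impose per-collection
contracts — required keys, data types, controlled vocabularies — on the
blessed subset. A study is three tiers: one **project**, many
**samples**, many **libraries** (extractions) per sample, plus exactly
one **environmental-package** block per sample (water, soil, air, …)
describing the sampled environment.

Checklists are *data*, not code: a template is a YAML document declaring
collections, fields and vocabulary references (`docs/template-format.md`),
and environmental packages can be attached from standalone files without
touching the software. Controlled-vocabulary fields (ENVO-style biome,
feature, material, plus the package name) resolve against frozen local
term tables with label/synonym matching and ranked prefix search.

Validation runs on two disjoint levels:

1. **value vs data type** — integers, decimals, ISO 8601 dates/times,
   range-checked decimal-degree coordinates, URLs, emails, regex
   "gatekeepers", vocabulary membership;
2. **structure vs template** — required fields present, hierarchy links
   intact, one environmental-package block per sample; unknown extra
   keys are warnings, never errors.

Reports are ordered, located (entity, collection, key, and sheet/row/
column where applicable) and deterministic. A seeded synthetic generator
produces valid projects and an error injector corrupts them while
recording an exact ledger — the ground truth against which the validator
is required to score perfect precision and recall.

## Worked example

```python
import metacap as mc

t = mc.load_template(mc.example_template_path())
b = mc.make_valid_bundle(t, seed=7, n_samples=2, n_libraries_per_sample=1)
b.samples[0].values["collection_date"] = "12/08/2014"   # US-style date
b.project.values["pi_organization"] = ""                # blank required field
b.samples[1].values["my_custom_note"] = "duplicate of site 4"
report = mc.validate_bundle(b)
print(report.to_text())
```

prints

```
ERROR   missing_required   project:p001.pi_organization: required field 'PI Organization' (pi_organization) is missing or blank
ERROR   not_iso_date       sample:sample_01.collection_date: '12/08/2014' is not an ISO 8601 date (YYYY-MM-DD)
WARNING unknown_key        sample:sample_02.my_custom_note: key 'my_custom_note' is not part of the 'sample' checklist
INVALID: 2 error(s), 1 warning(s)
```

The blank required organization and the non-ISO date are errors (the
bundle is invalid, CLI exit status 1); the extra key is flagged but
permitted — added fields are flexibility, not faults.

The same loop works from the shell: `metacap new` writes a blank
multi-sheet workbook (XLSX, or a diffable directory of TSVs), users edit
it, and `metacap validate` re-checks it, exiting 0 (valid), 1
(validation errors), 2 (usage/configuration) or 3 (I/O or parse
failure). `metacap generate` produces seeded synthetic workbooks,
optionally with injected errors and their ledger, and
`metacap vocab-search` explores the controlled vocabularies.

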