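# Methods

## The capture model

The storage primitive is an entity–attribute–value row,
`id | collection | key | value`. A fixed relational schema would be too
restrictive for metadata that is in constant flux, and a fully
schema-free store offers no validation; the hybrid keeps both: any key
can be captured on any entity, and entities grouped into a named
collection additionally answer to that collection's contract in the
template. Values are raw strings everywhere below the validation layer —
the store never interprets, so nothing is lost or coerced before
checking.

A project bundle is three tiers: one project entity, n samples, m
libraries per sample, plus exactly one environmental-package (ep) block
per sample. Children link to their sample through the reserved
`sample_name` key, the same convention a flat spreadsheet uses, so the
hierarchy needs no side tables and survives every serialization
(EAV TSV, XLSX, TSV directory) unchanged. One ep block per sample is a
modelling choice: a sample describes one sampled environment; a study
mixing environments assigns different packages to different samples.

## Validation

Two levels, disjoint by construction:

* **Level 1 — value vs data type.** Applied to every non-empty value
  whose key the template declares. Empty values are never level-1
  issues: whether emptiness matters depends on the required flag, which
  is level 2's concern. This split keeps each issue attributable to
  exactly one rule, which in turn is what makes the injection oracle
  (below) exact.
* **Level 2 — structure vs template.** Required-but-blank keys
  (`missing_required`), keys outside the contract (`unknown_key`,
  severity *warning* — extra fields are a feature), an empty sample tier
  (`no_samples`), dangling `sample_name` links (`broken_link`), and ep
  cardinality per sample (`missing_ep`, `extra_ep`).

Severity is a pure function of the issue code; the full table:

| code | level | severity |
|---|---|---|
| not_integer, not_decimal, not_iso_date, not_iso_time, not_iso_datetime, out_of_range, bad_url, bad_email, cv_violation, pattern_mismatch | 1 | error |
| missing_required, no_samples, missing_ep, extra_ep, broken_link | 2 | error |
| unknown_key | 2 | warning |
| duplicate_header, blank_id, duplicate_id | parse | error |
| unknown_sheet | parse | warning |

Reports order issues by (collection, entity, key, code), so identical
inputs serialize byte-identically. A report is valid iff it contains no
error-severity issue.

### Typing profile

* **Dates/times**: a single ISO 8601 profile — extended format only
  (`YYYY-MM-DD`, `HH:MM[:SS]`, date`T`time with optional `Z`/`±HH:MM`
  offset), years 0001–9999, no fractional seconds, real calendar
  validity (month lengths, Gregorian leap rule) computed in-package.
  Basic format (`YYYYMMDD`) is rejected: one unambiguous form beats
  permissiveness in spreadsheets. Datetimes without a zone designator
  are accepted and the offset is preserved when present.
* **Coordinates**: decimal degrees (WGS84 assumed), latitude in
  [-90, 90], longitude in [-180, 180]; DMS strings rejected — one
  canonical machine form.
* **Numbers**: plain/scientific notation; no locale parsing, comma
  decimals rejected.
* **URL/email**: structural minimum only (`scheme://authority`,
  `local@domain`); no deliverability claims.
* **Gatekeepers**: regexes are full-string anchored — controlled syntax
  means the whole value conforms. Compilability is checked at template
  load, so a bad pattern is a configuration error, never a runtime one.
* **Whitespace**: leading/trailing trimmed before every check; internal
  whitespace significant.

### Controlled vocabularies

Frozen local term tables stand behind the same narrow interface
(resolve, ranked search) a live ontology service would; this keeps the
package fully offline and testable while leaving a live adapter as an
extension point. Resolution matches exact term id, then case-insensitive
label, then case-insensitive synonym (labels shadow colliding synonyms,
deterministically). Search ranks exact label, label prefix, label
substring, then synonym matches, ties broken by case-folded label.
Case-insensitive matching reflects how values arrive from dropdowns and
hand-edited cells.

## Spreadsheet round trip

The workbook layout is this package's own dialect (documented in
`template-format.md`); the XLSX dialect is what users edit, the TSV
directory dialect exists because byte-deterministic, diffable output is
what tests and version control want. All cells are read as text — no
native date/number coercion — because silent spreadsheet coercion is the
classic way metadata gets mangled before validation can see it.
Deterministic tie-breaks on read: duplicate header columns and duplicate
entity-id rows keep the first occurrence and record a located error;
blank-id rows are skipped with an error; unknown sheets are warnings.
Empty cells under known columns read as empty strings, so a blanked
required field survives a round trip and is still caught at level 2.

## Synthetic data and the injection oracle

The generator emulates a well-run capture session: every declared field
of every entity filled with a type-valid value (CV terms drawn uniformly
from the vocabulary, dates from a fixed 2005–2020 window, coordinates
uniform in range, pattern fields using the field's example). It makes no
attempt at realistic biological value *distributions* — passing tests
demonstrate contract conformance and validator exactness, not that real
field data looks like this. Real-world failure modes outside the
injector's closed code set (encoding damage, merged cells, semantically
wrong but type-valid values) are correspondingly out of scope.

The injector corrupts *after* generation and records every defect in a
ledger, which is therefore exact ground truth. Design constraints that
keep it exact: structural deletions (`no_samples`, `missing_ep`) are
applied before value corruptions so every later defect lands on a
surviving entity; each (entity, key) location is corrupted at most once;
`broken_link` targets libraries only (breaking an ep block's link would
also orphan its sample and yield a second issue); `missing_required`
never blanks `sample_name` for the same reason. `extra_ep` has no
injector — it is reachable only through hand-edited workbooks — and is
covered by a direct test instead. Infeasible requests fail atomically.

The randomized trial driver draws bundle sizes (1–10 samples, 0–4
libraries each) and defect mixes (1–6 defects across all injectable
codes) from a seed, re-drawing deterministically when a mix is
infeasible for the drawn bundle. All randomness flows through one
explicit `random.Random`; nothing touches global PRNG state.

## Problem sizes

The self-checks run 500 randomized injection trials, 100 workbook round
trips per dialect, a ~8×10³-string date/time grammar, 100 bundles for CV
resolution and 50 ranked-search queries, and 20 prefill pairs — sizes at
which every property is exercised across all code paths while the whole
suite stays fast enough to run on every change.

## Known limitations

* The bundled template and vocabularies are illustrative subsets, not
  the authoritative GSC/ENVO lists; production deployments supply their
  own data files.
* Consistency between a sample's `env_package` value and the subtype of
  its ep block is not cross-validated.
* Multi-valued keys are supported in the EAV store but the workbook
  dialect treats cells as single values (tuples serialize
  pipe-separated, one way).
* Entity-id uniqueness is enforced within a workbook sheet, not across
  sheets.
* No unit conversion, no auto-repair of invalid values, no live
  ontology or repository clients.
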