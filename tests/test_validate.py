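"""Two-level validation engine: composition, disjointness, determinism."""

import pytest

import metacap as mc
from metacap.report import LEVEL1_CODES, LEVEL2_CODES


class TestValues:
    def test_bad_date_and_bad_latitude_give_exactly_two_errors(self, bundle):
        bundle.samples[0].values["collection_date"] = "12/08/2014"
        bundle.samples[1].values["latitude"] = "95.0"
        rep = mc.validate_values(bundle)
        assert sorted(rep.codes()) == ["not_iso_date", "out_of_range"]

    def test_fully_valid_bundle_gives_empty_report(self, bundle):
        rep = mc.validate_values(bundle)
        assert rep.issues == [] and rep.is_valid

    def test_cv_violation_reported_once(self, bundle):
        bundle.samples[0].values["biome"] = "not_a_real_biome"
        rep = mc.validate_values(bundle)
        assert rep.codes() == ["cv_violation"]
        assert rep.issues[0].location.key == "biome"

    def test_keys_outside_template_skipped_at_level_one(self, bundle):
        bundle.samples[0].values["my_custom_note"] = "12/08/2014"  # not a date field
        assert mc.validate_values(bundle).issues == []


class TestStructure:
    def test_blank_contact_organization_names_that_key(self, bundle):
        bundle.project.values["pi_organization"] = ""
        rep = mc.validate_structure(bundle)
        assert [(i.code, i.location.key) for i in rep.issues] == [
            ("missing_required", "pi_organization")
        ]
        assert not rep.is_valid

    def test_empty_project_entity_yields_k_missing_required(self, template, bundle):
        bundle.project.values.clear()
        rep = mc.validate_structure(bundle)
        required = mc.required_fields(template, "project")
        assert rep.codes() == ["missing_required"] * len(required)

    def test_extra_key_is_warning_not_error(self, bundle):
        bundle.samples[0].values["my_custom_note"] = "free text"
        rep = mc.validate_structure(bundle)
        assert rep.codes() == ["unknown_key"]
        assert rep.issues[0].severity == "warning"
        assert rep.is_valid  # flexibility: extra fields never invalidate

    def test_no_samples_error(self, template):
        b = mc.make_valid_bundle(template, seed=1, n_samples=0)
        rep = mc.validate_structure(b)
        assert rep.codes() == ["no_samples"]

    def test_broken_library_link(self, bundle):
        bundle.libraries[0].values["sample_name"] = "ghost"
        rep = mc.validate_structure(bundle)
        assert rep.codes() == ["broken_link"]

    def test_missing_and_extra_ep_blocks(self, bundle):
        removed = bundle.ep_blocks.pop(0)
        dup_values = dict(removed.values, sample_name=bundle.samples[1].id)
        bundle.ep_blocks.append(mc.Entity(
            id="dup_ep", collection=removed.collection, values=dup_values,
        ))
        rep = mc.validate_structure(bundle)
        assert sorted(rep.codes()) == ["extra_ep", "missing_ep"]


class TestMerge:
    def test_counts_additive_and_disjoint(self, bundle):
        bundle.project.values["pi_organization"] = ""   # level 2
        bundle.samples[0].values["collection_date"] = "bad"  # level 1
        bundle.samples[1].values["extra"] = "x"          # level 2 warning
        v = mc.validate_values(bundle)
        s = mc.validate_structure(bundle)
        full = mc.validate_bundle(bundle)
        assert len(full.issues) == len(v.issues) + len(s.issues)
        assert full.pairs() == v.pairs() | s.pairs()

    def test_level_code_families_never_overlap(self, bundle):
        bundle.samples[0].values["collection_date"] = "bad"
        bundle.project.values["pi_organization"] = ""
        assert {i.code for i in mc.validate_values(bundle).issues} <= LEVEL1_CODES
        assert {i.code for i in mc.validate_structure(bundle).issues} <= LEVEL2_CODES
        assert LEVEL1_CODES & LEVEL2_CODES == frozenset()

    def test_valid_bundle_is_valid(self, bundle):
        assert mc.validate_bundle(bundle).is_valid

    def test_injected_bundle_matches_ledger(self, template, bundle):
        corrupted, ledger = mc.inject_errors(
            bundle, {"missing_required": 2, "not_iso_date": 1, "broken_link": 1},
            seed=9,
        )
        rep = mc.validate_bundle(corrupted)
        assert rep.pairs() == ledger.pairs()
        assert len(rep.issues) == len(ledger)


class TestReportModel:
    def test_is_valid_iff_no_error_severity(self, bundle):
        bundle.samples[0].values["note"] = "x"  # warning only
        rep = mc.validate_bundle(bundle)
        assert rep.is_valid and rep.issues

    def test_deterministic_byte_identical_serialization(self, bundle):
        bundle.samples[2].values["collection_date"] = "bad"
        bundle.project.values["pi_organization"] = ""
        a = mc.validate_bundle(bundle).to_tsv()
        b = mc.validate_bundle(bundle).to_tsv()
        assert a == b
        header, *rows = a.splitlines()
        assert header.startswith("severity\tcode\tentity")
        assert rows == sorted(rows, key=lambda r: tuple(r.split("\t")[3:4]))

    def test_ordering_by_collection_entity_key_code(self, bundle):
        bundle.samples[1].values["collection_date"] = "bad"
        bundle.samples[0].values["latitude"] = "99"
        rep = mc.validate_bundle(bundle)
        keys = [i.sort_key() for i in rep.issues]
        assert keys == sorted(keys)

    def test_monotonicity_valid_optional_field_never_adds_errors(self, bundle):
        before = mc.validate_bundle(bundle).error_count
        bundle.samples[0].values["depth"] = "12.5"  # optional, valid
        assert mc.validate_bundle(bundle).error_count == before


def test_unknown_issue_code_rejected():
    with pytest.raises(ValueError):
        mc.ValidationIssue("error", "not_a_code", mc.Location("e", "sample"), "m")
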