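"""Workbook layout, determinism, and the read/write round-trip laws."""

import shutil

import pytest

import metacap as mc
from metacap.spreadsheet import sheet_name

EXPECTED_SHEETS = ["project", "sample", "library metagenome", "ep water", "ep soil"]


def _tsv_lines(path, stem):
    return (path / f"{stem}.tsv").read_text(encoding="utf-8").splitlines()


class TestBlankWorkbook:
    def test_one_sheet_per_collection(self, template, tmp_path):
        mc.blank_workbook(template, tmp_path / "blank", dialect="tsv-dir")
        stems = sorted(p.stem for p in (tmp_path / "blank").glob("*.tsv"))
        assert stems == sorted(s.replace(" ", "_") for s in EXPECTED_SHEETS)

    def test_xlsx_sheet_names_match_layout(self, template, tmp_path):
        import openpyxl

        out = tmp_path / "blank.xlsx"
        mc.blank_workbook(template, out, dialect="xlsx")
        wb = openpyxl.load_workbook(out)
        assert wb.sheetnames == EXPECTED_SHEETS

    def test_header_row_is_declaration_order(self, template, tmp_path):
        mc.blank_workbook(template, tmp_path / "blank", dialect="tsv-dir")
        header = _tsv_lines(tmp_path / "blank", "sample")[0].split("\t")
        assert header == ["id"] + template.collection("sample").keys()

    def test_annotation_row_marks_required_and_units(self, template, tmp_path):
        mc.blank_workbook(template, tmp_path / "blank", dialect="tsv-dir")
        annotation = _tsv_lines(tmp_path / "blank", "sample")[1]
        assert "Latitude (decimal degrees) *" in annotation
        assert "Collection Date *" in annotation

    def test_tsv_dir_output_is_deterministic(self, template, tmp_path):
        mc.blank_workbook(template, tmp_path / "a", dialect="tsv-dir")
        mc.blank_workbook(template, tmp_path / "b", dialect="tsv-dir")
        for stem in ("project", "sample", "ep_water"):
            assert (tmp_path / "a" / f"{stem}.tsv").read_bytes() == (
                tmp_path / "b" / f"{stem}.tsv"
            ).read_bytes()

    def test_unknown_dialect_rejected(self, template, tmp_path):
        with pytest.raises(ValueError):
            mc.blank_workbook(template, tmp_path / "x", dialect="ods")


class TestWriteWorkbook:
    def test_one_row_per_entity(self, template, bundle, tmp_path):
        mc.write_workbook(bundle, template, tmp_path / "wb", dialect="tsv-dir")
        assert len(_tsv_lines(tmp_path / "wb", "sample")) == 2 + 3
        assert len(_tsv_lines(tmp_path / "wb", "library_metagenome")) == 2 + 6
        assert len(_tsv_lines(tmp_path / "wb", "project")) == 2 + 1

    def test_empty_string_cell_distinguishable_from_absent_column(
        self, template, bundle, tmp_path
    ):
        bundle.samples[0].values["depth"] = ""
        mc.write_workbook(bundle, template, tmp_path / "wb", dialect="tsv-dir")
        again, issues = mc.read_workbook(tmp_path / "wb", template)
        assert issues == []
        assert again.samples[0].values["depth"] == ""
        assert "depth" in again.samples[0].values

    def test_collection_unknown_to_template_is_schema_error(self, template, bundle,
                                                            tmp_path):
        bundle.libraries[0].collection = "library/amplicon"
        with pytest.raises(mc.SchemaError):
            mc.write_workbook(bundle, template, tmp_path / "wb", dialect="tsv-dir")


class TestReadWorkbook:
    @pytest.mark.parametrize("dialect", ["xlsx", "tsv-dir"])
    def test_round_trip_identity(self, template, bundle, tmp_path, dialect):
        out = tmp_path / ("wb.xlsx" if dialect == "xlsx" else "wb")
        mc.write_workbook(bundle, template, out, dialect)
        again, issues = mc.read_workbook(out, template)
        assert issues == []
        assert again == bundle

    def test_cross_dialect_equivalence(self, template, tmp_path):
        for seed in range(5):
            b = mc.make_valid_bundle(template, seed=seed, n_samples=2,
                                     package="soil" if seed % 2 else "water")
            mc.write_workbook(b, template, tmp_path / f"x{seed}.xlsx", "xlsx")
            mc.write_workbook(b, template, tmp_path / f"t{seed}", "tsv-dir")
            bx, _ = mc.read_workbook(tmp_path / f"x{seed}.xlsx", template)
            bt, _ = mc.read_workbook(tmp_path / f"t{seed}", template)
            assert bx == bt == b

    def test_extra_sheet_warns_but_parses_rest(self, template, bundle, tmp_path):
        mc.write_workbook(bundle, template, tmp_path / "wb", dialect="tsv-dir")
        (tmp_path / "wb" / "notes.tsv").write_text("id\tnote\n", encoding="utf-8")
        again, issues = mc.read_workbook(tmp_path / "wb", template)
        assert again == bundle
        assert [i.code for i in issues] == ["unknown_sheet"]
        assert issues[0].severity == "warning"

    def test_duplicate_entity_id_first_row_wins(self, template, bundle, tmp_path):
        mc.write_workbook(bundle, template, tmp_path / "wb", dialect="tsv-dir")
        sample_tsv = tmp_path / "wb" / "sample.tsv"
        lines = sample_tsv.read_text(encoding="utf-8").splitlines()
        dup = lines[3].split("\t")
        dup[0] = lines[2].split("\t")[0]  # reuse first sample's id
        lines[3] = "\t".join(dup)
        sample_tsv.write_text("\n".join(lines) + "\n", encoding="utf-8")
        again, issues = mc.read_workbook(tmp_path / "wb", template)
        assert [i.code for i in issues] == ["duplicate_id"]
        assert issues[0].location.row == 4
        assert len(again.samples) == 2
        assert again.samples[0].values == bundle.samples[0].values

    def test_blank_id_row_skipped_with_located_error(self, template, bundle,
                                                     tmp_path):
        mc.write_workbook(bundle, template, tmp_path / "wb", dialect="tsv-dir")
        sample_tsv = tmp_path / "wb" / "sample.tsv"
        lines = sample_tsv.read_text(encoding="utf-8").splitlines()
        row = lines[2].split("\t")
        row[0] = ""
        lines.append("\t".join(row))
        sample_tsv.write_text("\n".join(lines) + "\n", encoding="utf-8")
        again, issues = mc.read_workbook(tmp_path / "wb", template)
        assert [i.code for i in issues] == ["blank_id"]
        assert issues[0].location.sheet == "sample"
        assert issues[0].location.row == 6
        assert len(again.samples) == 3

    def test_every_parse_issue_carries_sheet_row_column(self, template, bundle,
                                                        tmp_path):
        mc.write_workbook(bundle, template, tmp_path / "wb", dialect="tsv-dir")
        sample_tsv = tmp_path / "wb" / "sample.tsv"
        lines = sample_tsv.read_text(encoding="utf-8").splitlines()
        lines[0] += "\tdepth"  # duplicate header key
        row = lines[2].split("\t")
        row[0] = ""
        lines.append("\t".join(row))
        sample_tsv.write_text("\n".join(lines) + "\n", encoding="utf-8")
        (tmp_path / "wb" / "misc.tsv").write_text("id\n", encoding="utf-8")
        _, issues = mc.read_workbook(tmp_path / "wb", template)
        assert {i.code for i in issues} == {"duplicate_header", "blank_id",
                                            "unknown_sheet"}
        for i in issues:
            assert i.location.sheet and i.location.row and i.location.column

    def test_missing_workbook_raises_io_error(self, template, tmp_path):
        with pytest.raises(OSError):
            mc.read_workbook(tmp_path / "nope.xlsx", template)

    def test_dialect_inferred_from_path_shape(self, template, bundle, tmp_path):
        mc.write_workbook(bundle, template, tmp_path / "wb", dialect="tsv-dir")
        again, _ = mc.read_workbook(tmp_path / "wb", template)
        assert again == bundle
        shutil.rmtree(tmp_path / "wb")


def test_seeded_round_trip_sweep(template, tmp_path):
    """Round-trip identity holds across seeded bundles in both dialects."""
    for seed in range(10):
        b = mc.make_valid_bundle(
            template, seed=seed, n_samples=1 + seed % 4,
            n_libraries_per_sample=seed % 3,
            package=("water", "soil")[seed % 2],
        )
        for dialect, out in (("xlsx", tmp_path / f"s{seed}.xlsx"),
                             ("tsv-dir", tmp_path / f"s{seed}")):
            mc.write_workbook(b, template, out, dialect)
            again, issues = mc.read_workbook(out, template)
            assert issues == [] and again == b


def test_sheet_names(template):
    assert [sheet_name(c) for c in template.collections] == EXPECTED_SHEETS
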