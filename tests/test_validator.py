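"""Validator rule battery: generator/validator consistency, the one-defect
one-detection matrix, report determinism and JSON round-tripping."""

import copy

import pytest

from snirfkit import (DEFECTS, REQUIRED_METADATA_TAGS, Finding, Severity,
                      corrupt, report_from_json, report_to_json, validate)


class TestValidFiles:
    def test_minimal_model_valid(self, minimal_model):
        report = validate(minimal_model)
        assert report.valid and not report.errors()

    def test_fig2_model_valid(self, fig2_model):
        assert validate(fig2_model).valid

    def test_generated_file_valid_on_disk(self, corpus_path):
        report = validate(corpus_path)
        assert report.valid
        assert not report.errors()

    def test_reports_are_deterministic(self, corpus_path):
        assert report_to_json(validate(corpus_path)) == \
            report_to_json(validate(corpus_path))


class TestDefectMatrix:
    @pytest.mark.parametrize("defect", sorted(DEFECTS))
    def test_each_defect_detected_at_seeded_location(self, defect, tmp_path,
                                                     corpus_model):
        res = corrupt(corpus_model, defect, str(tmp_path / "bad.snirf"),
                      seed=3)
        report = validate(res.path)
        hits = [f for f in report.findings
                if f.code == res.code and f.location == res.location]
        assert hits, (f"{defect}: expected {res.code} at {res.location}, "
                      f"got {[(f.code, f.location) for f in report.findings]}")

    def test_uncorrupted_twin_has_no_error_findings(self, corpus_path):
        assert not validate(corpus_path).errors()

    def test_unknown_defect_name_rejected(self, tmp_path, corpus_model):
        with pytest.raises(ValueError):
            corrupt(corpus_model, "no_such_defect",
                    str(tmp_path / "x.snirf"))


class TestModelRules:
    def test_missing_data_block_fails(self, minimal_model):
        minimal_model.nirs[0].data.clear()
        report = validate(minimal_model)
        assert not report.valid
        assert report.by_code("REQUIRED_MISSING")

    def test_missing_probe_geometry_fails(self, minimal_model):
        minimal_model.nirs[0].probe.source_pos_3d = None
        report = validate(minimal_model)
        assert not report.valid

    def test_empty_nirs_collection_fails(self, minimal_model):
        minimal_model.nirs.clear()
        assert not validate(minimal_model).valid

    @pytest.mark.parametrize("tag", REQUIRED_METADATA_TAGS)
    def test_each_required_tag_enforced(self, tag, minimal_model):
        model = copy.deepcopy(minimal_model)
        del model.nirs[0].metadata.tags[tag]
        report = validate(model)
        findings = report.by_code("METADATA_MISSING")
        assert len(findings) == 1
        assert tag in findings[0].message

    def test_zero_channel_block_is_error(self, minimal_model):
        import numpy as np
        block = minimal_model.nirs[0].data[0]
        block.data_time_series = np.zeros((2, 0))
        block.measurement_list.clear()
        report = validate(minimal_model)
        assert report.by_code("EMPTY_DATA")
        assert not report.valid

    def test_unknown_data_type_is_warning_only(self, minimal_model):
        minimal_model.nirs[0].data[0].measurement_list[0].data_type = 301
        report = validate(minimal_model)
        assert report.by_code("UNKNOWN_DATA_TYPE")
        assert report.valid  # warnings never flip validity

    def test_processed_requires_label(self, minimal_model):
        ml = minimal_model.nirs[0].data[0].measurement_list[0]
        ml.data_type = 99999
        assert not validate(minimal_model).valid
        ml.data_type_label = "HbO"
        assert validate(minimal_model).valid

    @pytest.mark.parametrize("version, ok", [
        ("1.0", True), ("1.0.2", True), ("10.21.3", True),
        ("banana", False), ("1", False), ("1.a", False), ("1..2", False),
    ])
    def test_semantic_version_parsing(self, version, ok, minimal_model):
        minimal_model.format_version = version
        report = validate(minimal_model)
        assert bool(report.by_code("VERSION_UNPARSEABLE")) == (not ok)

    def test_probe_2d_3d_row_count_mismatch(self, fig2_model):
        import numpy as np
        fig2_model.nirs[0].probe.source_pos_2d = np.zeros((5, 2))
        report = validate(fig2_model)
        assert report.by_code("DIMENSION_MISMATCH")

    def test_findings_sorted_by_location_then_code(self, minimal_model):
        del minimal_model.nirs[0].metadata.tags["SubjectID"]
        minimal_model.format_version = "junk"
        minimal_model.nirs[0].data[0].measurement_list[0].wavelength_index = 9
        report = validate(minimal_model)
        keys = [(f.location, f.code) for f in report.findings]
        assert keys == sorted(keys)


class TestUnreadable:
    def test_garbage_file_yields_single_fatal(self, tmp_path):
        p = tmp_path / "junk.snirf"
        p.write_bytes(b"\x00\x01\x02 not hdf5")
        report = validate(str(p))
        assert not report.valid
        assert [f.severity for f in report.findings] == [Severity.FATAL]
        assert report.findings[0].code == "UNREADABLE"


class TestJsonReports:
    def test_empty_report_document(self, minimal_model):
        report = validate(minimal_model)
        doc = report_to_json(report)
        assert '"valid": true' in doc and '"findings": []' in doc

    def test_single_finding_fields_complete(self, minimal_model):
        del minimal_model.nirs[0].metadata.tags["SubjectID"]
        report = validate(minimal_model)
        back = report_from_json(report_to_json(report))
        assert back == report
        f = back.findings[0]
        assert isinstance(f, Finding)
        assert f.code and f.severity and f.location and f.message and f.spec_ref

    def test_serialize_parse_serialize_byte_identical(self, corpus_model,
                                                      tmp_path):
        res = corrupt(corpus_model, "metadata_missing",
                      str(tmp_path / "bad.snirf"))
        doc = report_to_json(validate(res.path))
        assert report_to_json(report_from_json(doc)) == doc

    def test_document_matches_shipped_schema_shape(self, minimal_model):
        """The shipped JSON schema is the report contract; check the
        document's shape against it by hand (field names, enums)."""
        import json
        from importlib import resources

        schema = json.loads(resources.files("snirfkit.schemas")
                            .joinpath("validation_report.schema.json")
                            .read_text())
        del minimal_model.nirs[0].metadata.tags["TimeUnit"]
        doc = json.loads(report_to_json(validate(minimal_model)))
        assert set(doc) == set(schema["required"])
        finding_schema = schema["properties"]["findings"]["items"]
        for f in doc["findings"]:
            assert set(f) == set(finding_schema["required"])
            assert f["code"] in finding_schema["properties"]["code"]["enum"]
            assert f["severity"] in \
                finding_schema["properties"]["severity"]["enum"]
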