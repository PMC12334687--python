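"""Dataset scanning, rule application, reports, determinism."""

import json
import shutil

import pytest

from mrsbids import (
    FixtureSpec,
    generate_dataset,
    render_report,
    scan,
    validate_dataset,
)
from mrsbids.validator import UnknownFormat


def error_rules(report):
    return {i.rule_id for i in report.issues if i.severity == "error"}


class TestScan:
    def test_inventory_counts(self, valid_dataset):
        inv = scan(valid_dataset)
        assert inv.subjects == ["01", "02"]
        assert inv.sessions["01"] == ["01"]
        assert len(inv.data_files) == 4
        assert len(inv.sidecars) == 4
        assert len(inv.anat_files) == 2
        assert inv.has_dataset_description

    def test_empty_directory(self, tmp_path):
        inv = scan(tmp_path)
        assert inv.subjects == [] and inv.data_files == []
        assert inv.has_dataset_description is False

    def test_not_a_directory(self, tmp_path):
        with pytest.raises(NotADirectoryError):
            scan(tmp_path / "missing")

    def test_stray_file_reported_unless_bidsignored(self, valid_dataset, tmp_path):
        root = tmp_path / "ds"
        shutil.copytree(valid_dataset, root)
        stray = root / "sub-01" / "ses-01" / "mrs" / "notes.txt"
        stray.write_text("scratch")
        report = validate_dataset(root)
        assert "MRS007" in error_rules(report)
        (root / ".bidsignore").write_text("notes.txt\n")
        report = validate_dataset(root)
        assert report.passed

    def test_sourcedata_and_derivatives_skipped(self, valid_dataset, tmp_path):
        root = tmp_path / "ds"
        shutil.copytree(valid_dataset, root)
        for extra in ("sourcedata", "derivatives"):
            d = root / extra / "mrs"
            d.mkdir(parents=True)
            (d / "whatever.dat").write_text("x")
        assert validate_dataset(root).passed


class TestRules:
    def test_valid_dataset_has_zero_issues_of_any_kind(self, valid_dataset):
        report = validate_dataset(valid_dataset)
        assert report.passed
        assert report.issues == []

    def test_missing_sidecar_is_exactly_one_error(self, mutable_dataset):
        from mrsbids import apply_mutation
        apply_mutation(mutable_dataset, "missing-sidecar")
        report = validate_dataset(mutable_dataset)
        errs = [i for i in report.issues if i.severity == "error"]
        assert len(errs) == 1 and errs[0].rule_id == "MRS020"

    def test_dangling_reference_signal(self, mutable_dataset):
        from mrsbids import apply_mutation
        apply_mutation(mutable_dataset, "dangling-referencesignal")
        assert error_rules(validate_dataset(mutable_dataset)) == {"MRS083"}

    def test_reference_must_be_mrsref(self, mutable_dataset):
        # repoint ReferenceSignal at an existing file of the wrong type
        svs_sidecars = sorted(mutable_dataset.rglob("*_svs.json"))
        sc = svs_sidecars[0]
        content = json.loads(sc.read_text())
        content["ReferenceSignal"] = content["AnatomicalImage"]
        sc.write_text(json.dumps(content, indent=2, sort_keys=True))
        assert error_rules(validate_dataset(mutable_dataset)) == {"MRS083"}

    def test_duplicate_acquisition_identity(self, mutable_dataset):
        # run-1 and run-01 are distinct strings but the same acquisition index
        mrs = sorted(mutable_dataset.rglob("*_svs.nii.gz"))[0].parent
        svs = sorted(mrs.glob("*_svs.nii.gz"))[0]
        stem = svs.name[: -len(".nii.gz")]
        base, suffix = stem.rsplit("_", 1)
        for run in ("run-1", "run-01"):
            shutil.copy(svs, mrs / f"{base}_{run}_{suffix}.nii.gz")
            shutil.copy(mrs / f"{stem}.json", mrs / f"{base}_{run}_{suffix}.json")
        assert "MRS081" in error_rules(validate_dataset(mutable_dataset))

    def test_orphan_sidecar_warns(self, mutable_dataset):
        svs = sorted(mutable_dataset.rglob("*_svs.nii.gz"))[0]
        svs.unlink()
        report = validate_dataset(mutable_dataset)
        assert any(
            i.rule_id == "MRS021" and i.severity == "warning"
            for i in report.issues
        )

    def test_voi_label_divergence_warns(self, mutable_dataset):
        # same voi label, different BodyPartDetails across subjects
        sidecars = sorted(mutable_dataset.rglob("*voi-acc_svs.json"))
        assert len(sidecars) >= 2
        content = json.loads(sidecars[0].read_text())
        content["BodyPartDetails"] = "somewhere else entirely"
        sidecars[0].write_text(json.dumps(content, indent=2, sort_keys=True))
        report = validate_dataset(mutable_dataset)
        assert any(i.rule_id == "MRS082" for i in report.issues)
        assert report.passed  # divergence is a warning, not an error

    def test_disabled_rules_are_filtered(self, mutable_dataset):
        from mrsbids import apply_mutation
        apply_mutation(mutable_dataset, "missing-echotime")
        assert not validate_dataset(mutable_dataset).passed
        report = validate_dataset(mutable_dataset, disabled_rules=["MRS030"])
        assert report.passed

    def test_inherited_fragment_supplies_missing_field(self, mutable_dataset):
        """A required field may live in a dataset-root fragment sidecar."""
        from mrsbids import apply_mutation
        apply_mutation(mutable_dataset, "missing-echotime")
        (mutable_dataset / "svs.json").write_text(
            json.dumps({"EchoTime": 0.03}))
        assert validate_dataset(mutable_dataset).passed

    def test_file_level_sidecar_overrides_fragment(self, mutable_dataset):
        # fragment carries a nonsense value; file-level sidecars win
        (mutable_dataset / "svs.json").write_text(
            json.dumps({"EchoTime": "bogus"}))
        assert validate_dataset(mutable_dataset).passed


class TestStrictness:
    def test_strict_errors_are_a_superset(self, mutable_dataset):
        # introduce a warning (recommended field removed) and an info
        sc = sorted(mutable_dataset.rglob("*_svs.json"))[0]
        content = json.loads(sc.read_text())
        del content["WaterSuppression"]
        sc.write_text(json.dumps(content, indent=2, sort_keys=True))
        normal = validate_dataset(mutable_dataset, strictness="normal")
        strict = validate_dataset(mutable_dataset, strictness="strict")
        assert error_rules(strict) >= error_rules(normal)
        assert normal.passed and not strict.passed
        assert strict.counts["warning"] == 0

    def test_unknown_strictness_rejected(self, valid_dataset):
        with pytest.raises(ValueError):
            validate_dataset(valid_dataset, strictness="pedantic")


class TestReport:
    def test_clean_text_report_signals_pass(self, valid_dataset):
        text = render_report(validate_dataset(valid_dataset), "text")
        assert "pass" in text and "0 error(s)" in text

    def test_counts_section(self, mutable_dataset):
        from mrsbids import apply_mutation
        apply_mutation(mutable_dataset, "missing-echotime")
        report = validate_dataset(mutable_dataset)
        text = render_report(report, "text")
        assert f"{report.counts['error']} error(s)" in text
        assert "FAIL" in text

    def test_json_round_trip(self, mutable_dataset):
        from mrsbids import apply_mutation
        apply_mutation(mutable_dataset, "voi-without-bodypart")
        report = validate_dataset(mutable_dataset)
        payload = json.loads(render_report(report, "json"))
        assert len(payload["issues"]) == len(report.issues)
        assert payload["passed"] is False
        assert payload["counts"] == report.counts

    def test_unknown_format(self, valid_dataset):
        with pytest.raises(UnknownFormat):
            render_report(validate_dataset(valid_dataset), "yaml")


class TestDeterminism:
    def test_repeated_runs_identical(self, mutable_dataset):
        from mrsbids import apply_mutation
        apply_mutation(mutable_dataset, "nuc-mismatch")
        a = render_report(validate_dataset(mutable_dataset), "json")
        b = render_report(validate_dataset(mutable_dataset), "json")
        assert a == b

    def test_copied_tree_yields_identical_json_report(self, mutable_dataset, tmp_path):
        from mrsbids import apply_mutation
        apply_mutation(mutable_dataset, "spectralwidth-mismatch")
        copy = tmp_path / "copy"
        shutil.copytree(mutable_dataset, copy)
        assert (
            render_report(validate_dataset(mutable_dataset), "json")
            == render_report(validate_dataset(copy), "json")
        )
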