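"""Sidecar field catalog, document validation, conditionals, inheritance."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsbids import (
    SidecarDocument,
    catalog,
    check_conditional_requirements,
    emit_rule_catalog,
    merge_inherited,
    parse_filename,
    validate_sidecar,
)
from mrsbids.schema import MalformedDocument, lookup

REQUIRED = {"ResonantNucleus", "SpectrometerFrequency", "SpectralWidth", "EchoTime"}

# every MRS-specific sidecar field the standard documents
ALL_FIELDS = REQUIRED | {
    "WaterSuppression", "NumberOfSpectralPoints", "MixingTime",
    "AcquisitionVoxelSize", "ReferenceSignal", "NumberOfTransients",
    "MatrixSize", "VolumeAffineMatrix", "EncodingTechnique", "AnatomicalImage",
    "NumberReceiveCoilActiveElements", "NumberTransmitCoilActiveElements",
    "WaterSuppressionTechnique", "OuterVolumeSuppression",
    "B0ShimmingTechnique", "B1ShimmingTechnique",
    "BodyPart", "BodyPartDetails", "BodyPartDetailsOntology",
    "ChemicalShiftOffset", "ChemicalShiftReference",
    "EditTarget", "EditPulse", "EditCondition", "EchoAcquisition",
    "PulseSequenceTiming", "PulseSequencePulses", "ReceiveGain",
    "PulseSequenceType",
}

GOOD_REQUIRED = {
    "ResonantNucleus": "1H",
    "SpectrometerFrequency": 123.25,
    "SpectralWidth": 2000.0,
    "EchoTime": 0.03,
}


def doc(content, name="sub-01_svs.nii.gz"):
    return SidecarDocument(content=dict(content), source_paths=("x.json",),
                           context=parse_filename(name))


def errors(issues):
    return [i for i in issues if i.severity == "error"]


class TestCatalog:
    def test_catalog_covers_every_documented_field(self):
        assert {f.name for f in catalog()} == ALL_FIELDS

    def test_requirement_levels(self):
        assert lookup("EchoTime").level == "required"
        assert {f.name for f in catalog() if f.level == "required"} == REQUIRED
        assert lookup("WaterSuppression").level == "recommended"
        assert lookup("ReceiveGain").level == "optional"

    def test_types_and_units(self):
        assert lookup("AcquisitionVoxelSize").value_type.name == "number_array(3)"
        assert lookup("AcquisitionVoxelSize").units == "mm"
        assert lookup("VolumeAffineMatrix").value_type.name == "square_matrix(4)"
        assert lookup("SpectrometerFrequency").units == "MHz"
        assert lookup("SpectralWidth").units == "Hz"
        assert lookup("EchoTime").units == "s"

    def test_suffix_applicability(self):
        assert lookup("NumberOfTransients").applicability == {"svs", "unloc"}
        assert lookup("MatrixSize").applicability == {"mrsi"}
        # required fields apply to every data type, reference scans included
        assert lookup("EchoTime").applicability == {"svs", "mrsi", "unloc", "mrsref"}

    def test_rule_catalog_export_is_json_ready(self):
        import json
        cat = emit_rule_catalog()
        assert "MRS030" in cat and cat["MRS030"]["severity"] == "error"
        json.dumps(cat)  # serializable


class TestValidateSidecar:
    def test_complete_required_set_yields_no_errors(self):
        issues = validate_sidecar(doc(GOOD_REQUIRED))
        assert errors(issues) == []
        # absent recommended fields surface as warnings
        assert any(i.rule_id == "MRS031" for i in issues)

    @pytest.mark.parametrize("missing", sorted(REQUIRED))
    def test_each_missing_required_field_is_an_error(self, missing):
        content = {k: v for k, v in GOOD_REQUIRED.items() if k != missing}
        errs = errors(validate_sidecar(doc(content)))
        assert [(e.rule_id, e.location) for e in errs] == [("MRS030", missing)]

    @pytest.mark.parametrize("field, bad", [
        ("WaterSuppression", "yes"),
        ("WaterSuppression", 1),
        ("AcquisitionVoxelSize", [20.0, 20.0]),
        ("AcquisitionVoxelSize", "20x20x20"),
        ("MatrixSize", [8.5, 8.0, 1.0]),       # integers required
        ("NumberOfSpectralPoints", 2048.0),    # integer, not float
        ("PulseSequencePulses", "excitation"), # array required
        ("EchoTime", "30ms"),
    ])
    def test_type_and_shape_violations(self, field, bad):
        content = {**GOOD_REQUIRED, field: bad}
        name = "sub-01_mrsi.nii.gz" if field == "MatrixSize" else "sub-01_svs.nii.gz"
        errs = errors(validate_sidecar(doc(content, name)))
        assert [(e.rule_id, e.location) for e in errs] == [("MRS032", field)]

    @pytest.mark.parametrize("field, bad", [
        ("SpectralWidth", -2000.0),
        ("SpectrometerFrequency", 0),
        ("EchoTime", -0.01),
        ("NumberOfTransients", 0),
    ])
    def test_physical_domain_violations(self, field, bad):
        errs = errors(validate_sidecar(doc({**GOOD_REQUIRED, field: bad})))
        assert [(e.rule_id, e.location) for e in errs] == [("MRS033", field)]

    def test_malformed_ontology_uri(self):
        errs = errors(validate_sidecar(doc(
            {**GOOD_REQUIRED, "BodyPartDetailsOntology": "not a uri"}
        )))
        assert [e.rule_id for e in errs] == ["MRS048"]
        ok = validate_sidecar(doc(
            {**GOOD_REQUIRED,
             "BodyPartDetailsOntology": "https://example.org/ontology"}
        ))
        assert errors(ok) == []

    def test_unknown_key_is_info_only(self):
        issues = validate_sidecar(doc({**GOOD_REQUIRED, "VendorSecret": 1}))
        extra = [i for i in issues if i.location == "VendorSecret"]
        assert [(i.rule_id, i.severity) for i in extra] == [("MRS034", "info")]

    def test_absent_optional_fields_are_silent(self):
        issues = validate_sidecar(doc(GOOD_REQUIRED))
        optional = {f.name for f in catalog() if f.level == "optional"}
        assert not any(i.location in optional for i in issues)

    def test_non_applicable_recommended_field_not_warned(self):
        # MatrixSize applies to MRSI only; its absence on SVS is silent
        issues = validate_sidecar(doc(GOOD_REQUIRED, "sub-01_svs.nii.gz"))
        assert not any(i.location == "MatrixSize" for i in issues)

    def test_deterministic_issue_order(self):
        content = {"WaterSuppression": "yes", "VendorSecret": 1}
        a = validate_sidecar(doc(content))
        b = validate_sidecar(doc(content))
        assert a == b

    def test_malformed_document_rejected_at_construction(self):
        with pytest.raises(MalformedDocument):
            SidecarDocument(content=["not", "an", "object"])  # type: ignore


class TestShapeSweeps:
    @pytest.mark.parametrize("field", ["AcquisitionVoxelSize", "MatrixSize"])
    @pytest.mark.parametrize("length", [2, 3, 4, 5])
    def test_only_length_three_arrays_accepted(self, field, length):
        value = [2] * length if field == "MatrixSize" else [2.0] * length
        content = {**GOOD_REQUIRED, field: value}
        errs = errors(validate_sidecar(doc(content, "sub-01_mrsi.nii.gz")))
        if length == 3:
            assert errs == []
        else:
            assert [e.location for e in errs] == [field]

    @pytest.mark.parametrize("size", [2, 3, 4, 5])
    def test_only_four_by_four_affine_accepted(self, size):
        matrix = [[1.0] * size for _ in range(size)]
        content = {**GOOD_REQUIRED, "VolumeAffineMatrix": matrix}
        errs = errors(validate_sidecar(doc(content, "sub-01_mrsi.nii.gz")))
        assert (errs == []) == (size == 4)

    def test_non_square_affine_rejected(self):
        matrix = [[1.0] * 4 for _ in range(3)]
        errs = errors(validate_sidecar(
            doc({**GOOD_REQUIRED, "VolumeAffineMatrix": matrix}, "sub-01_mrsi.nii.gz")
        ))
        assert [e.location for e in errs] == ["VolumeAffineMatrix"]


class TestConditionals:
    def test_nuc_requires_resonant_nucleus(self):
        content = dict(GOOD_REQUIRED)
        del content["ResonantNucleus"]
        issues = check_conditional_requirements(
            doc(content, "sub-01_nuc-1H_svs.nii.gz")
        )
        assert [(i.rule_id, i.severity) for i in issues] == [("MRS040", "error")]

    def test_matching_nucleus_is_silent(self):
        issues = check_conditional_requirements(
            doc(GOOD_REQUIRED, "sub-01_nuc-1H_svs.nii.gz")
        )
        assert issues == []

    def test_nucleus_mismatch_is_an_error(self):
        content = {**GOOD_REQUIRED, "ResonantNucleus": "31P"}
        issues = check_conditional_requirements(
            doc(content, "sub-01_nuc-1H_svs.nii.gz")
        )
        assert [i.rule_id for i in issues] == ["MRS041"]

    def test_dual_tuned_array_concatenation(self):
        content = {**GOOD_REQUIRED, "ResonantNucleus": ["1H", "13C"]}
        issues = check_conditional_requirements(
            doc(content, "sub-01_nuc-1H13C_svs.nii.gz")
        )
        assert issues == []

    def test_voi_requires_bodypart_and_details(self):
        issues = check_conditional_requirements(
            doc(GOOD_REQUIRED, "sub-01_voi-dlpfc_svs.nii.gz")
        )
        assert [(i.rule_id, i.severity) for i in issues] == [
            ("MRS042", "error"), ("MRS043", "error"),
        ]
        complete = {**GOOD_REQUIRED, "BodyPart": "brain",
                    "BodyPartDetails": "dorsolateral prefrontal cortex"}
        assert check_conditional_requirements(
            doc(complete, "sub-01_voi-dlpfc_svs.nii.gz")
        ) == []

    def test_acq_without_pulse_sequence_type_warns(self):
        issues = check_conditional_requirements(
            doc(GOOD_REQUIRED, "sub-01_acq-slaser_svs.nii.gz")
        )
        assert [(i.rule_id, i.severity) for i in issues] == [("MRS044", "warning")]

    def test_pulse_list_timing_length_equality(self):
        content = {**GOOD_REQUIRED,
                   "PulseSequencePulses": ["a", "b", "c"],
                   "PulseSequenceTiming": [0.0, 0.01]}
        issues = check_conditional_requirements(doc(content))
        assert [i.rule_id for i in issues] == ["MRS045"]
        # pulses listed without any timing is the same violation
        del content["PulseSequenceTiming"]
        assert [i.rule_id for i in check_conditional_requirements(doc(content))] \
            == ["MRS045"]

    def test_mrsi_recommendations_and_transients_notice(self):
        content = {**GOOD_REQUIRED, "NumberOfTransients": 64}
        issues = check_conditional_requirements(doc(content, "sub-01_mrsi.nii.gz"))
        got = {(i.rule_id, i.location, i.severity) for i in issues}
        assert got == {
            ("MRS046", "MatrixSize", "warning"),
            ("MRS046", "VolumeAffineMatrix", "warning"),
            ("MRS046", "EncodingTechnique", "warning"),
            ("MRS047", "NumberOfTransients", "info"),
        }


_fragment = st.dictionaries(
    st.sampled_from(["EchoTime", "SpectralWidth", "ReceiveGain", "BodyPart"]),
    st.sampled_from([0.02, 0.03, 2000.0, "brain", True, None]),
    max_size=4,
)


class TestMergeInherited:
    def test_disjoint_keys_union(self):
        merged = merge_inherited([
            SidecarDocument({"SpectrometerFrequency": 123.25}, ("root.json",)),
            SidecarDocument({"EchoTime": 0.03}, ("file.json",)),
        ])
        assert merged.content == {"SpectrometerFrequency": 123.25, "EchoTime": 0.03}
        assert merged.source_paths == ("root.json", "file.json")

    def test_deeper_source_overrides(self):
        merged = merge_inherited([
            SidecarDocument({"EchoTime": 0.02}, ("root.json",)),
            SidecarDocument({"EchoTime": 0.03}, ("file.json",)),
        ])
        assert merged.content["EchoTime"] == 0.03

    @settings(max_examples=50, derandomize=True)
    @given(a=_fragment, b=_fragment)
    def test_merge_idempotence(self, a, b):
        da = SidecarDocument(dict(a), ("a.json",))
        db = SidecarDocument(dict(b), ("b.json",))
        once = merge_inherited([da, db])
        twice = merge_inherited([once, db])
        assert twice.content == once.content
        assert twice.source_paths == once.source_paths
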