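"""Validate JSON sidecar metadata against the MRS field catalog.

The catalog knows every MRS-specific field's type, shape, units and
requirement level, plus the conditional rules tied to filename entities
(e.g. a voi- entity demands BodyPart/BodyPartDetails).  Issues carry stable
rule ids: errors violate the standard, warnings flag missing recommended
metadata.
"""

from mrsbids import (
    SidecarDocument,
    check_conditional_requirements,
    parse_filename,
    validate_sidecar,
)

context = parse_filename("sub-01_acq-press_nuc-1H_voi-acc_svs.nii.gz")
doc = SidecarDocument(
    content={
        "ResonantNucleus": "1H",
        "SpectrometerFrequency": 123.25,   # MHz
        "SpectralWidth": 2000.0,           # Hz
        "EchoTime": 0.03,                  # s
        "WaterSuppression": "yes",         # wrong: must be a boolean
        "AcquisitionVoxelSize": [20.0, 20.0],  # wrong: needs length 3 (mm)
    },
    source_paths=("sub-01/mrs/sub-01_acq-press_nuc-1H_voi-acc_svs.json",),
    context=context,
)

for issue in validate_sidecar(doc) + check_conditional_requirements(doc):
    print(f"[{issue.severity:7s}] {issue.rule_id} {issue.location}: {issue.message}")
# errors: WaterSuppression type, AcquisitionVoxelSize shape, and the missing
# BodyPart/BodyPartDetails demanded by the voi-acc entity; warnings list the
# absent recommended fields (and PulseSequenceType for the acq-press label).
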