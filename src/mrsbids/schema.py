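"""MRS-BIDS sidecar field catalog and metadata validation.

The catalog (:func:`catalog`) is a machine-readable description of every
MRS-specific sidecar field: its JSON value type and shape, physical units,
requirement level (required / recommended / optional), which data-type
suffixes it applies to, and any conditional trigger (e.g. the ``voi-`` entity
requiring ``BodyPart``).  :func:`validate_sidecar` checks one document against
the catalog; :func:`check_conditional_requirements` enforces the
entity-dependent and cross-field rules; :func:`merge_inherited` implements
metadata inheritance from dataset root down to the file-level sidecar.

Severity mapping follows an RFC-2119-style reading of the standard: "must" is
an error, "recommended"/"should" a warning, absent optional fields are silent,
and a malformed value is always an error regardless of level.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Sequence

from .entities import ParsedName

__all__ = [
    "FieldSpec",
    "SidecarDocument",
    "ValidationIssue",
    "MalformedDocument",
    "RULES",
    "catalog",
    "lookup",
    "validate_sidecar",
    "check_conditional_requirements",
    "merge_inherited",
    "emit_rule_catalog",
    "sort_issues",
    "ALL_SUFFIXES",
]

ALL_SUFFIXES = frozenset({"svs", "mrsi", "unloc", "mrsref"})

SEVERITY_ORDER = {"error": 0, "warning": 1, "info": 2}


class MalformedDocument(ValueError):
    """A sidecar whose content could not be parsed as a JSON object."""


@dataclass(frozen=True)
class ValidationIssue:
    """One finding: a stable rule id, severity, file, location, message."""

    rule_id: str
    severity: str  # error | warning | info
    file: str
    location: str
    message: str

    def sort_key(self) -> tuple:
        return (self.file, self.rule_id, self.location, self.message)


def sort_issues(issues: Iterable[ValidationIssue]) -> list[ValidationIssue]:
    """Deterministic issue ordering: by (file, rule_id, location, message)."""
    return sorted(issues, key=lambda i: i.sort_key())


# --------------------------------------------------------------------------
# Rule registry: every rule id the toolkit can emit, with default severity
# and a short statement of the requirement it enforces.  ``decision`` marks
# rules whose exact form was a project decision rather than a stated
# requirement of the standard.
# --------------------------------------------------------------------------

RULES: dict[str, dict[str, str]] = {
    # filename grammar
    "MRS001": {"severity": "error", "title": "unknown entity key",
               "anchor": "only the documented entity keys may appear in a filename"},
    "MRS002": {"severity": "error", "title": "duplicate entity",
               "anchor": "each entity may be used only once in a filename"},
    "MRS003": {"severity": "error", "title": "entity order violation",
               "anchor": "entities have a fixed canonical order; the placement of "
                         "rec/run/echo/inv after nuc/voi is a project decision "
                         "following the upstream BIDS MRS template",
               "decision": "true"},
    "MRS004": {"severity": "error", "title": "bad label charset",
               "anchor": "entity labels are alphanumeric"},
    "MRS005": {"severity": "error", "title": "bad index",
               "anchor": "run/echo/inv values are nonnegative integers"},
    "MRS006": {"severity": "error", "title": "missing or unknown suffix",
               "anchor": "every file ends in one of the suffixes svs, mrsi, unloc, mrsref"},
    "MRS007": {"severity": "error", "title": "unknown extension",
               "anchor": "data files are .nii or .nii.gz; sidecars are .json"},
    "MRS008": {"severity": "error", "title": "missing subject entity",
               "anchor": "filenames begin with sub-<label>"},
    # path placement
    "MRS010": {"severity": "error", "title": "path/entity mismatch",
               "anchor": "the sub/ses directory components must match the filename "
                         "entities, with MRS files in an mrs/ subdirectory"},
    # sidecar presence / parsing
    "MRS020": {"severity": "error", "title": "missing sidecar",
               "anchor": "every NIfTI-MRS data file has a corresponding JSON sidecar"},
    "MRS021": {"severity": "warning", "title": "orphan sidecar",
               "anchor": "a JSON sidecar without a matching data file",
               "decision": "true"},
    "MRS022": {"severity": "error", "title": "malformed sidecar JSON",
               "anchor": "sidecars must be valid JSON objects"},
    # field-level
    "MRS030": {"severity": "error", "title": "missing required field",
               "anchor": "ResonantNucleus, SpectrometerFrequency, SpectralWidth and "
                         "EchoTime must be included"},
    "MRS031": {"severity": "warning", "title": "missing recommended field",
               "anchor": "recommended fields should be present when applicable"},
    "MRS032": {"severity": "error", "title": "wrong type or shape",
               "anchor": "field values must match their documented JSON type and "
                         "array shape (e.g. AcquisitionVoxelSize length 3, "
                         "VolumeAffineMatrix 4x4)"},
    "MRS033": {"severity": "error", "title": "value outside physical domain",
               "anchor": "frequencies and bandwidths are positive; times are "
                         "nonnegative; counts are at least 1",
               "decision": "true"},
    "MRS034": {"severity": "info", "title": "unknown sidecar key",
               "anchor": "extra metadata keys are permitted and reported for information",
               "decision": "true"},
    # conditional rules
    "MRS040": {"severity": "error", "title": "nuc entity without ResonantNucleus",
               "anchor": "using nuc-<label> requires ResonantNucleus in the sidecar"},
    "MRS041": {"severity": "error", "title": "nuc label inconsistent with ResonantNucleus",
               "anchor": "the nuc label must equal the ResonantNucleus value "
                         "(case-insensitive alphanumeric comparison; arrays are "
                         "concatenated in order)",
               "decision": "true"},
    "MRS042": {"severity": "error", "title": "voi entity without BodyPart",
               "anchor": "using voi-<label> requires the BodyPart field"},
    "MRS043": {"severity": "error", "title": "voi entity without BodyPartDetails",
               "anchor": "using voi-<label> requires the BodyPartDetails field"},
    "MRS044": {"severity": "warning", "title": "acq entity without PulseSequenceType",
               "anchor": "an acq label should be described in PulseSequenceType"},
    "MRS045": {"severity": "error", "title": "pulse list/timing length mismatch",
               "anchor": "PulseSequencePulses must have the same array size as "
                         "PulseSequenceTiming"},
    "MRS046": {"severity": "warning", "title": "MRSI metadata absent",
               "anchor": "MatrixSize, VolumeAffineMatrix and EncodingTechnique are "
                         "recommended for MRSI"},
    "MRS047": {"severity": "info", "title": "NumberOfTransients on MRSI data",
               "anchor": "NumberOfTransients is recommended for SVS and unlocalized "
                         "acquisitions only"},
    "MRS048": {"severity": "error", "title": "malformed ontology URI",
               "anchor": "BodyPartDetailsOntology must be a URI (scheme plus "
                         "non-empty remainder); terms are not resolved",
               "decision": "true"},
    # container / header consistency
    "MRS060": {"severity": "error", "title": "unreadable NIfTI file",
               "anchor": "data files must be readable NIfTI-1 or NIfTI-2 containers"},
    "MRS061": {"severity": "warning", "title": "missing embedded JSON extension",
               "anchor": "a NIfTI-MRS file carries metadata in an embedded JSON "
                         "header extension"},
    "MRS062": {"severity": "warning", "title": "SpectrometerFrequency header/sidecar mismatch",
               "anchor": "the embedded header extension and the sidecar should agree",
               "decision": "true"},
    "MRS063": {"severity": "warning", "title": "ResonantNucleus header/sidecar mismatch",
               "anchor": "the embedded header extension and the sidecar should agree",
               "decision": "true"},
    "MRS064": {"severity": "error", "title": "SpectralWidth inconsistent with dwell time",
               "anchor": "the spectral width is the reciprocal of the time-axis "
                         "dwell time (relative tolerance 1e-3)",
               "decision": "true"},
    "MRS065": {"severity": "warning", "title": "NumberOfSpectralPoints mismatch",
               "anchor": "NumberOfSpectralPoints should equal the container's "
                         "time-dimension extent"},
    "MRS066": {"severity": "error", "title": "SVS file with spatial extent > 1",
               "anchor": "single-voxel data occupy a single spatial voxel"},
    "MRS067": {"severity": "warning", "title": "MRSI file with no spatial extent",
               "anchor": "MRSI data should have at least one spatial extent > 1"},
    # dataset-level and cross-file
    "MRS080": {"severity": "error", "title": "missing dataset_description.json",
               "anchor": "every BIDS dataset carries dataset_description.json at its root"},
    "MRS081": {"severity": "error", "title": "duplicate acquisition identity",
               "anchor": "two files may not share the same entity set and suffix "
                         "(indices compare as integers)"},
    "MRS082": {"severity": "warning", "title": "inconsistent voi label usage",
               "anchor": "the same voi label should map to identical "
                         "BodyPart/BodyPartDetails across files",
               "decision": "true"},
    "MRS083": {"severity": "error", "title": "dangling ReferenceSignal",
               "anchor": "ReferenceSignal paths must resolve to an existing mrsref file"},
    "MRS084": {"severity": "error", "title": "dangling AnatomicalImage",
               "anchor": "AnatomicalImage paths must resolve to an existing "
                         "anatomical image file"},
}


def emit_rule_catalog() -> dict[str, Any]:
    """The rule catalog as a JSON-serializable document."""
    return {
        rid: {
            "rule_id": rid,
            "severity": meta["severity"],
            "title": meta["title"],
            "anchor": meta["anchor"],
            "decision": meta.get("decision", "false") == "true",
        }
        for rid, meta in sorted(RULES.items())
    }


# --------------------------------------------------------------------------
# Value types
# --------------------------------------------------------------------------

def _is_number(v: Any) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool) and math.isfinite(v)


def _is_integer(v: Any) -> bool:
    return isinstance(v, int) and not isinstance(v, bool)


@dataclass(frozen=True)
class ValueType:
    """A named JSON value-type/shape constraint."""

    name: str
    check: Callable[[Any], bool]
    describe: str


def _number_array(n: int | None) -> ValueType:
    def check(v: Any) -> bool:
        if not isinstance(v, list) or (n is not None and len(v) != n):
            return False
        return all(_is_number(x) for x in v)

    label = f"array of numbers, length {n}" if n else "array of numbers"
    return ValueType(f"number_array({n or 'var'})", check, label)


def _int_array(n: int) -> ValueType:
    return ValueType(
        f"integer_array({n})",
        lambda v: isinstance(v, list) and len(v) == n and all(_is_integer(x) for x in v),
        f"array of integers, length {n}",
    )


def _square_matrix(n: int) -> ValueType:
    def check(v: Any) -> bool:
        if not isinstance(v, list) or len(v) != n:
            return False
        return all(
            isinstance(row, list) and len(row) == n and all(_is_number(x) for x in row)
            for row in v
        )

    return ValueType(f"square_matrix({n})", check, f"{n} x {n} array of arrays of numbers")


def _string_array(v: Any) -> bool:
    return isinstance(v, list) and len(v) >= 1 and all(isinstance(x, str) and x for x in v)


T_BOOL = ValueType("boolean", lambda v: isinstance(v, bool), "true or false")
T_NUM = ValueType("number", _is_number, "number")
T_INT = ValueType("integer", _is_integer, "integer")
T_STR = ValueType("string", lambda v: isinstance(v, str) and len(v) > 0, "non-empty string")
T_PATHS = ValueType(
    "path_or_path_array",
    lambda v: (isinstance(v, str) and v) or _string_array(v),
    "relative path as a string, or an array of such strings",
)
T_STR_ARR = ValueType("string_array", _string_array, "array of non-empty strings")
T_STR_OR_ARR = ValueType(
    "string_or_string_array",
    lambda v: (isinstance(v, str) and v) or _string_array(v),
    "string, or array of strings",
)

_URI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:.+$")


@dataclass(frozen=True)
class FieldSpec:
    """Catalog entry for one sidecar field."""

    name: str
    level: str  # required | recommended | optional
    value_type: ValueType
    units: str = ""
    applicability: frozenset[str] = ALL_SUFFIXES
    condition: str | None = None


def _domain_spectrometer_frequency(v: Any) -> str | None:
    return None if v > 0 else "SpectrometerFrequency must be > 0 MHz"


def _domain_spectral_width(v: Any) -> str | None:
    return None if v > 0 else "SpectralWidth must be > 0 Hz"


def _domain_nonneg_time(name: str) -> Callable[[Any], str | None]:
    return lambda v: None if v >= 0 else f"{name} must be >= 0 s"


def _domain_count(name: str) -> Callable[[Any], str | None]:
    return lambda v: None if v >= 1 else f"{name} must be >= 1"


def _domain_uri(v: Any) -> str | None:
    if _URI_RE.match(v):
        return None
    return "BodyPartDetailsOntology must be a URI with a scheme and non-empty remainder"


#: Per-field physical-domain predicates; return an error message or None.
#: These run only after the value passed its type check.
DOMAIN_CHECKS: dict[str, Callable[[Any], str | None]] = {
    "SpectrometerFrequency": _domain_spectrometer_frequency,
    "SpectralWidth": _domain_spectral_width,
    "EchoTime": _domain_nonneg_time("EchoTime"),
    "MixingTime": _domain_nonneg_time("MixingTime"),
    "NumberOfSpectralPoints": _domain_count("NumberOfSpectralPoints"),
    "NumberOfTransients": _domain_count("NumberOfTransients"),
    "BodyPartDetailsOntology": _domain_uri,
}

#: Fields whose missing-recommended warning is handled by the MRSI
#: conditional rule rather than the generic one (avoids double reporting).
_MRSI_TRIO = ("MatrixSize", "VolumeAffineMatrix", "EncodingTechnique")

#: Domain failures normally report MRS033; fields listed here use their own rule.
_DOMAIN_RULE_OVERRIDES = {"BodyPartDetailsOntology": "MRS048"}

_CATALOG: tuple[FieldSpec, ...] = (
    # required for every MRS data type, including reference acquisitions
    FieldSpec("ResonantNucleus", "required", T_STR_OR_ARR),
    FieldSpec("SpectrometerFrequency", "required", T_NUM, units="MHz"),
    FieldSpec("SpectralWidth", "required", T_NUM, units="Hz"),
    FieldSpec("EchoTime", "required", T_NUM, units="s"),
    # recommended
    FieldSpec("WaterSuppression", "recommended", T_BOOL),
    FieldSpec("NumberOfSpectralPoints", "recommended", T_INT),
    FieldSpec("MixingTime", "recommended", T_NUM, units="s",
              condition="stimulated-echo sequence"),
    FieldSpec("AcquisitionVoxelSize", "recommended", _number_array(3), units="mm",
              applicability=frozenset({"svs", "mrsi", "mrsref"})),
    FieldSpec("ReferenceSignal", "recommended", T_PATHS,
              applicability=frozenset({"svs", "mrsi", "unloc"})),
    FieldSpec("NumberOfTransients", "recommended", T_INT,
              applicability=frozenset({"svs", "unloc"})),
    FieldSpec("MatrixSize", "recommended", _int_array(3),
              applicability=frozenset({"mrsi"})),
    FieldSpec("VolumeAffineMatrix", "recommended", _square_matrix(4),
              applicability=frozenset({"mrsi"})),
    FieldSpec("EncodingTechnique", "recommended", T_STR,
              applicability=frozenset({"mrsi"})),
    FieldSpec("AnatomicalImage", "recommended", T_PATHS,
              condition="anatomical image collected"),
    # optional — scanner hardware
    FieldSpec("NumberReceiveCoilActiveElements", "optional", T_INT),
    FieldSpec("NumberTransmitCoilActiveElements", "optional", T_INT),
    # optional — sequence specifics
    FieldSpec("WaterSuppressionTechnique", "optional", T_STR),
    FieldSpec("OuterVolumeSuppression", "optional", T_BOOL),
    FieldSpec("B0ShimmingTechnique", "optional", T_STR),
    FieldSpec("B1ShimmingTechnique", "optional", T_STR),
    # optional — tissue description (conditionally required by the voi entity)
    FieldSpec("BodyPart", "optional", T_STR, condition="entity voi present"),
    FieldSpec("BodyPartDetails", "optional", T_STR, condition="entity voi present"),
    FieldSpec("BodyPartDetailsOntology", "optional", T_STR),
    # optional — MRS-relevant
    FieldSpec("ChemicalShiftOffset", "optional", T_NUM, units="ppm"),
    FieldSpec("ChemicalShiftReference", "optional", T_NUM, units="ppm"),
    FieldSpec("EditTarget", "optional", T_STR_OR_ARR),
    FieldSpec("EditPulse", "optional", T_STR_OR_ARR),
    FieldSpec("EditCondition", "optional", T_STR_OR_ARR),
    FieldSpec("EchoAcquisition", "optional", T_STR_OR_ARR),
    FieldSpec("PulseSequenceTiming", "optional", _number_array(None), units="s"),
    FieldSpec("PulseSequencePulses", "optional", T_STR_ARR),
    FieldSpec("ReceiveGain", "optional", T_NUM),
    FieldSpec("PulseSequenceType", "optional", T_STR, condition="entity acq present"),
)

_BY_NAME: dict[str, FieldSpec] = {f.name: f for f in _CATALOG}
assert len(_BY_NAME) == len(_CATALOG), "field names must be unique"


def catalog() -> list[FieldSpec]:
    """The complete MRS sidecar field catalog."""
    return list(_CATALOG)


def lookup(name: str) -> FieldSpec:
    """Look up one field by name; raises KeyError for unknown fields."""
    return _BY_NAME[name]


# --------------------------------------------------------------------------
# Documents and validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SidecarDocument:
    """Parsed sidecar content plus the filename context it describes."""

    content: dict[str, Any]
    source_paths: tuple[str, ...] = ()
    context: ParsedName | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.content, dict) or any(
            not isinstance(k, str) for k in self.content
        ):
            raise MalformedDocument("sidecar content must be a JSON object")

    @property
    def file(self) -> str:
        return self.source_paths[-1] if self.source_paths else "<memory>"


def _issue(rule_id: str, file: str, location: str, message: str) -> ValidationIssue:
    return ValidationIssue(
        rule_id=rule_id,
        severity=RULES[rule_id]["severity"],
        file=file,
        location=location,
        message=message,
    )


def validate_sidecar(doc: SidecarDocument) -> list[ValidationIssue]:
    """Validate one sidecar document against the field catalog.

    Emits an error per missing required field, a warning per missing
    recommended field applicable to the file's suffix, an error per type,
    shape or physical-domain violation, and an info per unknown key.  Absent
    optional fields are silent.  The list is deterministically sorted.
    """
    suffix = doc.context.suffix if doc.context is not None else None
    issues: list[ValidationIssue] = []

    for spec in _CATALOG:
        applicable = suffix is None or suffix in spec.applicability
        present = spec.name in doc.content
        if not present:
            if spec.level == "required" and applicable:
                issues.append(_issue(
                    "MRS030", doc.file, spec.name,
                    f"required field {spec.name!r} is missing",
                ))
            elif (
                spec.level == "recommended"
                and applicable
                and spec.name not in _MRSI_TRIO
            ):
                issues.append(_issue(
                    "MRS031", doc.file, spec.name,
                    f"recommended field {spec.name!r} is missing",
                ))
            continue
        value = doc.content[spec.name]
        if not spec.value_type.check(value):
            issues.append(_issue(
                "MRS032", doc.file, spec.name,
                f"{spec.name} must be {spec.value_type.describe}"
                + (f" (in {spec.units})" if spec.units else "")
                + f"; got {value!r}",
            ))
            continue
        domain = DOMAIN_CHECKS.get(spec.name)
        if domain is not None:
            msg = domain(value)
            if msg is not None:
                rid = _DOMAIN_RULE_OVERRIDES.get(spec.name, "MRS033")
                issues.append(_issue(rid, doc.file, spec.name, msg))

    for key in doc.content:
        if key not in _BY_NAME:
            issues.append(_issue(
                "MRS034", doc.file, key,
                f"unknown sidecar key {key!r} (extra metadata is permitted)",
            ))

    return sort_issues(issues)


def _normalize_nucleus(value: Any) -> str:
    """Case-insensitive alphanumeric normalization; arrays concatenate in order."""
    if isinstance(value, list):
        value = "".join(str(v) for v in value)
    return re.sub(r"[^a-z0-9]", "", str(value).lower())


def check_conditional_requirements(doc: SidecarDocument) -> list[ValidationIssue]:
    """Enforce entity-dependent and cross-field sidecar rules.

    Covers: the ``nuc`` entity requiring a matching ``ResonantNucleus``; the
    ``voi`` entity requiring ``BodyPart`` and ``BodyPartDetails``; the ``acq``
    entity suggesting ``PulseSequenceType``; the
    ``PulseSequencePulses``/``PulseSequenceTiming`` length equality; the MRSI
    recommended trio; and ``NumberOfTransients`` appearing on MRSI data.
    """
    issues: list[ValidationIssue] = []
    ctx = doc.context
    content = doc.content
    entities = ctx.entity_dict() if ctx is not None else {}
    suffix = ctx.suffix if ctx is not None else None

    if "nuc" in entities:
        if "ResonantNucleus" not in content:
            issues.append(_issue(
                "MRS040", doc.file, "ResonantNucleus",
                f"entity nuc-{entities['nuc']} requires the ResonantNucleus field",
            ))
        else:
            label = _normalize_nucleus(entities["nuc"])
            value = _normalize_nucleus(content["ResonantNucleus"])
            if label != value:
                issues.append(_issue(
                    "MRS041", doc.file, "ResonantNucleus",
                    f"nuc label {entities['nuc']!r} does not match "
                    f"ResonantNucleus {content['ResonantNucleus']!r}",
                ))

    if "voi" in entities:
        for fieldname, rid in (("BodyPart", "MRS042"), ("BodyPartDetails", "MRS043")):
            if fieldname not in content:
                issues.append(_issue(
                    rid, doc.file, fieldname,
                    f"entity voi-{entities['voi']} requires the {fieldname} field",
                ))

    if "acq" in entities and "PulseSequenceType" not in content:
        issues.append(_issue(
            "MRS044", doc.file, "PulseSequenceType",
            f"acq label {entities['acq']!r} should be described in PulseSequenceType",
        ))

    if "PulseSequencePulses" in content:
        pulses = content["PulseSequencePulses"]
        timing = content.get("PulseSequenceTiming")
        if not isinstance(timing, list) or (
            isinstance(pulses, list) and len(pulses) != len(timing)
        ):
            n_p = len(pulses) if isinstance(pulses, list) else "?"
            n_t = len(timing) if isinstance(timing, list) else "absent"
            issues.append(_issue(
                "MRS045", doc.file, "PulseSequencePulses",
                f"PulseSequencePulses (size {n_p}) must equal the array size of "
                f"PulseSequenceTiming (size {n_t})",
            ))

    if suffix == "mrsi":
        for fieldname in _MRSI_TRIO:
            if fieldname not in content:
                issues.append(_issue(
                    "MRS046", doc.file, fieldname,
                    f"{fieldname} is recommended for MRSI acquisitions",
                ))
        if "NumberOfTransients" in content:
            issues.append(_issue(
                "MRS047", doc.file, "NumberOfTransients",
                "NumberOfTransients is recommended for SVS and unlocalized "
                "acquisitions only",
            ))

    return sort_issues(issues)


def merge_inherited(sources: Sequence[SidecarDocument]) -> SidecarDocument:
    """Key-wise shallow merge of sidecar fragments, root first.

    Later (more specific) fragments override earlier ones; provenance is kept
    in ``source_paths``.  Merging is idempotent: re-merging an already-merged
    fragment changes nothing.
    """
    if not sources:
        return SidecarDocument(content={}, source_paths=(), context=None)
    content: dict[str, Any] = {}
    paths: list[str] = []
    context: ParsedName | None = None
    for doc in sources:
        content.update(doc.content)
        for p in doc.source_paths:
            if p not in paths:
                paths.append(p)
        if doc.context is not None:
            context = doc.context
    return SidecarDocument(content=content, source_paths=tuple(paths), context=context)
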