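"""Dataset-level validation: walk a BIDS tree and apply every MRS rule.

:func:`scan` inventories the tree (subjects, sessions, MRS data files,
sidecars, anatomical images); :func:`validate_dataset` runs the filename
grammar, path-placement, sidecar schema, conditional, container and
cross-file checks and returns a deterministic :class:`ValidationReport`;
:func:`render_report` serializes it as text or JSON.

Issue paths are dataset-root-relative POSIX strings, so validating a copied
tree yields a byte-identical JSON report.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath
from typing import Any, Iterable

from . import entities as ent
from . import nifti_mrs
from . import schema
from .entities import DataFileRecord, ParsedName
from .schema import RULES, SidecarDocument, ValidationIssue, sort_issues

__all__ = [
    "DatasetInventory",
    "ValidationReport",
    "UnknownFormat",
    "scan",
    "validate_dataset",
    "render_report",
]

#: Filename-grammar exception class -> rule id.
_FILENAME_RULES: tuple[tuple[type, str], ...] = (
    (ent.UnknownEntity, "MRS001"),
    (ent.DuplicateEntity, "MRS002"),
    (ent.OrderViolation, "MRS003"),
    (ent.BadLabel, "MRS004"),
    (ent.BadIndex, "MRS005"),
    (ent.MissingSuffix, "MRS006"),
    (ent.UnknownSuffix, "MRS006"),
    (ent.UnknownExtension, "MRS007"),
    (ent.MissingSubject, "MRS008"),
)


class UnknownFormat(ValueError):
    pass


class NotADirectory(NotADirectoryError):
    pass


def _issue(rule_id: str, file: str, location: str, message: str) -> ValidationIssue:
    return ValidationIssue(
        rule_id=rule_id,
        severity=RULES[rule_id]["severity"],
        file=file,
        location=location,
        message=message,
    )


def _filename_issue(exc: ent.FilenameError, relpath: str) -> ValidationIssue:
    for klass, rid in _FILENAME_RULES:
        if isinstance(exc, klass):
            return _issue(rid, relpath, "filename", str(exc))
    return _issue("MRS006", relpath, "filename", str(exc))


@dataclass
class DatasetInventory:
    """Everything :func:`scan` found under a dataset root."""

    root: Path
    subjects: list[str] = field(default_factory=list)
    sessions: dict[str, list[str]] = field(default_factory=dict)
    data_files: list[DataFileRecord] = field(default_factory=list)
    sidecars: list[str] = field(default_factory=list)
    anat_files: list[str] = field(default_factory=list)
    has_dataset_description: bool = False
    issues: list[ValidationIssue] = field(default_factory=list)


@dataclass
class ValidationReport:
    """Aggregate validation outcome; ``passed`` means zero errors."""

    root: str
    issues: list[ValidationIssue]

    @property
    def counts(self) -> dict[str, int]:
        c = {"error": 0, "warning": 0, "info": 0}
        for i in self.issues:
            c[i.severity] = c.get(i.severity, 0) + 1
        return c

    @property
    def passed(self) -> bool:
        return self.counts["error"] == 0


def _load_bidsignore(root: Path) -> list[str]:
    f = root / ".bidsignore"
    if not f.is_file():
        return []
    patterns = []
    for line in f.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            patterns.append(line.rstrip("/"))
    return patterns


def _ignored(relpath: str, patterns: list[str]) -> bool:
    parts = PurePosixPath(relpath).parts
    for pat in patterns:
        if fnmatch.fnmatch(relpath, pat):
            return True
        if any(fnmatch.fnmatch(p, pat) for p in parts):
            return True
    return False


def scan(root: str | Path) -> DatasetInventory:
    """Inventory a dataset tree.

    Walks ``sub-*`` directories (skipping ``sourcedata/``, ``derivatives/``
    and anything matched by ``.bidsignore``); files under ``mrs/``
    subdirectories are MRS candidates.  Unparseable filenames are recorded as
    issues in the inventory, never skipped silently.
    """
    root = Path(root)
    if not root.is_dir():
        raise NotADirectory(f"{root} is not a readable directory")
    inv = DatasetInventory(root=root)
    inv.has_dataset_description = (root / "dataset_description.json").is_file()
    patterns = _load_bidsignore(root)

    for subdir in sorted(root.glob("sub-*")):
        if not subdir.is_dir():
            continue
        label = subdir.name[len("sub-"):]
        inv.subjects.append(label)
        inv.sessions[label] = sorted(
            d.name[len("ses-"):] for d in subdir.glob("ses-*") if d.is_dir()
        )
        for f in sorted(subdir.rglob("*")):
            if not f.is_file():
                continue
            rel = f.relative_to(root).as_posix()
            if _ignored(rel, patterns):
                continue
            if f.parent.name == "anat":
                inv.anat_files.append(rel)
                continue
            if f.parent.name != "mrs":
                continue
            if f.name.endswith(".json"):
                inv.sidecars.append(rel)
                continue
            try:
                parsed = ent.parse_filename(f.name)
            except ent.FilenameError as exc:
                inv.issues.append(_filename_issue(exc, rel))
                continue
            stem = f.name[: -len(parsed.extension)]
            sidecar = f.parent / f"{stem}.json"
            inv.data_files.append(DataFileRecord(
                dataset_relative_path=rel,
                parsed=parsed,
                sidecar_path=(
                    sidecar.relative_to(root).as_posix() if sidecar.is_file() else None
                ),
            ))
    return inv


# --------------------------------------------------------------------------
# Inheritance
# --------------------------------------------------------------------------

def _parse_fragment(name: str) -> tuple[dict[str, str], str] | None:
    """Parse an inheritance-fragment sidecar name (``sub`` not required).

    Returns (entities, suffix) or None when the name is not a fragment for an
    MRS suffix.
    """
    if not name.endswith(".json"):
        return None
    tokens = name[: -len(".json")].split("_")
    suffix = tokens[-1]
    if "-" in suffix or suffix not in ent.SUFFIXES:
        return None
    entities: dict[str, str] = {}
    for tok in tokens[:-1]:
        key, dash, value = tok.partition("-")
        if not dash or key not in ent.ENTITY_ORDER or key in entities:
            return None
        entities[key] = value
    return entities, suffix


def _fragment_applies(
    frag_entities: dict[str, str], frag_suffix: str, parsed: ParsedName
) -> bool:
    if frag_suffix != parsed.suffix:
        return False
    have = parsed.entity_dict()
    return all(have.get(k) == v for k, v in frag_entities.items())


def _inherited_fragments(
    root: Path, record: DataFileRecord
) -> list[tuple[int, str]]:
    """Candidate fragment sidecars for one data file, shallowest first.

    Search order: dataset root, subject directory, session directory.  Only
    fragments with the same suffix whose entities are a subset of the data
    file's apply.
    """
    parsed = record.parsed
    levels: list[Path] = [root, root / f"sub-{parsed.sub}"]
    if parsed.ses is not None:
        levels.append(root / f"sub-{parsed.sub}" / f"ses-{parsed.ses}")
    out: list[tuple[int, str]] = []
    for depth, d in enumerate(levels):
        if not d.is_dir():
            continue
        for f in sorted(d.glob("*.json")):
            frag = _parse_fragment(f.name)
            if frag is None:
                continue
            if _fragment_applies(frag[0], frag[1], parsed):
                out.append((depth, f.relative_to(root).as_posix()))
    out.sort()
    return out


def _load_sidecar(root: Path, relpath: str, context: ParsedName | None):
    raw = (root / relpath).read_text(encoding="utf-8")
    content = json.loads(raw)
    if not isinstance(content, dict):
        raise schema.MalformedDocument(f"{relpath}: sidecar is not a JSON object")
    return SidecarDocument(content=content, source_paths=(relpath,), context=context)


# --------------------------------------------------------------------------
# Cross-file reference resolution
# --------------------------------------------------------------------------

def _as_path_list(value: Any) -> list[str]:
    if isinstance(value, str):
        return [value]
    if isinstance(value, list):
        return [v for v in value if isinstance(v, str)]
    return []


def _strip_bids_uri(p: str) -> str:
    if p.startswith("bids::"):
        return p[len("bids::"):]
    return p


def _resolve_candidates(root: Path, record: DataFileRecord, target: str) -> list[Path]:
    target = _strip_bids_uri(target)
    data_dir = (root / record.dataset_relative_path).parent
    return [root / target, data_dir / target]


def _check_reference_signal(
    root: Path, record: DataFileRecord, doc: SidecarDocument
) -> list[ValidationIssue]:
    issues = []
    for target in _as_path_list(doc.content.get("ReferenceSignal")):
        found = None
        for cand in _resolve_candidates(root, record, target):
            if cand.is_file():
                found = cand
                break
        if found is None:
            issues.append(_issue(
                "MRS083", record.dataset_relative_path, "ReferenceSignal",
                f"ReferenceSignal path {target!r} does not resolve to an existing file",
            ))
            continue
        try:
            tparsed = ent.parse_filename(found.name)
            ok = tparsed.suffix == "mrsref"
        except ent.FilenameError:
            ok = False
        if not ok:
            issues.append(_issue(
                "MRS083", record.dataset_relative_path, "ReferenceSignal",
                f"ReferenceSignal path {target!r} is not an mrsref data file",
            ))
    return issues


def _check_anatomical_image(
    root: Path, record: DataFileRecord, doc: SidecarDocument
) -> list[ValidationIssue]:
    issues = []
    anat_dir = root / f"sub-{record.parsed.sub}"
    for target in _as_path_list(doc.content.get("AnatomicalImage")):
        stripped = _strip_bids_uri(target)
        candidates = _resolve_candidates(root, record, target)
        # basename lookup under the same subject's anat/ directories
        candidates += sorted(anat_dir.rglob(f"anat/{PurePosixPath(stripped).name}"))
        if not any(c.is_file() for c in candidates):
            issues.append(_issue(
                "MRS084", record.dataset_relative_path, "AnatomicalImage",
                f"AnatomicalImage path {target!r} does not resolve to an existing file",
            ))
    return issues


# --------------------------------------------------------------------------
# Main validation
# --------------------------------------------------------------------------

def validate_dataset(
    root: str | Path,
    strictness: str = "normal",
    disabled_rules: Iterable[str] = (),
) -> ValidationReport:
    """Validate an MRS-BIDS dataset tree.

    Per data file: filename grammar, directory placement, sidecar resolution
    with inheritance, field catalog + conditional rules, NIfTI-MRS read and
    header/sidecar consistency.  Dataset level: ``dataset_description.json``
    presence, duplicate acquisition identities, consistent tissue metadata
    per ``voi`` label.  Cross-file: ``ReferenceSignal`` and
    ``AnatomicalImage`` targets must resolve.  ``strictness="strict"``
    promotes warnings to errors.
    """
    if strictness not in ("normal", "strict"):
        raise ValueError(f"strictness must be 'normal' or 'strict', got {strictness!r}")
    root = Path(root)
    inv = scan(root)
    issues: list[ValidationIssue] = list(inv.issues)

    if not inv.has_dataset_description:
        issues.append(_issue(
            "MRS080", "dataset_description.json", "dataset",
            "dataset_description.json is missing from the dataset root",
        ))

    docs: dict[str, SidecarDocument] = {}
    headers: dict[str, nifti_mrs.NiftiMrsHeader] = {}

    for record in inv.data_files:
        rel = record.dataset_relative_path
        parsed = record.parsed

        expected = ent.expected_relative_path(parsed)
        actual_dir = PurePosixPath(rel).parent.as_posix() + "/"
        if actual_dir != expected:
            issues.append(_issue(
                "MRS010", rel, "path",
                f"file located in {actual_dir!r} but its entities imply {expected!r}",
            ))

        doc: SidecarDocument | None = None
        if record.sidecar_path is None:
            issues.append(_issue(
                "MRS020", rel, "sidecar",
                "no JSON sidecar found for this data file",
            ))
        else:
            fragments: list[SidecarDocument] = []
            malformed = False
            for _, fragpath in _inherited_fragments(root, record):
                try:
                    fragments.append(_load_sidecar(root, fragpath, None))
                except (json.JSONDecodeError, schema.MalformedDocument) as exc:
                    issues.append(_issue("MRS022", fragpath, "json", str(exc)))
            try:
                fragments.append(_load_sidecar(root, record.sidecar_path, parsed))
            except (json.JSONDecodeError, schema.MalformedDocument) as exc:
                issues.append(_issue("MRS022", record.sidecar_path, "json", str(exc)))
                malformed = True
            if not malformed:
                doc = schema.merge_inherited(fragments)
                # report against the file-level sidecar path
                doc = SidecarDocument(
                    content=doc.content,
                    source_paths=doc.source_paths[:-1] + (record.sidecar_path,),
                    context=parsed,
                )
                docs[rel] = doc
                issues.extend(schema.validate_sidecar(doc))
                issues.extend(schema.check_conditional_requirements(doc))
                issues.extend(_check_reference_signal(root, record, doc))
                issues.extend(_check_anatomical_image(root, record, doc))

        try:
            header, _ = nifti_mrs.read(root / rel)
            headers[rel] = header
            if not header.has_extension:
                issues.append(_issue(
                    "MRS061", rel, "header",
                    "no embedded MRS JSON header extension",
                ))
            if doc is not None:
                issues.extend(
                    nifti_mrs.consistency_check(header, doc, file=rel)
                )
        except nifti_mrs.NiftiMrsError as exc:
            issues.append(_issue("MRS060", rel, "container", str(exc)))

    # duplicate acquisition identities (indices compare as integers)
    seen: dict[tuple, str] = {}
    for record in inv.data_files:
        ident = record.parsed.canonical_identity()
        prev = seen.get(ident)
        if prev is not None:
            issues.append(_issue(
                "MRS081", record.dataset_relative_path, "filename",
                f"same entity set and suffix as {prev!r}",
            ))
        else:
            seen[ident] = record.dataset_relative_path

    # same voi label should carry identical tissue metadata everywhere
    by_voi: dict[str, dict[str, set]] = {}
    voi_files: dict[str, list[str]] = {}
    for record in inv.data_files:
        voi = record.parsed.get("voi")
        doc = docs.get(record.dataset_relative_path)
        if voi is None or doc is None:
            continue
        slot = by_voi.setdefault(voi, {"BodyPart": set(), "BodyPartDetails": set()})
        for key in slot:
            slot[key].add(json.dumps(doc.content.get(key), sort_keys=True))
        voi_files.setdefault(voi, []).append(record.dataset_relative_path)
    for voi in sorted(by_voi):
        divergent = {k for k, v in by_voi[voi].items() if len(v) > 1}
        if divergent:
            issues.append(_issue(
                "MRS082", sorted(voi_files[voi])[0], "voi",
                f"voi-{voi} maps to differing {'/'.join(sorted(divergent))} "
                f"across {len(voi_files[voi])} files",
            ))

    # orphan sidecars: parseable MRS sidecar with no matching data file
    data_stems = {
        r.dataset_relative_path[: -len(r.parsed.extension)] for r in inv.data_files
    }
    for sc in inv.sidecars:
        stem = sc[: -len(".json")]
        try:
            ent.parse_filename(PurePosixPath(sc).name)
        except ent.FilenameError as exc:
            issues.append(_filename_issue(exc, sc))
            continue
        if stem not in data_stems:
            issues.append(_issue(
                "MRS021", sc, "sidecar",
                "sidecar has no matching .nii/.nii.gz data file",
            ))

    disabled = set(disabled_rules)
    issues = [i for i in issues if i.rule_id not in disabled]
    if strictness == "strict":
        issues = [
            ValidationIssue(i.rule_id, "error", i.file, i.location, i.message)
            if i.severity == "warning" else i
            for i in issues
        ]
    return ValidationReport(root=str(root), issues=sort_issues(issues))


def render_report(report: ValidationReport, format: str = "text") -> str:
    """Serialize a report as grouped text or as a stable JSON document."""
    if format == "json":
        payload = {
            "root": ".",  # path-independent, so copies of a tree compare equal
            "passed": report.passed,
            "counts": report.counts,
            "issues": [
                {
                    "rule_id": i.rule_id,
                    "severity": i.severity,
                    "file": i.file,
                    "location": i.location,
                    "message": i.message,
                }
                for i in sort_issues(report.issues)
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)
    if format != "text":
        raise UnknownFormat(f"unknown report format {format!r}")

    lines = [f"Dataset: {report.root}"]
    current = None
    for i in sort_issues(report.issues):
        if i.file != current:
            current = i.file
            lines.append(f"{i.file}:")
        lines.append(f"  [{i.severity.upper():7s}] {i.rule_id} ({i.location}): {i.message}")
    c = report.counts
    lines.append(
        f"Summary: {c['error']} error(s), {c['warning']} warning(s), "
        f"{c['info']} info — {'pass' if report.passed else 'FAIL'}"
    )
    return "\n".join(lines)
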