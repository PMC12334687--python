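"""MRS-BIDS filename grammar: parse, build, and locate data files.

A filename is ``<entities>_<suffix>.<extension>`` where each entity is a
``key-value`` pair (e.g. ``sub-01``, ``nuc-1H``), the suffix names the data
type (``svs``, ``mrsi``, ``unloc``, ``mrsref``) and the extension is ``.nii``,
``.nii.gz`` or ``.json``.  Entities have a fixed canonical order, each key may
appear at most once, labels are alphanumeric and indices are nonnegative
integers.  Parsing is strict: violations raise, they are never repaired.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ENTITY_ORDER",
    "INDEX_ENTITIES",
    "SUFFIXES",
    "EXTENSIONS",
    "EntityDescriptor",
    "ParsedName",
    "FilenameError",
    "UnknownEntity",
    "DuplicateEntity",
    "OrderViolation",
    "BadLabel",
    "BadIndex",
    "MissingSuffix",
    "UnknownSuffix",
    "UnknownExtension",
    "MissingSubject",
    "parse_filename",
    "parse_filename_lenient",
    "build_filename",
    "expected_relative_path",
]

#: Canonical entity order: sub and ses lead; task/acq/nuc/voi follow as in the
#: published worked example; rec/run/echo/inv trail per the upstream BIDS MRS
#: template (the relative order of the trailing four vs nuc/voi is a project
#: decision, recorded in the rule catalog).
ENTITY_ORDER: tuple[str, ...] = (
    "sub", "ses", "task", "acq", "nuc", "voi", "rec", "run", "echo", "inv",
)

#: Entities whose value is a nonnegative-integer index rather than a label.
INDEX_ENTITIES: frozenset[str] = frozenset({"run", "echo", "inv"})

#: MRS data-type suffixes.
SUFFIXES: frozenset[str] = frozenset({"svs", "mrsi", "unloc", "mrsref"})

#: Recognized extensions (data and sidecar).
EXTENSIONS: tuple[str, ...] = (".nii.gz", ".nii", ".json")

_RANK: dict[str, int] = {k: i for i, k in enumerate(ENTITY_ORDER)}
_LABEL_RE = re.compile(r"^[A-Za-z0-9]+$")
_INDEX_RE = re.compile(r"^[0-9]+$")


class FilenameError(ValueError):
    """Base class for filename grammar violations."""


class UnknownEntity(FilenameError):
    pass


class DuplicateEntity(FilenameError):
    pass


class OrderViolation(FilenameError):
    pass


class BadLabel(FilenameError):
    pass


class BadIndex(FilenameError):
    pass


class MissingSuffix(FilenameError):
    pass


class UnknownSuffix(FilenameError):
    pass


class UnknownExtension(FilenameError):
    pass


class MissingSubject(FilenameError):
    pass


@dataclass(frozen=True)
class EntityDescriptor:
    """Static description of one entity key."""

    key: str
    value_kind: str  # "label" | "index"
    rank: int
    filename_required: bool = False


#: Descriptor table for every known entity, in canonical order.
ENTITY_TABLE: tuple[EntityDescriptor, ...] = tuple(
    EntityDescriptor(
        key=k,
        value_kind="index" if k in INDEX_ENTITIES else "label",
        rank=_RANK[k],
        filename_required=(k == "sub"),
    )
    for k in ENTITY_ORDER
)


@dataclass(frozen=True)
class ParsedName:
    """Decomposition of a filename into ordered entities, suffix, extension.

    ``entities`` is an ordered tuple of ``(key, value)`` pairs; use
    :meth:`entity_dict` or :meth:`get` for mapping-style access.
    """

    entities: tuple[tuple[str, str], ...]
    suffix: str
    extension: str

    def entity_dict(self) -> dict[str, str]:
        return dict(self.entities)

    def get(self, key: str, default: str | None = None) -> str | None:
        return self.entity_dict().get(key, default)

    @property
    def sub(self) -> str:
        return self.entity_dict()["sub"]

    @property
    def ses(self) -> str | None:
        return self.entity_dict().get("ses")

    def filename(self) -> str:
        """Reassemble the canonical filename string."""
        parts = [f"{k}-{v}" for k, v in self.entities]
        return "_".join(parts + [self.suffix]) + self.extension

    def canonical_identity(self) -> tuple:
        """Identity used for duplicate-acquisition detection.

        Index values compare as integers so ``run-1`` and ``run-01`` collide;
        labels compare verbatim.  Extension is excluded (data file and sidecar
        describe the same acquisition).
        """
        ents = tuple(
            (k, int(v) if k in INDEX_ENTITIES else v) for k, v in self.entities
        )
        return (ents, self.suffix)


@dataclass(frozen=True)
class DataFileRecord:
    """One data file found in a dataset tree."""

    dataset_relative_path: str
    parsed: ParsedName
    sidecar_path: str | None = None


def _split_extension(name: str) -> tuple[str, str]:
    for ext in EXTENSIONS:
        if name.endswith(ext):
            return name[: -len(ext)], ext
    raise UnknownExtension(
        f"{name!r}: extension not one of {', '.join(EXTENSIONS)}"
    )


def _validate_value(key: str, value: str) -> None:
    if key in INDEX_ENTITIES:
        if not _INDEX_RE.match(value):
            raise BadIndex(
                f"entity {key}-{value!r}: index must be a nonnegative integer"
            )
    elif not _LABEL_RE.match(value):
        raise BadLabel(f"entity {key}-{value!r}: label must be alphanumeric")


def _tokenize(name: str) -> tuple[list[tuple[str, str]], str, str]:
    if not name:
        raise FilenameError("empty filename")
    stem, ext = _split_extension(name)
    tokens = stem.split("_")
    suffix = tokens[-1]
    if "-" in suffix:
        raise MissingSuffix(f"{name!r}: last token {suffix!r} is not a bare suffix")
    if suffix not in SUFFIXES:
        raise UnknownSuffix(
            f"{name!r}: suffix {suffix!r} not one of {sorted(SUFFIXES)}"
        )
    pairs: list[tuple[str, str]] = []
    for tok in tokens[:-1]:
        key, dash, value = tok.partition("-")
        if not dash or key not in _RANK:
            raise UnknownEntity(f"{name!r}: unknown entity token {tok!r}")
        pairs.append((key, value))
    if not pairs or pairs[0][0] != "sub":
        raise MissingSubject(f"{name!r}: filename must begin with sub-<label>")
    return pairs, suffix, ext


def parse_filename(name: str) -> ParsedName:
    """Parse a filename string into a :class:`ParsedName` (strict).

    Raises a :class:`FilenameError` subclass naming the first violation:
    unknown entity key, duplicate key, canonical-order violation, bad
    label/index charset, missing/unknown suffix, unknown extension, or a
    filename not starting with ``sub-``.
    """
    pairs, suffix, ext = _tokenize(name)
    seen: set[str] = set()
    for key, _ in pairs:
        if key in seen:
            raise DuplicateEntity(
                f"{name!r}: entity {key!r} used more than once"
            )
        seen.add(key)
    ranks = [_RANK[k] for k, _ in pairs]
    if ranks != sorted(ranks):
        raise OrderViolation(
            f"{name!r}: entities out of canonical order "
            f"({', '.join(k for k, _ in pairs)})"
        )
    for key, value in pairs:
        _validate_value(key, value)
    return ParsedName(entities=tuple(pairs), suffix=suffix, extension=ext)


def parse_filename_lenient(name: str) -> tuple[ParsedName, list[str]]:
    """Parse, downgrading order violations to warnings and re-sorting.

    Exists for interactive inspection only; dataset validation always uses the
    strict :func:`parse_filename`.  All other violations still raise.
    """
    pairs, suffix, ext = _tokenize(name)
    seen: set[str] = set()
    for key, _ in pairs:
        if key in seen:
            raise DuplicateEntity(f"{name!r}: entity {key!r} used more than once")
        seen.add(key)
    warnings: list[str] = []
    ranks = [_RANK[k] for k, _ in pairs]
    if ranks != sorted(ranks):
        warnings.append(
            f"entities out of canonical order ({', '.join(k for k, _ in pairs)}); re-sorted"
        )
        pairs = sorted(pairs, key=lambda kv: _RANK[kv[0]])
    for key, value in pairs:
        _validate_value(key, value)
    return ParsedName(entities=tuple(pairs), suffix=suffix, extension=ext), warnings


def build_filename(
    entities: Mapping[str, str], suffix: str, extension: str
) -> str:
    """Construct a canonical filename from an entity mapping.

    Keys may be given in any order; the output is emitted in canonical rank
    order, so ``parse_filename(build_filename(...))`` round-trips.  The same
    validation errors as :func:`parse_filename` apply.
    """
    for key in entities:
        if key not in _RANK:
            raise UnknownEntity(f"unknown entity key {key!r}")
    if "sub" not in entities:
        raise MissingSubject("entity mapping must include 'sub'")
    if "-" in suffix:
        raise MissingSuffix(f"{suffix!r} is not a bare suffix")
    if suffix not in SUFFIXES:
        raise UnknownSuffix(f"suffix {suffix!r} not one of {sorted(SUFFIXES)}")
    if extension not in EXTENSIONS:
        raise UnknownExtension(f"extension {extension!r} not recognized")
    ordered = sorted(entities.items(), key=lambda kv: _RANK[kv[0]])
    for key, value in ordered:
        _validate_value(key, str(value))
    parts = [f"{k}-{v}" for k, v in ordered]
    return "_".join(parts + [suffix]) + extension


def expected_relative_path(parsed: ParsedName) -> str:
    """Directory (dataset-relative, trailing slash) where this file belongs.

    MRS data files live under ``sub-<label>/[ses-<label>/]mrs/``.
    """
    parts = [f"sub-{parsed.sub}"]
    if parsed.ses is not None:
        parts.append(f"ses-{parsed.ses}")
    parts.append("mrs")
    return "/".join(parts) + "/"
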