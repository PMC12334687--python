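"""Minimal NIfTI-MRS container IO.

A NIfTI-MRS file is a standard NIfTI-1/NIfTI-2 image holding a complex-valued
data block of up to seven dimensions — the first three spatial, the fourth the
time-domain FID samples, the fifth to seventh free encoding dimensions (coils,
transients, edit conditions, ...) — plus an embedded JSON header extension
carrying spectroscopy metadata (at minimum the spectrometer frequency and the
resonant nucleus).  The dwell time (the time-axis grid spacing, in seconds;
the reciprocal of the spectral width) travels in the header's fourth pixdim
slot, and the intent-name field carries the format's version tag.

Reading and writing go through nibabel; this module adds the MRS conventions
on top and the consistency checks between the embedded metadata, the sidecar
and the data-block geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

from .schema import RULES, SidecarDocument, ValidationIssue, sort_issues

__all__ = [
    "NIFTI_MRS_ECODE",
    "NIFTI_MRS_VERSION_TAG",
    "NiftiMrsHeader",
    "SpectralData",
    "NiftiMrsError",
    "NotNifti",
    "UnreadableExtension",
    "DimOverflow",
    "SerializationError",
    "read",
    "write",
    "consistency_check",
]

#: NIfTI header-extension code designated for MRS JSON metadata by the
#: NIfTI-MRS standard's registration with the NIfTI extension registry.
NIFTI_MRS_ECODE: int = 44

#: Version tag written into the NIfTI intent-name field.
NIFTI_MRS_VERSION_TAG: str = "mrs_v0_2"

#: Relative tolerance for the spectral-width vs dwell-time reciprocal check.
SPECTRAL_WIDTH_RTOL: float = 1e-3


class NiftiMrsError(Exception):
    """Base class for container IO failures."""


class NotNifti(NiftiMrsError):
    pass


class UnreadableExtension(NiftiMrsError):
    """An MRS header extension is present but is not valid JSON."""


class DimOverflow(NiftiMrsError):
    """More than seven non-unit dimensions."""


class SerializationError(NiftiMrsError):
    pass


@dataclass
class NiftiMrsHeader:
    """Essential header state of a NIfTI-MRS file.

    dims
        Data-block extents, up to 7 entries, each >= 1.
    dwell_time
        Time-axis sample spacing in seconds; must be > 0 when a time
        dimension (4th axis) exists.
    intent_label
        The NIfTI-MRS version tag stored in the intent-name field.
    header_ext
        The embedded JSON metadata; empty (with ``has_extension`` False) when
        the file carries no MRS extension.
    """

    dims: tuple[int, ...]
    dwell_time: float
    intent_label: str = NIFTI_MRS_VERSION_TAG
    header_ext: dict[str, Any] = field(default_factory=dict)
    has_extension: bool = True

    def __post_init__(self) -> None:
        if not (1 <= len(self.dims) <= 7):
            raise DimOverflow(f"dims must have 1..7 entries, got {len(self.dims)}")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all extents must be >= 1, got {self.dims}")
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) >= 4 and not self.dwell_time > 0:
            raise ValueError("dwell_time must be > 0 when a time dimension exists")

    @property
    def spatial_extents(self) -> tuple[int, int, int]:
        padded = self.dims + (1,) * (7 - len(self.dims))
        return padded[0], padded[1], padded[2]

    @property
    def time_extent(self) -> int:
        padded = self.dims + (1,) * (7 - len(self.dims))
        return padded[3]


@dataclass
class SpectralData:
    """Complex data block whose element count matches the header dims."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.iscomplexobj(self.values):
            self.values = self.values.astype(np.complex64)


def _pad_to_7d(a: np.ndarray) -> np.ndarray:
    if a.ndim > 7:
        extra = a.shape[7:]
        if any(e != 1 for e in extra):
            raise DimOverflow(f"data has {a.ndim} dims with non-unit extents beyond 7")
        a = a.reshape(a.shape[:7])
    return a.reshape(a.shape + (1,) * (7 - a.ndim))


def write(
    header: NiftiMrsHeader,
    data: SpectralData,
    path: str | Path,
    *,
    double_precision: bool = False,
) -> Path:
    """Write a NIfTI-MRS file.

    The data block is padded with trailing singleton dimensions to exactly
    seven, stored complex single-precision by default (``double_precision``
    selects complex128), and the header extension is embedded as JSON with
    the MRS extension code.  ``read(write(x)) == x`` for dims, dwell time and
    extension content.
    """
    path = Path(path)
    values = _pad_to_7d(np.asarray(data.values))
    expected = tuple(header.dims) + (1,) * (7 - len(header.dims))
    if values.shape != expected:
        raise ValueError(
            f"data shape {values.shape} does not match header dims {header.dims}"
        )
    dtype = np.complex128 if double_precision else np.complex64
    values = values.astype(dtype, copy=False)

    img = nib.Nifti2Image(values, affine=np.eye(4))
    hdr = img.header
    hdr["pixdim"][4] = header.dwell_time
    hdr["intent_name"] = header.intent_label.encode()
    try:
        payload = json.dumps(header.header_ext, sort_keys=True).encode()
    except (TypeError, ValueError) as exc:
        raise SerializationError(f"header extension is not JSON-serializable: {exc}")
    if header.has_extension:
        hdr.extensions.append(nib.nifti1.Nifti1Extension(NIFTI_MRS_ECODE, payload))
    nib.save(img, str(path))
    return path


def read(path: str | Path) -> tuple[NiftiMrsHeader, SpectralData]:
    """Read a NIfTI-MRS file (or any NIfTI; see below).

    Returns the header (with the embedded JSON extension parsed) and the data
    block.  A NIfTI without an MRS extension is readable: the returned header
    has an empty ``header_ext`` and ``has_extension`` False.  An extension
    that is present but not valid JSON raises :class:`UnreadableExtension`;
    a non-NIfTI file raises :class:`NotNifti`.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise NotNifti(f"{path}: not a readable NIfTI file ({exc})")
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise NotNifti(f"{path}: not a NIfTI-1/NIfTI-2 image")

    hdr = img.header
    dims = tuple(int(d) for d in img.shape)
    if len(dims) > 7:
        if any(d != 1 for d in dims[7:]):
            raise DimOverflow(f"{path}: more than 7 non-unit dimensions")
        dims = dims[:7]

    header_ext: dict[str, Any] = {}
    has_extension = False
    for ext in hdr.extensions:
        if ext.get_code() == NIFTI_MRS_ECODE:
            has_extension = True
            raw = ext.get_content()
            if isinstance(raw, bytes):
                raw = raw.rstrip(b"\x00").decode("utf-8", errors="replace")
            elif isinstance(raw, dict):
                header_ext = raw
                break
            try:
                parsed = json.loads(raw)
            except (json.JSONDecodeError, UnicodeDecodeError) as exc:
                raise UnreadableExtension(
                    f"{path}: MRS header extension is not valid JSON ({exc})"
                )
            if not isinstance(parsed, dict):
                raise UnreadableExtension(
                    f"{path}: MRS header extension is not a JSON object"
                )
            header_ext = parsed
            break

    intent = hdr["intent_name"]
    intent_label = (
        intent.tobytes() if hasattr(intent, "tobytes") else bytes(intent)
    ).rstrip(b"\x00").decode("ascii", errors="replace")

    dwell = float(hdr["pixdim"][4])
    header = NiftiMrsHeader(
        dims=dims,
        dwell_time=dwell if dwell > 0 else (1.0 if len(dims) < 4 else dwell),
        intent_label=intent_label,
        header_ext=header_ext,
        has_extension=has_extension,
    )
    # tolerate dwell<=0 on foreign files with a time axis: keep the raw value
    if len(dims) >= 4 and not dwell > 0:
        header.__dict__["dwell_time"] = dwell
    values = np.asanyarray(img.dataobj)
    return header, SpectralData(values=values)


def _issue(rule_id: str, file: str, location: str, message: str) -> ValidationIssue:
    return ValidationIssue(
        rule_id=rule_id,
        severity=RULES[rule_id]["severity"],
        file=file,
        location=location,
        message=message,
    )


def consistency_check(
    header: NiftiMrsHeader,
    sidecar: SidecarDocument,
    *,
    file: str = "<memory>",
) -> list[ValidationIssue]:
    """Cross-check the embedded header metadata against the sidecar.

    Warns on spectrometer-frequency or nucleus disagreement between the
    embedded extension and the sidecar; errors when the sidecar's
    SpectralWidth is not the reciprocal of the dwell time (relative tolerance
    1e-3); warns when NumberOfSpectralPoints differs from the time-dimension
    extent; errors on SVS data with a spatial extent > 1; warns on MRSI data
    whose spatial extents are all 1.
    """
    issues: list[ValidationIssue] = []
    content = sidecar.content
    suffix = sidecar.context.suffix if sidecar.context is not None else None

    ext = header.header_ext

    def _scalarize(v: Any) -> Any:
        # the NIfTI-MRS dialect stores these as singleton arrays
        if isinstance(v, list) and len(v) == 1:
            return v[0]
        return v

    if "SpectrometerFrequency" in ext and "SpectrometerFrequency" in content:
        hv, sv = _scalarize(ext["SpectrometerFrequency"]), content["SpectrometerFrequency"]
        if isinstance(hv, (int, float)) and isinstance(sv, (int, float)):
            if abs(hv - sv) > 1e-6 * max(1.0, abs(sv)):
                issues.append(_issue(
                    "MRS062", file, "SpectrometerFrequency",
                    f"embedded header says {hv} MHz but sidecar says {sv} MHz",
                ))

    if "ResonantNucleus" in ext and "ResonantNucleus" in content:
        def norm(v: Any) -> str:
            if isinstance(v, list):
                v = "".join(str(x) for x in v)
            return "".join(ch for ch in str(v).lower() if ch.isalnum())

        if norm(ext["ResonantNucleus"]) != norm(content["ResonantNucleus"]):
            issues.append(_issue(
                "MRS063", file, "ResonantNucleus",
                f"embedded header says {_scalarize(ext['ResonantNucleus'])!r} "
                f"but sidecar says {content['ResonantNucleus']!r}",
            ))

    sw = content.get("SpectralWidth")
    if isinstance(sw, (int, float)) and not isinstance(sw, bool) and sw > 0:
        if header.dwell_time > 0:
            implied = 1.0 / header.dwell_time
            if abs(sw - implied) / sw > SPECTRAL_WIDTH_RTOL:
                issues.append(_issue(
                    "MRS064", file, "SpectralWidth",
                    f"SpectralWidth {sw} Hz inconsistent with dwell time "
                    f"{header.dwell_time} s (implies {implied:.6g} Hz)",
                ))

    nsp = content.get("NumberOfSpectralPoints")
    if isinstance(nsp, int) and not isinstance(nsp, bool):
        if nsp != header.time_extent:
            issues.append(_issue(
                "MRS065", file, "NumberOfSpectralPoints",
                f"NumberOfSpectralPoints {nsp} differs from the container's "
                f"time-dimension extent {header.time_extent}",
            ))

    sx, sy, sz = header.spatial_extents
    if suffix == "svs" and max(sx, sy, sz) > 1:
        issues.append(_issue(
            "MRS066", file, "dim",
            f"SVS data must occupy a single voxel; spatial extents are "
            f"({sx}, {sy}, {sz})",
        ))
    if suffix == "mrsi" and max(sx, sy, sz) == 1:
        issues.append(_issue(
            "MRS067", file, "dim",
            "MRSI data with all spatial extents equal to 1",
        ))

    return sort_issues(issues)
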