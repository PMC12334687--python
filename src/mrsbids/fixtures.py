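"""Synthetic MRS-BIDS datasets: valid by construction, plus targeted faults.

:func:`generate_dataset` writes a fully self-contained dataset — directory
scaffolding, ``dataset_description.json``, ``participants.tsv``, anatomical
stand-ins, NIfTI-MRS data files with embedded metadata, and sidecars carrying
every required and applicable recommended field — that the dataset validator
accepts with zero errors.  :func:`generate_fid` synthesizes the time-domain
signals as sums of damped complex exponentials with Gaussian noise.
:func:`apply_mutation` injects exactly one catalogued rule violation into an
otherwise valid tree, which is how the validator's diagnostics are tested
end to end.

All randomness is derived from the spec's single seed; two runs with the same
spec produce byte-identical sidecars.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import nibabel as nib
import numpy as np

from . import nifti_mrs
from .entities import build_filename
from .validator import DatasetInventory, scan

__all__ = [
    "Acquisition",
    "FixtureSpec",
    "Mutation",
    "MUTATIONS",
    "BadParameters",
    "UnknownMutation",
    "generate_fid",
    "generate_dataset",
    "apply_mutation",
    "default_fixture_spec",
    "mutation_fixture_spec",
    "random_entity_set",
    "random_fixture_spec",
]


class BadParameters(ValueError):
    pass


class UnknownMutation(KeyError):
    pass


@dataclass(frozen=True)
class Acquisition:
    """Acquisition parameters shared by the synthetic signals.

    Defaults emulate a routine 3 T proton exam: 123.25 MHz spectrometer
    frequency, 2000 Hz spectral width, 2048 complex points, and three damped
    resonances at the NAA/creatine/choline offsets relative to a water-centred
    carrier (4.65 ppm; 1 ppm = 123.25 Hz at this field).  Plausible defaults
    only — configuration, not claims about any scanner.
    """

    spectrometer_frequency: float = 123.25  # MHz
    spectral_width: float = 2000.0  # Hz
    n_points: int = 2048
    #: (amplitude, frequency offset in Hz, T2 decay constant in s)
    metabolites: tuple[tuple[float, float, float], ...] = (
        (1.0, (2.01 - 4.65) * 123.25, 0.10),   # NAA
        (0.8, (3.03 - 4.65) * 123.25, 0.09),   # total creatine
        (0.6, (3.20 - 4.65) * 123.25, 0.11),   # choline compounds
    )
    noise_sd: float = 0.01


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``kinds`` lists the acquisitions written per subject/session as
    ``(suffix, entity template)`` pairs; ``sessions_per_subject == 0`` omits
    the session level entirely.  ``seed`` fixes all randomness.
    """

    n_subjects: int = 2
    sessions_per_subject: int = 1
    kinds: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = (
        ("svs", (("acq", "press"), ("nuc", "1H"), ("voi", "acc"))),
        ("mrsref", (("acq", "concref"),)),
    )
    acquisition: Acquisition = field(default_factory=Acquisition)
    mrsi_matrix: tuple[int, int, int] = (4, 4, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise BadParameters("n_subjects must be >= 1")
        if self.sessions_per_subject < 0:
            raise BadParameters("sessions_per_subject must be >= 0")
        if self.acquisition.n_points < 2:
            raise BadParameters("n_points must be >= 2")
        if not self.acquisition.spectral_width > 0:
            raise BadParameters("spectral_width must be > 0")


def default_fixture_spec(seed: int = 0, **kwargs) -> FixtureSpec:
    """A two-subject SVS + water-reference dataset."""
    return FixtureSpec(seed=seed, **kwargs)


_LABEL_ALPHABET = (
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
)


def random_entity_set(
    rng: np.random.Generator,
) -> tuple[dict[str, str], str, str]:
    """Draw one random valid (entities, suffix, extension) triple.

    ``sub`` is always present; other entities appear with probability 1/2
    (labels) or 1/3 (indices).  The returned mapping's key order is shuffled,
    so building a filename from it also exercises output-side canonical
    sorting.
    """
    def label() -> str:
        n = int(rng.integers(1, 9))
        return "".join(
            _LABEL_ALPHABET[i] for i in rng.integers(0, len(_LABEL_ALPHABET), n)
        )

    entities: dict[str, str] = {"sub": label()}
    for key in ("ses", "task", "acq", "nuc", "voi", "rec"):
        if rng.random() < 0.5:
            entities[key] = label()
    for key in ("run", "echo", "inv"):
        if rng.random() < 1 / 3:
            entities[key] = str(int(rng.integers(0, 100)))
    keys = list(entities)
    rng.shuffle(keys)
    entities = {k: entities[k] for k in keys}
    suffix = ["svs", "mrsi", "unloc", "mrsref"][int(rng.integers(0, 4))]
    extension = [".nii", ".nii.gz"][int(rng.integers(0, 2))]
    return entities, suffix, extension


def random_fixture_spec(seed: int) -> FixtureSpec:
    """Draw one random dataset spec (structure varies; seed fixes it all).

    Signal lengths are kept short (64-256 points): dataset validation
    exercises structure and metadata, not spectral content.
    """
    rng = np.random.default_rng(seed)
    kinds: list[tuple[str, tuple[tuple[str, str], ...]]] = []
    svs_template: list[tuple[str, str]] = [("acq", "press")]
    if rng.random() < 0.7:
        svs_template.append(("nuc", "1H"))
    if rng.random() < 0.7:
        svs_template.append(("voi", ["acc", "pcc", "dlpfc"][int(rng.integers(0, 3))]))
    kinds.append(("svs", tuple(svs_template)))
    if rng.random() < 0.8:
        kinds.append(("mrsref", (("acq", "concref"),)))
    if rng.random() < 0.5:
        kinds.append(("mrsi", (("acq", "epsi"), ("nuc", "1H"))))
    if rng.random() < 0.3:
        kinds.append(("unloc", (("acq", "pulseacquire"), ("nuc", "31P"))))
    acq = Acquisition(
        n_points=int([64, 128, 256][int(rng.integers(0, 3))]),
        noise_sd=float([0.0, 0.01, 0.05][int(rng.integers(0, 3))]),
    )
    return FixtureSpec(
        n_subjects=int(rng.integers(1, 4)),
        sessions_per_subject=int(rng.integers(0, 3)),
        kinds=tuple(kinds),
        acquisition=acq,
        mrsi_matrix=[(2, 2, 1), (4, 4, 1), (2, 3, 2)][int(rng.integers(0, 3))],
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def mutation_fixture_spec(seed: int = 0) -> FixtureSpec:
    """A dataset exercising every mutation target: SVS, reference and MRSI."""
    return FixtureSpec(
        seed=seed,
        kinds=(
            ("svs", (("acq", "press"), ("nuc", "1H"), ("voi", "acc"))),
            ("mrsref", (("acq", "concref"),)),
            ("mrsi", (("acq", "epsi"), ("nuc", "1H"))),
        ),
    )


def generate_fid(
    metabolites: Sequence[tuple[float, float, float]],
    spectral_width: float,
    n_points: int,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Synthesize one FID as a sum of damped complex exponentials.

    ``s[n] = sum_k A_k exp(2 pi i f_k n dt) exp(-n dt / T2_k) + sd * (e_re + i e_im)``
    with ``dt = 1/spectral_width`` and standard-normal noise; deterministic
    for a given seed.  ``T2 = inf`` gives an undamped component.
    """
    if n_points < 2:
        raise BadParameters("n_points must be >= 2")
    if not spectral_width > 0:
        raise BadParameters("spectral_width must be > 0")
    if noise_sd < 0:
        raise BadParameters("noise_sd must be >= 0")
    dt = 1.0 / spectral_width
    t = np.arange(n_points) * dt
    s = np.zeros(n_points, dtype=np.complex128)
    for amp, freq, t2 in metabolites:
        if not t2 > 0:
            raise BadParameters(f"T2 must be > 0 (or inf), got {t2}")
        decay = np.exp(-t / t2) if np.isfinite(t2) else 1.0
        s += amp * np.exp(2j * np.pi * freq * t) * decay
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s += noise_sd * (rng.standard_normal(n_points)
                         + 1j * rng.standard_normal(n_points))
    return s


def _file_seed(base: int, index: int) -> int:
    return (base * 1000003 + index * 7919 + 17) % (2**31)


def _write_anat(path: Path) -> None:
    img = nib.Nifti1Image(np.zeros((4, 4, 4), dtype=np.int16), np.eye(4))
    nib.save(img, str(path))


def _dump_json(path: Path, content: dict) -> None:
    path.write_text(json.dumps(content, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def generate_dataset(spec: FixtureSpec, out_root: str | Path) -> DatasetInventory:
    """Write a complete, valid MRS-BIDS dataset under ``out_root``.

    Per subject (and session, when used): a small anatomical stand-in under
    ``anat/`` and one NIfTI-MRS file plus sidecar per entry in
    ``spec.kinds`` under ``mrs/``.  SVS/unloc/reference data are single-voxel
    FIDs; MRSI data carry ``spec.mrsi_matrix`` spatial extents.  SVS-style
    sidecars reference the generated water-reference file and the anatomical
    image by dataset-root-relative paths.  The result validates with zero
    errors; returns the scanned inventory.
    """
    root = Path(out_root)
    root.mkdir(parents=True, exist_ok=True)
    acq = spec.acquisition

    _dump_json(root / "dataset_description.json", {
        "Name": "Synthetic MRS fixture dataset",
        "BIDSVersion": "1.9.0",
        "DatasetType": "raw",
    })

    sub_labels = [f"{i + 1:02d}" for i in range(spec.n_subjects)]
    (root / "participants.tsv").write_text(
        "participant_id\n" + "".join(f"sub-{s}\n" for s in sub_labels),
        encoding="utf-8",
    )

    file_index = 0
    for sub in sub_labels:
        sessions: list[str | None]
        if spec.sessions_per_subject == 0:
            sessions = [None]
        else:
            sessions = [f"{j + 1:02d}" for j in range(spec.sessions_per_subject)]
        for ses in sessions:
            level = root / f"sub-{sub}" / (f"ses-{ses}" if ses else "")
            anat_dir = level / "anat"
            mrs_dir = level / "mrs"
            anat_dir.mkdir(parents=True, exist_ok=True)
            mrs_dir.mkdir(parents=True, exist_ok=True)

            anat_entities = {"sub": sub, **({"ses": ses} if ses else {})}
            anat_name = "_".join(
                [f"{k}-{v}" for k, v in anat_entities.items()] + ["T1w"]
            ) + ".nii.gz"
            _write_anat(anat_dir / anat_name)
            anat_rel = (anat_dir / anat_name).relative_to(root).as_posix()

            # reference file path is needed by the svs/mrsi/unloc sidecars
            ref_rel: str | None = None
            for suffix, template in spec.kinds:
                if suffix == "mrsref":
                    ents = {"sub": sub, **({"ses": ses} if ses else {}),
                            **dict(template)}
                    ref_name = build_filename(ents, "mrsref", ".nii.gz")
                    ref_rel = (mrs_dir / ref_name).relative_to(root).as_posix()
                    break

            for suffix, template in spec.kinds:
                entities = {"sub": sub, **({"ses": ses} if ses else {}),
                            **dict(template)}
                name = build_filename(entities, suffix, ".nii.gz")
                data_path = mrs_dir / name
                sidecar_path = mrs_dir / (name[: -len(".nii.gz")] + ".json")

                seed = _file_seed(spec.seed, file_index)
                file_index += 1

                if suffix == "mrsref":
                    components = ((50.0, 0.0, 0.05),)  # unsuppressed water
                else:
                    components = acq.metabolites
                fid = generate_fid(components, acq.spectral_width,
                                   acq.n_points, 0.0, seed)

                if suffix == "mrsi":
                    mx, my, mz = spec.mrsi_matrix
                    values = np.broadcast_to(
                        fid, (mx, my, mz, acq.n_points)
                    ).copy()
                    if acq.noise_sd > 0:
                        rng = np.random.default_rng(seed)
                        values = values + acq.noise_sd * (
                            rng.standard_normal(values.shape)
                            + 1j * rng.standard_normal(values.shape)
                        )
                    dims = (mx, my, mz, acq.n_points)
                else:
                    if acq.noise_sd > 0:
                        rng = np.random.default_rng(seed)
                        fid = fid + acq.noise_sd * (
                            rng.standard_normal(acq.n_points)
                            + 1j * rng.standard_normal(acq.n_points)
                        )
                    values = fid.reshape(1, 1, 1, acq.n_points)
                    dims = (1, 1, 1, acq.n_points)

                nucleus = dict(template).get("nuc", "1H")
                header = nifti_mrs.NiftiMrsHeader(
                    dims=dims,
                    dwell_time=1.0 / acq.spectral_width,
                    header_ext={
                        "SpectrometerFrequency": [acq.spectrometer_frequency],
                        "ResonantNucleus": [nucleus],
                    },
                )
                nifti_mrs.write(header, nifti_mrs.SpectralData(values), data_path)

                sidecar = _build_sidecar(
                    spec, suffix, dict(template), nucleus,
                    anat_rel=anat_rel,
                    ref_rel=ref_rel if suffix in ("svs", "mrsi", "unloc") else None,
                )
                _dump_json(sidecar_path, sidecar)
    return scan(root)


def _build_sidecar(
    spec: FixtureSpec,
    suffix: str,
    template: dict[str, str],
    nucleus: str,
    anat_rel: str,
    ref_rel: str | None,
) -> dict:
    acq = spec.acquisition
    content: dict = {
        # required
        "ResonantNucleus": nucleus,
        "SpectrometerFrequency": acq.spectrometer_frequency,
        "SpectralWidth": acq.spectral_width,
        "EchoTime": 0.03,
        # recommended everywhere
        "WaterSuppression": suffix != "mrsref",
        "NumberOfSpectralPoints": acq.n_points,
        "MixingTime": 0.0,
        "AnatomicalImage": anat_rel,
    }
    if suffix in ("svs", "mrsi", "mrsref"):
        content["AcquisitionVoxelSize"] = [20.0, 20.0, 20.0]
    if suffix in ("svs", "unloc"):
        content["NumberOfTransients"] = 64
    if ref_rel is not None:
        content["ReferenceSignal"] = ref_rel
    if suffix == "mrsi":
        mx, my, mz = spec.mrsi_matrix
        content["MatrixSize"] = [int(mx), int(my), int(mz)]
        content["VolumeAffineMatrix"] = [
            [20.0, 0.0, 0.0, 0.0],
            [0.0, 20.0, 0.0, 0.0],
            [0.0, 0.0, 20.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
        content["EncodingTechnique"] = "EPSI"
    if "acq" in template:
        content["PulseSequenceType"] = template["acq"]
    if "voi" in template:
        content["BodyPart"] = "brain"
        content["BodyPartDetails"] = {
            "acc": "anterior cingulate cortex",
            "pcc": "posterior cingulate cortex",
            "dlpfc": "dorsolateral prefrontal cortex",
        }.get(template["voi"], template["voi"])
    if suffix == "svs":
        content["PulseSequencePulses"] = ["excitation", "refocusing", "refocusing"]
        content["PulseSequenceTiming"] = [0.0, 0.0075, 0.0225]
    return content


# --------------------------------------------------------------------------
# Mutations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Mutation:
    """A named transform that violates exactly one catalogued rule."""

    name: str
    rule_id: str  # the validator rule the mutation must trigger
    description: str
    apply: Callable[[Path], None] = field(compare=False, repr=False)


def _find_pair(root: Path, suffix: str) -> tuple[Path, Path]:
    """First data file with the given suffix, plus its sidecar."""
    inv = scan(root)
    for rec in inv.data_files:
        if rec.parsed.suffix == suffix:
            data = root / rec.dataset_relative_path
            sidecar = data.parent / (
                rec.dataset_relative_path.rsplit("/", 1)[-1]
                [: -len(rec.parsed.extension)] + ".json"
            )
            return data, sidecar
    raise UnknownMutation(f"dataset has no {suffix!r} file to mutate")


def _rename_pair(root: Path, suffix: str, transform: Callable[[str], str]) -> None:
    data, sidecar = _find_pair(root, suffix)
    stem = data.name[: -len(".nii.gz")]
    new_stem = transform(stem)
    data.rename(data.parent / (new_stem + ".nii.gz"))
    if sidecar.is_file():
        sidecar.rename(sidecar.parent / (new_stem + ".json"))


def _edit_sidecar(root: Path, suffix: str, edit: Callable[[dict], None]) -> None:
    _, sidecar = _find_pair(root, suffix)
    content = json.loads(sidecar.read_text(encoding="utf-8"))
    edit(content)
    _dump_json(sidecar, content)


def _mut_duplicate_entity(root: Path) -> None:
    def t(stem: str) -> str:
        first, rest = stem.split("_", 1)
        return f"{first}_{first}_{rest}"
    _rename_pair(root, "svs", t)


def _mut_order_swap(root: Path) -> None:
    def t(stem: str) -> str:
        toks = stem.split("_")
        toks[-3], toks[-2] = toks[-2], toks[-3]  # swap the last two entities
        return "_".join(toks)
    _rename_pair(root, "svs", t)


def _mut_bad_label(root: Path) -> None:
    _rename_pair(root, "svs", lambda s: s.replace("acq-press", "acq-pre.ss"))


def _mut_unknown_suffix(root: Path) -> None:
    _rename_pair(root, "svs", lambda s: s[: -len("svs")] + "svz")


def _mut_missing_sidecar(root: Path) -> None:
    _, sidecar = _find_pair(root, "svs")
    sidecar.unlink()


def _mut_missing_echotime(root: Path) -> None:
    _edit_sidecar(root, "svs", lambda c: c.pop("EchoTime"))


def _mut_watersuppression_string(root: Path) -> None:
    _edit_sidecar(root, "svs", lambda c: c.update(WaterSuppression="yes"))


def _mut_voxelsize_length_2(root: Path) -> None:
    _edit_sidecar(root, "svs", lambda c: c.update(AcquisitionVoxelSize=[20.0, 20.0]))


def _mut_matrixsize_length_4(root: Path) -> None:
    _edit_sidecar(root, "mrsi", lambda c: c.update(MatrixSize=[4, 4, 1, 1]))


def _mut_affine_3x3(root: Path) -> None:
    _edit_sidecar(root, "mrsi", lambda c: c.update(VolumeAffineMatrix=[
        [20.0, 0.0, 0.0], [0.0, 20.0, 0.0], [0.0, 0.0, 1.0],
    ]))


def _mut_voi_without_bodypart(root: Path) -> None:
    _edit_sidecar(root, "svs", lambda c: c.pop("BodyPart"))


def _mut_nuc_mismatch(root: Path) -> None:
    _edit_sidecar(root, "svs", lambda c: c.update(ResonantNucleus="31P"))


def _mut_pulse_length_mismatch(root: Path) -> None:
    _edit_sidecar(
        root, "svs",
        lambda c: c.update(PulseSequenceTiming=c["PulseSequenceTiming"][:-1]),
    )


def _mut_dangling_reference(root: Path) -> None:
    _edit_sidecar(
        root, "svs",
        lambda c: c.update(ReferenceSignal="sub-99/mrs/sub-99_mrsref.nii.gz"),
    )


def _mut_dangling_anatomical(root: Path) -> None:
    _edit_sidecar(
        root, "svs",
        lambda c: c.update(AnatomicalImage="sub-99/anat/sub-99_T1w.nii.gz"),
    )


def _mut_missing_dataset_description(root: Path) -> None:
    (root / "dataset_description.json").unlink()


def _mut_spectralwidth_mismatch(root: Path) -> None:
    _edit_sidecar(
        root, "svs",
        lambda c: c.update(SpectralWidth=c["SpectralWidth"] * 1.25),
    )


def _mut_svs_spatial_extent(root: Path) -> None:
    data, _ = _find_pair(root, "svs")
    header, spectral = nifti_mrs.read(data)
    values = np.broadcast_to(
        spectral.values, (2,) + spectral.values.shape[1:]
    ).copy()
    new_header = nifti_mrs.NiftiMrsHeader(
        dims=(2,) + tuple(header.dims[1:]),
        dwell_time=header.dwell_time,
        intent_label=header.intent_label,
        header_ext=header.header_ext,
    )
    nifti_mrs.write(new_header, nifti_mrs.SpectralData(values), data)


def _mut_wrong_directory(root: Path) -> None:
    data, sidecar = _find_pair(root, "svs")
    # place the pair in an mrs/ directory that contradicts its entities
    target = root / data.relative_to(root).parts[0] / "misplaced" / "mrs"
    target.mkdir(parents=True, exist_ok=True)
    data.rename(target / data.name)
    if sidecar.is_file():
        sidecar.rename(target / sidecar.name)


def _registry() -> dict[str, Mutation]:
    entries = [
        ("duplicate-entity", "MRS002",
         "rename an SVS pair so the sub entity appears twice",
         _mut_duplicate_entity),
        ("entity-order-swap", "MRS003",
         "swap two entities out of canonical order in an SVS filename",
         _mut_order_swap),
        ("bad-label-charset", "MRS004",
         "insert a non-alphanumeric character into the acq label",
         _mut_bad_label),
        ("unknown-suffix", "MRS006",
         "rename the svs suffix to an unknown token",
         _mut_unknown_suffix),
        ("missing-sidecar", "MRS020",
         "delete the SVS file's JSON sidecar",
         _mut_missing_sidecar),
        ("missing-echotime", "MRS030",
         "remove the required EchoTime field",
         _mut_missing_echotime),
        ("watersuppression-string", "MRS032",
         "store WaterSuppression as the string 'yes' instead of a boolean",
         _mut_watersuppression_string),
        ("voxelsize-length-2", "MRS032",
         "truncate AcquisitionVoxelSize to length 2",
         _mut_voxelsize_length_2),
        ("matrixsize-length-4", "MRS032",
         "extend MatrixSize to length 4",
         _mut_matrixsize_length_4),
        ("affine-3x3", "MRS032",
         "shrink VolumeAffineMatrix to 3x3",
         _mut_affine_3x3),
        ("voi-without-bodypart", "MRS042",
         "remove BodyPart from a voi-tagged acquisition",
         _mut_voi_without_bodypart),
        ("nuc-mismatch", "MRS041",
         "set ResonantNucleus to a nucleus different from the nuc label",
         _mut_nuc_mismatch),
        ("pulse-length-mismatch", "MRS045",
         "drop one element of PulseSequenceTiming",
         _mut_pulse_length_mismatch),
        ("dangling-referencesignal", "MRS083",
         "point ReferenceSignal at a nonexistent file",
         _mut_dangling_reference),
        ("dangling-anatomicalimage", "MRS084",
         "point AnatomicalImage at a nonexistent file",
         _mut_dangling_anatomical),
        ("missing-dataset-description", "MRS080",
         "delete dataset_description.json",
         _mut_missing_dataset_description),
        ("spectralwidth-mismatch", "MRS064",
         "scale the sidecar SpectralWidth away from 1/dwell-time",
         _mut_spectralwidth_mismatch),
        ("svs-spatial-extent", "MRS066",
         "rewrite an SVS file with a spatial extent of 2",
         _mut_svs_spatial_extent),
        ("wrong-directory", "MRS010",
         "move an SVS pair into a directory contradicting its entities",
         _mut_wrong_directory),
    ]
    return {
        name: Mutation(name=name, rule_id=rid, description=desc, apply=fn)
        for name, rid, desc, fn in entries
    }


#: Registry of targeted single-rule mutations, keyed by name.
MUTATIONS: dict[str, Mutation] = _registry()


def apply_mutation(root: str | Path, mutation: str | Mutation) -> Mutation:
    """Inject one targeted violation into a generated dataset (in place)."""
    if isinstance(mutation, str):
        try:
            mutation = MUTATIONS[mutation]
        except KeyError:
            raise UnknownMutation(
                f"unknown mutation {mutation!r}; known: {sorted(MUTATIONS)}"
            )
    mutation.apply(Path(root))
    return mutation
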