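# Methods

## Scope and model

`mrsbids` treats an MRS-BIDS dataset as three nested contracts:

1. a **naming contract** — every data file's name is a sequence of
   key-value entities in a fixed canonical order, one suffix, one extension,
   and the file sits in the directory its entities imply;
2. a **metadata contract** — each data file's JSON sidecar carries the
   required acquisition parameters with the documented types, shapes and
   units, plus whatever conditional fields its filename entities trigger;
3. a **container contract** — the NIfTI-MRS file itself is internally
   consistent (geometry matches the data type, dwell time matches the
   declared bandwidth) and consistent with its sidecar, and any cross-file
   references (water reference, anatomical image) resolve.

The validator is the composition of the three; the fixture generator is the
constructive inverse (it emits trees satisfying all three by construction),
and the mutation registry spans the rule catalog so that validator coverage
is testable as a one-fault-diagnosis property rather than rule by rule.

## Naming grammar

Canonical entity order is `sub, ses, task, acq, nuc, voi, rec, run, echo,
inv`. The relative order of `rec/run/echo/inv` versus `nuc/voi` is not
fixed by any single worked example; we follow the upstream BIDS MRS
template, place the index-valued entities last, and flag the choice in the
rule catalog (`MRS003` carries a `decision` marker). Labels are
case-sensitive `[A-Za-z0-9]+` and preserved verbatim; indices are digit
strings whose leading zeros are preserved for display but compared as
integers when detecting duplicate acquisitions (`run-1` vs `run-01`
collide). Parsing never repairs: the only lenient behaviour (re-sorting
mis-ordered entities, with a warning) lives in the `inspect` command and is
unreachable from validation.

Error precedence when several violations coexist: extension, suffix,
unknown entity, missing subject, duplicate, order, value charset. Each
class is reachable by a single-token mutation of a valid name, which the
test suite exercises.

## Sidecar catalog and severities

Requirement wording maps to severities RFC-2119 style: "must" → error,
"recommended"/"should" → warning, absent optional fields → silent, any
malformed value → error regardless of level. Unknown keys are info-level:
extra metadata is legitimate.

Decisions taken where the standard's text leaves room:

- **Required fields apply to all four suffixes**, reference acquisitions
  included — a reference scan without a bandwidth or echo time is as
  unusable as a metabolite scan without them. Flagged in the rule docs.
- **`nuc` ↔ `ResonantNucleus` equality** uses case-insensitive alphanumeric
  normalization; an array value (dual-tuned acquisitions, e.g. `nuc-1H13C`)
  is compared as the in-order concatenation of its elements. Mismatch is an
  error.
- **Physical domains**: `SpectrometerFrequency > 0`, `SpectralWidth > 0`,
  `EchoTime ≥ 0`, `MixingTime ≥ 0`, counts ≥ 1, integers where stated.
  Units (MHz, Hz, s, mm, ppm) are fixed by the standard; no conversion is
  attempted, units only scope the domain checks and messages.
- **`BodyPartDetailsOntology`** is checked for URI shape only (scheme plus
  non-empty remainder); resolving ontology terms is out of scope.
- **Edit-related fields** (`EditTarget`, `EditPulse`, `EditCondition`,
  `EchoAcquisition`) have no documented structure; they are accepted as
  strings or arrays of strings.
- **`MixingTime`** is recommended-level and its absence warns on every
  suffix even though it is only physically meaningful for stimulated-echo
  sequences; the sequence type is not reliably inferable from metadata, so
  the mechanical reading was kept.
- The missing-recommended warnings for `MatrixSize`, `VolumeAffineMatrix`
  and `EncodingTechnique` are emitted by the MRSI conditional rule
  (`MRS046`) rather than the generic rule, so MRSI sidecars are not
  double-reported.

Inheritance follows the BIDS principle restricted to what MRS files need:
fragments are searched at dataset root, subject and session level; a
fragment applies only if its suffix matches and its entities are a subset of
the data file's, and deeper fragments override shallower ones key-wise. The
rule catalog itself is exported as JSON (`emit_rule_catalog`) so reports can
be traced to the requirement each rule enforces.

## Container conventions

Files are written as NIfTI-2 with a complex64 data block (complex128 on
request) padded with trailing singletons to exactly seven dimensions — axes
are x, y, z, time, then three free encoding dimensions. The dwell time is
stored in the fourth `pixdim` slot, the version tag in `intent_name`, and
the embedded metadata as a JSON header extension under the MRS-designated
extension code (a named constant, `NIFTI_MRS_ECODE = 44`). The full
dimension-tag vocabulary of the NIfTI-MRS standard (per-axis role tags) is
out of scope here; only the geometric conventions needed for validation are
implemented.

Consistency checks and their tolerances:

- `|SpectralWidth − 1/Δt| / SpectralWidth > 1e-3` is an error; the
  tolerance absorbs rounding in vendor exports while catching unit
  mistakes (Hz vs kHz) by orders of magnitude.
- sidecar vs embedded-extension disagreement (frequency, nucleus) warns —
  neither source is authoritative, so mismatches are reported, never
  auto-resolved;
- `NumberOfSpectralPoints` vs time extent warns;
- spatial extents > 1 on `svs` is an error; all-singleton spatial extents
  on `mrsi` warns.

Reading a NIfTI without the MRS extension is not an error: the header comes
back with empty metadata and a flag, which lets the validator distinguish
"foreign NIfTI" (warning) from "corrupt extension" (error).

## Synthetic data

FIDs are sums of damped complex exponentials,
`s[n] = Σ_k A_k exp(2πi f_k nΔt) exp(−nΔt/T2_k) + σ(ε_re + iε_im)`,
with `Δt = 1/SpectralWidth` and standard-normal noise. Defaults emulate a
routine 3 T proton exam: 123.25 MHz, 2000 Hz bandwidth, 2048 points, three
resonances at the NAA/creatine/choline chemical shifts (2.01/3.03/3.20 ppm)
expressed as Hz offsets from a water-centred carrier at 4.65 ppm
(1 ppm = 123.25 Hz at this field), amplitudes 1.0/0.8/0.6, T2 of
90–110 ms, noise σ = 0.01. These are plausible configuration values, not
claims about any scanner. Reference acquisitions get a single large
resonance at the carrier (unsuppressed water). MRSI blocks broadcast one
FID across the spatial grid with independent per-voxel noise.

What the generator deliberately does **not** model: J-coupled multiplets,
realistic lineshapes (it is pure Lorentzian decay), eddy-current or phase
distortions, frequency drift, coil dimensions, or vendor header quirks.
Passing tests therefore demonstrate that the *structural* machinery —
naming, metadata, container geometry, cross-file wiring — behaves per the
standard on well-formed and deliberately broken trees; they say nothing
about robustness to the metadata chaos of real vendor exports.

Determinism: one seed fixes everything. Per-file seeds are derived by a
fixed affine map of the spec seed and a file counter; sidecars are written
with sorted keys and default float repr, so repeated runs are byte-identical
(dataset JSON/TSV content; gzip containers are value-identical on read-back).
Anatomical stand-ins are 4×4×4 zero-valued NIfTI files — placeholders for
path-resolution checks, labelled as synthetic fixtures, not images.

## Mutation registry

Nineteen named mutations each flip one rule on an otherwise valid tree:
filename faults (duplicate entity, order swap, bad charset, unknown suffix,
wrong directory), sidecar faults (missing sidecar, missing required field,
type/shape errors for the boolean, length-3 and 4×4 rules, conditional
violations, pulse list/timing mismatch), container faults (bandwidth vs
dwell-time inconsistency, multi-voxel SVS) and dataset faults (missing
scaffolding, dangling references). Filename mutations rename the data file
and its sidecar together, so the one-fault property holds over the *set* of
error rules in the report. The registry invariant — every mutation yields
exactly its targeted error rule and no other error — is verified across the
whole registry in the acceptance suite.

## Problem sizes and numerical choices

The randomized generator/validator sweep uses 50 dataset specs with 1–3
subjects, 0–2 sessions, one to four acquisition kinds and 64–256 point
FIDs: validation exercises structure and metadata, so short signals carry
the same evidential weight as long ones, and the default 2048-point
configuration is still covered by the fixed fixtures. Round-trip checks use
200 random entity sets and 500 random complex arrays over all ndim ∈ 1..7.
Issue ordering is lexicographic in (file, rule id, location, message);
reports are path-relative, so a copied tree produces a byte-identical JSON
report.

## Known limitations

- Only MRS rules are enforced; other modalities in the same tree are
  ignored beyond existence checks for referenced anatomical images.
- No events-file rule for `task-` functional MRS acquisitions (the
  standard's text does not define one); documented gap.
- The inheritance implementation covers root/subject/session JSON
  fragments with suffix and entity-subset matching — sufficient for MRS
  sidecars, not a general BIDS inheritance engine.
- Unreconstructed MRSI (k-space) data are out of scope by design;
  `sourcedata/` and `derivatives/` trees are skipped entirely.
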