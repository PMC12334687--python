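# mrsbids

A toolkit for organizing and validating *in vivo* magnetic resonance
spectroscopy (MRS) data under the MRS extension of the Brain Imaging Data
Structure (BIDS). It is aimed at spectroscopists who want to share or reuse
SVS/MRSI datasets and at pipeline developers who need machine-checkable
guarantees about a dataset before processing it.

The package implements five connected pieces:

1. **Filename grammar** — MRS filenames are
   `<entities>_<suffix>.<extension>`, where entities are `key-value` pairs
   (`sub-01`, `ses-02`, `task-nback`, `acq-slaser`, `nuc-1H`, `voi-dlpfc`,
   `rec-`, `run-`, `echo-`, `inv-`) in a fixed canonical order, the suffix is
   one of `svs` (single-voxel), `mrsi` (spectroscopic imaging), `unloc`
   (unlocalized) or `mrsref` (reference acquisition), and the extension is
   `.nii`/`.nii.gz` (data) or `.json` (sidecar). Parsing is strict; every
   violation maps to a typed error. Data files live under
   `sub-<label>/[ses-<label>/]mrs/`.
2. **Sidecar field catalog** — a machine-readable description of every
   MRS-specific metadata field: the four required ones (`ResonantNucleus`,
   `SpectrometerFrequency` in MHz, `SpectralWidth` in Hz, `EchoTime` in s),
   the recommended set (`WaterSuppression`, `AcquisitionVoxelSize` as a
   length-3 array in mm, `MatrixSize` length-3, `VolumeAffineMatrix` 4×4,
   `ReferenceSignal`, `AnatomicalImage`, ...), and the optional fields, with
   their types, shapes, units, suffix applicability and conditional
   triggers (`nuc-` ⇒ matching `ResonantNucleus`; `voi-` ⇒ `BodyPart` +
   `BodyPartDetails`; `PulseSequencePulses` ⇔ `PulseSequenceTiming` length
   equality).
3. **NIfTI-MRS IO** — minimal read/write of the NIfTI-MRS container: a
   NIfTI-2 file holding a complex 7-D data block (x, y, z, time, three free
   encoding dimensions), the dwell time `Δt = 1/SpectralWidth` in the
   header, and spectroscopy metadata embedded as a JSON header extension.
4. **Dataset validator** — walks a tree, applies ~30 catalogued rules
   (filename, placement, sidecar schema, conditionals, container geometry,
   header/sidecar consistency, cross-file reference resolution) and emits a
   deterministic report with stable rule ids.
5. **Fixture generator** — fully synthetic, valid-by-construction datasets
   (FIDs are sums of damped complex exponentials
   `s[n] = Σ_k A_k e^{2πi f_k nΔt} e^{−nΔt/T2_k} + noise`), plus a registry
   of 19 targeted single-rule mutations used to verify that the validator
   diagnoses each fault exactly.

## Worked example

```sh
$ mrsbids example --out /tmp/ds --subjects 2 --seed 7
wrote 4 data file(s) and 4 sidecar(s) for 2 subject(s) under /tmp/ds
$ mrsbids validate /tmp/ds
Dataset: /tmp/ds
Summary: 0 error(s), 0 warning(s), 0 info — pass
$ mrsbids mutate --rule missing-echotime /tmp/ds
applied missing-echotime: remove the required EchoTime field (violates MRS030)
$ mrsbids validate /tmp/ds
Dataset: /tmp/ds
sub-01/ses-01/mrs/sub-01_ses-01_acq-press_nuc-1H_voi-acc_svs.json:
  [ERROR  ] MRS030 (EchoTime): required field 'EchoTime' is missing
Summary: 1 error(s), 0 warning(s), 0 info — FAIL
```

The four files are one single-voxel acquisition (`svs`) and one water
reference (`mrsref`) per subject; the report's `MRS030` line pinpoints the
one sidecar whose required echo-time field was deleted. Exit codes are 0
(pass), 1 (errors found), 2 (usage/IO failure), so `validate` drops into CI
directly. The same functionality is available from Python — see
`examples/01_filenames.py` through `examples/04_dataset_validation.py` for
short narrative scripts covering each capability.

```python
>>> from mrsbids import parse_filename, expected_relative_path
>>> p = parse_filename("sub-06_ses-02_task-nback_acq-slaser_nuc-1H_voi-dlpfc_svs.nii.gz")
>>> p.suffix, p.get("voi")
('svs', 'dlpfc')
>>> expected_relative_path(p)
'sub-06/ses-02/mrs/'
```

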