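"""Parse and construct MRS-BIDS filenames.

An MRS filename is a chain of key-value entities, a data-type suffix and an
extension; this script decomposes a full example, rebuilds a name from an
unordered mapping, and prints where in the dataset tree the file belongs.
"""

from mrsbids import build_filename, expected_relative_path, parse_filename
from mrsbids.entities import FilenameError

name = "sub-06_ses-02_task-nback_acq-slaser_nuc-1H_voi-dlpfc_svs.nii.gz"
parsed = parse_filename(name)
print(f"filename : {name}")
print(f"entities : {parsed.entity_dict()}")
print(f"suffix   : {parsed.suffix}   (single-voxel spectroscopy)")
print(f"location : {expected_relative_path(parsed)}")
# -> the file must live under sub-06/ses-02/mrs/ in the dataset tree

# construction sorts entities into canonical order, whatever order you give
built = build_filename({"acq": "ecc", "sub": "01"}, "mrsref", ".nii.gz")
print(f"built    : {built}")   # sub-01_acq-ecc_mrsref.nii.gz

# parsing is strict: a duplicated entity raises instead of being repaired
try:
    parse_filename("sub-01_sub-01_svs.nii.gz")
except FilenameError as exc:
    print(f"rejected : {exc}")
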