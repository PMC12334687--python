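"""Generate a synthetic dataset, validate it, break it, validate again.

The fixture generator writes a complete MRS-BIDS tree (scaffolding files,
NIfTI-MRS data, sidecars) that validates cleanly; a targeted mutation then
injects exactly one rule violation, and the validator pinpoints it.
"""

import tempfile
from pathlib import Path

from mrsbids import (
    apply_mutation,
    generate_dataset,
    render_report,
    validate_dataset,
)
from mrsbids.fixtures import default_fixture_spec

with tempfile.TemporaryDirectory() as td:
    root = Path(td) / "dataset"
    inventory = generate_dataset(default_fixture_spec(seed=7), root)
    print(f"generated {len(inventory.data_files)} data files for "
          f"{len(inventory.subjects)} subjects")

    report = validate_dataset(root)
    print(f"valid tree -> passed={report.passed}, counts={report.counts}")

    mutation = apply_mutation(root, "missing-echotime")
    print(f"applied mutation: {mutation.description}")

    report = validate_dataset(root)
    print(render_report(report, "text"))
    # the report contains exactly one error, MRS030, on the mutated sidecar:
    # the required EchoTime field is gone.
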