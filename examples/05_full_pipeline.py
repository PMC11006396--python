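"""One reproducible end-to-end run.

Simulates a dataset in which two thirds of records are reported as
linearly standardized rates, harmonizes them back to measured rates, fits
the scaling model with interaction reduction, audits the misestimation of
the standardized reports, and writes a manifest with SHA-256 hashes of
every artifact.
"""

import tempfile
from pathlib import Path

from spermscaling.pipeline import RunConfig, run_pipeline

out_dir = Path(tempfile.mkdtemp()) / "run"
result = run_pipeline(RunConfig(out_dir=out_dir, seed=1))

print((out_dir / "report.txt").read_text())
print("artifacts:")
for name, digest in result.manifest["outputs"].items():
    print(f"  {name}: sha256 {digest[:16]}…")
print()
print("Re-running with the same seed reproduces identical hashes.")
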