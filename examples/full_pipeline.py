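"""Run the whole pipeline end to end and print the acceptance report.

Simulates every input modality, processes ECoG to BSR, summarises deficit
scores, counts the cell field, runs the statistics, and writes a manifest
with checksums; then recomputes the package's pinned checks.
"""

import json
import tempfile
from pathlib import Path

from ca_recovery.pipeline import RunConfig, render_report, reproduce_acceptance, run_pipeline

outdir = Path(tempfile.mkdtemp(prefix="ca_recovery_"))
manifest = run_pipeline(RunConfig(outdir=str(outdir), seed=42))

print("stage status:")
for stage, entry in manifest["stages"].items():
    print(f"  {stage:10s} {entry['status']}  outputs: {sorted(entry['outputs'])}")

stats = json.loads((outdir / "stats.json").read_text())
print(f"\nlog-rank chi2 on the simulated cohort: {stats['logrank']['statistic']:.3f}")

print()
print(render_report(reproduce_acceptance(seed=42)))

# The manifest records per-stage seeds and SHA-256 checksums, so a rerun
# with the same config reproduces byte-identical outputs; the report
# re-derives the pinned study quantities (log-rank 4.510, rubric maxima,
# 17,880 um span) plus compact recovery properties.
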