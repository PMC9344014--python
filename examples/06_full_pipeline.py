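"""Run the whole pipeline from a simulate-mode configuration.

Executes every stage (simulate, parse, associations, enrichment, MMI,
clustering, commonality, disease overlays, virus, rewiring) and prints
the manifest's per-stage output files; rerunning with the same seed
reproduces identical checksums.
"""

import tempfile

from mminet import PipelineConfig, UniverseConfig, run_pipeline

outdir = tempfile.mkdtemp(prefix="mminet_run_")
config = PipelineConfig(outdir=outdir, simulate=UniverseConfig(seed=1))
manifest = run_pipeline(config)

print(f"outputs written under {outdir}")
for stage, files in manifest["stages"].items():
    print(f"  {stage:13s} {len(files):2d} file(s): {', '.join(sorted(files))}")
print(
    "-> the manifest records a SHA-256 checksum per file; a rerun at the same "
    "seed reproduces every checksum."
)
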