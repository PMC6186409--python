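"""The whole pipeline end to end on synthetic data.

Runs simulate -> dge -> enrich -> overlap -> network -> mcode with one seed
and prints the manifest counts.  The same run is available from the shell as
`phenonet run-all --seed 42 --outdir <dir>`.
"""

import json

from phenonet import PipelineConfig, run_pipeline

config = PipelineConfig(seed=42, outdir="scratch/example_run")
run_dir = run_pipeline(config)

manifest = json.loads((run_dir / "manifest.json").read_text())
print(f"run directory: {run_dir}")
for key, value in sorted(manifest["counts"].items()):
    print(f"  {key}: {value}")
print(f"  topology: {manifest['topology']}")
# n_up/n_down are consensus DEG counts; the planted pathway sets drive
# n_enriched_up; the network counts track assembly, hub curation and the
# component census; n_clusters are MCODE complex predictions.
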