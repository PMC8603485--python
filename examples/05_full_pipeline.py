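"""Run the whole pipeline (design -> OC -> generate -> endpoints -> fit ->
report) with fixed seeds and show the run manifest.

Equivalent to `gspilot run-all`.  Every output file is checksummed into the
manifest, so rerunning with the same configuration is verifiably identical.
"""

import json
import tempfile

from gspilot import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(out_dir=tmp, oc_n_sims=2000)
    manifest = run_pipeline(cfg)
    print(open(f"{tmp}/report.txt").read())
    print("manifest stages:",
          json.dumps(manifest["stages"], indent=2))
    print("output checksums:")
    for name, info in manifest["outputs"].items():
        print(f"  {name:<18} {info['sha256'][:16]}...")
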