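"""One-config end-to-end run: simulate -> detect -> estimate -> carbon.

Executes the whole pipeline on a 64x64 synthetic scene and prints the
manifest stage summaries; all products (rasters, CSVs, config copy,
manifest) land in the output directory.
"""

import json

import marshchange as mc

config = mc.RunConfig(out_dir="scratch/demo_run", height=64, width=64,
                      n_draws=10_000, seed=123)
manifest = mc.run_pipeline(config)
print(json.dumps(manifest["stages"], indent=2))
print(f"config hash {manifest['config_hash']}; "
      f"{len(manifest['outputs'])} products written to {config.out_dir}")
# Re-running with the same config + seed reproduces every output
# byte-for-byte; the manifest makes each number traceable.
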