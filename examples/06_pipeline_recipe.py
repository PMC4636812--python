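"""Run the end-to-end synthetic recipe from a config and inspect the manifest.

The recipe simulates a dataset, runs every analysis stage and writes TSVs
plus a manifest whose hash is reproducible for a given seed.
"""

import json

import pandas as pd

from chipmeta import PipelineConfig, run_recipe

config = PipelineConfig(
    recipe="end-to-end-synthetic",
    outdir="e2e_out",
    params={"simulation": {"n_genes": 150, "n_enhancers": 60, "n_super_enhancers": 5,
                           "chrom_sizes": {"chr1": 2_000_000},
                           "se_length": (5_000, 12_000)}},
    seed=4,
)
manifest = run_recipe(config)
print("outputs:", ", ".join(manifest["outputs"]))
print("manifest hash:", manifest["hash"][:16], "(identical on every rerun)")

summary = pd.read_csv("e2e_out/summary.tsv", sep="\t")
print(summary.to_string(index=False))
se = pd.read_csv("e2e_out/se_profile.tsv", sep="\t")
print(f"mean super-enhancer body ratio: {se['enrichment'].mean():.2f} "
      "(~1 here: this factor has no planted enrichment inside the regions)")
with open("e2e_out/manifest.json") as fh:
    print("decisions recorded in manifest:", sorted(json.load(fh)["params_used"]))
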