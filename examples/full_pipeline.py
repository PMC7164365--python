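"""End-to-end run: simulate a study-shaped dataset, execute every stage.

Builds a tree, coded traits, occurrences and abundance counts with the
synthetic-data generators, writes them as the TSV/newick inputs the
pipeline reads, and runs diversity extrapolation, trait coding,
birth-death fits, signal/PD and the mapping+OU stage under one seed.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

import terebra as tb
from terebra.pipeline import RunConfig, run_all

tmp = Path(tempfile.mkdtemp(prefix="terebra_demo_"))

tree = tb.simulate_yule_tree(0.12, 60, seed=10)
(tmp / "tree.nwk").write_text(tb.write_newick(tree))

states, hist = tb.simulate_mk(tree, 0.05, 0.05, 0, seed=1)
size = tb.simulate_ou(hist, {0: 0.3, 1: 0.67}, {0: 83.0, 1: 15.0},
                      {0: 70.0, 1: 21.0}, seed=2)[0].abs()
pd.DataFrame({"species": tree.tip_labels,
              "vg_state": [states[l] for l in tree.tip_labels],
              "larval_state": [states[l] for l in tree.tip_labels],
              "size_mm": [size[l] for l in tree.tip_labels]}
             ).to_csv(tmp / "traits.tsv", sep="\t", index=False)

counts = tb.simulate_abundance_sample(80, 3000, seed=3)
pd.DataFrame({"species": counts.index, "count": counts.values}
             ).to_csv(tmp / "counts.tsv", sep="\t", index=False)

config = RunConfig({
    "seed": 7,
    "tree": str(tmp / "tree.nwk"),
    "traits_table": str(tmp / "traits.tsv"),
    "stages": {"diversity": True, "bdfit": True, "signal": True,
               "pd": True, "ou": True},
    "diversity": {"abundance_counts": str(tmp / "counts.tsv"),
                  "worms_described": 407, "newly_delimited": 69},
    "bdfit": {"f": 0.26, "n_starts": 2, "grid_step": 2.0},
    "signal": {"continuous": ["size_mm"], "binary": ["vg_state"],
               "n_null": 500},
    "pd": {"binary": ["vg_state"], "metrics": ["MPD", "MNTD"],
           "n_rand": 499},
    "ou": {"discrete": "larval_state", "continuous": "size_mm",
           "n_maps": 5, "n_starts": 1},
})

report = run_all(config, output_dir=tmp / "run")
print(f"artifacts under {report['output_dir']}")
print("stages completed:", sorted(report["stages"]))
if report["errors"]:
    print("skipped/failed:", report["errors"])
div = json.loads((tmp / "run" / "diversity.json").read_text())
print(f"estimated total richness: {div['total']:.0f} "
      f"(ratio {div['ratio']:.2f})")
bd = json.loads((tmp / "run" / "bdfit.json").read_text())
print(f"best diversification model: {bd['best']}")
ou = json.loads((tmp / "run" / "ou.json").read_text())
print(f"best trait-evolution model: {ou['summary']['best']}")
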