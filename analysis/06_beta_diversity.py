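"""Unweighted UniFrac distances between rarefied mat layers.

Produces the sample-by-sample distance matrix that downstream clustering or
ordination would consume, averaged over matched rarefactions to the
smallest layer. Prints the most- and least-similar layer pairs. Writes
results/unifrac.tsv.
"""

from pathlib import Path

import numpy as np

from matdiv.io import read_config, write_distance_matrix
from matdiv.pipeline import load_inputs
from matdiv.unifrac import unifrac_matrix

BASE = Path(__file__).resolve().parent.parent / "results" / "study"
ROOT = Path(__file__).resolve().parent.parent / "results"
if not (BASE / "config.txt").exists():
    raise SystemExit("run 01_simulate_study.py first")

cfg = read_config(BASE / "config.txt")
table, tree, _, _ = load_inputs(cfg, BASE)

bdm = unifrac_matrix(table, tree, n_reps=cfg.n_rarefactions, seed=cfg.seed)
write_distance_matrix(bdm, ROOT / "unifrac.tsv", {"seed": cfg.seed, "depth": bdm.depth})
print(f"wrote {ROOT / 'unifrac.tsv'} (depth {bdm.depth}, {bdm.n_reps} rarefactions)")

v = bdm.values.copy()
np.fill_diagonal(v, np.nan)
i, j = np.unravel_index(np.nanargmin(v), v.shape)
k, l = np.unravel_index(np.nanargmax(v), v.shape)
print(f"most similar layers: {bdm.labels[i]} vs {bdm.labels[j]} (d={v[i, j]:.3f})")
print(f"least similar layers: {bdm.labels[k]} vs {bdm.labels[l]} (d={v[k, l]:.3f})")
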