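"""Shared fixtures: small hand-built trees and a miniature simulated study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from matdiv.synthetic import (
    assemble_community,
    evolve_trait,
    sample_counts,
    simulate_tree,
)
from matdiv.tables import CommunityTable
from matdiv.tree import read_newick


@pytest.fixture
def caterpillar():
    """((A:1,B:1)90:1,C:2); — the worked 3-tip example."""
    return read_newick("((A:1,B:1)90:1,C:2);")


@pytest.fixture
def balanced4():
    """((A:1,B:1):1,(C:1,D:1):1); — the UniFrac worked example."""
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def tree200():
    """One 200-tip pure-birth tree reused by dispersion tests."""
    return simulate_tree(200, 1.0, 0.0, seed=42)


@pytest.fixture(scope="session")
def traits200(tree200):
    return evolve_trait(tree200, 1.0, seed=43)


def make_study(tree, traits, regime, strength, n_samples, seed, richness=30, depth=2000):
    """Build a CommunityTable of communities assembled under one regime."""
    ss = np.random.SeedSequence(seed)
    cols = {}
    for s in range(n_samples):
        sd = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
        taxa = assemble_community(tree, traits, regime, strength, richness, sd[0])
        counts = sample_counts(taxa, 1.0, depth, sd[1])
        col = pd.Series(0, index=list(tree.tip_labels), dtype=np.int64)
        col[counts.index] = counts
        cols[f"S{s + 1:02d}"] = col
    meta = pd.DataFrame(
        {
            "core": "C1",
            "year": 2010,
            "layer": [f"L{i}" for i in range(n_samples)],
            "depth_top_mm": np.arange(n_samples, dtype=float),
            "depth_bottom_mm": np.arange(1, n_samples + 1, dtype=float),
        },
        index=list(cols),
    )
    return CommunityTable(pd.DataFrame(cols), meta)
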