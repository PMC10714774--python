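import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import oralmicro as om


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic cohort reused by read-only tests."""
    cfg = om.CohortConfig(n_patients=12, n_taxa=60, seed=7)
    return om.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dm(small_bundle):
    return om.unifrac_distance_matrix(small_bundle.counts, small_bundle.tree)


def make_meta(rows):
    """rows: (sample_id, patient, site, timepoint, day) tuples."""
    return pd.DataFrame(
        rows, columns=["sample_id", "patient", "site", "timepoint", "day"]
    )


def tree_from_newick(nwk: str) -> TreeNode:
    from io import StringIO

    return TreeNode.read(StringIO(nwk), format="newick")


def brute_force_unifrac(p, q, tree, taxa, normalized):
    """Branch-by-branch enumeration oracle, independent of the vectorized
    incidence-matrix kernel: walks every branch, collects its descendant
    tip set explicitly, and sums l_b * |P_b - Q_b|."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    idx = {t: i for i, t in enumerate(taxa)}
    raw = 0.0
    for node in tree.traverse(include_self=False):
        tips = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        cols = [idx[t] for t in tips if t in idx]
        raw += node.length * abs(p[cols].sum() - q[cols].sum())
    if not normalized:
        return raw
    div = 0.0
    for tip in tree.tips():
        if tip.name not in idx:
            continue
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length
            node = node.parent
        div += depth * (p[idx[tip.name]] + q[idx[tip.name]])
    return raw / div if div > 0 else 0.0
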