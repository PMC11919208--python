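"""Edge-set annotation: canonical-network distribution and cognitive terms.

The seed-region set of an edge list (the union of edge endpoints) is mapped
onto canonical networks by voxel overlap (relative distribution, %RD) and
annotated with cognitive terms by a coactivation ratio tested against
size-matched random region sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NetworkOverlapTable, TermActivationTable

Edge = tuple[int, int]


def seed_regions(edges: list[Edge]) -> list[int]:
    """Union of edge endpoints, de-duplicated, ascending."""
    if not edges:
        raise ValueError("empty edge list")
    return sorted({r for e in edges for r in e})


def relative_distribution(
    edges: list[Edge],
    overlap: NetworkOverlapTable,
    region_labels: list[str] | None = None,
) -> pd.Series:
    """%RD per network: overlapping voxels of the seed set in each network,
    as a percentage of the total seed-region size.

    ``region_labels`` maps edge endpoint indices to overlap-table regions;
    when omitted, endpoints index the overlap table directly.
    """
    seeds = seed_regions(edges)
    if region_labels is not None:
        rows = [overlap.row(region_labels[r]) for r in seeds]
    else:
        for r in seeds:
            if r >= len(overlap.region_labels):
                raise KeyError(f"region index {r} not in overlap table")
        rows = seeds
    total = overlap.region_size[rows].sum()
    rd = 100.0 * overlap.overlap[rows].sum(axis=0) / total
    return pd.Series(rd, index=overlap.network_names, name="rd_percent")


@dataclass
class TermAnnotation:
    table: pd.DataFrame  # term, ratio, p, significant
    n_perm: int
    seed_size: int


def term_annotation(
    edges: list[Edge],
    terms: TermActivationTable,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    region_labels: list[str] | None = None,
) -> TermAnnotation:
    """Permutation-tested term coactivation ratios for an edge set.

    Per term: ratio = mean activation over seed regions / mean over all
    regions. The null resamples region sets of the same size uniformly
    without replacement; p = (1 + #{null >= observed}) / (1 + n_perm), so p
    is never 0.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    seeds = seed_regions(edges)
    if region_labels is not None:
        index = {lab: k for k, lab in enumerate(terms.region_labels)}
        rows = [index[region_labels[r]] for r in seeds]
    else:
        rows = seeds
    m = len(terms.region_labels)
    if max(rows) >= m:
        raise KeyError("seed region outside the term table")

    act = terms.activation
    overall = act.mean(axis=1)
    observed = act[:, rows].mean(axis=1) / overall

    rng = np.random.default_rng(seed)
    size = len(rows)
    null_ge = np.zeros(len(terms.term_names), dtype=int)
    for _ in range(n_perm):
        perm = rng.choice(m, size=size, replace=False)
        null_ratio = act[:, perm].mean(axis=1) / overall
        null_ge += null_ratio >= observed
    p = (1 + null_ge) / (1 + n_perm)
    table = pd.DataFrame({
        "term": terms.term_names,
        "ratio": observed,
        "p": p,
        "significant": p < alpha,
    })
    return TermAnnotation(table=table, n_perm=n_perm, seed_size=size)
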