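"""Overrepresentation, network-interaction and list-overlap statistics.

All tests are enrichment-directional (one-sided): the overrepresentation and
overlap tests use the hypergeometric upper tail (Fisher exact), the network
test compares the observed within-query edge count against uniformly drawn
node sets of equal size.  The background universe is the set of proteins
that survived the detection filter, not the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = [
    "overrepresentation_test",
    "bh_fdr",
    "interaction_enrichment",
    "InteractionEnrichment",
    "overlap_test",
]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation_test(
    query: Iterable[str],
    annotation: GeneSetCollection,
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of ``query`` in each annotation set.

    Set members are first intersected with the background universe; the
    2x2 table per set is (in query & in set, in query & not, not in query &
    in set, neither), tested with the hypergeometric upper tail, then
    BH-adjusted across all tested sets.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background universe is empty")
    q = set(query)
    stray = q - bg
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:10]}")
    N, n_query = len(bg), len(q)
    rows = []
    for gs in annotation:
        members = set(gs.members) & bg
        if not members:
            continue
        inter = sorted(q & members)
        k, K = len(inter), len(members)
        p = float(hypergeom.sf(k - 1, N, K, n_query))
        rows.append(
            {
                "set_name": gs.name,
                "overlap": k,
                "set_size": K,
                "query_size": n_query,
                "background_size": N,
                "p": p,
                "intersection": ";".join(inter),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_fdr(df["p"])
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


@dataclass
class InteractionEnrichment:
    """Observed vs expected within-query edge counts and the permutation p."""

    observed_edges: int
    expected_edges: float
    p: float
    n_mapped: int
    unmapped: list[str]


def interaction_enrichment(
    query: Iterable[str],
    network: nx.Graph,
    n_random: int = 1000,
    seed: int = 0,
    degree_binned: bool = False,
    n_bins: int = 10,
) -> InteractionEnrichment:
    """Are there more interactions among the query proteins than chance allows?

    The null draws ``n_random`` node sets of the same mapped size — uniformly
    from all network nodes by default, or stratified by degree decile when
    ``degree_binned`` — and counts their induced edges.  The p-value uses the
    add-one permutation convention p = (1 + #null >= observed) / (1 + n_random),
    so it is bounded below by 1/(1 + n_random).
    """
    nodes = list(network.nodes)
    qset = set(query)
    mapped = sorted(qset & set(nodes))
    unmapped = sorted(qset - set(nodes))
    if len(mapped) < 2:
        raise ValueError(f"fewer than 2 query genes map to the network (mapped={mapped})")
    k = len(mapped)
    observed = network.subgraph(mapped).number_of_edges()
    rng = np.random.default_rng(seed)

    if degree_binned:
        degrees = np.array([network.degree(v) for v in nodes])
        edges_q = np.quantile(degrees, np.linspace(0, 1, n_bins + 1))
        bin_of = np.clip(np.searchsorted(edges_q, degrees, side="right") - 1, 0, n_bins - 1)
        by_bin = {b: [n for n, bb in zip(nodes, bin_of) if bb == b] for b in range(n_bins)}
        q_bins = [int(np.clip(np.searchsorted(edges_q, network.degree(v), side="right") - 1, 0, n_bins - 1)) for v in mapped]

        def draw():
            picked: list[str] = []
            for b in q_bins:
                pool = by_bin[b]
                picked.append(pool[rng.integers(len(pool))])
            return set(picked)
    else:

        def draw():
            idx = rng.choice(len(nodes), size=k, replace=False)
            return {nodes[i] for i in idx}

    null_counts = np.empty(n_random)
    for b in range(n_random):
        null_counts[b] = network.subgraph(draw()).number_of_edges()
    p = (1 + int((null_counts >= observed).sum())) / (1 + n_random)
    return InteractionEnrichment(
        observed_edges=observed,
        expected_edges=float(null_counts.mean()),
        p=float(p),
        n_mapped=k,
        unmapped=unmapped,
    )


def overlap_test(
    list_a: Iterable[str], list_b: Iterable[str], background_size: int
) -> tuple[int, float]:
    """One-sided Fisher test of the overlap between two gene lists.

    Under independence the overlap of lists of sizes a and b drawn from a
    universe of ``background_size`` genes is hypergeometric; the returned p
    is the upper tail P(X >= observed overlap).
    """
    a, b = set(list_a), set(list_b)
    union = a | b
    if background_size < len(union):
        raise ValueError(
            f"background ({background_size}) smaller than the union of the lists ({len(union)})"
        )
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, background_size, len(b), len(a)))
    return k, p
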