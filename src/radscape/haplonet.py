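"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are connected in a minimum-spanning network over mutational-step
(Hamming) distances; edges longer than the parsimony connection limit are
excluded, which may leave the network in several components (the classic
95 % rule).  All minimal alternative connections of equal length are
retained — loops are reported, not broken.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .errors import DegenerateInputError, EmptyInputError
from .io import HaplotypeTable


def _parsimony_probability(j: int, m: int) -> float:
    """Probability that j observed differences over m sites arose without
    any superimposed (multiple-hit) change.

    Per-site hit counts are Poisson with depth d chosen so the expected
    number of observable differences under a 4-state symmetric model
    equals j; the probability of full parsimony is then the product of
    P(single hit | site differs) over the j differing sites and
    P(no hit | site identical) over the m - j identical ones.
    """
    if j <= 0:
        return 1.0
    x = 1.0 - 4.0 * j / (3.0 * m)
    if x <= 0.0:
        return 0.0  # divergence beyond the model's resolvable range
    d = -0.75 * math.log(x)
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    one_hit_and_diff = d * math.exp(-d)  # a single hit always shows
    no_hit_and_same = math.exp(-d)
    log_p = j * (math.log(one_hit_and_diff) - math.log(p_diff)) + (m - j) * (
        math.log(no_hit_and_same) - math.log(1.0 - p_diff)
    )
    return math.exp(log_p)


def parsimony_connection_limit(sequence_length: int, alpha: float = 0.95) -> int:
    """Largest number of mutational steps whose probability of parsimony
    is still >= alpha (at least 1: single-step connections always join).
    """
    if sequence_length <= 0:
        raise DegenerateInputError("sequence length must be positive")
    if not 0.0 < alpha < 1.0:
        raise DegenerateInputError("alpha must lie in (0, 1)")
    j = 1
    while j < sequence_length:
        if _parsimony_probability(j + 1, sequence_length) < alpha:
            break
        j += 1
    return j


def hamming_steps(a: np.ndarray, b: np.ndarray) -> int:
    """Mutational steps between two code rows, pairwise deletion for N."""
    both = (a >= 0) & (b >= 0)
    return int(np.sum(a[both] != b[both]))


def build_parsimony_network(
    table: HaplotypeTable,
    max_steps: int | None = None,
    alpha: float = 0.95,
    force_connect: bool = False,
) -> nx.Graph:
    """Minimum-spanning network over haplotype step distances.

    Edges are considered in increasing step order; within one distance
    class an edge joins only components that were distinct before the
    class started (so all equal-length alternatives are kept).  Edges
    longer than `max_steps` (default: the parsimony limit for the
    alignment length at `alpha`) are excluded, unless `force_connect`
    later bridges the remaining components with their shortest links,
    flagged forced=True.

    Nodes carry count/region attributes; each edge records its step count
    and the number of inferred intermediate (unsampled) haplotypes
    (steps - 1).
    """
    if table.n_haplotypes == 0:
        raise EmptyInputError("empty haplotype table")
    if max_steps is None:
        max_steps = parsimony_connection_limit(table.length, alpha)

    k = table.n_haplotypes
    graph = nx.Graph(connection_limit=int(max_steps))
    totals = table.counts()
    for h in range(k):
        graph.add_node(
            h,
            count=int(totals[h]),
            regions={r: int(c[h]) for r, c in table.region_counts.items() if c[h]},
        )

    pairs = [
        (hamming_steps(table.haplotypes[i], table.haplotypes[j]), i, j)
        for i in range(k)
        for j in range(i + 1, k)
    ]
    pairs.sort()

    comp = {h: h for h in range(k)}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    idx = 0
    while idx < len(pairs):
        steps = pairs[idx][0]
        if steps > max_steps:
            break
        cls = []
        while idx < len(pairs) and pairs[idx][0] == steps:
            cls.append(pairs[idx])
            idx += 1
        # components as of the start of this distance class
        before = {h: find(h) for h in range(k)}
        added = []
        for steps_, i, j in cls:
            if steps_ == 0:
                continue
            if before[i] != before[j]:
                graph.add_edge(i, j, steps=steps_, intermediates=steps_ - 1, forced=False)
                added.append((i, j))
        for i, j in added:
            ri, rj = find(i), find(j)
            if ri != rj:
                comp[ri] = rj

    if force_connect:
        remaining = [p for p in pairs if p[0] > 0]
        for steps, i, j in remaining:
            if find(i) != find(j):
                graph.add_edge(i, j, steps=steps, intermediates=steps - 1, forced=True)
                comp[find(i)] = find(j)

    return graph


def network_tables(graph: nx.Graph):
    """Node and edge tables (pandas) for TSV export."""
    import pandas as pd

    nodes = pd.DataFrame(
        [
            {"haplotype": h, "count": d["count"],
             "regions": ";".join(f"{r}:{c}" for r, c in sorted(d["regions"].items()))}
            for h, d in graph.nodes(data=True)
        ]
    )
    edges = pd.DataFrame(
        [
            {"a": a, "b": b, "steps": d["steps"],
             "intermediates": d["intermediates"], "forced": d["forced"]}
            for a, b, d in graph.edges(data=True)
        ]
    )
    return nodes, edges
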