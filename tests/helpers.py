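"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithmic shortcuts: the NLR
oracle builds the full pairwise approaching matrix and takes connected
components; the rarefaction oracle enumerates orderings with Python sets;
the FST oracle spells out the Weir-Cockerham haploid components
population by population.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def nlr_arrangement_oracle(genes) -> dict[str, str]:
    """Brute-force singleton/pair/cluster categories per NLR gene id.

    Builds the explicit pairwise approaching matrix (fewer than two
    non-NLR genes in rank order between the two NLRs) and extracts
    connected components by BFS.
    """
    categories: dict[str, str] = {}
    by_key: dict[tuple[str, str], list] = {}
    for g in genes:
        by_key.setdefault((g.accession_id, g.chrom), []).append(g)
    for chrom_genes in by_key.values():
        ordered = sorted(chrom_genes, key=lambda g: (g.start, g.end, g.gene_id))
        nlr_idx = [i for i, g in enumerate(ordered) if g.is_nlr]
        n = len(nlr_idx)
        approaching = [[False] * n for _ in range(n)]
        for a, b in itertools.combinations(range(n), 2):
            lo, hi = nlr_idx[a], nlr_idx[b]
            between = ordered[lo + 1 : hi]
            non_nlr_between = sum(1 for g in between if not g.is_nlr)
            if non_nlr_between < 2:
                approaching[a][b] = approaching[b][a] = True
        seen = [False] * n
        for start in range(n):
            if seen[start]:
                continue
            comp, queue = [], deque([start])
            seen[start] = True
            while queue:
                cur = queue.popleft()
                comp.append(cur)
                for other in range(n):
                    if approaching[cur][other] and not seen[other]:
                        seen[other] = True
                        queue.append(other)
            category = {1: "singleton", 2: "pair"}.get(len(comp), "cluster")
            for member in comp:
                categories[ordered[nlr_idx[member]].gene_id] = category
    return categories


def rarefaction_oracle(presence_sets: list[set[str]]) -> tuple[list[float], list[float], list[float], list[float]]:
    """Exact per-step pan/core means and sds over all orderings, using
    plain set unions/intersections.

    ``presence_sets`` holds each accession's orthogroup set.  Returns
    (pan_means, pan_sds, core_means, core_sds) indexed by step - 1.
    """
    n = len(presence_sets)
    pan_counts = [[] for _ in range(n)]
    core_counts = [[] for _ in range(n)]
    for order in itertools.permutations(range(n)):
        union: set[str] = set()
        inter: set[str] | None = None
        for step, idx in enumerate(order):
            union = union | presence_sets[idx]
            inter = presence_sets[idx] if inter is None else inter & presence_sets[idx]
            pan_counts[step].append(len(union))
            core_counts[step].append(len(inter))

    def stats(rows):
        means = [sum(r) / len(r) for r in rows]
        sds = [math.sqrt(sum((x - m) ** 2 for x in r) / len(r)) for r, m in zip(rows, means)]
        return means, sds

    pan_means, pan_sds = stats(pan_counts)
    core_means, core_sds = stats(core_counts)
    return pan_means, pan_sds, core_means, core_sds


def wc_fst_oracle(calls_pop1, calls_pop2) -> float:
    """Weir-Cockerham haploid FST for one site, written out longhand."""
    n1, n2 = len(calls_pop1), len(calls_pop2)
    p1 = sum(calls_pop1) / n1
    p2 = sum(calls_pop2) / n2
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
    a = (n_bar / n_c) * (s2 - inner / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * inner
    return a / (a + b)


def pairwise_divergence_oracle(presence: np.ndarray, i: int, j: int) -> tuple[int, float]:
    """Symmetric difference count and union-normalized ratio via sets."""
    set_i = {g for g in range(presence.shape[0]) if presence[g, i]}
    set_j = {g for g in range(presence.shape[0]) if presence[g, j]}
    diff = len(set_i ^ set_j)
    union = len(set_i | set_j)
    return diff, diff / union
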