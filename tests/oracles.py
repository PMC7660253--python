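"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration or naive algorithms,
never by calling the implementation under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd


def brute_force_network_edges(S: pd.DataFrame) -> set[tuple[str, str]]:
    """Edge set of the least-epistasis network by exhaustive scan.

    For each source chromosome, scan every other chromosome and keep the
    one with the smallest |S|, breaking ties by smallest target id.
    """
    edges = set()
    for src in S.index:
        best = None
        for tgt in sorted(S.columns):
            if tgt == src or pd.isna(S.loc[src, tgt]):
                continue
            key = (abs(S.loc[src, tgt]), tgt)
            if best is None or key < best[0]:
                best = (key, tgt)
        if best is not None:
            edges.add((src, best[1]))
    return edges


def exact_mean_distribution(values, set_size) -> dict[float, Fraction]:
    """Exact distribution of the mean of a without-replacement draw.

    Enumerates every combination of ``set_size`` elements; probabilities
    are exact fractions.
    """
    values = list(values)
    combos = list(itertools.combinations(range(len(values)), set_size))
    dist: dict[float, Fraction] = {}
    for combo in combos:
        mean = sum(values[i] for i in combo) / set_size
        dist[mean] = dist.get(mean, Fraction(0)) + Fraction(1, len(combos))
    return dist


def naive_average_linkage_leaves(dist: np.ndarray) -> list[int]:
    """Leaf order of average-linkage agglomeration, re-implemented naively.

    Mirrors the standard convention: repeatedly merge the closest pair of
    clusters (ties toward smaller cluster ids), record merges with the two
    member ids sorted ascending, and read leaves by depth-first traversal
    visiting the smaller-id child first.
    """
    n = dist.shape[0]
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    children: dict[int, tuple[int, int]] = {}
    next_id = n
    while len(active) > 1:
        best = min(d, key=lambda k: (d[k], k))
        i, j = best
        children[next_id] = (i, j)
        merged = active[i] + active[j]
        ni, nj = len(active[i]), len(active[j])
        del active[i], active[j]
        new_d = {}
        for k in active:
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            new_d[(k, next_id)] = (ni * d[a] + nj * d[b]) / (ni + nj)
        d = {
            k: v for k, v in d.items() if i not in k and j not in k
        }
        d.update({(min(a, b), max(a, b)): v for (a, b), v in new_d.items()})
        active[next_id] = merged
        next_id += 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return leaves(left) + leaves(right)

    return leaves(next_id - 1)
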