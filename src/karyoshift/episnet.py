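"""Signed chromosome-pair epistasis sums and the least-epistasis network.

For every unordered pair of chromosomes, the signed genetic-interaction
scores of all retained gene pairs spanning the two chromosomes are summed;
positive interactions compensate negative ones, so S(i, j) measures the
net epistatic coupling of the pair. Intra-chromosomal pairs are excluded.

The directed "least-epistasis" network draws, from every chromosome, one
arrow to the partner whose pairwise sum is nearest to zero — the
chromosome whose copy-number change would have the most neutral epistatic
effect. High in-degree nodes (hubs) are the recurrently most-neutral
partners; mutual edges (i->j and j->i) mark pairs that are each other's
most neutral partner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_model import GenomeMap, InteractionTable

logger = logging.getLogger(__name__)


@dataclass
class LeastEpistasisNetwork:
    """Directed network with exactly one out-edge per eligible chromosome.

    ``edges`` has columns (source, target, S, abs_S); ``in_degree`` covers
    every chromosome of the sum matrix; ``mutual_pairs`` lists unordered
    pairs connected in both directions.
    """

    edges: pd.DataFrame
    in_degree: pd.Series
    mutual_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.in_degree.index)
        for rec in self.edges.itertuples(index=False):
            g.add_edge(rec.source, rec.target, S=rec.S, abs_S=rec.abs_S)
        return g


def pairwise_interaction_sums(
    table: InteractionTable, genome_map: GenomeMap
) -> pd.DataFrame:
    """Symmetric chromosome x chromosome matrix of summed signed scores.

    S(i, j) sums the scores of retained pairs with one gene on i and the
    other on j; the diagonal is NaN (intra-chromosomal pairs are excluded
    from the network statistic). Pairs with a gene that cannot be resolved
    to a chromosome are skipped and their count logged. Chromosome pairs
    with no interactions keep an exact 0.
    """
    if table.kind != "genetic":
        raise ValueError("epistasis sums require a genetic interaction table")
    chroms = genome_map.chrom_ids
    S = pd.DataFrame(0.0, index=pd.Index(chroms, name="chrom"), columns=chroms)
    gene_chrom = genome_map.gene_chrom
    df = table.rows
    if len(df):
        ca = df["gene_a"].map(gene_chrom)
        cb = df["gene_b"].map(gene_chrom)
        unresolved = ca.isna() | cb.isna()
        if unresolved.any():
            logger.info(
                "skipped %d pair(s) with unresolvable gene(s)",
                int(unresolved.sum()),
            )
        keep = ~unresolved & (ca != cb)
        for i, j, score in zip(ca[keep], cb[keep], df.loc[keep, "score"]):
            S.loc[i, j] += score
            S.loc[j, i] += score
    np.fill_diagonal(S.values, np.nan)
    return S


def least_epistasis_network(S: pd.DataFrame) -> LeastEpistasisNetwork:
    """One arrow per chromosome to the partner with |S| nearest to zero.

    Ties at equal |S| break toward the lexicographically smallest target
    id, so the network is deterministic. Requires >= 2 chromosomes.
    """
    chroms = list(S.index)
    if len(chroms) < 2:
        raise ValueError("network needs >= 2 chromosomes")
    rows = []
    for src in chroms:
        partners = S.loc[src].drop(labels=[src]).dropna()
        if partners.empty:
            continue
        abs_s = partners.abs()
        best = min(sorted(partners.index), key=lambda c: (abs_s[c], c))
        rows.append((src, best, float(partners[best]), float(abs_s[best])))
    edges = pd.DataFrame(rows, columns=["source", "target", "S", "abs_S"])
    in_degree = (
        edges["target"].value_counts().reindex(chroms, fill_value=0).astype(int)
    )
    in_degree.index.name = "chrom"
    edge_set = set(zip(edges["source"], edges["target"]))
    mutual = sorted(
        {tuple(sorted((a, b))) for a, b in edge_set if (b, a) in edge_set and a != b}
    )
    return LeastEpistasisNetwork(
        edges=edges, in_degree=in_degree, mutual_pairs=mutual
    )


def network_hubs(net: LeastEpistasisNetwork, k: int = 2) -> list[str]:
    """Top-k chromosomes by in-degree (ties broken by chromosome id)."""
    order = sorted(net.in_degree.index, key=lambda c: (-net.in_degree[c], c))
    return order[:k]


def write_network(
    net: LeastEpistasisNetwork, path: str | Path, format: str = "tsv"
) -> None:
    """Write the network as a TSV edge list or a DOT digraph."""
    path = Path(path)
    if format == "tsv":
        net.edges.to_csv(path, sep="\t", index=False)
    elif format == "dot":
        lines = ["digraph least_epistasis {"]
        for node in net.in_degree.index:
            lines.append(f'    "{node}";')
        for rec in net.edges.itertuples(index=False):
            lines.append(f'    "{rec.source}" -> "{rec.target}" [label="{rec.S:.4g}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_network_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a TSV edge list written by :func:`write_network`."""
    return pd.read_csv(path, sep="\t")
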