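"""Functional coherence of gene modules against an association network.

A module is functionally coherent when its genes are connected by more
known functional associations (protein-protein links, database pathways)
than random gene sets of the same size drawn from the expression universe.
The test statistic is the proportion of associated pairs among all
C(n, 2) within-module pairs; significance comes from an empirical
permutation p-value over random size-matched sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import DomainError, empirical_p


@dataclass
class AssociationNetwork:
    """Undirected, scored gene-gene association network.

    Stored as a dense boolean adjacency over an indexed gene list (fast
    within-set edge counting is the hot operation of the permutation test)
    plus a score per edge for serialization.
    """

    genes: list
    adjacency: np.ndarray
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genes)}
        if np.any(np.diagonal(self.adjacency)):
            raise DomainError("self-loops are not allowed")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise DomainError("adjacency must be symmetric")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def has_edge(self, a, b) -> bool:
        ia, ib = self._index.get(a), self._index.get(b)
        return ia is not None and ib is not None and bool(self.adjacency[ia, ib])

    def indices_of(self, genes) -> np.ndarray:
        return np.array([self._index[g] for g in genes if g in self._index], dtype=int)

    def edges_within(self, genes) -> int:
        idx = self.indices_of(genes)
        if idx.size < 2:
            return 0
        return int(self.adjacency[np.ix_(idx, idx)].sum()) // 2

    @classmethod
    def from_edges(cls, edges, genes=None) -> "AssociationNetwork":
        """Build from an edge table with columns gene_a, gene_b, score."""
        edges = _as_edge_frame(edges)
        if genes is None:
            genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
        genes = list(genes)
        index = {g: i for i, g in enumerate(genes)}
        n = len(genes)
        adj = np.zeros((n, n), dtype=bool)
        scores: dict = {}
        for a, b, s in zip(edges["gene_a"], edges["gene_b"], edges["score"]):
            if a == b:
                continue
            if not (0 < s <= 1):
                raise DomainError(f"edge score {s} outside (0, 1]")
            ia, ib = index[a], index[b]
            adj[ia, ib] = adj[ib, ia] = True
            scores[(min(a, b), max(a, b))] = float(s)
        return cls(genes=genes, adjacency=adj, scores=scores)

    def to_edges(self) -> pd.DataFrame:
        rows = sorted(self.scores.items())
        return pd.DataFrame(
            {
                "gene_a": [k[0] for k, _ in rows],
                "gene_b": [k[1] for k, _ in rows],
                "score": [v for _, v in rows],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_edges().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genes=None) -> "AssociationNetwork":
        return cls.from_edges(pd.read_csv(path, sep="\t"), genes=genes)


def _as_edge_frame(edges) -> pd.DataFrame:
    if isinstance(edges, pd.DataFrame):
        df = edges.copy()
    else:
        rows = list(edges)
        width = len(rows[0]) if rows else 3
        cols = ["gene_a", "gene_b", "score", "channel"][:width]
        df = pd.DataFrame(rows, columns=cols)
    if "score" not in df.columns:
        df["score"] = 1.0
    return df


def filter_network(
    raw_edges,
    min_score: float = 0.4,
    excluded_channels=("coexpression",),
    genes=None,
) -> AssociationNetwork:
    """Drop excluded evidence channels, low-confidence edges and self-loops.

    ``raw_edges`` is an edge table (gene_a, gene_b, score[, channel]).
    When several channel rows describe one gene pair, the pair's score is
    the maximum over the channels that survive exclusion; the pair is kept
    when that score exceeds ``min_score`` (strictly).
    """
    df = _as_edge_frame(raw_edges)
    excluded = set(excluded_channels or ())
    if excluded and "channel" in df.columns:
        df = df[~df["channel"].isin(excluded)]
    df = df[df["gene_a"] != df["gene_b"]]
    if len(df):
        key = df.apply(
            lambda r: (min(r["gene_a"], r["gene_b"]), max(r["gene_a"], r["gene_b"])),
            axis=1,
        )
        df = (
            df.assign(_a=[k[0] for k in key], _b=[k[1] for k in key])
            .groupby(["_a", "_b"], as_index=False)["score"]
            .max()
            .rename(columns={"_a": "gene_a", "_b": "gene_b"})
        )
        df = df[df["score"] > min_score]
    return AssociationNetwork.from_edges(df, genes=genes)


def coherence_test(
    module_genes,
    net: AssociationNetwork,
    universe,
    n_random: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Proportion of associated pairs in the module, and its empirical P.

    Random sets are drawn uniformly without replacement from ``universe``
    (the expression universe, not only network-covered genes); drawn genes
    absent from the network contribute no edges but still count toward the
    pair denominator. One-sided: enrichment only.
    """
    module_genes = sorted(set(module_genes))
    if len(module_genes) < 2:
        raise DomainError("coherence test needs at least 2 module genes")
    universe = list(universe)
    if not set(module_genes) <= set(universe):
        warnings.warn("module genes outside the declared universe", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    k = len(module_genes)
    n_pairs = math.comb(k, 2)
    observed = net.edges_within(module_genes) / n_pairs

    # precomputed universe -> network-index map makes the null loop cheap
    uni_idx = np.array([net._index.get(g, -1) for g in universe], dtype=int)
    null = np.empty(n_random)
    for t in range(n_random):
        draw = rng.choice(len(universe), size=k, replace=False)
        idx = uni_idx[draw]
        idx = idx[idx >= 0]
        cnt = int(net.adjacency[np.ix_(idx, idx)].sum()) // 2 if idx.size >= 2 else 0
        null[t] = cnt / n_pairs
    return observed, empirical_p(observed, null)
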