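"""Phenotype-conditional taxon-gene association networks.

A bipartite network is read off an association table: one edge per
BH-significant (taxon, gene) pair, signed by the slope and weighted by |Z| =
|beta / se|. Reporting follows the largest-connected-component convention:
hub taxa are characterized by degree/betweenness within the LCC and by their
share of all edges. The per-taxon *network shift* test asks whether a taxon's
associated genes rank differently (by Z score against the full gene
background) between two phenotype groups, using a paired Wilcoxon signed-rank
test on the two rank lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .linmod import bh_adjust, wilcoxon_rank_sum, wilcoxon_signed_rank

logger = logging.getLogger("mucolink.network")

__all__ = [
    "AssocNetwork",
    "build_network",
    "largest_connected_component",
    "centrality",
    "taxon_edge_share",
    "compare_taxon_clusters",
]


@dataclass
class AssocNetwork:
    """Bipartite taxon-gene association network."""

    graph: nx.Graph
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        for a, b in self.graph.edges():
            ta, tb = self.graph.nodes[a]["kind"], self.graph.nodes[b]["kind"]
            if {ta, tb} != {"taxon", "gene"}:
                raise ValueError(f"edge {a}-{b} is not taxon-gene; network must be bipartite")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def taxa(self) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "taxon")

    @property
    def genes(self) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene")

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, d in self.graph.edges(data=True):
            taxon, gene = (a, b) if self.graph.nodes[a]["kind"] == "taxon" else (b, a)
            rows.append((taxon, gene, "+" if d["sign"] > 0 else "-", d["weight"]))
        out = pd.DataFrame(rows, columns=["taxon", "gene", "sign", "weight"])
        return out.sort_values(["taxon", "gene"]).reset_index(drop=True)


def build_network(
    assoc: pd.DataFrame,
    alpha: float = 0.05,
    group_label: Optional[str] = None,
) -> AssocNetwork:
    """One edge per association with adjusted p below ``alpha``.

    Edge sign is the sign of the slope; edge weight is |beta / se|.
    """
    required = {"gene_id", "taxon_id", "beta", "se", "p_adj"}
    missing = required - set(assoc.columns)
    if missing:
        raise ValueError(f"association table lacks columns: {sorted(missing)}")
    sig = assoc[assoc["p_adj"] < alpha]
    if sig.duplicated(subset=["gene_id", "taxon_id"]).any():
        raise ValueError("duplicate (gene, taxon) pairs in the association table")
    g = nx.Graph()
    for row in sig.itertuples(index=False):
        weight = abs(row.beta / row.se) if row.se > 0 else 0.0
        if weight <= 0:
            continue
        g.add_node(row.taxon_id, kind="taxon")
        g.add_node(row.gene_id, kind="gene")
        g.add_edge(row.taxon_id, row.gene_id, sign=1 if row.beta > 0 else -1, weight=weight)
    return AssocNetwork(graph=g, group_label=group_label)


def largest_connected_component(net: AssocNetwork) -> AssocNetwork:
    """Subgraph induced by the largest connected node set.

    Size ties resolve to the lexicographically smallest member set; an empty
    network yields an empty LCC.
    """
    if net.graph.number_of_nodes() == 0:
        return AssocNetwork(graph=nx.Graph(), group_label=net.group_label)
    comps = [tuple(sorted(c)) for c in nx.connected_components(net.graph)]
    best = min(comps, key=lambda c: (-len(c), c))
    return AssocNetwork(graph=net.graph.subgraph(best).copy(), group_label=net.group_label)


def centrality(net: AssocNetwork) -> pd.DataFrame:
    """Per-node degree and normalized betweenness (Brandes) on the LCC.

    Degree counts incident edges in the full network; betweenness is computed
    on the unweighted largest connected component (nodes outside it score 0).
    """
    lcc = largest_connected_component(net)
    btw = nx.betweenness_centrality(lcc.graph, normalized=True) if lcc.graph.number_of_nodes() else {}
    rows = [
        (node, data["kind"], net.graph.degree(node), btw.get(node, 0.0))
        for node, data in net.graph.nodes(data=True)
    ]
    out = pd.DataFrame(rows, columns=["node", "kind", "degree", "betweenness"])
    return out.sort_values(["degree", "node"], ascending=[False, True]).reset_index(drop=True)


def taxon_edge_share(net: AssocNetwork, taxon_id: str) -> float:
    """Fraction of all network edges incident to ``taxon_id`` (0 if empty)."""
    total = net.n_edges
    if total == 0:
        return 0.0
    if taxon_id not in net.graph:
        logger.warning("taxon %s not present in network", taxon_id)
        return 0.0
    return net.graph.degree(taxon_id) / total


def compare_taxon_clusters(
    assoc_a: pd.DataFrame,
    assoc_b: pd.DataFrame,
    background: Sequence[str],
    alpha: float = 0.05,
    method: str = "signed_rank",
    gene_scope: str = "union",
) -> pd.DataFrame:
    """Per-taxon network-shift test between two phenotype groups.

    Within each group, every background gene is ranked by its Z = beta / se
    for the taxon (average ranks on ties, over the full background so scale
    differences between groups cancel). The comparison gene set is, per
    taxon, the union of genes BH-significant for that taxon in either group
    (``gene_scope="union"``; ``"all"`` uses the full background). The two
    rank lists over that set are compared with a paired Wilcoxon signed-rank
    test (``method="rank_sum"`` switches to unpaired rank-sum); p-values are
    BH-adjusted across taxa. Taxa whose comparison set has fewer than 3 genes
    are skipped and logged.
    """
    if method not in ("signed_rank", "rank_sum"):
        raise ValueError("method must be 'signed_rank' or 'rank_sum'")
    if gene_scope not in ("union", "all"):
        raise ValueError("gene_scope must be 'union' or 'all'")
    background = list(dict.fromkeys(background))
    if len(background) < 3:
        raise ValueError("background must contain at least 3 genes")

    def _pivot(tab: pd.DataFrame, col: str) -> pd.DataFrame:
        return tab.pivot(index="taxon_id", columns="gene_id", values=col)

    za = _pivot(assoc_a.assign(z=assoc_a["beta"] / assoc_a["se"]), "z")
    zb = _pivot(assoc_b.assign(z=assoc_b["beta"] / assoc_b["se"]), "z")
    pa = _pivot(assoc_a, "p_adj")
    pb = _pivot(assoc_b, "p_adj")
    taxa = sorted(set(za.index) & set(zb.index))
    genes = [g for g in background if g in za.columns and g in zb.columns]
    if len(genes) < 3:
        raise ValueError("fewer than 3 background genes present in both tables")

    rows = []
    for taxon in taxa:
        z1 = za.loc[taxon, genes].to_numpy(dtype=float)
        z2 = zb.loc[taxon, genes].to_numpy(dtype=float)
        if np.any(~np.isfinite(z1)) or np.any(~np.isfinite(z2)):
            logger.info("skipping taxon %s: missing Z scores", taxon)
            continue
        r1 = rankdata(z1, method="average")
        r2 = rankdata(z2, method="average")
        sig_a = pa.loc[taxon, genes].to_numpy(dtype=float) < alpha
        sig_b = pb.loc[taxon, genes].to_numpy(dtype=float) < alpha
        if gene_scope == "union":
            mask = sig_a | sig_b
        else:
            mask = np.ones(len(genes), dtype=bool)
        if mask.sum() < 3:
            logger.info("skipping taxon %s: comparison set has %d genes", taxon, int(mask.sum()))
            continue
        diffs = r1[mask] - r2[mask]
        try:
            if method == "signed_rank":
                stat, p = wilcoxon_signed_rank(diffs)
            else:
                stat, p = wilcoxon_rank_sum(r1[mask], r2[mask])
        except ValueError:
            # identical rank lists: no evidence of a shift
            stat, p = 0.0, 1.0
        direction = "A" if float(np.mean(diffs)) > 0 else "B"
        rows.append(
            (taxon, int(sig_a.sum()), int(sig_b.sum()), stat, p, direction, int(mask.sum()))
        )
    out = pd.DataFrame(
        rows,
        columns=["taxon_id", "n_assoc_A", "n_assoc_B", "wilcoxon_stat", "p", "direction", "n_genes_compared"],
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["p_adj"] = []
    return out
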