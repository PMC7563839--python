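"""Condition-specific subnetwork extraction and degree analysis.

A subnetwork is the subgraph of the background interactome induced by
the DEG set of one condition: every edge whose two endpoints are both
differentially expressed, plus isolated DE nodes (kept with degree 0 so
the biotype composition of the response is visible even off-network).
Optionally edges can be filtered or signed by the expression correlation
of their endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import INHIBITORY, MIRNA, STIMULATORY, UNSIGNED
from .degs import DESet
from .interactome import Interactome

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    """Induced DE subgraph of one condition.

    ``graph`` is a directed graph whose nodes carry ``biotype`` and
    ``direction`` attributes and whose edges carry a ``sign`` attribute in
    {stimulatory, inhibitory, unsigned}.
    """

    condition: str
    graph: nx.DiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def biotype(self, node: str) -> str:
        return self.graph.nodes[node]["biotype"]

    def nodes_of_biotype(self, biotype: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["biotype"] == biotype}

    def edge_list(self) -> pd.DataFrame:
        rows = [
            (u, v, self.graph.nodes[u]["biotype"], self.graph.nodes[v]["biotype"], d.get("sign", UNSIGNED))
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "source_biotype", "target_biotype", "sign"])

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(self.graph.edges()):
                fh.write(f"{u}\t{self.graph.nodes[u]['biotype'].lower()}-{self.graph.nodes[v]['biotype'].lower()}\t{v}\n")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def extract_subnetwork(
    interactome: Interactome,
    deset: DESet,
    correlation_filter: tuple[pd.DataFrame, float] | None = None,
) -> Subnetwork:
    """Induce the DE subgraph of one condition from the background network.

    DE ids absent from the interactome are retained as isolated nodes with
    their DESet biotype.  With ``correlation_filter=(expression, r_min)``
    an edge is kept only when |Pearson r| of the endpoint expression
    profiles is >= r_min; edges with endpoints missing from the matrix are
    kept (with a warning) rather than silently dropped.
    """
    de_ids = deset.ids()
    g = nx.DiGraph()
    for gene in sorted(de_ids):
        biotype, direction = deset.members[gene]
        # interactome biotype wins when present: registry relabeling may have
        # promoted the node there as well, and the two must agree.
        g.add_node(gene, biotype=interactome.nodes.get(gene, biotype), direction=direction)

    edges = interactome.edges
    if not edges.empty and de_ids:
        keep = edges["source"].isin(de_ids) & edges["target"].isin(de_ids)
        sub = edges[keep]
        if correlation_filter is not None:
            expr, r_min = correlation_filter
            kept_rows = []
            n_missing = 0
            for row in sub.itertuples(index=False):
                if row.source in expr.index and row.target in expr.index:
                    r = _pearson(expr.loc[row.source].to_numpy(float), expr.loc[row.target].to_numpy(float))
                    if np.isnan(r) or abs(r) >= r_min:
                        kept_rows.append(row)
                else:
                    n_missing += 1
                    kept_rows.append(row)
            if n_missing:
                logger.warning(
                    "correlation filter: %d edge(s) with endpoints missing from the expression matrix kept unsigned",
                    n_missing,
                )
            sub = pd.DataFrame(kept_rows, columns=sub.columns) if kept_rows else sub.iloc[0:0]
        for row in sub.itertuples(index=False):
            g.add_edge(row.source, row.target, sign=UNSIGNED, evidence=row.evidence)
    return Subnetwork(condition=deset.condition, graph=g)


def assign_edge_signs(subnetwork: Subnetwork, expression: pd.DataFrame | None) -> Subnetwork:
    """Sign edges by endpoint expression correlation.

    Pearson r > 0 -> stimulatory, r < 0 -> inhibitory.  Edges whose
    endpoints are absent from the matrix stay unsigned, except
    miRNA-source edges which default to inhibitory (miRNAs act by target
    repression).  Constant expression rows leave the edge unsigned with a
    warning.  Signs are written in place and the subnetwork returned.
    """
    g = subnetwork.graph
    for u, v, data in g.edges(data=True):
        have = (
            expression is not None
            and u in expression.index
            and v in expression.index
        )
        if have:
            r = _pearson(expression.loc[u].to_numpy(float), expression.loc[v].to_numpy(float))
            if np.isnan(r):
                logger.warning("constant expression for edge (%s, %s); left unsigned", u, v)
                data["sign"] = UNSIGNED
            elif r > 0:
                data["sign"] = STIMULATORY
            elif r < 0:
                data["sign"] = INHIBITORY
            else:
                data["sign"] = UNSIGNED
        elif g.nodes[u]["biotype"] == MIRNA:
            data["sign"] = INHIBITORY
        else:
            data["sign"] = UNSIGNED
    return subnetwork


@dataclass
class DegreeReport:
    """Per-node in/out-degrees and the out-degree hub list."""

    table: pd.DataFrame  # columns: node, biotype, in_degree, out_degree
    hubs: list[str]

    def total_in(self) -> int:
        return int(self.table["in_degree"].sum()) if len(self.table) else 0

    def total_out(self) -> int:
        return int(self.table["out_degree"].sum()) if len(self.table) else 0


def degree_report(subnetwork: Subnetwork, top_k: int = 10) -> DegreeReport:
    """Node connectivity report; hubs are the top_k nodes by out-degree.

    Ties in out-degree are broken lexicographically by node id so hub
    lists are reproducible.
    """
    g = subnetwork.graph
    rows = [
        (n, g.nodes[n]["biotype"], g.in_degree(n), g.out_degree(n))
        for n in sorted(g.nodes())
    ]
    table = pd.DataFrame(rows, columns=["node", "biotype", "in_degree", "out_degree"])
    ranked = sorted(rows, key=lambda r: (-r[3], r[0]))
    hubs = [r[0] for r in ranked[: max(top_k, 0)] if r[3] > 0]
    return DegreeReport(table=table, hubs=hubs)
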