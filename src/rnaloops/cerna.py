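"""Shared-miRNA ceRNA candidate derivation.

A lncRNA that shares a miRNA regulator with an mRNA inside a
condition-specific subnetwork is a candidate competing endogenous RNA
(sponge): it can titrate the miRNA away from the mRNA.  The derivation
is purely structural — one triple per (miRNA, lncRNA target, mRNA
target) combination — so for each miRNA the number of triples equals
(#lncRNA targets) x (#mRNA targets).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import LNCRNA, MIRNA, MRNA
from .subnetwork import Subnetwork


@dataclass(frozen=True, slots=True, order=True)
class CeRNATriple:
    mirna: str
    lncrna: str
    mrna: str


def find_cerna(
    subnetwork: Subnetwork, mirna_allowlist: Iterable[str] | None = None
) -> list[CeRNATriple]:
    """All (miRNA, lncRNA, mRNA) triples with both miRNA->target edges.

    ``mirna_allowlist`` restricts the scan (the pipeline passes the
    miRNAs that participate in feed-forward loops); ``None`` scans every
    miRNA in the subnetwork.  Deterministically sorted output.
    """
    g = subnetwork.graph
    mirnas = sorted(subnetwork.nodes_of_biotype(MIRNA))
    if mirna_allowlist is not None:
        allow = set(mirna_allowlist)
        mirnas = [m for m in mirnas if m in allow]
    triples: list[CeRNATriple] = []
    for m in mirnas:
        targets = list(g.successors(m))
        lncs = sorted(t for t in targets if g.nodes[t]["biotype"] == LNCRNA)
        mrnas = sorted(t for t in targets if g.nodes[t]["biotype"] == MRNA)
        triples.extend(CeRNATriple(m, l, r) for l in lncs for r in mrnas)
    return triples


def triples_to_frame(
    triples: list[CeRNATriple], expression: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tabulate triples; with an expression matrix, annotate the Pearson
    correlation between the lncRNA and mRNA partners (NaN when either is
    missing or constant)."""
    rows = [(t.mirna, t.lncrna, t.mrna) for t in triples]
    df = pd.DataFrame(rows, columns=["mirna", "lncrna", "mrna"])
    if expression is not None and len(df):
        rs = []
        for t in triples:
            if t.lncrna in expression.index and t.mrna in expression.index:
                x = expression.loc[t.lncrna].to_numpy(float)
                y = expression.loc[t.mrna].to_numpy(float)
                rs.append(np.nan if x.std() == 0 or y.std() == 0 else float(np.corrcoef(x, y)[0, 1]))
            else:
                rs.append(np.nan)
        df["r_lnc_mrna"] = rs
    return df


def cerna_network_export(
    triples: list[CeRNATriple], subnetwork: Subnetwork | None = None
) -> pd.DataFrame:
    """Per-miRNA star edge list over the distinct sponge partners.

    Each miRNA contributes one edge to every distinct lncRNA/mRNA partner
    appearing in its triples; partner biotype and DE direction (when a
    subnetwork is supplied) travel as attributes.
    """
    stars: set[tuple[str, str, str]] = set()
    for t in triples:
        stars.add((t.mirna, t.lncrna, LNCRNA))
        stars.add((t.mirna, t.mrna, MRNA))
    rows = []
    for mirna, partner, biotype in sorted(stars):
        direction = ""
        if subnetwork is not None and partner in subnetwork.graph:
            direction = subnetwork.graph.nodes[partner].get("direction", "")
        rows.append((mirna, partner, biotype, direction))
    return pd.DataFrame(rows, columns=["mirna", "partner", "partner_biotype", "direction"])


def write_triples(
    triples: list[CeRNATriple], path: str | Path, expression: pd.DataFrame | None = None
) -> None:
    triples_to_frame(triples, expression).to_csv(path, sep="\t", index=False)
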