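"""Feed-forward loop (FFL) enumeration and classification.

An FFL here is a 3-node motif over one TF, one miRNA and one target
(mRNA or lncRNA) in which both regulators point at the target and the
regulators are themselves connected:

* ``tf_mediated``    — TF->miRNA, TF->target, miRNA->target
* ``mirna_mediated`` — miRNA->TF, TF->target, miRNA->target
* ``mixed``          — TF<->miRNA mutual regulation plus both edges to
  the target.

Classification is exclusive by default: a mutually-regulated pair is
reported once as ``mixed``, never additionally under the first two
types, so per-type counts partition the motif set.  Setting
``mixed_exclusive=False`` reports a mutual triple under all three types.

Enumeration iterates over (TF, miRNA) regulator pairs and intersects
successor sets, which is O(|TF|·|miRNA| + output) — the brute-force
O(n^3) triple scan is kept in the test suite as the independent oracle.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import LNCRNA, MIRNA, MRNA, TF, UNSIGNED
from .subnetwork import Subnetwork


@dataclass(frozen=True, slots=True, order=True)
class FFLMotif:
    """One classified 3-node feed-forward loop."""

    tf: str
    mirna: str
    target: str
    target_biotype: str
    ffl_type: str

    def edges(self) -> list[tuple[str, str]]:
        """Directed edges of the loop (4 for mixed, 3 otherwise)."""
        out = [(self.tf, self.target), (self.mirna, self.target)]
        if self.ffl_type in ("tf_mediated", "mixed"):
            out.append((self.tf, self.mirna))
        if self.ffl_type in ("mirna_mediated", "mixed"):
            out.append((self.mirna, self.tf))
        return out


def _graph_of(subnetwork) -> nx.DiGraph:
    return subnetwork.graph if isinstance(subnetwork, Subnetwork) else subnetwork


def enumerate_ffls(subnetwork, mixed_exclusive: bool = True) -> list[FFLMotif]:
    """Enumerate every feed-forward loop in a typed directed graph.

    Accepts a :class:`Subnetwork` or a bare :class:`networkx.DiGraph`
    whose nodes carry a ``biotype`` attribute.  Targets are restricted to
    biotypes mRNA and lncRNA; the three nodes of a motif are distinct by
    construction (one id, one biotype, one role).  Output is sorted by
    (tf, mirna, target) and contains each (triple, type) exactly once.
    """
    g = _graph_of(subnetwork)
    biotype = nx.get_node_attributes(g, "biotype")
    tfs = sorted(n for n, b in biotype.items() if b == TF)
    mirnas = sorted(n for n, b in biotype.items() if b == MIRNA)
    succ = {n: set(g.successors(n)) for n in g.nodes()}

    motifs: list[FFLMotif] = []
    for t in tfs:
        for m in mirnas:
            t2m = m in succ[t]
            m2t = t in succ[m]
            if not (t2m or m2t):
                continue
            for x in succ[t] & succ[m]:
                bx = biotype.get(x)
                if bx not in (MRNA, LNCRNA):
                    continue
                if t2m and m2t:
                    if mixed_exclusive:
                        motifs.append(FFLMotif(t, m, x, bx, "mixed"))
                    else:
                        motifs.append(FFLMotif(t, m, x, bx, "tf_mediated"))
                        motifs.append(FFLMotif(t, m, x, bx, "mirna_mediated"))
                        motifs.append(FFLMotif(t, m, x, bx, "mixed"))
                elif t2m:
                    motifs.append(FFLMotif(t, m, x, bx, "tf_mediated"))
                else:
                    motifs.append(FFLMotif(t, m, x, bx, "mirna_mediated"))
    motifs.sort(key=lambda f: (f.tf, f.mirna, f.target, f.ffl_type))
    return motifs


@dataclass
class MotifSummary:
    """Counts per (type x target biotype), node participation, regulator rosters."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    participation: dict[str, int] = field(default_factory=dict)
    target_ids: frozenset[str] = frozenset()
    tf_roster: frozenset[str] = frozenset()
    mirna_roster: frozenset[str] = frozenset()

    @property
    def n_loops(self) -> int:
        return sum(self.counts.values())

    def count_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (ffl_type, _), n in self.counts.items():
            out[ffl_type] = out.get(ffl_type, 0) + n
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, b, n) for (t, b), n in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["ffl_type", "target_biotype", "count"])


def summarize_motifs(motifs: list[FFLMotif]) -> MotifSummary:
    counts = Counter((f.ffl_type, f.target_biotype) for f in motifs)
    participation = Counter()
    for f in motifs:
        participation.update((f.tf, f.mirna, f.target))
    return MotifSummary(
        counts=dict(counts),
        participation=dict(participation),
        target_ids=frozenset(f.target for f in motifs),
        tf_roster=frozenset(f.tf for f in motifs),
        mirna_roster=frozenset(f.mirna for f in motifs),
    )


def lncrna_loop_summary(motifs: list[FFLMotif]) -> MotifSummary:
    """Summary restricted to loops whose target is a lncRNA.

    ``target_ids`` is then the set of distinct loop lncRNAs and the
    rosters list the distinct TFs and miRNAs regulating them.
    """
    return summarize_motifs([f for f in motifs if f.target_biotype == LNCRNA])


def export_hive(
    motifs: list[FFLMotif], signs: dict[tuple[str, str], str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hive-plot-ready tables for lncRNA-containing loops.

    Returns (axes, edges): ``axes`` assigns each node to one of the three
    radial axes TF / miRNA / lncRNA; ``edges`` lists the deduplicated
    directed loop edges with a sign column (``unsigned`` when no sign map
    is supplied).  Both tables are deterministically sorted.
    """
    lnc = [f for f in motifs if f.target_biotype == LNCRNA]
    axis_rows = sorted(
        {(f.tf, TF) for f in lnc}
        | {(f.mirna, MIRNA) for f in lnc}
        | {(f.target, LNCRNA) for f in lnc}
    )
    edge_pairs = sorted({e for f in lnc for e in f.edges()})
    signs = signs or {}
    edge_rows = [(u, v, signs.get((u, v), UNSIGNED)) for u, v in edge_pairs]
    axes = pd.DataFrame(axis_rows, columns=["node", "axis"])
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "sign"])
    return axes, edges


def motifs_to_frame(motifs: list[FFLMotif]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.tf, f.mirna, f.target, f.target_biotype, f.ffl_type) for f in motifs],
        columns=["tf", "mirna", "target", "target_biotype", "ffl_type"],
    )


def write_motifs(motifs: list[FFLMotif], path: str | Path) -> None:
    motifs_to_frame(motifs).to_csv(path, sep="\t", index=False)
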