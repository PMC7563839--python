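"""Assembly of the background RNA interactome.

The background network is the union of regulator->target associations
compiled from evidence databases (ChIP-seq TF binding, CLIP-supported
miRNA targeting, predicted miRNA--lncRNA pairing and the like), prior to
any condition-specific filtering.  Association tables arrive as plain
TSV, one table per edge class; the class fixes the endpoint biotypes.

Two rules from the study design are applied during assembly:

* duplicate (source, target) pairs reported by different databases are
  merged into a single edge whose evidence is the union of the database
  labels (associations are treated as binary regulations, not weighted);
* any target listed in the TF registry is relabeled to biotype TF, so
  miRNA->TF edges emerge from miRNA->mRNA records whose target codes for
  a transcription factor.

Edges are stored in a pandas DataFrame rather than a graph object: the
full interactome is ~10^6 edges and is only ever filtered, never
traversed.  Small condition-specific subnetworks are turned into
:class:`networkx.DiGraph` downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .core import (
    EDGE_CLASSES,
    LNCRNA,
    MIRNA,
    MRNA,
    TF,
    BiotypeConflictError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: canonical column order of the internal edge frame
EDGE_COLUMNS = ["source", "target", "source_biotype", "target_biotype", "evidence"]


@dataclass(frozen=True, slots=True)
class AssociationEdge:
    """One directed regulator->target record; the atom of the background network."""

    source_id: str
    source_biotype: str
    target_id: str
    target_biotype: str
    evidence_sources: frozenset[str]

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise ValueError(f"self-loop edge {self.source_id!r}")
        if self.source_biotype == MIRNA and self.target_biotype == MIRNA:
            raise ValueError("miRNA->miRNA edges are not allowed")


@dataclass
class Interactome:
    """Deduplicated heterogeneous directed graph over typed nodes.

    Attributes
    ----------
    nodes
        Mapping node id -> biotype (TF/miRNA/lncRNA/mRNA).
    edges
        DataFrame with columns ``source, target, source_biotype,
        target_biotype, evidence``; evidence is a ``|``-joined sorted set
        of database labels.  No duplicate (source, target) pairs.
    provenance
        Edge support count per database label (an edge supported by two
        databases counts once for each).
    """

    nodes: dict[str, str]
    edges: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for bio in self.nodes.values():
            counts[bio] = counts.get(bio, 0) + 1
        return counts

    def edge_class_counts(self) -> dict[str, int]:
        if self.edges.empty:
            return {}
        labels = self.edges["source_biotype"] + "->" + self.edges["target_biotype"]
        return labels.value_counts().to_dict()

    def edge_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["source"], self.edges["target"]))

    def to_graph(self) -> nx.DiGraph:
        """Materialize as a networkx DiGraph (intended for small networks)."""
        g = nx.DiGraph()
        for node, biotype in self.nodes.items():
            g.add_node(node, biotype=biotype)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, evidence=row.evidence)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))

    def write_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.edges.itertuples(index=False):
                fh.write(f"{row.source}\t{row.source_biotype.lower()}-{row.target_biotype.lower()}\t{row.target}\n")


def read_association_table(
    path: str | Path, edge_class: str, source_db: str
) -> pd.DataFrame:
    """Read one association TSV into a (source, target, source_db) frame.

    The declared ``edge_class`` fixes the endpoint biotypes.  Rows with an
    empty identifier raise :class:`ParseError` naming the offending lines;
    self-loop rows are dropped with a logged warning.
    """
    if edge_class not in EDGE_CLASSES:
        raise ValueError(f"unknown edge class {edge_class!r}; expected one of {sorted(EDGE_CLASSES)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"association file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected >=2 columns, found {df.shape[1]}")
    cols = list(df.columns)
    out = pd.DataFrame(
        {
            "source": df[cols[0]].str.strip(),
            "target": df[cols[1]].str.strip(),
        }
    )
    if "source_db" in df.columns:
        out["source_db"] = df["source_db"].str.strip()
    else:
        out["source_db"] = source_db
    bad = out.index[(out["source"] == "") | (out["target"] == "")]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:20])
        raise ParseError(f"{path}: empty identifier on line(s) {lines}")
    loops = out["source"] == out["target"]
    if loops.any():
        for i in out.index[loops][:20]:
            logger.warning("%s: self-loop %r on line %d rejected", path, out.at[i, "source"], i + 2)
        out = out[~loops].reset_index(drop=True)
    return out


def load_associations(
    path: str | Path, edge_class: str, source_db: str
) -> list[AssociationEdge]:
    """Parse one association file into :class:`AssociationEdge` records."""
    frame = read_association_table(path, edge_class, source_db)
    sbio, tbio = EDGE_CLASSES[edge_class]
    return [
        AssociationEdge(row.source, sbio, row.target, tbio, frozenset({row.source_db}))
        for row in frame.itertuples(index=False)
    ]


def _normalize_input(item) -> pd.DataFrame:
    """Coerce one edge input into a long frame with biotype + source_db columns."""
    if isinstance(item, pd.DataFrame):
        df = item.copy()
        if "evidence" in df.columns and "source_db" not in df.columns:
            # an Interactome edge frame fed back in: explode merged evidence
            df = df.rename(columns={"evidence": "source_db"})
            df["source_db"] = df["source_db"].str.split("|")
            df = df.explode("source_db", ignore_index=True)
        missing = {"source", "target", "source_biotype", "target_biotype"} - set(df.columns)
        if missing:
            raise ValueError(f"edge frame missing columns {sorted(missing)}")
        if "source_db" not in df.columns:
            df["source_db"] = "unknown"
        return df[["source", "target", "source_biotype", "target_biotype", "source_db"]]
    if isinstance(item, tuple) and len(item) == 2 and item[0] in EDGE_CLASSES:
        edge_class, df = item
        sbio, tbio = EDGE_CLASSES[edge_class]
        df = df.copy()
        if "source_db" not in df.columns:
            df["source_db"] = "unknown"
        df["source_biotype"] = sbio
        df["target_biotype"] = tbio
        return df[["source", "target", "source_biotype", "target_biotype", "source_db"]]
    # iterable of AssociationEdge
    rows = [
        (e.source_id, e.target_id, e.source_biotype, e.target_biotype, db)
        for e in item
        for db in sorted(e.evidence_sources)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "source_biotype", "target_biotype", "source_db"])


def build_interactome(edge_inputs, tf_registry: Iterable[str] = ()) -> Interactome:
    """Assemble the deduplicated background network.

    Parameters
    ----------
    edge_inputs
        Either a mapping ``edge_class -> DataFrame(source, target[, source_db])``,
        or an iterable whose items are ``(edge_class, DataFrame)`` pairs,
        lists of :class:`AssociationEdge`, or edge frames that already carry
        biotype columns (e.g. ``Interactome.edges`` — assembly is idempotent).
    tf_registry
        Identifiers of transcription-factor-coding genes.  Any such id seen
        with biotype mRNA is relabeled TF; seeing one declared lncRNA or
        miRNA is a :class:`BiotypeConflictError`.
    """
    registry = frozenset(tf_registry)
    if isinstance(edge_inputs, Mapping):
        items: list = [(k, v) for k, v in edge_inputs.items()]
    elif isinstance(edge_inputs, pd.DataFrame):
        items = [edge_inputs]
    else:
        items = list(edge_inputs)
    frames = [_normalize_input(it) for it in items]
    if frames:
        long = pd.concat(frames, ignore_index=True)
    else:
        long = pd.DataFrame(columns=["source", "target", "source_biotype", "target_biotype", "source_db"])

    if long.empty:
        return Interactome(nodes={}, edges=pd.DataFrame(columns=EDGE_COLUMNS), provenance={})

    loops = long["source"] == long["target"]
    if loops.any():
        logger.warning("dropping %d self-loop record(s)", int(loops.sum()))
        long = long[~loops]

    if registry:
        bad_src = long.loc[long["source_biotype"].isin([LNCRNA, MIRNA]) & long["source"].isin(registry), "source"]
        bad_tgt = long.loc[long["target_biotype"].isin([LNCRNA, MIRNA]) & long["target"].isin(registry), "target"]
        conflicts = pd.concat([bad_src, bad_tgt]).unique()
        if len(conflicts):
            raise BiotypeConflictError(
                f"id(s) in TF registry but declared lncRNA/miRNA in an edge file: {sorted(conflicts)[:10]}"
            )
        promote = (long["target_biotype"] == MRNA) & long["target"].isin(registry)
        long.loc[promote, "target_biotype"] = TF

    # node biotype map; an id must resolve to exactly one biotype
    node_frame = pd.concat(
        [
            long[["source", "source_biotype"]].rename(columns={"source": "id", "source_biotype": "biotype"}),
            long[["target", "target_biotype"]].rename(columns={"target": "id", "target_biotype": "biotype"}),
        ],
        ignore_index=True,
    ).drop_duplicates()
    multi = node_frame["id"].value_counts()
    multi = multi[multi > 1]
    if len(multi):
        # mRNA/TF pairs can only remain if the registry was incomplete on some
        # input; any residual multiplicity is a genuine conflict.
        raise BiotypeConflictError(f"inconsistent biotypes for id(s): {sorted(multi.index[:10])}")
    nodes = dict(zip(node_frame["id"], node_frame["biotype"]))
    # registry ids that appear in edges only as plain sources keep their TF label;
    # registry ids absent from all edges are not added as isolated nodes.

    dedup = long.drop_duplicates(["source", "target", "source_db"])
    provenance = dedup["source_db"].value_counts().to_dict()

    # evidence union per (source, target): only pairs reported by >1 database
    # need a python-level merge; the (large) remainder keeps its single label.
    pair_dup = dedup.duplicated(["source", "target"], keep=False)
    unique_part = dedup[~pair_dup].copy()
    unique_part["evidence"] = unique_part["source_db"]
    if pair_dup.any():
        merged = (
            dedup[pair_dup]
            .groupby(["source", "target", "source_biotype", "target_biotype"], sort=False)["source_db"]
            .agg(lambda s: "|".join(sorted(set(s))))
            .reset_index()
            .rename(columns={"source_db": "evidence"})
        )
        edges = pd.concat([unique_part[EDGE_COLUMNS], merged[EDGE_COLUMNS]], ignore_index=True)
    else:
        edges = unique_part[EDGE_COLUMNS]
    edges = edges.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)
    return Interactome(nodes=nodes, edges=edges, provenance=provenance)


@dataclass
class CompositionReport:
    """Node counts per biotype and edge counts per regulator->target class."""

    node_counts: dict[str, int]
    edge_counts: dict[str, int]
    total_edges: int
    provenance: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [("node", bio, n) for bio, n in sorted(self.node_counts.items())]
        rows += [("edge", cls, n) for cls, n in sorted(self.edge_counts.items())]
        rows.append(("edge", "total", self.total_edges))
        return pd.DataFrame(rows, columns=["kind", "category", "count"])


def summarize(interactome: Interactome) -> CompositionReport:
    """Composition report of a built interactome."""
    return CompositionReport(
        node_counts=interactome.node_counts(),
        edge_counts=interactome.edge_class_counts(),
        total_edges=interactome.n_edges,
        provenance=dict(interactome.provenance),
    )


def read_tf_registry(path: str | Path) -> list[str]:
    """Read a TF registry file: one identifier per line, blanks ignored."""
    with open(path) as fh:
        ids = [line.strip() for line in fh]
    return [i for i in ids if i]


def load_interactome_tables(
    paths: Mapping[str, Sequence[tuple[str | Path, str]]], tf_registry_path: str | Path
) -> Interactome:
    """Build from files: ``paths`` maps edge_class -> [(path, source_db), ...]."""
    inputs = []
    for edge_class, entries in paths.items():
        for p, db in entries:
            inputs.append((edge_class, read_association_table(p, edge_class, db)))
    return build_interactome(inputs, read_tf_registry(tf_registry_path))
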