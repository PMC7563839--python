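"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import rnaloops as rl
from rnaloops.core import LNCRNA, MIRNA, MRNA, TF


def brute_force_ffls(graph: nx.DiGraph, mixed_exclusive: bool = True) -> set[tuple]:
    """Independent O(n^3) feed-forward-loop oracle: scan every ordered
    (TF, miRNA, target) triple and test the edge patterns directly."""
    biotype = nx.get_node_attributes(graph, "biotype")
    nodes = list(graph.nodes())
    out: set[tuple] = set()
    for t, m, x in itertools.product(nodes, repeat=3):
        if biotype.get(t) != TF or biotype.get(m) != MIRNA:
            continue
        if biotype.get(x) not in (MRNA, LNCRNA) or len({t, m, x}) != 3:
            continue
        if not (graph.has_edge(t, x) and graph.has_edge(m, x)):
            continue
        t2m, m2t = graph.has_edge(t, m), graph.has_edge(m, t)
        if t2m and m2t:
            if mixed_exclusive:
                out.add((t, m, x, biotype[x], "mixed"))
            else:
                out.add((t, m, x, biotype[x], "tf_mediated"))
                out.add((t, m, x, biotype[x], "mirna_mediated"))
                out.add((t, m, x, biotype[x], "mixed"))
        elif t2m:
            out.add((t, m, x, biotype[x], "tf_mediated"))
        elif m2t:
            out.add((t, m, x, biotype[x], "mirna_mediated"))
    return out


def random_typed_graph(rng: np.random.Generator, n_nodes: int = 30, density: float = 0.15) -> nx.DiGraph:
    """Random heterogeneous digraph with edges in every regulator class
    (including miRNA->TF) at the given density."""
    n_tf = max(2, n_nodes // 6)
    n_mir = max(2, n_nodes // 5)
    n_lnc = max(2, n_nodes // 4)
    n_mrna = max(2, n_nodes - n_tf - n_mir - n_lnc)
    g = nx.DiGraph()
    groups = {
        TF: [f"T{i}" for i in range(n_tf)],
        MIRNA: [f"M{i}" for i in range(n_mir)],
        LNCRNA: [f"L{i}" for i in range(n_lnc)],
        MRNA: [f"G{i}" for i in range(n_mrna)],
    }
    for bio, ids in groups.items():
        g.add_nodes_from(ids, biotype=bio)
    classes = [
        (TF, MRNA), (TF, LNCRNA), (TF, MIRNA),
        (MIRNA, MRNA), (MIRNA, LNCRNA), (MIRNA, TF),
    ]
    for sbio, tbio in classes:
        for u in groups[sbio]:
            for v in groups[tbio]:
                if u != v and rng.random() < density:
                    g.add_edge(u, v)
    return g


def subnetwork_from_graph(g: nx.DiGraph, condition: str = "test") -> rl.Subnetwork:
    for _, d in g.nodes(data=True):
        d.setdefault("direction", "up")
    return rl.Subnetwork(condition=condition, graph=g)


@pytest.fixture(scope="session")
def small_config() -> rl.SimConfig:
    return rl.SimConfig(
        n_tf=6, n_mirna=8, n_lncrna=20, n_mrna=25,
        edge_density={k: 0.15 for k in rl.synthetic_data.DEFAULT_EDGE_DENSITY},
        n_planted_ffl={"tf_mediated": 3, "mirna_mediated": 3, "mixed": 2},
        n_planted_cerna=4,
        de_fraction={TF: 0.3, MRNA: 0.3, MIRNA: 0.3, LNCRNA: 0.3},
        n_samples=12, survival_n=80, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> rl.SimulatedDataset:
    return rl.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_interactome(small_dataset) -> rl.Interactome:
    return rl.build_interactome(dict(small_dataset.background.tables), small_dataset.background.tf_registry)


@pytest.fixture()
def toy_interactome() -> rl.Interactome:
    """T1->G1, M1->G1, M1->L1 over four typed nodes."""
    frames = {
        "tf_mrna": pd.DataFrame({"source": ["T1"], "target": ["G1"], "source_db": ["chipbase"]}),
        "mirna_mrna": pd.DataFrame({"source": ["M1"], "target": ["G1"], "source_db": ["starbase"]}),
        "mirna_lncrna": pd.DataFrame({"source": ["M1"], "target": ["L1"], "source_db": ["starbase"]}),
    }
    return rl.build_interactome(frames, tf_registry=["T1"])
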