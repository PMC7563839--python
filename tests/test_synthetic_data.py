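"""Generator contracts: determinism, planted ground truth, statistical structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import rnaloops as rl
from rnaloops.core import LNCRNA, MIRNA, MRNA, TF, ConfigurationError
from rnaloops.degs import ThresholdConfig
from rnaloops.synthetic_data import DEFAULT_EDGE_DENSITY


def _cfg(**kw) -> rl.SimConfig:
    base = dict(
        n_tf=5, n_mirna=5, n_lncrna=10, n_mrna=10,
        edge_density={k: 0.2 for k in DEFAULT_EDGE_DENSITY},
        n_planted_ffl={"tf_mediated": 0, "mirna_mediated": 0, "mixed": 0},
        n_planted_cerna=0, n_samples=6, survival_n=40, seed=7,
    )
    base.update(kw)
    return rl.SimConfig(**base)


def test_zero_density_no_planting_gives_empty_tables():
    cfg = _cfg(edge_density={k: 0.0 for k in DEFAULT_EDGE_DENSITY})
    bg = rl.generate_background(cfg)
    assert all(len(df) == 0 for df in bg.tables.values())
    assert len(bg.tables) == 5
    assert bg.tf_registry == [f"TF_{i:05d}" for i in range(5)]


def test_same_seed_identical_tables_and_files(tmp_path):
    cfg = _cfg(seed=1, n_planted_ffl={"tf_mediated": 1, "mirna_mediated": 1, "mixed": 1}, n_planted_cerna=2)
    ds1 = rl.simulate_dataset(cfg)
    ds2 = rl.simulate_dataset(cfg)
    for cls in ds1.background.tables:
        pd.testing.assert_frame_equal(ds1.background.tables[cls], ds2.background.tables[cls])
    d1, d2 = tmp_path / "a", tmp_path / "b"
    rl.write_dataset(ds1, d1)
    rl.write_dataset(ds2, d2)
    for p1 in sorted(d1.iterdir()):
        assert p1.read_bytes() == (d2 / p1.name).read_bytes(), p1.name


def test_emitted_files_recount_matches_tables(tmp_path):
    """Independent recount of the written TSVs equals the in-memory edge counts."""
    cfg = _cfg()
    ds = rl.simulate_dataset(cfg, with_expression=False, with_survival=False)
    paths = rl.write_dataset(ds, tmp_path)
    for cls, df in ds.background.tables.items():
        lines = paths[cls].read_text().rstrip("\n").split("\n")
        assert len(lines) - 1 == len(df)  # minus header
        body = [ln.split("\t") for ln in lines[1:]]
        # no duplicate (source, target, db) rows; endpoints carry class prefixes
        assert len({tuple(r) for r in body}) == len(body)


def test_planted_demand_exceeding_universe_raises():
    with pytest.raises(ConfigurationError):
        rl.generate_background(_cfg(n_planted_ffl={"tf_mediated": 26, "mirna_mediated": 0, "mixed": 0}))
    with pytest.raises(ConfigurationError):
        rl.generate_background(_cfg(n_planted_cerna=11))
    with pytest.raises(ConfigurationError):
        rl.SimConfig(n_tf=-1)


def test_planted_edges_present_in_background_tables():
    cfg = _cfg(n_planted_ffl={"tf_mediated": 2, "mirna_mediated": 2, "mixed": 2}, n_planted_cerna=3)
    bg = rl.generate_background(cfg)
    pairs = {
        cls: set(zip(df["source"], df["target"])) for cls, df in bg.tables.items()
    }
    all_pairs = set().union(*pairs.values())
    for f in bg.planted_ffls:
        for e in f.edges():
            assert e in all_pairs, (f, e)
    for c in bg.planted_cerna:
        assert (c.mirna, c.lncrna) in pairs["mirna_lncrna"]
        assert (c.mirna, c.mrna) in pairs["mirna_mrna"]


def test_no_reverse_edge_between_planted_nonmutual_pairs():
    cfg = _cfg(
        edge_density={k: 0.5 for k in DEFAULT_EDGE_DENSITY},
        n_planted_ffl={"tf_mediated": 3, "mirna_mediated": 3, "mixed": 0},
    )
    bg = rl.generate_background(cfg)
    tf_mirna = set(zip(bg.tables["tf_mirna"]["source"], bg.tables["tf_mirna"]["target"]))
    mir_any = set(zip(bg.tables["mirna_mrna"]["source"], bg.tables["mirna_mrna"]["target"]))
    for f in bg.planted_ffls:
        if f.ffl_type == "tf_mediated":
            assert (f.mirna, f.tf) not in mir_any
        if f.ffl_type == "mirna_mediated":
            assert (f.tf, f.mirna) not in tf_mirna


class TestDETables:
    def test_null_case_all_fdr_above_threshold(self):
        cfg = _cfg(de_fraction={TF: 0.0, MRNA: 0.0, MIRNA: 0.0, LNCRNA: 0.0})
        bg = rl.generate_background(cfg)
        tables, truth = rl.generate_de_tables(cfg, bg)
        for cond, df in tables.items():
            assert (df["fdr"] >= 0.05).all()
            assert truth.de_genes[cond] == set()

    def test_planted_nodes_pass_thresholds_in_first_condition(self):
        cfg = _cfg(n_planted_ffl={"tf_mediated": 2, "mirna_mediated": 1, "mixed": 1}, n_planted_cerna=2)
        bg = rl.generate_background(cfg)
        tables, truth = rl.generate_de_tables(cfg, bg)
        thr = ThresholdConfig()
        first = tables[cfg.conditions[0]].set_index("gene_id")
        planted = {n for f in bg.planted_ffls for n in (f.tf, f.mirna, f.target)}
        planted |= {n for c in bg.planted_cerna for n in (c.mirna, c.lncrna, c.mrna)}
        for g in planted:
            row = first.loc[g]
            assert thr.passes(row["biotype"], row["log2fc"], row["fdr"]), g
            assert g in truth.de_genes[cfg.conditions[0]]

    def test_second_condition_excludes_planted_set(self):
        cfg = _cfg(
            de_fraction={TF: 0.0, MRNA: 0.0, MIRNA: 0.0, LNCRNA: 0.0},
            n_planted_ffl={"tf_mediated": 2, "mirna_mediated": 0, "mixed": 0},
        )
        bg = rl.generate_background(cfg)
        _, truth = rl.generate_de_tables(cfg, bg)
        c1, c2 = cfg.conditions
        assert truth.de_genes[c1] and not truth.de_genes[c2]
        assert truth.de_genes[c1] & truth.de_genes[c2] == set()

    def test_every_node_present_with_finite_stats(self):
        cfg = _cfg()
        bg = rl.generate_background(cfg)
        tables, _ = rl.generate_de_tables(cfg, bg)
        df = tables[cfg.conditions[0]]
        assert len(df) == 5 + 5 + 10 + 10
        assert np.isfinite(df["log2fc"]).all()
        assert df["fdr"].between(0, 1).all()


class TestExpression:
    def test_noise_free_pair_perfectly_correlated(self):
        cfg = _cfg(n_planted_ffl={"tf_mediated": 1, "mirna_mediated": 0, "mixed": 0},
                   n_planted_cerna=2, expr_pair_weight=1.0, expr_noise_sd=0.0)
        bg = rl.generate_background(cfg)
        expr = rl.generate_expression(cfg, bg)
        for c in bg.planted_cerna:
            r = np.corrcoef(expr.loc[c.lncrna], expr.loc[c.mrna])[0, 1]
            assert r == pytest.approx(1.0)
        assert (expr.to_numpy() >= 0).all()

    def test_independent_genes_mostly_uncorrelated(self):
        cfg = _cfg(n_lncrna=30, n_mrna=30, n_samples=200, seed=3)
        bg = rl.generate_background(cfg)
        expr = rl.generate_expression(cfg, bg)
        rng = np.random.default_rng(0)
        genes = list(expr.index)
        rs = []
        for _ in range(200):
            a, b = rng.choice(len(genes), 2, replace=False)
            rs.append(abs(np.corrcoef(expr.iloc[a], expr.iloc[b])[0, 1]))
        assert np.mean(np.array(rs) < 0.2) >= 0.95

    def test_degenerate_config_constant_rows(self):
        cfg = _cfg(expr_pair_weight=0.0, expr_noise_sd=0.0)
        bg = rl.generate_background(cfg)
        expr = rl.generate_expression(cfg, bg)
        assert (expr.std(axis=1) == 0).all()

    def test_too_few_samples_rejected(self):
        cfg = _cfg(n_samples=2)
        bg = rl.generate_background(cfg)
        with pytest.raises(ConfigurationError):
            rl.generate_expression(cfg, bg)


class TestSurvival:
    def test_effect_direction_recovered_at_large_hazard_ratio(self):
        hits = 0
        for seed in range(10):
            cfg = _cfg(survival_n=400, survival_hr=4.0, seed=seed)
            cohort, directions = rl.generate_survival(cfg, ["LNC_00000"], {"LNC_00000": 1})
            res = rl.survival_screen(cohort, "LNC_00000")
            if res.hazard_ratio > 1 and res.p_value < 0.05:
                hits += 1
        assert hits >= 9

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ConfigurationError):
            rl.generate_survival(_cfg(survival_n=5), ["LNC_00000"])

    def test_cohort_schema(self):
        cfg = _cfg()
        cohort, directions = rl.generate_survival(cfg, ["LNC_00000", "LNC_00001"])
        assert list(cohort.columns[:3]) == ["sample_id", "time", "event"]
        assert set(cohort["event"]) <= {0, 1}
        assert directions == {"LNC_00000": 1, "LNC_00001": 0}
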