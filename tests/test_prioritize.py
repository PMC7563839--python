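"""Prioritization statistics: exact hypergeometric tails, BH behaviour,
log-rank against hand/R-worked values, median-split determinism."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import rnaloops as rl
from rnaloops.core import DegenerateInputError
from rnaloops.prioritize import (
    GeneSetCollection,
    survival_screen_all,
    top_pathway_matrix,
)


def exact_hypergeom_tail(M: int, K: int, N: int, k: int) -> float:
    """Independent combinatorial oracle: P[X >= k] by direct summation."""
    num = sum(math.comb(K, j) * math.comb(M - K, N - j) for j in range(k, min(K, N) + 1))
    return num / math.comb(M, N)


class TestExpressedInAll:
    def test_all_positive_retained_zero_dropped(self):
        expr = pd.DataFrame({"g1": [1.0, 2.0, 3.0], "g2": [1.0, 0.0, 2.0]}).T
        assert rl.expressed_in_all(expr, ["g1", "g2"], min_value=0.0) == ["g1"]

    def test_missing_gene_excluded_with_warning(self, caplog):
        expr = pd.DataFrame({"g1": [1.0, 1.0]}).T
        import logging

        with caplog.at_level(logging.WARNING):
            assert rl.expressed_in_all(expr, ["g1", "absent"]) == ["g1"]
        assert any("absent" in r.message for r in caplog.records)

    def test_22_candidates_8_constructed_positive(self):
        """Only the genes detected in every sample survive the presence filter."""
        rng = np.random.default_rng(0)
        rows = {}
        for i in range(22):
            v = rng.uniform(1, 5, 10)
            if i >= 8:
                v[rng.integers(0, 10)] = 0.0  # silent in one sample
            rows[f"L{i:02d}"] = v
        expr = pd.DataFrame(rows).T
        kept = rl.expressed_in_all(expr, list(rows), min_value=0.0)
        assert kept == [f"L{i:02d}" for i in range(8)]


class TestCorrelation:
    def test_identical_and_anticorrelated_rows(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame({"l1": x, "m1": x, "m2": -x}).T
        out = rl.correlate_lncrna_mrna(expr, ["l1"], ["m1", "m2"])["l1"]
        r = dict(zip(out["mrna"], out["r"]))
        assert r["m1"] == pytest.approx(1.0)
        assert r["m2"] == pytest.approx(-1.0)

    def test_closed_form_toy_vectors(self):
        # r = 5.5 / sqrt(5 * 8.75) for x=[1,2,3,4], y=[1,3,2,5]
        expr = pd.DataFrame({"l1": [1.0, 2.0, 3.0, 4.0], "m1": [1.0, 3.0, 2.0, 5.0]}).T
        out = rl.correlate_lncrna_mrna(expr, ["l1"], ["m1"])["l1"]
        assert out["r"].iloc[0] == pytest.approx(5.5 / math.sqrt(5 * 8.75))

    def test_spearman_is_rank_based(self):
        expr = pd.DataFrame({"l1": [1.0, 2.0, 3.0, 4.0], "m1": [1.0, 10.0, 100.0, 1000.0]}).T
        out = rl.correlate_lncrna_mrna(expr, ["l1"], ["m1"], method="spearman")["l1"]
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_row_excluded_with_warning(self, caplog):
        import logging

        expr = pd.DataFrame({"l1": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]}).T
        with caplog.at_level(logging.WARNING):
            out = rl.correlate_lncrna_mrna(expr, ["l1"], ["flat"])
        assert len(out["l1"]) == 0
        assert any("constant" in r.message for r in caplog.records)

    def test_selection_by_top_n_and_r_min(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(6, 30)), index=["l1", "a", "b", "c", "d", "e"])
        top2 = rl.correlate_lncrna_mrna(expr, ["l1"], ["a", "b", "c", "d", "e"], top_n=2)["l1"]
        assert len(top2) == 2
        assert top2["r"].abs().is_monotonic_decreasing
        strict = rl.correlate_lncrna_mrna(expr, ["l1"], ["a", "b", "c", "d", "e"], r_min=0.99)["l1"]
        assert (strict["r"].abs() >= 0.99).all()


class TestORA:
    def _collection(self, M=100, sets=None):
        universe = frozenset(f"g{i}" for i in range(M))
        sets = sets or {"S": frozenset(f"g{i}" for i in range(10))}
        return GeneSetCollection(sets=sets, universe=universe)

    def test_full_containment_exact_tail(self):
        coll = self._collection()
        query = [f"g{i}" for i in range(5)]
        res = rl.hypergeometric_ora(query, coll)[0]
        assert res.overlap == 5
        assert res.p_value == pytest.approx(exact_hypergeom_tail(100, 10, 5, 5), rel=1e-12)

    @pytest.mark.parametrize("M,K,N,k", [(20, 5, 8, 2), (30, 12, 10, 6), (25, 4, 25, 4), (12, 6, 3, 0)])
    def test_matches_enumeration_on_small_universes(self, M, K, N, k):
        universe = frozenset(f"g{i}" for i in range(M))
        geneset = frozenset(f"g{i}" for i in range(K))
        query = [f"g{i}" for i in range(K - k, K)] + [f"g{i}" for i in range(K, K + N - k)]
        assert len(set(query)) == N and len(set(query) & geneset) == k
        coll = GeneSetCollection(sets={"S": geneset}, universe=universe)
        res = rl.hypergeometric_ora(query, coll)[0]
        assert res.p_value == pytest.approx(exact_hypergeom_tail(M, K, N, k), rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        coll = self._collection(sets={"S": frozenset({"g0", "g1"})})
        res = rl.hypergeometric_ora(["g50", "g51"], coll)[0]
        assert res.p_value == pytest.approx(1.0)

    def test_set_order_invariance(self):
        sets = {f"S{i}": frozenset(f"g{j}" for j in range(i, i + 5)) for i in range(6)}
        c1 = GeneSetCollection(sets=sets, universe=frozenset(f"g{i}" for i in range(100)))
        c2 = GeneSetCollection(sets=dict(reversed(list(sets.items()))), universe=c1.universe)
        q = [f"g{i}" for i in range(4)]
        assert rl.hypergeometric_ora(q, c1) == rl.hypergeometric_ora(q, c2)

    def test_empty_query_empty_result(self):
        assert rl.hypergeometric_ora([], self._collection()) == []

    def test_query_outside_universe_dropped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            res = rl.hypergeometric_ora(["g0", "not_a_gene"], self._collection())
        assert res[0].overlap == 1
        assert any("outside" in r.message for r in caplog.records)

    def test_bh_is_monotone_after_sorting_and_caps_at_max_raw(self):
        rng = np.random.default_rng(2)
        sets = {
            f"S{i}": frozenset(rng.choice([f"g{j}" for j in range(60)], size=8, replace=False))
            for i in range(12)
        }
        coll = GeneSetCollection(sets=sets, universe=frozenset(f"g{i}" for i in range(60)))
        res = rl.hypergeometric_ora([f"g{i}" for i in range(10)], coll)
        ps = [r.p_value for r in res]
        qs = [r.fdr_bh for r in res]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))  # sorted by p => BH monotone
        assert max(qs) == pytest.approx(max(ps))

    def test_gmt_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("pathA\tdesc\tg1\tg2\ng_short\npathB\tdesc\tg2\tg3\n")
        coll = GeneSetCollection.from_gmt(p)
        assert set(coll.sets) == {"pathA", "pathB"}
        assert coll.universe == frozenset({"g1", "g2", "g3"})

    def test_top_pathway_matrix_shape(self):
        res = {
            "l1": rl.hypergeometric_ora(["g0", "g1"], self._collection()),
            "l2": rl.hypergeometric_ora(["g50"], self._collection()),
        }
        m = top_pathway_matrix(res, top=10)
        assert set(m.columns) == {"l1", "l2"}
        assert ((m == 0) | (m == 1)).all().all()


class TestSurvivalScreen:
    def _cohort(self, times, events, expr):
        return pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(times))],
                             "time": times, "event": events, "gene": expr})

    def test_identical_groups_chi2_zero(self):
        cohort = self._cohort([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1], [1, 1, 1, 2, 2, 2])
        res = rl.survival_screen(cohort, "gene")
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)
        assert res.hazard_ratio == pytest.approx(1.0)

    def test_hand_worked_six_subject_table(self):
        """Frozen oracle: R survival::survdiff on the same 6-subject cohort
        gives chisq = 0.4848762603, obs = (3, 2), exp = (2.2333, 2.7667)."""
        cohort = self._cohort([1, 3, 5, 2, 4, 6], [1, 1, 1, 1, 1, 0], [1, 1, 1, 2, 2, 2])
        res = rl.survival_screen(cohort, "gene")
        assert res.logrank_chi2 == pytest.approx(0.4848762603, rel=1e-6)
        assert res.p_value == pytest.approx(0.4862218339, rel=1e-6)
        # HR = (O_high/E_high)/(O_low/E_low) = (2/2.766667)/(3/2.233333)
        assert res.hazard_ratio == pytest.approx((2 / 2.7666667) / (3 / 2.2333333), rel=1e-6)
        assert (res.n_low, res.n_high) == (3, 3)

    def test_median_ties_go_to_low_group(self):
        cohort = self._cohort([1, 2, 3, 4], [1, 1, 1, 1], [1.0, 1.0, 1.0, 2.0])
        res = rl.survival_screen(cohort, "gene")
        assert (res.n_low, res.n_high) == (3, 1)

    def test_zero_event_group_is_degenerate(self):
        cohort = self._cohort([1, 2, 3, 4], [1, 1, 0, 0], [1, 1, 2, 2])
        with pytest.raises(DegenerateInputError, match="gene"):
            rl.survival_screen(cohort, "gene")

    def test_all_censored_is_degenerate(self):
        cohort = self._cohort([1, 2, 3, 4], [0, 0, 0, 0], [1, 1, 2, 2])
        with pytest.raises(DegenerateInputError):
            rl.survival_screen(cohort, "gene")

    def test_screen_all_reports_degenerate_as_nan(self):
        cohort = self._cohort([1, 2, 3, 4], [1, 1, 1, 1], [1, 1, 2, 2])
        cohort["dead_gene"] = [1.0, 1.0, 1.0, 1.0]  # median split empty high arm
        out = survival_screen_all(cohort, ["gene", "dead_gene"])
        assert not math.isnan(out.loc[0, "hazard_ratio"])
        assert math.isnan(out.loc[1, "hazard_ratio"]) and out.loc[1, "note"]

    def test_high_expression_hazard_direction(self):
        cfg = rl.SimConfig(n_tf=2, n_mirna=2, n_lncrna=4, n_mrna=4, survival_n=400,
                           survival_hr=4.0, n_planted_ffl={}, n_planted_cerna=0, seed=3)
        cohort, _ = rl.generate_survival(cfg, ["g_up", "g_down"], {"g_up": 1, "g_down": -1})
        up = rl.survival_screen(cohort, "g_up")
        down = rl.survival_screen(cohort, "g_down")
        assert up.hazard_ratio > 1 and up.p_value < 0.01
        assert down.hazard_ratio < 1 and down.p_value < 0.01
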