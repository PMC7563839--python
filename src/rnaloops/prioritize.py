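"""Candidate lncRNA prioritization.

Four successive screens mirror how loop lncRNAs are triaged for
functional follow-up:

1. *expression presence* — keep lncRNAs detected in every sample;
2. *guilt by association* — rank mRNAs by |correlation| with each
   lncRNA and take the top-n (or those above a correlation floor) as its
   putative functional neighborhood;
3. *over-representation analysis (ORA)* — exact one-sided hypergeometric
   tail of the neighborhood against each pathway gene set, BH-adjusted
   across sets, top pathways reported per lncRNA;
4. *median-split survival screen* — split a cohort at the median
   expression of the gene, compare the two Kaplan-Meier arms by the
   log-rank test, and report the O/E hazard ratio
   HR = (O_high/E_high) / (O_low/E_low).

The log-rank chi-square and p-value come from lifelines; the
observed/expected tabulation behind the hazard ratio is computed here
(lifelines does not expose it).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DegenerateInputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- expression

def expressed_in_all(
    expression: pd.DataFrame, genes: Iterable[str], min_value: float = 0.0
) -> list[str]:
    """Genes whose expression exceeds ``min_value`` in every sample.

    Genes absent from the matrix are excluded with a warning.  Order of
    the input is preserved.
    """
    out = []
    for g in genes:
        if g not in expression.index:
            logger.warning("gene %s absent from expression matrix; excluded", g)
            continue
        if (expression.loc[g].to_numpy(float) > min_value).all():
            out.append(g)
    return out


def correlate_lncrna_mrna(
    expression: pd.DataFrame,
    lncrnas: Sequence[str],
    mrnas: Sequence[str],
    method: str = "pearson",
    top_n: int | None = 200,
    r_min: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-lncRNA mRNA association lists ranked by |correlation|.

    Selection is by ``top_n`` (default 200) or by ``r_min`` when given.
    Constant expression rows are excluded with a warning (their
    correlation is undefined).  Requires >= 3 samples.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate expression")

    def usable(gene: str) -> bool:
        if gene not in expression.index:
            logger.warning("gene %s absent from expression matrix; excluded", gene)
            return False
        if expression.loc[gene].to_numpy(float).std() == 0:
            logger.warning("gene %s has constant expression; excluded", gene)
            return False
        return True

    lncs = [g for g in lncrnas if usable(g)]
    ms = [g for g in mrnas if usable(g)]
    out: dict[str, pd.DataFrame] = {}
    if not lncs or not ms:
        return {g: pd.DataFrame(columns=["mrna", "r"]) for g in lncs}
    lmat = expression.loc[lncs].to_numpy(float)
    mmat = expression.loc[ms].to_numpy(float)
    if method == "spearman":
        lmat = np.apply_along_axis(stats.rankdata, 1, lmat)
        mmat = np.apply_along_axis(stats.rankdata, 1, mmat)
    lz = (lmat - lmat.mean(1, keepdims=True)) / lmat.std(1, keepdims=True)
    mz = (mmat - mmat.mean(1, keepdims=True)) / mmat.std(1, keepdims=True)
    rmat = lz @ mz.T / lmat.shape[1]
    for i, lnc in enumerate(lncs):
        df = pd.DataFrame({"mrna": ms, "r": rmat[i]})
        df = df[df["mrna"] != lnc]
        df = df.reindex(df["r"].abs().sort_values(ascending=False, kind="mergesort").index)
        if r_min is not None:
            df = df[df["r"].abs() >= r_min]
        elif top_n is not None:
            df = df.head(top_n)
        out[lnc] = df.reset_index(drop=True)
    return out


# ----------------------------------------------------------------------- ORA

@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets over a common gene universe."""

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if not genes <= self.universe:
                raise ValueError(f"gene set {name!r} not contained in the universe")

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None) -> "GeneSetCollection":
        """Read a GMT file (name <tab> description <tab> gene...).  Without an
        explicit universe, the union of all sets is used."""
        sets: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = frozenset(g for g in parts[2:] if g)
        uni = frozenset(universe) if universe is not None else frozenset().union(*sets.values())
        return cls(sets=sets, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    overlap: int
    set_size: int
    p_value: float
    fdr_bh: float


def hypergeometric_ora(
    gene_list: Iterable[str], gene_sets: GeneSetCollection, top: int | None = None
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per gene set.

    For a universe of M genes, a set of K and a query list of N with k in
    the overlap, p = P[X >= k], X ~ Hypergeom(M, K, N).  BH adjustment is
    applied across all sets of the collection; results are sorted by
    (p, pathway) and optionally truncated to the ``top`` smallest.
    Query ids outside the universe are dropped with a warning.
    """
    query = set(gene_list)
    outside = query - gene_sets.universe
    if outside:
        logger.warning("%d query id(s) outside the universe dropped", len(outside))
        query &= gene_sets.universe
    if not query:
        return []
    M = len(gene_sets.universe)
    N = len(query)
    names = sorted(gene_sets.sets)
    pvals, overlaps, sizes = [], [], []
    for name in names:
        genes = gene_sets.sets[name]
        k = len(query & genes)
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        pvals.append(min(p, 1.0))
        overlaps.append(k)
        sizes.append(K)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(n, o, s, p, q)
        for n, o, s, p, q in zip(names, overlaps, sizes, pvals, fdr)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results[:top] if top is not None else results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pathway, r.overlap, r.set_size, r.p_value, r.fdr_bh) for r in results],
        columns=["pathway", "overlap", "set_size", "p_value", "fdr_bh"],
    )


def top_pathway_matrix(
    per_lncrna: Mapping[str, list[EnrichmentResult]], top: int = 10
) -> pd.DataFrame:
    """Binary lncRNA x pathway membership matrix over each lncRNA's top
    pathways (the shared-pathway heatmap input)."""
    chosen: dict[str, set[str]] = {
        lnc: {r.pathway for r in res[:top]} for lnc, res in per_lncrna.items()
    }
    pathways = sorted(set().union(*chosen.values())) if chosen else []
    data = {lnc: [int(p in chosen[lnc]) for p in pathways] for lnc in sorted(chosen)}
    return pd.DataFrame(data, index=pd.Index(pathways, name="pathway"))


# ------------------------------------------------------------------ survival

@dataclass(frozen=True)
class SurvivalScreenResult:
    gene: str
    hazard_ratio: float  # high-expression arm vs low-expression arm
    logrank_chi2: float
    p_value: float
    n_low: int
    n_high: int


def _observed_expected(
    time: np.ndarray, event: np.ndarray, high: np.ndarray
) -> tuple[float, float, float, float]:
    """Log-rank O/E tabulation: returns (O_high, E_high, O_low, E_low)."""
    o_high = float(event[high].sum())
    o_low = float(event[~high].sum())
    e_high = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = float(((time == t) & (event == 1)).sum())
        n_high_t = float((at_risk & high).sum())
        e_high += d * n_high_t / n
    e_low = (o_high + o_low) - e_high
    return o_high, e_high, o_low, e_low


def survival_screen(
    cohort: pd.DataFrame, gene: str, time_col: str = "time", event_col: str = "event"
) -> SurvivalScreenResult:
    """Median-split Kaplan-Meier comparison for one gene.

    The cohort is split at the median expression of ``gene``; values
    equal to the median go to the low arm (deterministic tie policy).
    Both arms must contain at least one event, otherwise a
    :class:`DegenerateInputError` naming the gene is raised.  The hazard
    ratio is the O/E approximation (O_high/E_high)/(O_low/E_low).
    """
    if gene not in cohort.columns:
        raise KeyError(f"gene {gene!r} not in cohort table")
    expr = cohort[gene].to_numpy(float)
    time = cohort[time_col].to_numpy(float)
    event = cohort[event_col].to_numpy(int)
    med = float(np.median(expr))
    high = expr > med
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise DegenerateInputError(f"{gene}: median split produced an empty group")
    if event[high].sum() == 0 or event[~high].sum() == 0:
        raise DegenerateInputError(f"{gene}: a median-split group has zero events")
    o_h, e_h, o_l, e_l = _observed_expected(time, event, high)
    hr = (o_h / e_h) / (o_l / e_l)
    res = logrank_test(time[high], time[~high], event_observed_A=event[high], event_observed_B=event[~high])
    return SurvivalScreenResult(
        gene=gene,
        hazard_ratio=float(hr),
        logrank_chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        n_low=n_low,
        n_high=n_high,
    )


def survival_screen_all(
    cohort: pd.DataFrame, genes: Sequence[str], time_col: str = "time", event_col: str = "event"
) -> pd.DataFrame:
    """Screen several genes; degenerate genes are reported with NaN statistics."""
    rows = []
    for g in genes:
        try:
            r = survival_screen(cohort, g, time_col, event_col)
            rows.append((g, r.hazard_ratio, r.logrank_chi2, r.p_value, r.n_low, r.n_high, ""))
        except (DegenerateInputError, KeyError) as exc:
            rows.append((g, math.nan, math.nan, math.nan, 0, 0, str(exc)))
    return pd.DataFrame(
        rows,
        columns=["gene", "hazard_ratio", "logrank_chi2", "p_value", "n_low", "n_high", "note"],
    )
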