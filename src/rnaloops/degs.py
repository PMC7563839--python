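"""Differential-expression thresholding and DEG-set intersection.

DE statistics are computed upstream; this module only applies the
biotype-specific cut-offs (strict inequalities): FDR < 0.05 for every
biotype, |fold change| > 2 for mRNAs/TFs and > 1.5 for miRNAs and
lncRNAs.  The fold-change scale is configurable (log2 or linear) because
published threshold statements are ambiguous between the two readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BIOTYPES, DOWN, MRNA, TF, UP, AmbiguityError

DE_COLUMNS = ["gene_id", "biotype", "log2fc", "fdr"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Cut-offs for calling a record differentially expressed.

    fc_min_mrna applies to mRNAs and TFs, fc_min_ncrna to miRNAs and
    lncRNAs.  With ``fc_scale="log2"`` the fold-change thresholds are read
    on the log2 scale (|log2FC| > fc_min); with ``"linear"`` they are read
    on the linear scale (2**|log2FC| > fc_min).  All comparisons strict.
    """

    fdr_max: float = 0.05
    fc_min_mrna: float = 2.0
    fc_min_ncrna: float = 1.5
    fc_scale: str = "log2"

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must be in (0, 1]")
        if self.fc_min_mrna <= 0 or self.fc_min_ncrna <= 0:
            raise ValueError("fold-change thresholds must be positive")
        if self.fc_scale not in ("log2", "linear"):
            raise ValueError("fc_scale must be 'log2' or 'linear'")

    def fc_min(self, biotype: str) -> float:
        return self.fc_min_mrna if biotype in (MRNA, TF) else self.fc_min_ncrna

    def passes(self, biotype: str, log2fc: float, fdr: float) -> bool:
        if not fdr < self.fdr_max:
            return False
        mag = abs(log2fc) if self.fc_scale == "log2" else 2.0 ** abs(log2fc)
        return mag > self.fc_min(biotype)


@dataclass
class DESet:
    """Thresholded DEG set of one condition: id -> (biotype, direction)."""

    condition: str
    members: dict[str, tuple[str, str]] = field(default_factory=dict)

    def ids(self) -> set[str]:
        return set(self.members)

    def by_biotype(self, biotype: str) -> set[str]:
        return {g for g, (b, _) in self.members.items() if b == biotype}

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, b, d) for g, (b, d) in sorted(self.members.items())]
        return pd.DataFrame(rows, columns=["gene_id", "biotype", "direction"])


def filter_degs(
    records: pd.DataFrame,
    thresholds: ThresholdConfig | None = None,
    tf_registry: Iterable[str] = (),
    condition: str = "all",
) -> dict[str, DESet]:
    """Apply the DE thresholds to a statistics table.

    ``records`` needs columns gene_id, biotype, log2fc, fdr and optionally
    condition; without a condition column all rows are assigned the
    ``condition`` argument.  mRNA records whose gene is in the TF registry
    are relabeled TF (same fold-change threshold as mRNA).  Returns one
    :class:`DESet` per condition.
    """
    thresholds = thresholds or ThresholdConfig()
    df = records.copy()
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    if "condition" not in df.columns:
        df["condition"] = condition

    unknown = set(df["biotype"]) - set(BIOTYPES)
    if unknown:
        raise ValueError(f"unknown biotype(s) in DE table: {sorted(unknown)}")
    dup = df.duplicated(["gene_id", "condition"], keep=False)
    if dup.any():
        genes = sorted(df.loc[dup, "gene_id"].unique()[:10])
        raise AmbiguityError(f"duplicate (gene, condition) rows for: {genes}")
    fdr = pd.to_numeric(df["fdr"])
    lfc = pd.to_numeric(df["log2fc"])
    if ((fdr < 0) | (fdr > 1)).any():
        raise ValueError("fdr outside [0, 1]")
    if not np.isfinite(lfc).all():
        raise ValueError("non-finite log2fc")

    registry = frozenset(tf_registry)
    if registry:
        df.loc[(df["biotype"] == MRNA) & df["gene_id"].isin(registry), "biotype"] = TF

    out: dict[str, DESet] = {}
    if df.empty:
        return {condition: DESet(condition=condition)}
    for cond, sub in df.groupby("condition", sort=True):
        members: dict[str, tuple[str, str]] = {}
        for row in sub.itertuples(index=False):
            if thresholds.passes(row.biotype, float(row.log2fc), float(row.fdr)):
                members[row.gene_id] = (row.biotype, UP if float(row.log2fc) > 0 else DOWN)
        out[str(cond)] = DESet(condition=str(cond), members=members)
    return out


@dataclass
class IntersectionReport:
    """Cross-condition DEG overlap: Venn-style region counts per biotype."""

    membership: pd.DataFrame  # index gene_id; bool column per condition + biotype
    region_counts: pd.DataFrame  # columns: region (sorted '+'-joined conditions), biotype, count

    def region(self, conditions: Sequence[str]) -> set[str]:
        """Genes DE in exactly the given set of conditions."""
        want = "+".join(sorted(conditions))
        regions = self.membership[self._condition_cols()].apply(
            lambda r: "+".join(sorted(c for c in r.index if r[c])), axis=1
        )
        return set(self.membership.index[regions == want])

    def _condition_cols(self) -> list[str]:
        return [c for c in self.membership.columns if c != "biotype"]


def intersect_desets(desets: Sequence[DESet]) -> IntersectionReport:
    """Membership matrix and exact-region counts for >=2 DEG sets."""
    if len(desets) < 2:
        raise ValueError("need at least two DE sets to intersect")
    conditions = [d.condition for d in desets]
    if len(set(conditions)) != len(conditions):
        raise ValueError("duplicate condition labels")
    all_ids = sorted(set().union(*(d.ids() for d in desets)))
    data = {d.condition: [g in d for g in all_ids] for d in desets}
    biotype = []
    for g in all_ids:
        for d in desets:
            if g in d:
                biotype.append(d.members[g][0])
                break
    membership = pd.DataFrame(data, index=pd.Index(all_ids, name="gene_id"))
    membership["biotype"] = biotype
    if all_ids:
        cond_cols = [d.condition for d in desets]
        region = membership[cond_cols].apply(
            lambda r: "+".join(sorted(c for c in cond_cols if r[c])), axis=1
        )
        counts = (
            pd.DataFrame({"region": region, "biotype": membership["biotype"]})
            .groupby(["region", "biotype"], sort=True)
            .size()
            .reset_index(name="count")
        )
    else:
        counts = pd.DataFrame(columns=["region", "biotype", "count"])
    return IntersectionReport(membership=membership, region_counts=counts)


def pairwise_intersection(a: DESet, b: DESet) -> set[str]:
    return a.ids() & b.ids()


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    return df


def write_deset(deset: DESet, path: str | Path) -> None:
    deset.to_frame().to_csv(path, sep="\t", index=False)
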