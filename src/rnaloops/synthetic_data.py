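"""Synthetic regulatory-network benchmark generator.

Emulates the inputs of the analysis with known ground truth: a
biotype-partitioned node universe at the scale of a genome-wide
compendium (default 107 TFs, 1851 miRNAs, 10,970 lncRNAs, 18,812
mRNAs), sparse per-class regulator->target association tables totalling
~1.1M edges, per-condition differential-expression statistics with
guaranteed threshold separation, an expression matrix with correlated
planted ceRNA partners, and a survival cohort with a group-dependent
hazard.

Planted structure
-----------------
Feed-forward loops of all three types and ceRNA triples are planted on
unique (TF, miRNA) regulator pairs; their edges are injected into the
association tables and their nodes forced into the DE set of the first
condition, so a correct pipeline must recover 100% of them.  Randomly
drawn edges that would reverse-connect a planted TF-mediated or
miRNA-mediated regulator pair are removed — otherwise chance mutual
regulation would reclassify a planted loop as mixed and typed recall
would be impossible by construction.

Identifiers are opaque strings with biotype prefixes (``TF_``,
``MIR_``, ``LNC_``, ``MRNA_``).  All randomness flows from
``numpy.random.default_rng`` seeded from ``SimConfig.seed``; equal
configurations produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cerna import CeRNATriple
from .core import LNCRNA, MIRNA, MRNA, TF, ConfigurationError
from .degs import ThresholdConfig
from .motifs import FFLMotif

#: default per-class Bernoulli edge densities; at the default node universe
#: these give an expected ~1.145M-edge background network.
DEFAULT_EDGE_DENSITY = {
    "tf_mrna": 0.15,
    "tf_lncrna": 0.08,
    "tf_mirna": 0.10,
    "mirna_mrna": 0.014,
    "mirna_lncrna": 0.0118,
}

DEFAULT_PLANTED_FFL = {"tf_mediated": 20, "mirna_mediated": 20, "mixed": 20}

#: DE fractions per biotype, matching the order of magnitude of a strongly
#: responding condition (~600 mRNAs, ~50 miRNAs, ~200 lncRNAs genome-wide).
DEFAULT_DE_FRACTION = {TF: 0.033, MRNA: 0.033, MIRNA: 0.028, LNCRNA: 0.019}


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults define the benchmark conditions."""

    n_tf: int = 107
    n_mirna: int = 1851
    n_lncrna: int = 10970
    n_mrna: int = 18812
    edge_density: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EDGE_DENSITY))
    n_planted_ffl: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_PLANTED_FFL))
    n_planted_cerna: int = 10
    de_fraction: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DE_FRACTION))
    lfc_effect_size: float = 1.0  # log2 units added beyond the DE threshold
    n_samples: int = 24
    survival_n: int = 400
    survival_hr: float = 2.0
    conditions: tuple[str, ...] = ("sensitive", "resistant")
    duplicate_fraction: float = 0.05  # miRNA->lncRNA rows re-emitted under a 2nd database label
    expr_pair_weight: float = 1.0
    expr_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_mirna", "n_lncrna", "n_mrna", "n_planted_cerna", "n_samples", "survival_n"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for k, v in self.edge_density.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"edge_density[{k!r}] must be in [0, 1]")
        for k, v in self.de_fraction.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"de_fraction[{k!r}] must be in [0, 1]")
        if any(v < 0 for v in self.n_planted_ffl.values()):
            raise ConfigurationError("n_planted_ffl counts must be >= 0")
        if self.survival_hr <= 0:
            raise ConfigurationError("survival_hr must be > 0")
        if not (0.0 <= self.duplicate_fraction <= 1.0):
            raise ConfigurationError("duplicate_fraction must be in [0, 1]")
        if not self.conditions:
            raise ConfigurationError("need at least one condition label")


@dataclass
class Background:
    """Generated association tables plus the planted structures behind them."""

    tables: dict[str, pd.DataFrame]  # edge_class -> (source, target, source_db)
    tf_registry: list[str]
    tf_ids: list[str]
    mirna_ids: list[str]
    lncrna_ids: list[str]
    mrna_ids: list[str]
    planted_ffls: list[FFLMotif]
    planted_cerna: list[CeRNATriple]


@dataclass
class GroundTruth:
    """What the pipeline must recover from a generated dataset."""

    planted_ffls: list[FFLMotif]
    planted_cerna: list[CeRNATriple]
    de_genes: dict[str, set[str]]
    survival_effect_direction: dict[str, int] = field(default_factory=dict)


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:05d}" for i in range(n)]


def _sample_class(rng: np.random.Generator, sources: Sequence[str], targets: Sequence[str], p: float) -> pd.DataFrame:
    cols = {"source": [], "target": []}
    if p > 0 and sources and targets:
        tarr = np.array(targets, dtype=object)
        src_parts, tgt_parts = [], []
        for s in sources:
            mask = rng.random(len(tarr)) < p
            k = int(mask.sum())
            if k:
                src_parts.append(np.full(k, s, dtype=object))
                tgt_parts.append(tarr[mask])
        if src_parts:
            return pd.DataFrame({"source": np.concatenate(src_parts), "target": np.concatenate(tgt_parts)})
    return pd.DataFrame(cols, dtype=object)


def _plant_structures(
    rng: np.random.Generator, config: SimConfig
) -> tuple[list[FFLMotif], list[CeRNATriple]]:
    tf_ids = _ids("TF", config.n_tf)
    mir_ids = _ids("MIR", config.n_mirna)
    lnc_ids = _ids("LNC", config.n_lncrna)
    mrna_ids = _ids("MRNA", config.n_mrna)

    order = ["tf_mediated", "mirna_mediated", "mixed"]
    counts = [int(config.n_planted_ffl.get(t, 0)) for t in order]
    total = sum(counts)
    if total > 0 and (config.n_tf == 0 or config.n_mirna == 0):
        raise ConfigurationError("cannot plant FFLs without TFs and miRNAs")
    if total > config.n_tf * config.n_mirna:
        raise ConfigurationError(
            f"{total} planted FFLs exceed the {config.n_tf}x{config.n_mirna} (TF, miRNA) pair universe"
        )
    n_lnc_targets = (total + 1) // 2
    n_mrna_targets = total // 2
    if n_lnc_targets > config.n_lncrna or n_mrna_targets > config.n_mrna:
        raise ConfigurationError("planted FFL targets exceed the target universes")

    ffls: list[FFLMotif] = []
    if total:
        pair_idx = rng.choice(config.n_tf * config.n_mirna, size=total, replace=False)
        lnc_t = list(rng.choice(np.array(lnc_ids, dtype=object), size=n_lnc_targets, replace=False))
        mrna_t = list(rng.choice(np.array(mrna_ids, dtype=object), size=n_mrna_targets, replace=False))
        k = 0
        for ffl_type, n in zip(order, counts):
            for _ in range(n):
                t = tf_ids[pair_idx[k] // config.n_mirna]
                m = mir_ids[pair_idx[k] % config.n_mirna]
                if k % 2 == 0:
                    target, tbio = lnc_t[k // 2], LNCRNA
                else:
                    target, tbio = mrna_t[k // 2], MRNA
                ffls.append(FFLMotif(t, m, str(target), tbio, ffl_type))
                k += 1

    cernas: list[CeRNATriple] = []
    if config.n_planted_cerna:
        if config.n_mirna == 0 or config.n_planted_cerna > min(config.n_lncrna, config.n_mrna):
            raise ConfigurationError("planted ceRNA triples exceed the node universe")
        if ffls:
            mir_pool = sorted({f.mirna for f in ffls})
        else:
            mir_pool = mir_ids
        lncs = rng.choice(np.array(lnc_ids, dtype=object), size=config.n_planted_cerna, replace=False)
        mrnas = rng.choice(np.array(mrna_ids, dtype=object), size=config.n_planted_cerna, replace=False)
        for i in range(config.n_planted_cerna):
            cernas.append(CeRNATriple(mir_pool[i % len(mir_pool)], str(lncs[i]), str(mrnas[i])))
    return ffls, cernas


def generate_background(config: SimConfig) -> Background:
    """Generate the five per-class association tables and the TF registry.

    Tables may contain the same (source, target) pair under two database
    labels (a fraction of miRNA->lncRNA rows is re-emitted as a second,
    'predicted' source) to exercise downstream deduplication; within one
    label pairs are unique.  miRNA->TF regulations are emitted inside the
    miRNA->mRNA table targeting registry ids, as in CLIP target lists.
    """
    rng = np.random.default_rng([config.seed, 1])
    tf_ids = _ids("TF", config.n_tf)
    mir_ids = _ids("MIR", config.n_mirna)
    lnc_ids = _ids("LNC", config.n_lncrna)
    mrna_ids = _ids("MRNA", config.n_mrna)

    ffls, cernas = _plant_structures(rng, config)

    dens = {k: float(config.edge_density.get(k, 0.0)) for k in DEFAULT_EDGE_DENSITY}
    raw = {
        "tf_mrna": _sample_class(rng, tf_ids, mrna_ids, dens["tf_mrna"]),
        "tf_lncrna": _sample_class(rng, tf_ids, lnc_ids, dens["tf_lncrna"]),
        "tf_mirna": _sample_class(rng, tf_ids, mir_ids, dens["tf_mirna"]),
        "mirna_mrna": _sample_class(rng, mir_ids, mrna_ids + tf_ids, dens["mirna_mrna"]),
        "mirna_lncrna": _sample_class(rng, mir_ids, lnc_ids, dens["mirna_lncrna"]),
    }

    # strip random edges that would flip the type of a planted loop
    forbid_m2t = {(f.mirna, f.tf) for f in ffls if f.ffl_type == "tf_mediated"}
    forbid_t2m = {(f.tf, f.mirna) for f in ffls if f.ffl_type == "mirna_mediated"}
    if forbid_m2t and len(raw["mirna_mrna"]):
        keys = list(zip(raw["mirna_mrna"]["source"], raw["mirna_mrna"]["target"]))
        raw["mirna_mrna"] = raw["mirna_mrna"][[k not in forbid_m2t for k in keys]]
    if forbid_t2m and len(raw["tf_mirna"]):
        keys = list(zip(raw["tf_mirna"]["source"], raw["tf_mirna"]["target"]))
        raw["tf_mirna"] = raw["tf_mirna"][[k not in forbid_t2m for k in keys]]

    add: dict[str, list[tuple[str, str]]] = {k: [] for k in raw}
    for f in ffls:
        target_class = "tf_lncrna" if f.target_biotype == LNCRNA else "tf_mrna"
        mir_class = "mirna_lncrna" if f.target_biotype == LNCRNA else "mirna_mrna"
        add[target_class].append((f.tf, f.target))
        add[mir_class].append((f.mirna, f.target))
        if f.ffl_type in ("tf_mediated", "mixed"):
            add["tf_mirna"].append((f.tf, f.mirna))
        if f.ffl_type in ("mirna_mediated", "mixed"):
            add["mirna_mrna"].append((f.mirna, f.tf))
    for c in cernas:
        add["mirna_lncrna"].append((c.mirna, c.lncrna))
        add["mirna_mrna"].append((c.mirna, c.mrna))

    source_db = {
        "tf_mrna": "chipbase",
        "tf_lncrna": "chipbase",
        "tf_mirna": "chipbase",
        "mirna_mrna": "starbase",
        "mirna_lncrna": "starbase",
    }
    tables: dict[str, pd.DataFrame] = {}
    for cls, df in raw.items():
        if add[cls]:
            df = pd.concat([df, pd.DataFrame(add[cls], columns=["source", "target"])], ignore_index=True)
        df = df.drop_duplicates(["source", "target"]).copy()
        df["source_db"] = source_db[cls]
        if cls == "mirna_lncrna" and config.duplicate_fraction > 0 and len(df):
            n_dup = int(len(df) * config.duplicate_fraction)
            if n_dup:
                idx = rng.choice(len(df), size=n_dup, replace=False)
                dup = df.iloc[np.sort(idx)].copy()
                dup["source_db"] = "mircode"
                df = pd.concat([df, dup], ignore_index=True)
        df = df.sort_values(["source", "target", "source_db"], kind="mergesort").reset_index(drop=True)
        tables[cls] = df

    return Background(
        tables=tables,
        tf_registry=list(tf_ids),
        tf_ids=tf_ids,
        mirna_ids=mir_ids,
        lncrna_ids=lnc_ids,
        mrna_ids=mrna_ids,
        planted_ffls=ffls,
        planted_cerna=cernas,
    )


def generate_de_tables(
    config: SimConfig, background: Background, thresholds: ThresholdConfig | None = None
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-condition DE statistics tables with guaranteed threshold separation.

    Every node id appears in every condition's table.  DE genes get
    FDR ~ U(0, 0.05) and |log2FC| = threshold + |N(0, effect)|; non-DE
    genes get FDR ~ U(0.05, 1) and |log2FC| strictly below threshold.
    Planted-structure nodes are DE in the first condition and excluded
    from the DE draw of the others.
    """
    thresholds = thresholds or ThresholdConfig()
    rng = np.random.default_rng([config.seed, 2])
    ids: list[str] = background.tf_ids + background.mirna_ids + background.lncrna_ids + background.mrna_ids
    biotypes: list[str] = (
        [TF] * len(background.tf_ids)
        + [MIRNA] * len(background.mirna_ids)
        + [LNCRNA] * len(background.lncrna_ids)
        + [MRNA] * len(background.mrna_ids)
    )
    planted_nodes: set[str] = set()
    for f in background.planted_ffls:
        planted_nodes.update((f.tf, f.mirna, f.target))
    for c in background.planted_cerna:
        planted_nodes.update((c.mirna, c.lncrna, c.mrna))

    thr = np.array([thresholds.fc_min(b) for b in biotypes])
    frac = np.array([float(config.de_fraction.get(b, 0.0)) for b in biotypes])
    planted_mask = np.array([g in planted_nodes for g in ids])

    tables: dict[str, pd.DataFrame] = {}
    de_genes: dict[str, set[str]] = {}
    for j, cond in enumerate(config.conditions):
        de = rng.random(len(ids)) < frac
        if j == 0:
            de |= planted_mask
        else:
            de &= ~planted_mask
        n = len(ids)
        fdr = np.where(de, rng.uniform(0.0, thresholds.fdr_max, n), rng.uniform(thresholds.fdr_max, 1.0, n))
        sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        lfc_de = sign * (thr + np.abs(rng.normal(0.0, config.lfc_effect_size, n)) + 1e-9)
        lfc_null = rng.uniform(-1.0, 1.0, n) * thr * 0.999
        lfc = np.where(de, lfc_de, lfc_null)
        tables[cond] = pd.DataFrame(
            {"gene_id": ids, "biotype": biotypes, "log2fc": lfc, "fdr": fdr}
        )
        de_genes[cond] = {g for g, flag in zip(ids, de) if flag}

    truth = GroundTruth(
        planted_ffls=list(background.planted_ffls),
        planted_cerna=list(background.planted_cerna),
        de_genes=de_genes,
    )
    return tables, truth


def generate_expression(config: SimConfig, background: Background) -> pd.DataFrame:
    """Non-negative expression matrix (lncRNAs + mRNAs) x samples.

    Log-expression is N(0, expr_noise_sd) noise; each planted ceRNA
    (lncRNA, mRNA) pair additionally shares a latent N(0, 1) factor with
    weight ``expr_pair_weight``, giving the pair an expected positive
    correlation.  With weight 1 and zero noise a pair is perfectly
    correlated; with zero weight and zero noise rows are constant (and
    flagged for exclusion downstream).
    """
    if config.n_samples < 3:
        raise ConfigurationError("n_samples must be >= 3 for downstream correlation")
    rng = np.random.default_rng([config.seed, 3])
    genes = background.lncrna_ids + background.mrna_ids
    pos = {g: i for i, g in enumerate(genes)}
    log_expr = config.expr_noise_sd * rng.standard_normal((len(genes), config.n_samples))
    for c in background.planted_cerna:
        f = rng.standard_normal(config.n_samples)
        for g in (c.lncrna, c.mrna):
            if g in pos:
                log_expr[pos[g]] += config.expr_pair_weight * f
    expr = np.exp(log_expr)
    cols = [f"S{i+1:02d}" for i in range(config.n_samples)]
    return pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=cols)


def generate_survival(
    config: SimConfig,
    gene_ids: Sequence[str],
    effect_directions: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Survival cohort with exponential event times and uniform censoring.

    Each sample's hazard is ``0.1 * survival_hr ** sum_g(dir_g * high_g)``
    over the effect genes, where ``high_g`` indicates expression above the
    cohort median of gene g.  By default the first listed gene carries a
    +1 effect and the rest are null.  Censoring times are U(0, 15),
    independent of everything else.
    """
    if config.survival_n < 10:
        raise ConfigurationError("survival_n must be >= 10")
    rng = np.random.default_rng([config.seed, 4])
    gene_ids = list(gene_ids)
    if effect_directions is None:
        effect_directions = {gene_ids[0]: 1} if gene_ids else {}
    directions = {g: int(effect_directions.get(g, 0)) for g in gene_ids}
    n = config.survival_n
    base_hazard = 0.1
    expr = {g: rng.lognormal(0.0, 1.0, n) for g in gene_ids}
    log_mult = np.zeros(n)
    for g, d in directions.items():
        if d:
            high = expr[g] > np.median(expr[g])
            log_mult += d * high * np.log(config.survival_hr)
    hazard = base_hazard * np.exp(log_mult)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, 15.0, n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    df = pd.DataFrame({"sample_id": [f"P{i+1:04d}" for i in range(n)], "time": observed, "event": event})
    for g in gene_ids:
        df[g] = expr[g]
    return df, directions


@dataclass
class SimulatedDataset:
    """Everything one benchmark run produces, in memory."""

    config: SimConfig
    background: Background
    de_tables: dict[str, pd.DataFrame]
    ground_truth: GroundTruth
    expression: pd.DataFrame
    survival: pd.DataFrame


def simulate_dataset(config: SimConfig, with_expression: bool = True, with_survival: bool = True) -> SimulatedDataset:
    """Generate a complete dataset: background, DE tables, expression, survival.

    Survival candidate genes are the planted loop/ceRNA lncRNAs (up to
    10); effect directions alternate +1/-1 across them so both prognostic
    signs occur.
    """
    background = generate_background(config)
    de_tables, truth = generate_de_tables(config, background)
    expression = generate_expression(config, background) if with_expression else pd.DataFrame()
    survival = pd.DataFrame()
    if with_survival and config.survival_n >= 10:
        candidates = sorted(
            {f.target for f in background.planted_ffls if f.target_biotype == LNCRNA}
            | {c.lncrna for c in background.planted_cerna}
        )[:10]
        if candidates:
            survival, directions = generate_survival(
                config, candidates, {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(candidates)}
            )
            truth.survival_effect_direction = directions
    return SimulatedDataset(config, background, de_tables, truth, expression, survival)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all dataset files (TSV/JSON) under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cls, df in dataset.background.tables.items():
        p = outdir / f"{cls}.tsv"
        df.rename(columns={"source": "source_id", "target": "target_id"}).to_csv(p, sep="\t", index=False)
        paths[cls] = p
    p = outdir / "tf_registry.txt"
    p.write_text("".join(f"{g}\n" for g in dataset.background.tf_registry))
    paths["tf_registry"] = p
    for cond, df in dataset.de_tables.items():
        p = outdir / f"de_{cond}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"de_{cond}"] = p
    if len(dataset.expression):
        p = outdir / "expression.tsv"
        dataset.expression.to_csv(p, sep="\t")
        paths["expression"] = p
    if len(dataset.survival):
        p = outdir / "survival.tsv"
        dataset.survival.to_csv(p, sep="\t", index=False)
        paths["survival"] = p
    truth = dataset.ground_truth
    p = outdir / "ground_truth.json"
    p.write_text(
        json.dumps(
            {
                "planted_ffls": [
                    {"tf": f.tf, "mirna": f.mirna, "target": f.target,
                     "target_biotype": f.target_biotype, "ffl_type": f.ffl_type}
                    for f in truth.planted_ffls
                ],
                "planted_cerna": [
                    {"mirna": c.mirna, "lncrna": c.lncrna, "mrna": c.mrna} for c in truth.planted_cerna
                ],
                "de_genes": {k: sorted(v) for k, v in truth.de_genes.items()},
                "survival_effect_direction": truth.survival_effect_direction,
            },
            indent=1,
        )
    )
    paths["ground_truth"] = p
    return paths
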