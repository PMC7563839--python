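"""End-to-end pipeline orchestration.

Stages run in a fixed order — build-net, filter-degs, then per
condition subnet / ffl / cerna, then prioritize — and exchange data
exclusively through plain files (TSV / GraphML / JSON), so every stage
can be re-run from its predecessor's outputs alone.  A run manifest
records the package version, the seed, a sha256 checksum of every input
and the row count of every artifact written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cerna import cerna_network_export, find_cerna, write_triples
from .core import BIOTYPES, PipelineError
from .degs import ThresholdConfig, filter_degs, intersect_desets, read_de_table, write_deset
from .interactome import load_interactome_tables, summarize
from .motifs import enumerate_ffls, export_hive, lncrna_loop_summary, summarize_motifs, write_motifs
from .prioritize import (
    GeneSetCollection,
    correlate_lncrna_mrna,
    enrichment_to_frame,
    expressed_in_all,
    hypergeometric_ora,
    survival_screen_all,
    top_pathway_matrix,
)
from .subnetwork import assign_edge_signs, degree_report, extract_subnetwork

logger = logging.getLogger(__name__)

STAGES = ("build-net", "filter-degs", "subnet", "ffl", "cerna", "prioritize")


@dataclass
class PipelineConfig:
    """File-level configuration of a full run."""

    associations: dict[str, list[tuple[str, str]]]  # edge_class -> [(path, source_db)]
    tf_registry: str
    de_tables: dict[str, str]  # condition -> DE table path
    outdir: str
    expression: str | None = None
    gene_sets: str | None = None
    survival: str | None = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    mixed_exclusive: bool = True
    corr_min: float | None = None  # optional |r| filter on subnetwork edges
    top_n: int = 200
    method: str = "pearson"
    min_expression: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = ThresholdConfig(**raw.get("thresholds", {}))
        assoc = {
            cls_name: [(e["path"], e.get("source_db", "unknown")) for e in entries]
            for cls_name, entries in raw.get("associations", {}).items()
        }
        kwargs = {k: v for k, v in raw.items() if k not in ("thresholds", "associations")}
        return cls(associations=assoc, thresholds=thr, **kwargs)

    def input_paths(self) -> list[str]:
        paths = [p for entries in self.associations.values() for p, _ in entries]
        paths.append(self.tf_registry)
        paths.extend(self.de_tables.values())
        for p in (self.expression, self.gene_sets, self.survival):
            if p:
                paths.append(p)
        return paths

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        d["associations"] = {
            k: [{"path": p, "source_db": db} for p, db in v] for k, v in self.associations.items()
        }
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _tsv_rows(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)  # minus header


def validate_inputs(config: PipelineConfig) -> list[dict[str, Any]]:
    """Schema-check every input file; returns line-level diagnostics
    (empty list when everything is well-formed).  Report-only: never raises."""
    diags: list[dict[str, Any]] = []

    def diag(file: str, line: int | None, message: str) -> None:
        diags.append({"file": str(file), "line": line, "message": message})

    for edge_class, entries in config.associations.items():
        for path, _db in entries:
            p = Path(path)
            if not p.exists():
                diag(path, None, "file not found")
                continue
            try:
                df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
            except Exception as exc:  # noqa: BLE001
                diag(path, None, f"unreadable: {exc}")
                continue
            if df.shape[1] < 2:
                diag(path, 1, "expected at least 2 tab-separated columns")
                continue
            src, tgt = df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()
            for i in df.index[(src == "") | (tgt == "")][:50]:
                diag(path, int(i) + 2, "empty identifier")
            for i in df.index[src == tgt][:50]:
                diag(path, int(i) + 2, f"self-loop {src[i]!r}")
    if not Path(config.tf_registry).exists():
        diag(config.tf_registry, None, "file not found")
    for cond, path in config.de_tables.items():
        p = Path(path)
        if not p.exists():
            diag(path, None, "file not found")
            continue
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        missing = {"gene_id", "biotype", "log2fc", "fdr"} - set(df.columns)
        if missing:
            diag(path, 1, f"missing column(s) {sorted(missing)}")
            continue
        for col in ("log2fc", "fdr"):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & (df[col] != "")
            for i in df.index[bad][:50]:
                diag(path, int(i) + 2, f"non-numeric {col} value {df.at[i, col]!r}")
        unknown = ~df["biotype"].isin(BIOTYPES)
        for i in df.index[unknown][:50]:
            diag(path, int(i) + 2, f"unknown biotype token {df.at[i, 'biotype']!r}")
    for label, path in (("expression", config.expression), ("gene_sets", config.gene_sets), ("survival", config.survival)):
        if path and not Path(path).exists():
            diag(path, None, f"{label} file not found")
    return diags


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns (and writes) the run manifest.

    Any missing input aborts before outputs are written, naming the path.
    A stage failure writes a ``FAILED`` marker naming the stage and keeps
    whatever partial outputs exist.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        (outdir / "error.log").write_text("missing input path(s):\n" + "\n".join(missing) + "\n")
        raise PipelineError(f"missing input path(s): {missing}")

    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {p: _sha256(p) for p in config.input_paths()},
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, path: Path) -> None:
        manifest["outputs"][path.name] = {"stage": stage, "rows": _tsv_rows(path)}

    stage = "build-net"
    try:
        inter = load_interactome_tables(config.associations, config.tf_registry)
        report = summarize(inter)
        p = outdir / "interactome_edges.tsv"
        inter.edges.to_csv(p, sep="\t", index=False)
        record(stage, p)
        p = outdir / "composition.tsv"
        report.to_frame().to_csv(p, sep="\t", index=False)
        record(stage, p)
        inter.write_sif(outdir / "interactome.sif")
        manifest["stages"][stage] = {
            "nodes": report.node_counts,
            "edges": report.total_edges,
            "edge_classes": report.edge_counts,
        }

        stage = "filter-degs"
        registry = [g for g in Path(config.tf_registry).read_text().split() if g]
        desets = {}
        for cond, path in sorted(config.de_tables.items()):
            table = read_de_table(path)
            desets[cond] = filter_degs(table, config.thresholds, registry, condition=cond)[cond]
            p = outdir / f"degs_{cond}.tsv"
            write_deset(desets[cond], p)
            record(stage, p)
        if len(desets) >= 2:
            report_x = intersect_desets(list(desets.values()))
            p = outdir / "deg_intersection.tsv"
            report_x.region_counts.to_csv(p, sep="\t", index=False)
            record(stage, p)
        manifest["stages"][stage] = {cond: len(d) for cond, d in desets.items()}

        expression = None
        if config.expression:
            expression = pd.read_csv(config.expression, sep="\t", index_col=0)

        loop_lncrnas: set[str] = set()
        for cond, deset in sorted(desets.items()):
            stage = "subnet"
            corr = (expression, config.corr_min) if (config.corr_min is not None and expression is not None) else None
            sub = extract_subnetwork(inter, deset, corr)
            assign_edge_signs(sub, expression)
            sub.write_graphml(outdir / f"subnet_{cond}.graphml")
            p = outdir / f"subnet_{cond}_edges.tsv"
            sub.edge_list().to_csv(p, sep="\t", index=False)
            record(stage, p)
            deg = degree_report(sub)
            p = outdir / f"degrees_{cond}.tsv"
            deg.table.to_csv(p, sep="\t", index=False)
            record(stage, p)
            manifest["stages"].setdefault(stage, {})[cond] = {"nodes": sub.n_nodes, "edges": sub.n_edges}

            stage = "ffl"
            motifs = enumerate_ffls(sub, mixed_exclusive=config.mixed_exclusive)
            p = outdir / f"motifs_{cond}.tsv"
            write_motifs(motifs, p)
            record(stage, p)
            summ = summarize_motifs(motifs)
            p = outdir / f"motif_summary_{cond}.tsv"
            summ.to_frame().to_csv(p, sep="\t", index=False)
            record(stage, p)
            lnc_summ = lncrna_loop_summary(motifs)
            loop_lncrnas |= set(lnc_summ.target_ids)
            signs = {
                (u, v): d.get("sign", "unsigned") for u, v, d in sub.graph.edges(data=True)
            }
            axes, hive_edges = export_hive(motifs, signs)
            axes.to_csv(outdir / f"hive_axes_{cond}.tsv", sep="\t", index=False)
            hive_edges.to_csv(outdir / f"hive_edges_{cond}.tsv", sep="\t", index=False)
            manifest["stages"].setdefault(stage, {})[cond] = {
                "motifs": summ.n_loops,
                "by_type": summ.count_by_type(),
                "lncrna_loops": lnc_summ.n_loops,
                "lncrna_targets": len(lnc_summ.target_ids),
            }

            stage = "cerna"
            triples = find_cerna(sub, sorted(summ.mirna_roster) if summ.mirna_roster else [])
            p = outdir / f"cerna_{cond}.tsv"
            write_triples(triples, p, expression)
            record(stage, p)
            star = cerna_network_export(triples, sub)
            p = outdir / f"cerna_star_{cond}.tsv"
            star.to_csv(p, sep="\t", index=False)
            record(stage, p)
            manifest["stages"].setdefault(stage, {})[cond] = {"triples": len(triples)}

        stage = "prioritize"
        if expression is not None and loop_lncrnas:
            candidates = expressed_in_all(expression, sorted(loop_lncrnas), config.min_expression)
            pd.Series(candidates, name="lncrna").to_csv(outdir / "expressed_lncrnas.tsv", sep="\t", index=False)
            mrnas = [g for g in expression.index if g not in loop_lncrnas]
            assoc = correlate_lncrna_mrna(
                expression, candidates, mrnas, method=config.method, top_n=config.top_n
            )
            info: dict[str, Any] = {"candidates": len(candidates)}
            if config.gene_sets:
                collection = GeneSetCollection.from_gmt(config.gene_sets)
                per_lnc = {}
                for lnc, table in assoc.items():
                    results = hypergeometric_ora(table["mrna"], collection)
                    per_lnc[lnc] = results
                    p = outdir / f"enrichment_{lnc}.tsv"
                    enrichment_to_frame(results).to_csv(p, sep="\t", index=False)
                    record(stage, p)
                matrix = top_pathway_matrix(per_lnc, top=10)
                matrix.to_csv(outdir / "top_pathways.tsv", sep="\t")
                info["pathway_matrix"] = list(matrix.shape)
            if config.survival:
                cohort = pd.read_csv(config.survival, sep="\t")
                screen_genes = [g for g in candidates if g in cohort.columns]
                screen = survival_screen_all(cohort, screen_genes)
                p = outdir / "survival_screen.tsv"
                screen.to_csv(p, sep="\t", index=False)
                record(stage, p)
                info["screened"] = len(screen_genes)
            manifest["stages"][stage] = info
    except PipelineError:
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
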