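# rnaloops

Regulatory-loop analysis of drug-induced transcriptomes.

When tumor cells are profiled by RNA-seq and small RNA-seq before and
after a drug challenge, the differentially expressed genes (DEGs) are a
flat list: the regulatory program behind them is invisible. `rnaloops`
reconstructs that program. It integrates public regulator→target
association compendia (ChIP-seq TF binding, CLIP-supported miRNA
targeting, predicted miRNA–lncRNA pairing) into a background **RNA
interactome** over four node biotypes — transcription factors (TFs),
miRNAs, mRNAs and long non-coding RNAs (lncRNAs) — maps each
condition's DEGs onto it, and mines the induced subnetworks for
higher-order regulatory structure. It is written for computational
biologists triaging noncoding RNAs for functional follow-up, e.g. in
chemoresistance studies.

## What it computes

**Feed-forward loops (FFLs).** Three-node motifs over one TF *t*, one
miRNA *m* and one target *x* ∈ {mRNA, lncRNA} with both regulators
pointing at the target:

- *TF-mediated*: t→m, t→x, m→x
- *miRNA-mediated*: m→t, t→x, m→x
- *mixed*: t⇄m, t→x, m→x

Classification is exclusive — a mutually regulated pair is counted once
as mixed — so the three per-type counts partition the motif set.
Enumeration is O(|TF|·|miRNA| + output) via successor-set intersection
and is validated against a brute-force O(n³) triple scan.

**ceRNA candidates.** A lncRNA and an mRNA sharing a miRNA regulator
inside a DE subnetwork form a candidate sponge triple (m, l, g); per
miRNA the triple count is (#lncRNA targets) × (#mRNA targets).

**DEG thresholds.** A record is DE when FDR < 0.05 and |FC| exceeds a
biotype-specific threshold (2 for mRNAs/TFs, 1.5 for miRNAs and
lncRNAs), all inequalities strict; the fold-change scale (log2 vs
linear) is configurable.

**lncRNA prioritization.** Expression-presence filtering,
guilt-by-association via top-*n* |Pearson/Spearman r| mRNA neighborhoods,
exact hypergeometric over-representation with Benjamini–Hochberg
adjustment, and a median-split survival screen: Kaplan–Meier arms above
and below the cohort median expression, compared by the log-rank test,
with the O/E hazard ratio HR = (O₁/E₁)/(O₂/E₂).

A `synthetic_data` module generates all inputs at compendium scale
(107 TFs, 1851 miRNAs, 10,970 lncRNAs, 18,812 mRNAs, ~1.1M
regulations) with planted FFLs, ceRNA triples, correlated sponge-pair
expression and group-dependent survival hazards, so the entire pipeline
is testable against known ground truth without any download.

## Worked example

```python
import rnaloops as rl
from rnaloops.synthetic_data import DEFAULT_EDGE_DENSITY

config = rl.SimConfig(
    n_tf=10, n_mirna=12, n_lncrna=40, n_mrna=60,
    edge_density={k: 0.1 for k in DEFAULT_EDGE_DENSITY},
    n_planted_ffl={"tf_mediated": 3, "mirna_mediated": 3, "mixed": 2},
    n_planted_cerna=4,
    de_fraction={"TF": 0.3, "mRNA": 0.3, "miRNA": 0.3, "lncRNA": 0.3},
    n_samples=12, survival_n=100, seed=7,
)
dataset = rl.simulate_dataset(config)
inter = rl.build_interactome(dict(dataset.background.tables),
                             dataset.background.tf_registry)
deset = rl.filter_degs(dataset.de_tables["sensitive"],
                       tf_registry=dataset.background.tf_registry,
                       condition="sensitive")["sensitive"]
sub = rl.extract_subnetwork(inter, deset)
motifs = rl.enumerate_ffls(sub)
print(rl.summarize_motifs(motifs).count_by_type())
```

prints

```
{'mixed': 4, 'tf_mediated': 7, 'mirna_mediated': 8}
```

the FFL census of the "sensitive" condition's DE subnetwork (62 DE
nodes, 108 background edges): 7 TF-mediated, 8 miRNA-mediated and 4
mixed loops, a superset of the 8 planted ones — chance loops arise from
the random background on top of the planted structure. The scripts in
`examples/` continue from here: `02_subnetwork_and_loops.py` confirms
`planted loops recovered: 8/8`, `03_cerna_triples.py` finds 81 ceRNA
triples containing all 4 planted sponge pairs, and `04_prioritize.py`
shows the survival screen recovering the planted prognostic directions
(e.g. HR = 2.70, log-rank p = 2.8e-07 for a lncRNA planted with a
hazard-increasing high-expression arm).

A thin CLI mirrors the library: `rnaloops simulate | build-net |
filter-degs | subnet | ffl | cerna | prioritize | run-all | validate`.
`rnaloops run-all --config pipeline.yaml` executes everything and
writes a manifest with input checksums and per-artifact row counts.

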