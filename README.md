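# spheroseq

Replicate-free transcriptome analysis of cytokine-stimulated 3D neural
cultures (human cortical spheroids and similar multi-cell-type models).

A common design in organoid inflammation studies is one pooled bulk
RNA-seq library per condition: an unstimulated control plus stimulations
with TNFα and IL-1β for 4 h, 12 h and 36 h. With no biological replicates,
differential expression, pathway readout and cell-type attribution all
have to be done with two-library exact statistics and set-level summaries.
`spheroseq` implements that analysis end to end, together with a seeded
synthetic-study generator (with full ground truth) so every stage can be
validated without any external data.

## What it computes

**Differential expression (two pooled libraries).** For gene *g* with
counts *x* (control) and *y* (stimulated) and library sizes *N₁*, *N₂*,
counts are modelled as Poisson; conditional on *t = x + y*,

&nbsp;&nbsp;&nbsp;&nbsp;*y* ~ Binomial(*t*, *N₂* / (*N₁* + *N₂*))

under the null of equal relative abundance (the Audic–Claverie exact test).
The two-sided p doubles the smaller inclusive tail. Fold changes use
counts rescaled to the geometric mean of the library sizes with a +1
pseudocount; a gene is a DEG when FC ≥ 2.00 and Benjamini–Hochberg
FDR ≤ 0.001 (both inclusive). FPKM(g, s) = 10⁹ · count / (length_bp ·
library size).

**Pathway enrichment.** Upper-tail hypergeometric p per gene set
(P(X ≥ k) for k DEGs in a K-gene set, n DEGs, N-gene universe), BH-FDR
across sets, significance at FDR < 0.01; "core" pathways are sets
recurrently in the per-condition top-4 with raw p < 10⁻¹¹.

**Boolean time-course clustering.** Each gene's (log2FC at 4 h, 12 h,
36 h) triplet is discretised into bands split at 0 and ±2.5 (strong-up,
mild-up, mild-down, strong-down); clusters are distinct band patterns.
Cross-cytokine overlap per cluster is the Jaccard percentage.

**Cell-type attribution.** From a cell-type × brain-region reference, a
gene is a marker of a cell type when its expression is ≥ 10-fold that of
every other cell type in the region; the attribution score of a DEG list
is |markers ∩ DEGs| / |markers| averaged over regions.

**qPCR validation.** Relative expression Q_x = μ_eff^(ct_min − ct_x) per
primer, normalized to the geometric mean of two housekeeping genes,
condition-mean log2 fold changes, and a one-tailed Pearson correlation
(alternative r > 0) against the RNA-seq log2FC.

## Worked example

```python
from spheroseq.pipeline import PipelineConfig, run_pipeline
from spheroseq.simulate import SimulationConfig

summary = run_pipeline(PipelineConfig(sim=SimulationConfig(seed=1)))
print(summary["deg_counts"]["TNFA_4h"])   # {'total': 347, 'up': 189, 'down': 158}
print(summary["n_common_degs"])           # 325
print(summary["core_pathways"])
# ['CYTOKINE_RECEPTOR_INTERACTION_LIKE', 'TNF_SIGNALING_LIKE', 'NFKB_SIGNALING_LIKE']
print(summary["qpcr_validation"]["TNFA_4h"])
# {'r': 0.9973, 'p_one_tailed': 1.16e-10, 'n': 10}
```

This simulates an 18,000-gene study (one 10M-fragment library per
condition), tests every gene in six contrasts, and reports: 347 genes
passed the FC ≥ 2 / FDR ≤ 0.001 gate after 4 h of TNFα stimulation (189
up, 158 down); 325 genes were DEGs under both cytokines at some time
point; the three synthetic inflammation-signaling gene sets were
recovered as core pathways; and qPCR-derived fold changes for a 10-gene
panel correlated with the RNA-seq values at r = 0.997.

The same analyses run from the shell on TSV/GMT inputs:

```bash
spheroseq simulate --outdir study --seed 1
spheroseq deg --counts study/counts.tsv --control CTRL_0h --case TNFA_4h --out deg.tsv
spheroseq run --outdir results --seed 1
```

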