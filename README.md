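# mifpipe

Consensus phenotyping, spatial neighborhood analysis, and gene-signature
scoring for multiplex immunofluorescence (mIF) cell tables.

## The problem

Cyclic multiplex immunofluorescence (e.g. MILAN) produces, for every
segmented cell in a tissue section, its X/Y position (μm), nuclear size,
and the mean fluorescence intensity (MFI) of each antibody marker.  In
melanoma biopsies from patients on anti-PD1 therapy, a question of
interest is whether *inflamed* tumor blood vessels (VCAM1⁺, optionally
STING⁺, endothelial cells) sit closer to cytotoxic CD8⁺ T cells in
responders (R) than in non-responders (NR).  `mifpipe` implements the
downstream analysis for that question as a tested, reusable pipeline,
plus the gene-signature machinery used to characterize inflamed
endothelium transcriptionally:

1. **Normalization** — per-sample Z-scores per marker, trimmed to
   [−5, 5]: `z = clip((x − μ)/σ, −5, 5)` with sample sd (ddof = 1).
2. **Consensus phenotyping** — a stratified proportional sample of
   2,500 cells is clustered three ways on the six lineage markers
   (AQP1, CD31, CD4, CD8, MelanA, SOX10): a Jaccard-weighted kNN graph
   (k = 20) partitioned by Louvain modularity, a self-organizing map
   meta-clustered to the graph's community count, and k-means with the
   same k.  Clusters map to phenotypes — Melanoma (SOX10⁺|MelanA⁺),
   BloodVessel (AQP1⁺|CD31⁺), Thelper (CD4⁺), CytotoxicT (CD8⁺) — by a
   marker-score rule; a cell keeps a phenotype only if ≥ 2 methods
   agree, otherwise it is NOS ("not otherwise specified").
3. **Label propagation** — a 2D reference embedding is fitted on up to
   500 labeled cells per phenotype; every cell receives the majority
   label of its 100 nearest reference cells in that space.
4. **Spatial analysis** — compartment assignment (tumoral bulk /
   tumor–stroma interface / non-tumoral polygons), cutoff-based
   functional calls (VCAM1⁺/STING⁺ vessels, PD1⁺/GrzB⁺ T cells),
   per-compartment Wilcoxon rank-sum enrichment (unadjusted), and
   neighborhood curves `N(r)` = mean number of target cells within
   radius *r* of a reference cell, compared R vs NR by two-sided
   t-tests radius by radius.
5. **Signature scoring** — differential expression on two-group count
   panels (total-count normalization, log2(x+1), Welch t); signature
   selection by log2FC ≥ 0.7 AND p < 0.05; per-cell rank-recovery AUC
   scores in [0, 1] (AUCell-style, top 5% of ranks); EC selection at
   score > 0.1; Spearman correlation of signatures across samples.

A synthetic-cohort generator (`mifpipe.simulate`) plants known ground
truth — phenotypes, inflamed-vessel flags, a responder-only excess of
CD8 cells near inflamed endothelium, DE genes, enriched gene sets — so
every stage is testable against a recoverable signal.

## Worked example

```python
import mifpipe as m
from mifpipe.spatial import sample_curves, compare_curves, call_positive

# 12-sample cohort (6 R / 6 NR), 1,000 cells each, on/off markers 4 sd apart
cfg = m.separation_config(4.0, cells_per_sample=1000, seed=11)
tables, regions, truth = m.generate_cohort(cfg)

# normalize -> consensus phenotype -> propagate to all cells
labels = m.phenotype_cohort(tables, seed=11)
mg = labels.merge(truth.cells, on=["sample_id", "cell_id"])
print("recovery: %.4f" % (mg.phenotype_x == mg.phenotype_y).mean())

# inflamed-vessel -> CD8 neighborhood curves, R vs NR
norm = m.normalize_cohort(tables)
by, ref, tgt = {}, {}, {}
for t in norm:
    lab = labels[labels.sample_id == t.sample_id]
    by[t.sample_id] = t.df
    ref[t.sample_id] = call_positive(
        t.df, "VCAM1", 1.0, phenotype=lab.phenotype.reset_index(drop=True)
    ).to_numpy()
    tgt[t.sample_id] = (lab.phenotype == "CytotoxicT").to_numpy()
stats = compare_curves(sample_curves(by, ref, tgt, radii=[20, 40, 60]),
                       truth.groups)
print(stats.round(4).to_string(index=False))
```

Output:

```
recovery: 0.9946
 radius       t  p_value  mean_R  mean_NR
   20.0 13.8939   0.0000  0.7222   0.1885
   40.0  9.7326   0.0000  1.5933   0.7619
   60.0  5.4824   0.0003  2.4862   1.7160
```

99.5% of the 12,000 cells recover their planted phenotype, and the
planted excess of CD8 cells near inflamed vessels in responders shows up
as significantly higher neighborhood counts at short range (at 20 μm a
responder's inflamed vessel has on average 0.72 CD8 cells nearby versus
0.19 in non-responders).

The same stages are scriptable from the shell:

```bash
mifpipe simulate cohort --out sim/ --seed 11
mifpipe normalize --in sim/R1.cells.csv --out norm/R1.csv
mifpipe phenotype norm/*.csv --seed 11 --out labels.csv
mifpipe propagate norm/*.csv --labels labels.csv --out all_labels.csv
```

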