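# metabosubtype

Tools for HER2-associated metabolic profiling and metabolic subtyping of
gastric cancer cohorts, built for analysts working with serum metabolomics
and bulk expression data. The package covers the full chain from a raw
metabolite abundance table and a gene-expression matrix to:

* **differential serum-metabolite screening** between tumour and healthy arms
  (empirical-Bayes moderated *t* on log2 intensities, BH FDR < 0.05, fold
  change > 1.2 or < 5/6);
* **weighted metabolite co-expression network analysis** (WMCNA): soft
  threshold selection against a scale-free fit target, unsigned adjacency
  |r|^β, topological overlap TOM, average-linkage modules, eigenmetabolites,
  module–trait statistics against the HER2 IHC score, and hub selection at
  MM > 0.7 and MES > 0.15;
* a **metabolite–metabolite interaction network** with edges at
  |Pearson r| > 0.4;
* **ssGSEA** pathway/immune scoring, top/bottom-30% grouping, two-group GSEA
  with permutation NES, and Spearman trait–score correlation;
* **consensus-clustering quadrant subtyping**: Monti consensus clustering
  (reps = 100, pItem = 0.8, pFeature = 1, Ward linkage on 1 − Pearson
  distance, k = 3) of the two KEGG pathway gene sets
  (alanine–aspartate–glutamate metabolism, "AAG", and
  glycolysis/gluconeogenesis, "GG"), selection of the coexpressed gene group
  per pathway, per-sample median z-scores, and the quadrant rule
  quiescent (AAG ≤ 0, GG ≤ 0) / AAG (> 0, ≤ 0) / GG (≤ 0, > 0) /
  mixed (> 0, > 0);
* **subtype characterisation**: subtype-specific molecules (upregulated
  versus every other subtype at BH FDR < 0.05), Kruskal–Wallis screening of
  immune features (retain p < 0.05), and Kaplan–Meier / log-rank survival
  comparison for OS and DSS.

A first-class synthetic-data module generates expression cohorts with planted
subtypes and survival hazards, and two-arm metabolomes with planted fold
changes, correlated metabolite modules and an HER2-linked module, so every
stage is testable against known ground truth without external downloads.

## Worked example

```python
from metabosubtype.simulate import (
    MetabolomeSimConfig, SubtypeSimConfig, make_gene_sets,
    simulate_expression_cohort, simulate_metabolome_cohort,
)
from metabosubtype.dem import DifferentialAbundance
from metabosubtype.subtype import ConsensusParams, MetabolicSubtyper

# 112 tumour + 112 healthy sera, 1300 metabolites, 50 up / 100 down planted
matrix, clinical, truth = simulate_metabolome_cohort(MetabolomeSimConfig(seed=1))
print(DifferentialAbundance(matrix).fit().summary())

# 400-sample expression cohort with four planted metabolic subtypes
cfg = SubtypeSimConfig(seed=7)
expr, eclin, etruth = simulate_expression_cohort(cfg)
model = MetabolicSubtyper(expr, make_gene_sets(cfg), clinical=eclin,
                          params=ConsensusParams(seed=7))
result = model.fit()
print(result.summary())
surv = result.survival("OS")
print(f"OS log-rank: chi2 = {surv['test'].statistic:.2f}, p = {surv['test'].p:.2e}")
```

prints

```
Differential metabolite screen
  comparison : GC vs healthy
  criteria   : FDR < 0.05, FC > 1.2 or < 0.833333
  metabolites: 1300
  up         : 50
  down       : 100

Metabolic quadrant subtyping
  samples       : 400
  AAG genes kept: 20
  GG genes kept : 20
  quiescent     : 107
  AAG           : 84
  GG            : 100
  mixed         : 109

OS log-rank: chi2 = 60.34, p = 4.97e-13
```

The screen recovers exactly the 50 upregulated and 100 downregulated
metabolites that were planted; the subtyper keeps precisely the 20-gene
coexpressed core of each pathway and splits the cohort into the four
quadrant subtypes, whose planted hazard differences (GG worst, mixed best)
the log-rank test detects decisively.

The same stages are available from the shell:

```bash
metabosubtype simulate --seed 1 --out-dir cohort/
metabosubtype dem --matrix cohort/metabolome.tsv --clinical cohort/metabolome_clinical.csv --out dem.tsv
metabosubtype wmcna --matrix cohort/metabolome.tsv --clinical cohort/metabolome_clinical.csv --out-dir wmcna/
metabosubtype subtype --expr cohort/expression.tsv --gmt cohort/gene_sets.gmt \
    --clinical cohort/expression_clinical.csv --seed 7 --out-dir subtype/
```

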