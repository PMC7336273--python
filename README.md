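# moascan

Drug mechanism-of-action discovery from paired pharmacological and
CRISPR-Cas9 loss-of-function screens in cancer cell lines.

Large drug-sensitivity panels measure a half-maximal inhibitory
concentration (IC50) for hundreds of compounds across hundreds of cell
lines; genome-wide CRISPR screens measure the fitness cost of knocking out
each gene in the same lines. If a drug works through a protein target, the
lines most sensitive to the drug should also be the lines most dependent on
the target's gene — so regressing the drug-response profile on every gene's
fitness profile recovers drug targets, isoform selectivity, off-target
activity and pathway context in a single unsupervised pass. `moascan`
implements that analysis for statisticians and computational biologists
working with cell-line screening panels, together with a synthetic-panel
generator with planted ground truth so every stage can be validated offline.

## The model

For each drug `d` (vector of ln IC50 values across cell lines) and each
candidate predictor `e` (a gene's scaled fitness profile, an expression
profile, or a binary genomic feature), `moascan` fits the linear mixed model

```
d = M β₀ + e β₁ + u + ε,     u ~ N(0, σ²g K),     ε ~ N(0, σ²e I)
```

where `M` holds the fixed covariates (intercept, institute-of-origin
indicators, drug-response PC1 — a correlate of growth rate — and culture
conditions) and `K` is a cell-line kinship matrix built from the genome-wide
fitness profiles, absorbing sample structure that would otherwise inflate
associations. Parameters are estimated by maximum likelihood through the
spectral decomposition of `K`; significance of `β₁` is a likelihood-ratio
test against the model without `e`, calibrated on χ²(1), with
Benjamini–Hochberg FDR applied per drug (significance at q < 10%).

Around the scan, the package provides:

* **Preprocessing** — guide/replicate aggregation, per-sample quantile
  normalization and median scaling of CRISPR fold changes so essential genes
  sit at −1 and non-essential genes at 0 in every cell line, dependency
  calling (scaled fold change < −0.5), the drug inclusion filter (IC50 below
  half the maximum screened concentration in ≥ 3 lines), growth rates, and
  mean-imputation PCA.
* **Network annotation** — a STRING-derived protein network (combined score
  > 900), with every association labelled by the shortest-path distance from
  the gene to the drug's nearest nominal target (`T`, `1`, `2`, `3`, …, `−`),
  fitness-correlation edge weights and per-drug subnetworks.
* **Robust pharmacogenomic biomarkers** — molecular features significantly
  associated (same mixed model) with *both* a drug's response and its paired
  gene's fitness, BH-corrected per drug–gene pair.
* **Response models** — ridge regression with internal cross-validated
  penalty selection over repeated 70/30 train/test splits, reporting
  held-out R² and per-feature effect sizes.
* **ChEMBL-style target calling** — putative active targets from bioactivity
  records using family activity thresholds (kinases ≤ 30 nM, GPCRs and
  nuclear receptors ≤ 100 nM, ion channels ≤ 10 µM, others ≤ 1 µM).

## Worked example

Generate a small synthetic panel with known drug targets, run the scan and
classify each drug by its best network-distance category:

```python
import moascan as m
from moascan import preprocess, lmm, ppi, pipeline

config = m.PanelConfig(n_cell_lines=120, n_genes=300, n_drugs=5,
                       n_essential=30, n_nonessential=30, seed=0)
panel = m.generate_panel(config)

sfm = preprocess.scale_fold_changes(panel.fold_changes, panel.gene_sets)
kinship = lmm.build_kinship(sfm)
pca = preprocess.pca_with_imputation(panel.drug_response.values, 5,
                                     panel.cell_meta["growth_rate"])
covariates = lmm.build_covariates(sfm.cell_lines,
                                  institute=panel.cell_meta["institute"],
                                  culture=panel.cell_meta["culture"],
                                  drug_pc1=pca.scores["PC1"])

results = m.scan(panel.drug_response, sfm.values, covariates, kinship)
print(results.nsmallest(3, "pval")[["drug_id", "predictor_id",
                                    "beta", "pval", "qval"]])
```

```
drug_id predictor_id     beta         pval         qval
   D004       G00122 2.183244 1.626801e-24 4.880402e-22
   D005       G00112 1.732337 5.167023e-15 1.550107e-12
   D002       G00161 1.533857 3.117945e-13 9.353834e-11
```

The three strongest associations are exactly the planted targets of D004,
D005 and D002 (`panel.truth.targets`), with positive effect sizes: lines
whose target knockout costs the most fitness (more negative scaled fold
change) have the lowest ln IC50, i.e. are most sensitive. Annotating with a
protein network and summarizing per drug:

```python
graph, _ = m.generate_ppi_network(config, panel.truth)
annotated = ppi.annotate_target_distance(results, graph,
                                         panel.drug_response.targets)
print(pipeline.summarize_drugs(annotated, panel.drug_response.targets))
```

```
drug_id category  n_significant  annotated
   D001        T              1       True
   D002        T              2       True
   D003        T              1       True
   D004        T              2       True
   D005        T              1       True
```

Every drug is labelled `T`: its significant associations include its own
nominal target.

A YAML-configured command line drives the same stages end to end:

```bash
moascan simulate --out inputs/ --seed 3
moascan run-all --config config.yaml --seed 3
```

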