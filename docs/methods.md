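# Methods

This note documents the statistical model, the synthetic study conditions,
the numerical choices and the known limitations of `moascan`.

## The association model

Each test relates one drug's response profile to one predictor profile over
the cell lines where the drug was measured (missing IC50 entries are dropped
per drug). Writing `d` for the vector of natural-log IC50 values (ln µM),
the model is

```
d = M β₀ + e β₁ + u + ε,   u ~ N(0, σ²g K),   ε ~ N(0, σ²e I)
```

* `M` — fixed covariates: intercept; institute-of-origin indicators (the
  two CRISPR data sources have a library-specific signature that separates
  them on the first fitness principal component); the first principal
  component of the drug-response matrix, a strong correlate of growth rate
  (fast-growing lines are broadly more drug-sensitive, especially to
  chemotherapeutics); and culture-condition indicators
  (adherent / suspension / semi-adherent). Categorical covariates are
  one-hot encoded with the first level absorbed by the intercept;
  rank-deficient columns are dropped per drug by a greedy QR check.
  PC1 is computed jointly across screen batches by default (a per-batch
  option exists); batch identity itself is handled by correcting FDR per
  drug, which never mixes the two platforms within one correction family.
* `e` — the predictor: a gene's scaled fitness profile in the primary scan;
  a binary mutation/copy-number feature or a continuous (assumed
  variance-stabilized) expression feature in the biomarker stage.
* `K` — kinship: `Z Zᵀ / p` over the `p` genes with non-zero variance,
  where `Z` holds per-gene standardized scaled fold changes, rescaled to
  mean diagonal 1. Lines from the same lineage share correlated fitness
  profiles *and* correlated drug responses, so without this random effect
  the scan's null is badly miscalibrated.

Estimation is maximum likelihood (not REML): the likelihood-ratio test
compares models differing in a fixed effect, and ML keeps the two
likelihoods directly comparable. The LRT statistic (clamped at zero) is
referred to χ² with one degree of freedom; the reference distribution is a
calibration choice, verified empirically on null panels (see below). FDR is
Benjamini–Hochberg per drug, significance at q < 0.10.

The notation above reads the similarity matrix as the covariance of a
random effect (`u ~ N(0, σ²g K)`), the standard interpretation when sample
structure is summarized by a similarity matrix.

## Spectral likelihood and the delta search

With `K = U S Uᵀ`, rotating `d`, `M`, `e` by `Uᵀ` diagonalizes the
covariance to `σ²g diag(S + δ)` where `δ = σ²e / σ²g`. At fixed `δ` the
fixed effects are weighted least squares and `σ²g = RSS_w / n`, so only `δ`
needs a search: a 100-point log-spaced grid on [1e−5, 1e5] followed by a
bounded scalar refinement around the best grid point. Ties within 1e−6
log-likelihood are broken toward smaller `δ` (more structure). Eigenvalues
are floored at 1e−10. Sub-panel eigendecompositions (one per missingness
pattern) are cached by cell-line subset.

**Fast mode.** Within a drug, the null-model `δ̂` is reused across all
predictor tests, reducing each test to a rank-one update of the whitened
null regression — the whole scan is vectorized across predictors. The
reuse approximation is accurate when a predictor explains little variance
but deteriorates as the explained fraction grows; tests whose screening
statistic exceeds 30 (p below ~4e−8) are therefore re-fitted with a
per-test `δ` optimization. With this refinement, fast and exact mode agree
on all strong hits while the scan cost stays within a small factor of a
plain regression pass. `exact` mode re-optimizes `δ` for every test.

Degenerate cases: a predictor with zero variance on the observed subset
returns p = 1, β = 0, flagged; a predictor collinear with the covariates
yields a zero statistic and is flagged rather than raising. Drugs with
fewer than 15 observed lines (configurable) are skipped.

## Preprocessing conventions

* Quantile normalization is per sample against the mean-of-sorted-values
  reference; ties receive the mean of their tied reference positions. It is
  applied to the assembled joint gene × cell line matrix.
* Median scaling maps each sample by `x → (x − m_ne) / (m_ne − m_e)`, the
  unique affine map sending the essential/non-essential medians to (−1, 0).
  Equal medians in a sample are a fatal calibration error.
* Dependency calls use scaled fold change < −0.5, strictly.
* The drug filter compares in ln-concentration space — ln IC50 <
  ln(Cmax/2) — because IC50s are stored as natural logs of µM values.
* Growth rate is returned as mean(day4 DMSO controls)/mean(day1 untreated
  controls), so larger means faster growth; the orientation is recorded in
  the result's metadata and the literal inverse is available, since the
  ratio's direction is a convention rather than a measurement.
* Amplification calls are ploidy-aware: (ploidy ≤ 2.7 and CN ≥ 5) or
  (ploidy > 2.7 and CN ≥ 9), boundaries inclusive.

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes, with
one seed governing all four generators (panel, network, molecular features,
bioactivity records):

| parameter | default | meaning |
| --- | --- | --- |
| `n_cell_lines` | 484 | panel size |
| `n_genes` | 1,000 | gene space (scaled down from genome-wide) |
| `n_drugs` | 20 | drugs, one planted target each |
| `n_essential` / `n_nonessential` | 50 / 50 | reference calibration sets |
| `n_latent` | 5 | shared lineage factors |
| `target_effect` | 1.0 | planted β₁, ln IC50 per scaled-fitness unit |
| `noise_sd` | 0.5 | residual SD of both matrices |
| `covariate_sd` | 0.5 | per-drug institute/growth/culture effect spread |
| `latent_scale` | 0.5 | lineage contribution to both matrices |
| `missing_rate` | 0.10 | IC50 entries masked completely at random |
| `biomarker_effect` | 1.0 | planted biomarker shift on both outcomes |

Raw fitness is a per-gene baseline (essential ≈ −2 raw log2 FC,
non-essential ≈ 0, so the −1/0 calibration is produced by scaling, not by
the generator) plus the low-rank lineage component plus noise. Drug ln IC50
is an intercept plus the planted effect on the target's *scaled* fitness,
covariate effects, the lineage component, the planted biomarker shift and
noise. The biomarker sign convention is coherent across outcomes: an
altered feature deepens the target's loss of fitness and lowers the drug's
ln IC50. Missingness masks exactly `round(rate × drugs × lines)` entries.
The nuisance scales were set once so that planted signal, lineage
confounding and residual noise are of comparable magnitude — strong enough
confounding to make the kinship term consequential, weak enough that a
unit planted effect is recoverable.

The network generator places designated panel genes at exact shortest-path
distances 1–4 from each planted target (separate components per target, so
the designated distances cannot be short-circuited) plus an unreachable
two-node decoy component, and emits the true distance table.

What the generator does **not** emulate: dose–response curve shapes and
informative missingness (entries are masked at random; the analysis drops
missing cells per drug either way), copy-number artefacts in CRISPR counts,
guide-level sequence effects, paralog redundancy, and realistic linkage
between genomic features. Passing tests therefore demonstrate the
statistical machinery under the assumed model, not robustness to those
real-data pathologies.

## Response models

Ridge regression with the penalty chosen per split by leave-one-out
generalized cross-validation on the training 70% (grid 1e−3…1e3, 13
points); features are standardized inside each split on training statistics
only, to avoid leakage. Held-out R² is computed on the remaining 30%;
splits are a deterministic function of (seed, n, n_splits, train fraction),
shared across feature sets for paired comparison. Effect sizes are averaged
over splits (a refit-on-all-data option exists); they are in response units
per standardized feature unit. The default feature panel for MCL1-inhibitor
style modelling is the canonical mitochondrial-apoptosis regulator list
(MARCH5, MCL1, BCL2, BCL2L1, BCL2L11, PMAIP1, BAX, BAK1, BBC3, BID, BIK,
BAD), supplied through configuration so the machinery stays generic.

## Robust biomarkers

Only drug–gene pairs significant in the primary scan are tested. Each
feature is tested against both outcomes on the drug's observed cell-line
subset with the scan's covariates and kinship. BH correction is applied
within each (drug, gene) pair block, separately per outcome and per feature
class (a correct-across-pairs switch exists); `robust` requires q < 0.10 on
both outcomes. Genomic features need at least 3 altered lines among the
observed samples (and at least 3 unaltered), mirroring the spirit of the
drug inclusion filter; expression features are used untransformed.

## Bioactivity target calling

Records must have a defined pChEMBL, relation "=", a protein-level target
type and human target organism. Activity is `10^(−pChEMBL)` molar compared
inclusively against the family threshold, with a 1e−9 relative guard so a
value stated exactly at a threshold is not lost to round-off. A single
qualifying record suffices (the most permissive reading; no minimum assay
count is imposed).

## Validation summary

The test suite checks, among others: the spectral likelihood against a
dense multivariate-normal oracle (|Δll| < 1e−8, 50 instances, n ≤ 12);
type-I error within [0.04, 0.06] at p < 0.05 on ≥ 10,000 null tests with
lineage confounding present; planted-target top-5 recovery ≥ 80% of drugs
at default conditions; BH q-values against the literal step-up definition;
BFS target distances against a Floyd–Warshall oracle; and mean held-out
R² ≥ 0.99 on noiseless planted linear responses. Each of these is computed
by the suite itself at run time.

## Known limitations

* The χ²(1) calibration is asymptotic; at a few hundred observations the
  ML likelihood-ratio test is very slightly anticonservative (the null
  suites above quantify this).
* One kinship matrix is estimated from the full panel and subset per drug;
  no leave-one-chromosome-out-style exclusion of the tested gene from `K`
  is performed, which slightly shrinks very strong signals.
* Only a single variance component is modelled (no separate batch random
  effect); batch enters through fixed covariates and per-drug FDR.
* Permutation-based calibration and REML are out of scope.
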