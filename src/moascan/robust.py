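"""Robust pharmacogenomic associations.

For each significant drug-gene pair from the primary scan, every molecular
feature (binary mutation/copy-number status or continuous expression) is
tested twice with the same mixed model, covariates and kinship as the scan:
once against the drug's response profile and once against the gene's fitness
profile.  P-values are Benjamini-Hochberg corrected within each (drug, gene)
pair block, separately per outcome and per feature class.  A feature
significant on *both* outcomes (q < 10% each) is a robust pharmacogenomic
association: a biomarker independently supported by two orthogonal assays.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import lmm

logger = logging.getLogger("moascan")

FDR_THRESHOLD = 0.10
#: genomic features need this many altered lines among the observed samples
MIN_ALTERED = 3

ROBUST_COLUMNS = [
    "drug_id", "gene_id", "feature_id", "feature_class",
    "beta_drug", "pval_drug", "qval_drug",
    "beta_gene", "pval_gene", "qval_gene", "robust",
]


def test_pair_features(
    pair: tuple[str, str],
    genomic: pd.DataFrame | None,
    expression: pd.DataFrame | None,
    drm,
    sfm,
    covariates: pd.DataFrame,
    kinship: lmm.Kinship,
    min_altered: int = MIN_ALTERED,
) -> pd.DataFrame:
    """Unadjusted feature tests for one significant drug-gene pair.

    Runs two likelihood-ratio tests per eligible feature: feature against the
    drug's ln IC50 vector and feature against the gene's scaled fitness
    vector, both on the cell lines where the drug response is observed.
    Genomic features with fewer than ``min_altered`` altered lines on that
    subset, and constant features of either class, are skipped.
    """
    drug, gene = pair
    y_drug_all = drm.values.loc[drug]
    fitness = sfm.values if isinstance(getattr(sfm, "values", None), pd.DataFrame) else sfm
    shared = y_drug_all.dropna().index
    shared = shared.intersection(fitness.columns)
    shared = shared.intersection(covariates.index).intersection(kinship.cell_lines)
    obs = list(shared)

    # both outcomes are tested on the drug's observed cell-line subset, with
    # the scan's covariates and kinship
    outcomes = pd.DataFrame(
        [y_drug_all.loc[obs].to_numpy(dtype=float),
         fitness.loc[gene, obs].to_numpy(dtype=float)],
        index=["__drug__", "__gene__"], columns=obs,
    )

    rows = []
    for fclass, matrix in (("genomic", genomic), ("expression", expression)):
        if matrix is None:
            continue
        if not set(obs).issubset(matrix.columns):
            raise ValueError(f"{fclass} features not aligned to observed cell lines")
        feats = matrix.loc[:, obs].astype(float)
        variable = feats.apply(np.ptp, axis=1) > 0
        if fclass == "genomic":
            altered = feats.sum(axis=1)
            variable &= np.minimum(altered, len(obs) - altered) >= min_altered
        feats = feats[variable]
        if feats.empty:
            continue
        res = lmm.scan(
            outcomes, feats, covariates, kinship,
            min_obs=min(lmm.MIN_OBS, len(obs)), predictor_class=fclass,
        )
        wide = res.pivot(index="predictor_id", columns="drug_id", values=["beta", "pval"])
        for feature_id in feats.index:
            rows.append({
                "drug_id": drug,
                "gene_id": gene,
                "feature_id": feature_id,
                "feature_class": fclass,
                "beta_drug": wide.loc[feature_id, ("beta", "__drug__")],
                "pval_drug": wide.loc[feature_id, ("pval", "__drug__")],
                "beta_gene": wide.loc[feature_id, ("beta", "__gene__")],
                "pval_gene": wide.loc[feature_id, ("pval", "__gene__")],
            })
    return pd.DataFrame(rows)


def adjust_per_pair(rows: pd.DataFrame, across_pairs: bool = False) -> pd.DataFrame:
    """BH correction of the two p-value columns.

    Default blocks: within each (drug, gene) pair and feature class,
    separately for the drug-response and gene-fitness outcomes.  Setting
    ``across_pairs`` corrects over all pairs at once instead (each feature
    class still separate).
    """
    if rows.empty:
        out = rows.copy()
        out["qval_drug"] = out["qval_gene"] = pd.Series(dtype=float)
        return out
    keys = ["feature_class"] if across_pairs else ["drug_id", "gene_id", "feature_class"]
    out = rows.copy()
    for col in ("pval_drug", "pval_gene"):
        if ((out[col] < 0) | (out[col] > 1)).any() or out[col].isna().any():
            raise ValueError(f"{col} must lie in [0, 1]")
        out[col.replace("pval", "qval")] = out.groupby(keys, sort=False)[col].transform(
            lambda p: multipletests(p.to_numpy(), method="fdr_bh")[1]
        )
    return out


def flag_robust(rows: pd.DataFrame, fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Set the robust flag: significant against both outcomes.

    ``robust = (qval_drug < threshold) and (qval_gene < threshold)``.
    """
    out = rows.copy()
    if out.empty:
        out["robust"] = pd.Series(dtype=bool)
        return out
    out["robust"] = (out["qval_drug"] < fdr_threshold) & (out["qval_gene"] < fdr_threshold)
    return out[ROBUST_COLUMNS]


def summarize_robust(flagged: pd.DataFrame) -> dict:
    """Summary counts: robust associations per feature class and the fraction
    of tested drug-gene pairs holding at least one robust marker."""
    if flagged.empty:
        return {"n_pairs_tested": 0, "n_pairs_robust": 0,
                "fraction_pairs_robust": float("nan"), "per_class": {}}
    pairs = flagged.groupby(["drug_id", "gene_id"])["robust"].any()
    per_class = (
        flagged[flagged["robust"]].groupby("feature_class").size().to_dict()
    )
    return {
        "n_pairs_tested": int(len(pairs)),
        "n_pairs_robust": int(pairs.sum()),
        "fraction_pairs_robust": float(pairs.mean()),
        "per_class": per_class,
    }


def robust_pair_fraction(n_robust_pairs: int, n_significant_pairs: int) -> float:
    """Percentage of significant drug-gene pairs with >= 1 robust marker."""
    if n_significant_pairs <= 0:
        raise ValueError("n_significant_pairs must be positive")
    return 100.0 * n_robust_pairs / n_significant_pairs
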