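"""Regularized multilinear prediction of drug response.

A drug's response vector is predicted from a designated feature panel (gene
fitness, gene expression, or both) with L2-regularized linear regression.
The data are split randomly into 70% training / 30% held-out test many times
(1,000 by default); inside each split features are standardized on the
training portion only and the ridge penalty is chosen on the training
portion by leave-one-out generalized cross-validation over a log-spaced
grid.  Performance is the R2 between predicted and observed response on the
held-out samples; per-feature effect sizes (response units per standardized
feature unit) are averaged over splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import RidgeCV
from sklearn.metrics import r2_score

ALPHA_GRID = np.logspace(-3, 3, 13)
N_SPLITS = 1000
TRAIN_FRACTION = 0.7
MIN_SAMPLES = 20

#: canonical mitochondrial-apoptosis regulator panel used for MCL1-inhibitor
#: models; any feature list can be supplied instead
MCL1_REGULATORS = [
    "MARCH5", "MCL1", "BCL2", "BCL2L1", "BCL2L11", "PMAIP1",
    "BAX", "BAK1", "BBC3", "BID", "BIK", "BAD",
]


@dataclass
class ModelReport:
    """Repeated-split evaluation of one drug / feature-set model."""

    drug_id: str
    feature_set: str
    r2_per_split: np.ndarray
    effect_sizes: pd.Series
    n_splits: int
    train_fraction: float
    seed: int

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_per_split))

    @property
    def median_r2(self) -> float:
        return float(np.median(self.r2_per_split))


def _split_indices(
    n: int, n_splits: int, train_frac: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic train/test index pairs, a function of (seed, n, n_splits, train_frac)."""
    rng = np.random.default_rng([int(seed), n, n_splits, int(round(train_frac * 1000))])
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 2)  # at least 2 test samples
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        splits.append((perm[:n_train], perm[n_train:]))
    return splits


def ridge_cv_evaluate(
    y: pd.Series,
    features: pd.DataFrame,
    drug_id: str = "",
    feature_set: str = "features",
    n_splits: int = N_SPLITS,
    train_frac: float = TRAIN_FRACTION,
    seed: int = 0,
    splits: list | None = None,
) -> ModelReport:
    """Repeated-split ridge evaluation of one drug.

    ``y`` is the drug's response across cell lines (missing entries are
    dropped); ``features`` is a feature x cell line matrix, complete on the
    observed samples.  ``splits`` allows sharing identical splits across
    feature sets for paired comparison.
    """
    obs = y.dropna().index.intersection(features.columns)
    if len(obs) < MIN_SAMPLES:
        raise ValueError(
            f"drug {drug_id or '<unnamed>'}: {len(obs)} observed samples, "
            f"need at least {MIN_SAMPLES}"
        )
    if features.empty:
        raise ValueError("empty feature set")
    X = features.loc[:, obs].to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise ValueError("features must be complete on the observed samples")
    yv = y.loc[obs].to_numpy(dtype=float)
    n = len(obs)

    if splits is None:
        splits = _split_indices(n, n_splits, train_frac, seed)
    r2s = np.empty(len(splits))
    coefs = np.zeros((len(splits), X.shape[1]))
    for k, (tr, te) in enumerate(splits):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        model = RidgeCV(alphas=ALPHA_GRID)
        model.fit(Xtr, yv[tr])
        r2s[k] = r2_score(yv[te], model.predict(Xte))
        coefs[k] = model.coef_
    return ModelReport(
        drug_id=drug_id,
        feature_set=feature_set,
        r2_per_split=r2s,
        effect_sizes=pd.Series(coefs.mean(axis=0), index=features.index, name="effect_size"),
        n_splits=len(splits),
        train_fraction=train_frac,
        seed=seed,
    )


def compare_feature_sets(
    y: pd.Series,
    feature_sets: dict[str, pd.DataFrame],
    drug_id: str = "",
    n_splits: int = N_SPLITS,
    train_frac: float = TRAIN_FRACTION,
    seed: int = 0,
) -> dict[str, ModelReport]:
    """Evaluate several feature sets on identical splits of one drug.

    Every report shares the same train/test partitions (derived from the
    seed and the shared observed-sample universe), so per-split R2 values
    are directly paired across feature sets.
    """
    if not feature_sets:
        raise ValueError("no feature sets supplied")
    for label, F in feature_sets.items():
        if F.empty:
            raise ValueError(f"feature set {label!r} is empty")
    shared = y.dropna().index
    for F in feature_sets.values():
        shared = shared.intersection(F.columns)
    y_shared = y.loc[shared]
    splits = _split_indices(len(shared), n_splits, train_frac, seed)
    return {
        label: ridge_cv_evaluate(
            y_shared, F.loc[:, shared], drug_id=drug_id, feature_set=label,
            train_frac=train_frac, seed=seed, splits=splits,
        )
        for label, F in feature_sets.items()
    }


def reports_to_frame(reports: dict[str, ModelReport] | list[ModelReport]) -> pd.DataFrame:
    """Flatten model reports into a summary table."""
    if isinstance(reports, dict):
        reports = list(reports.values())
    rows = [
        {
            "drug_id": r.drug_id,
            "feature_set": r.feature_set,
            "mean_r2": r.mean_r2,
            "median_r2": r.median_r2,
            "n_splits": r.n_splits,
            "train_fraction": r.train_fraction,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)
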