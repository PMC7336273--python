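"""Linear mixed-model association scan between drug response and gene fitness.

For each drug ``d`` (vector of ln IC50 across cell lines) and each candidate
predictor ``e`` (a gene's scaled fitness profile, an expression profile, or a
binary genomic feature) the model

    d = M b0 + e b1 + u + eps,   u ~ N(0, sg2 * K),   eps ~ N(0, se2 * I)

is fitted by maximum likelihood, where ``M`` is a fixed-effect covariate
matrix (intercept, institute-of-origin indicators, drug-response PC1, culture
conditions) and ``K`` a cell-line kinship matrix built from genome-wide
fitness profiles, absorbing sample structure.  Significance of ``b1`` is a
likelihood-ratio test of the alternative model against the null model without
``e``, calibrated against chi-square with one degree of freedom; p-values are
Benjamini-Hochberg adjusted independently per drug.

The likelihood is evaluated through the spectral decomposition of ``K``:
rotating by the eigenvectors diagonalizes the covariance, so for a fixed
variance ratio ``delta = se2 / sg2`` the fixed effects and ``sg2`` have
closed-form generalized-least-squares solutions and only ``delta`` needs a
one-dimensional search (log-spaced grid plus bounded local refinement).
Within a drug the null-model ``delta`` can be reused across all predictor
tests ("fast" mode, fully vectorized) or re-optimized per test ("exact").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("moascan")

#: delta = se2/sg2 profiling grid: 100 log-spaced points
DELTA_GRID = np.logspace(-5, 5, 100)
#: log-likelihood tolerance for delta ties (ties broken toward smaller delta)
LL_TOL = 1e-6
#: eigenvalue floor for numerical stability
EIG_FLOOR = 1e-10
#: default minimum observed cell lines per drug
MIN_OBS = 15
#: in fast mode, tests whose screening LRT statistic exceeds this are
#: re-fitted with a per-test delta optimization: the delta-reuse
#: approximation is accurate for small effects but its error grows with the
#: fraction of variance a predictor explains, which only matters for the
#: strongest hits
REFINE_STAT = 30.0
#: default per-drug FDR significance threshold
FDR_THRESHOLD = 0.10

RESULT_COLUMNS = [
    "drug_id", "predictor_id", "beta", "lrt_stat", "pval", "qval",
    "n_obs", "predictor_class", "flagged",
]


def planned_test_count(n_drugs: int, n_predictors: int) -> int:
    """Number of single-feature association tests in a full scan."""
    return int(n_drugs) * int(n_predictors)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

@dataclass
class Kinship:
    """Cell-line similarity matrix acting as the random-effect covariance.

    Symmetric positive semi-definite, normalized so the mean diagonal is 1.
    Eigendecompositions of cell-line subsets are cached by subset signature,
    since the scan revisits the same missingness patterns across drugs.
    """

    matrix: pd.DataFrame
    _eig_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        arr = self.matrix.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        smallest = np.linalg.eigvalsh(arr)[0]
        if smallest < -1e-8:
            raise ValueError(f"kinship matrix is not PSD (min eigenvalue {smallest:.3g})")

    @property
    def cell_lines(self) -> pd.Index:
        return self.matrix.index

    def eigen(self, cell_lines: tuple) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of the sub-matrix for ``cell_lines``.

        Returns ``(S, U)`` with eigenvalues floored at ``EIG_FLOOR``.
        """
        key = cell_lines
        if key not in self._eig_cache:
            sub = self.matrix.loc[list(cell_lines), list(cell_lines)].to_numpy(dtype=float)
            S, U = np.linalg.eigh(sub)
            self._eig_cache[key] = (np.maximum(S, EIG_FLOOR), U)
        return self._eig_cache[key]


def build_kinship(sfm) -> Kinship:
    """Kinship from scaled gene-fitness profiles.

    ``K = Z Z' / p`` with ``Z`` the cell-line x gene matrix of per-gene
    standardized scaled fold changes (zero-variance genes dropped), rescaled
    so the mean diagonal equals 1.
    """
    values = sfm.values if hasattr(sfm, "values") and isinstance(sfm.values, pd.DataFrame) else sfm
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("build_kinship: dropped %d zero-variance genes", n_dropped)
    if not keep.any():
        raise ValueError("no genes with non-zero variance")
    z = (arr[keep] - arr[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    K = z.T @ z / keep.sum()
    K /= np.diag(K).mean()
    return Kinship(pd.DataFrame(K, index=values.columns, columns=values.columns))


def build_covariates(
    cell_lines,
    institute: pd.Series | None = None,
    culture: pd.Series | None = None,
    drug_pc1: pd.Series | None = None,
) -> pd.DataFrame:
    """Fixed-effect covariate matrix M: intercept, institute-of-origin
    indicators, drug-response PC1 and culture-condition indicators.

    Categorical covariates are one-hot encoded with the first level dropped
    (the intercept absorbs it); rank-deficient columns are removed later at
    fit time by a QR check on the observed subset.
    """
    cell_lines = pd.Index(cell_lines)
    M = pd.DataFrame({"intercept": 1.0}, index=cell_lines)
    for name, series in (("institute", institute), ("culture", culture)):
        if series is None:
            continue
        dummies = pd.get_dummies(series.reindex(cell_lines), prefix=name, drop_first=True)
        M = M.join(dummies.astype(float))
    if drug_pc1 is not None:
        M["drug_pc1"] = drug_pc1.reindex(cell_lines).astype(float)
    if M.isna().any().any():
        bad = M.columns[M.isna().any()].tolist()
        raise ValueError(f"covariates with missing values: {bad}")
    return M


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Column indices of a full-column-rank subset of X (greedy QR check)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return np.asarray(keep, dtype=int)


# ---------------------------------------------------------------------------
# spectral likelihood
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Maximum-likelihood fit of one mixed model.

    ``betas`` are the fixed-effect coefficients in the column order of the
    design (the predictor, when present, is the last column).  ``sigma_g2``
    is the genetic variance component (scale of the kinship random effect),
    ``sigma_e2`` the residual variance and ``delta = sigma_e2 / sigma_g2``.
    """

    betas: np.ndarray
    sigma_g2: float
    sigma_e2: float
    delta: float
    log_likelihood: float
    n_obs: int
    flagged: bool = False


def _profile_loglik(S, yr, Xr, delta):
    """Profile ML log-likelihood at a fixed variance ratio delta.

    With the model rotated into the eigenbasis of K the covariance is
    ``sg2 * diag(S + delta)``; betas are weighted least squares and
    ``sg2 = RSS_w / n``.
    """
    n = yr.shape[0]
    w = 1.0 / (S + delta)
    sw = np.sqrt(w)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma_g2 = max(rss / n, 1e-300)
    ll = -0.5 * (
        n * np.log(2.0 * np.pi) + n * np.log(sigma_g2) + np.log(S + delta).sum() + n
    )
    return ll, beta, sigma_g2, rank


def _optimize_delta(S, yr, Xr):
    """Maximize the profile likelihood over delta.

    Log-spaced grid search followed by bounded refinement around the best
    grid point; ties within ``LL_TOL`` broken toward smaller delta.
    """
    lls = np.array([_profile_loglik(S, yr, Xr, d)[0] for d in DELTA_GRID])
    best = lls.max()
    i = int(np.nonzero(lls >= best - LL_TOL)[0][0])  # smallest delta among ties
    lo = DELTA_GRID[max(i - 1, 0)]
    hi = DELTA_GRID[min(i + 1, len(DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_profile_loglik(S, yr, Xr, np.exp(t))[0],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta_ref, ll_ref = float(np.exp(res.x)), -float(res.fun)
    if ll_ref > lls[i] + LL_TOL:
        return delta_ref, ll_ref
    return float(DELTA_GRID[i]), float(lls[i])


def fit_lmm(y, M, K, e=None, delta=None) -> LMMFit:
    """Fit the mixed model by maximum likelihood.

    Parameters
    ----------
    y : outcome vector (complete; callers drop missing entries first).
    M : covariate matrix, n x k (DataFrame or array).
    K : `Kinship`, or a raw PSD similarity matrix aligned with ``y``.
    e : optional predictor vector appended as the last design column.
    delta : optionally fix the variance ratio instead of profiling it.
    """
    y = np.asarray(y, dtype=float)
    Marr = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)
    n = y.shape[0]
    if Marr.shape[0] != n:
        raise ValueError("outcome and covariates have mismatched lengths")

    if isinstance(K, Kinship):
        if len(K.cell_lines) != n:
            raise ValueError("kinship not aligned with outcome; subset it first")
        S, U = K.eigen(tuple(K.cell_lines))
    else:
        Karr = np.asarray(K, dtype=float)
        S, U = np.linalg.eigh(Karr)
        if S[0] < -1e-8:
            raise ValueError("similarity matrix is not positive semi-definite")
        S = np.maximum(S, EIG_FLOOR)

    X = Marr if e is None else np.column_stack([Marr, np.asarray(e, dtype=float)])
    if n < X.shape[1] + 2:
        raise ValueError("too few observations for the requested design")

    yr = U.T @ y
    Xr = U.T @ X

    flagged = False
    if e is not None and np.linalg.matrix_rank(Xr) < X.shape[1]:
        flagged = True  # collinear predictor: fit proceeds, LRT will be ~0

    if delta is None:
        delta, _ = _optimize_delta(S, yr, Xr)
    ll, beta, sigma_g2, _ = _profile_loglik(S, yr, Xr, delta)
    return LMMFit(
        betas=beta,
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        delta=float(delta),
        log_likelihood=float(ll),
        n_obs=n,
        flagged=flagged,
    )


def lrt_single(y, M, K, e, predictor_class: str = "fitness") -> dict:
    """Likelihood-ratio test of one predictor against the null model.

    Returns a result row (dict) with the fitted ``beta`` for the predictor,
    the LRT statistic (clamped at zero) and its chi-square(1) upper-tail
    p-value.  A degenerate predictor (zero variance on the observed subset)
    yields p = 1, beta = 0, flagged.
    """
    e = np.asarray(e, dtype=float)
    n = len(e)
    if np.ptp(e) == 0:
        return {
            "beta": 0.0, "lrt_stat": 0.0, "pval": 1.0, "n_obs": n,
            "predictor_class": predictor_class, "flagged": True,
        }
    null = fit_lmm(y, M, K)
    alt = fit_lmm(y, M, K, e=e)
    stat = max(2.0 * (alt.log_likelihood - null.log_likelihood), 0.0)
    pval = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return {
        "beta": float(alt.betas[-1]),
        "lrt_stat": float(stat),
        "pval": pval,
        "n_obs": n,
        "predictor_class": predictor_class,
        "flagged": bool(alt.flagged),
    }


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def scan(
    drm,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame,
    kinship: Kinship,
    mode: str = "fast",
    min_obs: int = MIN_OBS,
    predictor_class: str = "fitness",
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """All-pairs association scan: every drug against every predictor.

    For each drug, cell lines with missing response are dropped, the null
    model is fitted once on the observed subset, and every predictor is
    tested by LRT.  In ``fast`` mode the null-model variance ratio is reused
    for the alternative fits, which makes each test a rank-one weighted
    least-squares update (fully vectorized across predictors); the few tests
    whose screening statistic exceeds ``REFINE_STAT`` are then re-fitted with
    a per-test delta optimization, since the reuse approximation loses
    accuracy exactly for the strongest signals.  ``exact`` re-optimizes delta
    for every test.  Drugs with fewer than ``min_obs`` observed lines are
    skipped with a warning.  Returns the result table with per-drug
    Benjamini-Hochberg q-values already attached.
    """
    if mode not in ("fast", "exact"):
        raise ValueError(f"unknown scan mode {mode!r}")

    values = drm.values if hasattr(drm, "values") and isinstance(drm.values, pd.DataFrame) else drm
    shared = values.columns.intersection(predictors.columns)
    shared = shared.intersection(covariates.index).intersection(kinship.cell_lines)
    if shared.empty:
        raise ValueError("no shared cell lines between inputs")
    logger.info(
        "scan: %d drugs x %d predictors = %d planned tests",
        len(values.index), len(predictors.index),
        planned_test_count(len(values.index), len(predictors.index)),
    )

    pred_ids = predictors.index
    blocks: list[pd.DataFrame] = []
    for drug in values.index:
        y_all = values.loc[drug, shared]
        obs = shared[y_all.notna().to_numpy()]
        if len(obs) < min_obs:
            logger.warning(
                "scan: skipping drug %s (%d < %d observed cell lines)",
                drug, len(obs), min_obs,
            )
            continue
        y = y_all.loc[obs].to_numpy(dtype=float)
        S, U = kinship.eigen(tuple(obs))
        Mfull = covariates.loc[obs].to_numpy(dtype=float)
        Mobs = Mfull[:, _drop_collinear(Mfull)]
        E = predictors.loc[:, obs].to_numpy(dtype=float).T  # n_obs x n_pred

        yr = U.T @ y
        Mr = U.T @ Mobs
        delta0, ll_null = _optimize_delta(S, yr, Mr)

        if mode == "fast":
            block = _scan_drug_fast(S, U, yr, Mr, E, delta0, ll_null)
            refine = block.index[block["lrt_stat"] > REFINE_STAT]
            for j in refine:
                alt = fit_lmm(y, Mobs, _Precomputed(S, U), e=E[:, j])
                stat = max(2.0 * (alt.log_likelihood - ll_null), 0.0)
                block.loc[j, ["beta", "lrt_stat", "pval"]] = (
                    float(alt.betas[-1]), stat,
                    float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0,
                )
        else:
            block = _scan_drug_exact(y, Mobs, S, U, E, ll_null)
        block.insert(0, "drug_id", drug)
        block.insert(1, "predictor_id", pred_ids)
        block["n_obs"] = len(obs)
        block["predictor_class"] = predictor_class
        blocks.append(block)

    if not blocks:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    results = pd.concat(blocks, ignore_index=True)
    results = adjust_fdr_per_drug(results, threshold=fdr_threshold)
    return results[RESULT_COLUMNS + ["significant"]]


def _scan_drug_fast(S, U, yr, Mr, E, delta0, ll_null) -> pd.DataFrame:
    """Vectorized per-drug tests with the null delta reused.

    At fixed delta the LRT reduces to ``n * log(RSS_null / RSS_alt)`` in the
    whitened basis, and the alternative RSS is a rank-one update from the
    covariate-residualized predictor.
    """
    n = yr.shape[0]
    sw = np.sqrt(1.0 / (S + delta0))
    Mw = Mr * sw[:, None]
    yw = yr * sw
    Q, _ = np.linalg.qr(Mw)
    y_perp = yw - Q @ (Q.T @ yw)
    rss_null = float(y_perp @ y_perp)

    Ew = (U.T @ E) * sw[:, None]
    E_perp = Ew - Q @ (Q.T @ Ew)
    denom = np.einsum("ij,ij->j", E_perp, E_perp)
    num = E_perp.T @ y_perp

    scale = np.einsum("ij,ij->j", Ew, Ew)
    degenerate = denom <= np.maximum(scale, 1.0) * 1e-12
    safe_denom = np.where(degenerate, 1.0, denom)
    beta = np.where(degenerate, 0.0, num / safe_denom)
    rss_alt = np.maximum(rss_null - num**2 / safe_denom, 1e-300)
    lrt = np.where(degenerate, 0.0, np.maximum(n * np.log(rss_null / rss_alt), 0.0))
    pval = np.where(lrt > 0, stats.chi2.sf(lrt, df=1), 1.0)
    return pd.DataFrame({
        "beta": beta, "lrt_stat": lrt, "pval": pval, "flagged": degenerate,
    })


def _scan_drug_exact(y, Mobs, S, U, E, ll_null) -> pd.DataFrame:
    rows = []
    for j in range(E.shape[1]):
        e = E[:, j]
        if np.ptp(e) == 0:
            rows.append((0.0, 0.0, 1.0, True))
            continue
        alt = fit_lmm(y, Mobs, _Precomputed(S, U), e=e)
        stat = max(2.0 * (alt.log_likelihood - ll_null), 0.0)
        pval = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
        rows.append((float(alt.betas[-1]), stat, pval, alt.flagged))
    return pd.DataFrame(rows, columns=["beta", "lrt_stat", "pval", "flagged"])


class _Precomputed(Kinship):
    """Adapter handing a precomputed eigendecomposition to ``fit_lmm``."""

    def __init__(self, S, U):  # noqa: D401 - thin adapter, skip dataclass init
        self._S, self._U = S, U
        self.matrix = pd.DataFrame(np.empty((0, 0)))

    @property
    def cell_lines(self):
        return pd.RangeIndex(len(self._S))

    def eigen(self, cell_lines):
        return self._S, self._U


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def adjust_fdr_per_drug(
    results: pd.DataFrame,
    threshold: float = FDR_THRESHOLD,
    group_col: str = "drug_id",
) -> pd.DataFrame:
    """Benjamini-Hochberg step-up applied independently within each drug block.

    Adds ``qval`` and a ``significant`` flag at ``qval < threshold``.
    Per-drug correction keeps the two screening platforms separate and
    prevents drugs tested across many more lines from dominating a global
    correction.
    """
    pvals = results["pval"]
    if ((pvals < 0) | (pvals > 1)).any() or pvals.isna().any():
        raise ValueError("p-values must lie in [0, 1]")
    out = results.copy()
    out["qval"] = (
        out.groupby(group_col, sort=False)["pval"]
        .transform(lambda p: multipletests(p.to_numpy(), method="fdr_bh")[1])
    )
    out["significant"] = out["qval"] < threshold
    return out
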