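"""Preprocessing of CRISPR fitness screens and drug-sensitivity panels.

Turns raw screen outputs into the calibrated matrices the association scan
consumes:

* guide/replicate aggregation of log2 fold changes to gene level,
* per-sample quantile normalization followed by median scaling against
  reference essential / non-essential gene sets, so that in every cell line
  essential genes sit at a median scaled fold change of -1 and non-essential
  genes at 0,
* binary dependency calling (scaled fold change < -0.5),
* the drug inclusion filter (ln IC50 below half the maximum screened
  concentration in at least three cell lines),
* growth-rate computation from day-1 / day-4 negative-control readings,
* mean-imputation PCA of the drug-response matrix with per-component growth
  correlations, and
* ploidy-aware copy-number amplification calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("moascan")

DEPENDENCY_THRESHOLD = -0.5
#: minimum number of responsive cell lines for a drug to be retained
MIN_RESPONSIVE_LINES = 3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeMatrix:
    """Gene-level log2 fold changes (genes x cell lines).

    ``stage`` records how far along the normalization the matrix is:
    ``raw`` -> ``quantile-normalized`` -> ``scaled``.  Downstream callers
    that require calibrated input check the tag rather than guessing.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("fold-change matrix must not contain missing values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in fold-change matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell-line identifiers in fold-change matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cell_lines(self) -> pd.Index:
        return self.values.columns


@dataclass
class EssentialGeneSets:
    """Reference gene sets used to calibrate the per-sample fitness scale."""

    essential: frozenset
    nonessential: frozenset

    def __post_init__(self) -> None:
        self.essential = frozenset(self.essential)
        self.nonessential = frozenset(self.nonessential)
        if not self.essential or not self.nonessential:
            raise ValueError("essential and non-essential sets must be non-empty")
        if self.essential & self.nonessential:
            raise ValueError("essential and non-essential sets must be disjoint")

    def validate_against(self, genes: Iterable[str]) -> None:
        genes = set(genes)
        missing = (self.essential | self.nonessential) - genes
        if missing:
            raise ValueError(
                f"reference genes absent from matrix: {sorted(missing)[:5]}..."
            )


@dataclass
class DrugResponseMatrix:
    """Drug-sensitivity panel: drugs x cell lines natural-log IC50 (ln uM).

    Missing entries (drug not screened in a line) are NaN.  Per-drug
    metadata: maximum screened concentration (uM), screen batch
    (``GDSC1``/``GDSC2``) and the curated nominal target gene set (possibly
    empty).
    """

    values: pd.DataFrame
    max_conc: pd.Series
    batch: pd.Series
    targets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        drugs = self.values.index
        self.max_conc = self.max_conc.reindex(drugs)
        self.batch = self.batch.reindex(drugs)
        if self.max_conc.isna().any():
            bad = self.max_conc.index[self.max_conc.isna()].tolist()
            raise ValueError(f"missing max screened concentration for drugs: {bad}")
        if (self.max_conc <= 0).any():
            bad = self.max_conc.index[self.max_conc <= 0].tolist()
            raise ValueError(f"non-positive max concentration for drugs: {bad}")
        if self.batch.isna().any():
            bad = self.batch.index[self.batch.isna()].tolist()
            raise ValueError(f"missing screen batch label for drugs: {bad}")
        self.targets = {d: frozenset(self.targets.get(d, ())) for d in drugs}

    @property
    def drugs(self) -> pd.Index:
        return self.values.index

    @property
    def cell_lines(self) -> pd.Index:
        return self.values.columns


@dataclass
class PCAResult:
    """Scores/loadings of a mean-imputed PCA plus growth-rate correlations."""

    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components
    explained_variance_ratio: np.ndarray
    growth_correlation: pd.Series   # Pearson r of each component with growth


# ---------------------------------------------------------------------------
# guide aggregation
# ---------------------------------------------------------------------------

def aggregate_guides(
    guide_fc: pd.DataFrame,
    guide_to_gene: Mapping[str, str],
    replicate_to_line: Mapping[str, str],
) -> FoldChangeMatrix:
    """Collapse a guide x replicate fold-change matrix to gene x cell line.

    Replicate columns of the same cell line are mean-averaged first, then
    guide rows mapping to the same gene are mean-averaged.  Every guide must
    map to exactly one gene and every replicate to exactly one cell line.
    """
    unmapped_guides = [g for g in guide_fc.index if g not in guide_to_gene]
    if unmapped_guides:
        raise ValueError(f"unmapped guide identifiers: {unmapped_guides}")
    unmapped_reps = [r for r in guide_fc.columns if r not in replicate_to_line]
    if unmapped_reps:
        raise ValueError(f"unmapped replicate identifiers: {unmapped_reps}")

    by_line = guide_fc.T.groupby([replicate_to_line[r] for r in guide_fc.columns]).mean().T
    by_gene = by_line.groupby([guide_to_gene[g] for g in by_line.index]).mean()
    by_gene.index.name = "gene"
    by_gene.columns.name = "cell_line"
    return FoldChangeMatrix(values=by_gene, stage="raw")


# ---------------------------------------------------------------------------
# quantile normalization + median scaling
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Per-sample (column) quantile normalization.

    The reference distribution is the mean of the per-sample sorted values;
    tied values within a sample receive the mean of their tied reference
    positions (average ranks interpolated into the reference).
    """
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def scale_fold_changes(
    fc: FoldChangeMatrix, sets: EssentialGeneSets
) -> FoldChangeMatrix:
    """Quantile-normalize per sample then median-scale to the -1/0 calibration.

    After quantile normalization, each sample is affinely mapped by
    ``x -> (x - m_ne) / (m_ne - m_e)`` where ``m_e`` and ``m_ne`` are that
    sample's essential and non-essential medians.  This is the unique affine
    map sending ``(m_e, m_ne)`` to ``(-1, 0)``, so per sample the essential
    median is exactly -1 and the non-essential median exactly 0.
    """
    sets.validate_against(fc.genes)
    normed = quantile_normalize(fc.values)
    m_e = normed.loc[sorted(sets.essential)].median(axis=0)
    m_ne = normed.loc[sorted(sets.nonessential)].median(axis=0)
    span = m_ne - m_e
    degenerate = span == 0
    if degenerate.any():
        bad = span.index[degenerate].tolist()
        raise ValueError(
            f"degenerate calibration (essential median equals non-essential) "
            f"in samples: {bad}"
        )
    scaled = (normed - m_ne) / span
    return FoldChangeMatrix(values=scaled, stage="scaled")


def call_dependencies(sfm: FoldChangeMatrix) -> pd.DataFrame:
    """Binary dependency calls: scaled log2 fold change strictly below -0.5.

    A cell line is called dependent on a gene when knockout depletion reaches
    at least half of that seen for essential genes in that line.
    """
    if sfm.stage != "scaled":
        raise ValueError(
            f"dependency calling requires a scaled matrix, got stage={sfm.stage!r}"
        )
    return sfm.values < DEPENDENCY_THRESHOLD


# ---------------------------------------------------------------------------
# drug-response filtering and growth rate
# ---------------------------------------------------------------------------

def filter_drugs(
    drm: DrugResponseMatrix, min_lines: int = MIN_RESPONSIVE_LINES
) -> DrugResponseMatrix:
    """Retain drugs responsive in at least ``min_lines`` cell lines.

    A cell line counts as responsive when its ln IC50 is strictly below
    ``ln(Cmax / 2)`` for that drug (comparison in ln-concentration space,
    since IC50s are stored as natural logs of uM concentrations).  Retained
    values are untouched and drug order is preserved.
    """
    threshold = np.log(drm.max_conc / 2.0)
    responsive = drm.values.lt(threshold, axis=0).sum(axis=1)
    keep = responsive[responsive >= min_lines].index
    dropped = drm.drugs.difference(keep)
    if len(dropped):
        logger.info("filter_drugs: dropped %d of %d drugs", len(dropped), len(drm.drugs))
    return DrugResponseMatrix(
        values=drm.values.loc[keep],
        max_conc=drm.max_conc.loc[keep],
        batch=drm.batch.loc[keep],
        targets={d: drm.targets[d] for d in keep},
    )


def compute_growth_rate(
    day1: Mapping[str, Sequence[float]],
    day4: Mapping[str, Sequence[float]],
    orientation: str = "day4_over_day1",
) -> pd.Series:
    """Growth rate per cell line from negative-control readings.

    ``day1`` holds untreated control readings at the time of drug treatment
    and ``day4`` DMSO-treated control readings 72 h later.  The default
    orientation, ``day4_over_day1`` = mean(day4)/mean(day1), makes larger
    values mean faster growth; ``day1_over_day4`` gives the literal inverse.
    The chosen orientation is recorded in ``Series.attrs``.
    """
    if orientation not in ("day4_over_day1", "day1_over_day4"):
        raise ValueError(f"unknown orientation {orientation!r}")
    lines = sorted(set(day1) | set(day4))
    rates = {}
    for line in lines:
        if line not in day1 or line not in day4:
            raise ValueError(f"cell line {line!r} missing readings for one day")
        r1 = np.asarray(list(day1[line]), dtype=float)
        r4 = np.asarray(list(day4[line]), dtype=float)
        if r1.size == 0 or r4.size == 0:
            raise ValueError(f"cell line {line!r} has an empty reading set")
        if (r1 <= 0).any() or (r4 <= 0).any():
            raise ValueError(f"non-positive control reading for cell line {line!r}")
        ratio = r4.mean() / r1.mean()
        rates[line] = ratio if orientation == "day4_over_day1" else 1.0 / ratio
    out = pd.Series(rates, name="growth_rate")
    out.attrs["orientation"] = orientation
    return out


# ---------------------------------------------------------------------------
# PCA with drug-mean imputation
# ---------------------------------------------------------------------------

def pca_with_imputation(
    values: pd.DataFrame,
    n_components: int,
    growth: pd.Series | None = None,
) -> PCAResult:
    """PCA of a features x samples matrix after per-feature mean imputation.

    Rows are features (drugs), columns samples (cell lines).  Each missing
    entry is replaced with its feature's observed mean across the remaining
    samples; samples are then decomposed with mean-centred PCA.  When a
    growth-rate vector is supplied, the Pearson correlation of every
    component's sample scores with growth is reported.
    """
    from sklearn.decomposition import PCA

    if values.isna().all(axis=1).any():
        bad = values.index[values.isna().all(axis=1)].tolist()
        raise ValueError(f"features with no observed values: {bad}")
    if n_components > min(values.shape):
        raise ValueError("n_components exceeds matrix rank bound")

    imputed = values.apply(lambda row: row.fillna(row.mean()), axis=1)
    X = imputed.T.to_numpy(dtype=float)  # samples x features
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=values.columns, columns=comp_names)
    loadings_df = pd.DataFrame(pca.components_.T, index=values.index, columns=comp_names)

    if growth is not None:
        aligned = growth.reindex(values.columns)
        corr = scores_df.apply(lambda s: s.corr(aligned))
    else:
        corr = pd.Series(np.nan, index=comp_names)
    corr.name = "growth_correlation"
    return PCAResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        growth_correlation=corr,
    )


# ---------------------------------------------------------------------------
# amplification calling
# ---------------------------------------------------------------------------

def call_amplifications(copy_number, ploidy) -> np.ndarray:
    """Ploidy-aware amplification calls.

    A sample is amplified when (ploidy <= 2.7 and copy number >= 5) or
    (ploidy > 2.7 and copy number >= 9); both boundaries inclusive.
    """
    cn = np.asarray(copy_number, dtype=float)
    pl = np.asarray(ploidy, dtype=float)
    if cn.shape != pl.shape:
        raise ValueError("copy-number and ploidy vectors must have equal length")
    if (pl <= 0).any():
        raise ValueError("ploidy must be positive")
    if (cn < 0).any():
        raise ValueError("negative copy number")
    return np.where(pl <= 2.7, cn >= 5, cn >= 9)
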