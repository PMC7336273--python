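"""Synthetic screening panels with planted ground truth.

Generates the full complement of inputs the analysis consumes — a raw
gene-level CRISPR fold-change matrix, a drug-response (ln IC50) matrix with
missing entries, cell-line metadata, a protein-interaction network, binary
genomic and continuous expression feature matrices, and a ChEMBL-style
bioactivity table — with known planted structure so every downstream stage
can be scored against truth:

* each drug gets a planted target gene whose scaled fitness profile drives
  its response with effect size ``target_effect`` (ln IC50 units per scaled
  fitness unit), mirroring the fixed-effect term of the association model;
* low-rank Gaussian lineage factors are shared between the fitness and drug
  matrices, so the kinship random effect is genuinely confounding;
* institute-of-origin, growth-rate and culture-condition effects confound
  the response exactly as the scan's fixed covariates assume;
* per drug, one molecular biomarker (alternating genomic / expression) shifts
  both the drug's response and its target gene's fitness by
  ``biomarker_effect``, the structure the robust-biomarker stage looks for;
* IC50 entries are masked completely at random at ``missing_rate``.

All randomness flows from the single ``seed`` in `PanelConfig`; each
generator derives an independent deterministic stream from it, so identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .preprocess import (
    DrugResponseMatrix,
    EssentialGeneSets,
    FoldChangeMatrix,
    scale_fold_changes,
)

CULTURE_LEVELS = ("adherent", "suspension", "semi-adherent")
INSTITUTES = ("Sanger", "Broad")

# per-generator stream keys, combined with the config seed
_STREAM_PANEL, _STREAM_PPI, _STREAM_FEATURES, _STREAM_BIOACTIVITY = 0, 1, 2, 3

# family activity thresholds (molar) used to emit the bioactivity truth;
# the generator applies them by direct enumeration, independently of the
# target-calling module it is used to test
_FAMILY_THRESHOLDS_M = {
    "Kinase": 30e-9,
    "GPCR": 100e-9,
    "NuclearReceptor": 100e-9,
    "IonChannel": 10e-6,
    "Other": 1e-6,
}


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for one synthetic panel.

    Defaults emulate a pan-cancer screening panel of 484 cell lines with a
    gene space scaled down to 1,000, drugs with a single nominal target
    each, unit planted effect size, roughly comparable signal and nuisance
    variance, and 10% of IC50 entries missing at random.
    """

    n_cell_lines: int = 484
    n_genes: int = 1000
    n_drugs: int = 20
    n_essential: int = 50
    n_nonessential: int = 50
    n_latent: int = 5
    target_effect: float = 1.0
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    biomarker_effect: float = 1.0
    seed: int = 0
    # nuisance scales (not part of the planted truth): per-drug covariate
    # effect spread and the lineage-factor contribution to both matrices
    covariate_sd: float = 0.5
    latent_scale: float = 0.5
    n_decoy_features: int = 30

    def __post_init__(self) -> None:
        for name in (
            "n_cell_lines", "n_genes", "n_drugs", "n_essential",
            "n_nonessential", "n_latent",
        ):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_essential + self.n_nonessential > self.n_genes:
            raise ValueError(
                "n_essential + n_nonessential must not exceed n_genes"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.covariate_sd < 0:
            raise ValueError("covariate_sd must be non-negative")
        if self.latent_scale < 0:
            raise ValueError("latent_scale must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic panel, recoverable for scoring."""

    targets: dict                      # drug_id -> target gene
    betas: dict                        # drug_id -> planted effect size
    biomarkers: pd.DataFrame           # feature_id, drug_id, gene_id, feature_class, effect
    biomarker_values: dict             # feature_id -> np.ndarray over cell lines
    latent_loadings: pd.DataFrame      # cell lines x latent factors
    essential: list
    nonessential: list


@dataclass
class SyntheticPanel:
    """Everything `generate_panel` emits, bundled."""

    config: PanelConfig
    fold_changes: FoldChangeMatrix     # raw, genes x cell lines
    drug_response: DrugResponseMatrix
    cell_meta: pd.DataFrame            # institute, culture, growth_rate
    gene_sets: EssentialGeneSets
    truth: GroundTruth


def _rng(config: PanelConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def generate_panel(config: PanelConfig) -> SyntheticPanel:
    """Generate the raw fitness matrix, drug-response matrix and metadata.

    Fitness values are a per-gene baseline (essential genes around -2 raw
    log2 fold change, non-essential around 0) plus a shared low-rank lineage
    component plus Gaussian noise.  Drug ln IC50 is an intercept plus the
    planted target effect on the target's *scaled* fitness, covariate effects
    (institute, growth rate, culture), the lineage component, the planted
    biomarker shift and noise; entries are then masked at ``missing_rate``.
    """
    rng = _rng(config, _STREAM_PANEL)
    nc, ng, nd = config.n_cell_lines, config.n_genes, config.n_drugs

    cells = [f"CL{i + 1:04d}" for i in range(nc)]
    genes = [f"G{i + 1:05d}" for i in range(ng)]
    drugs = [f"D{i + 1:03d}" for i in range(nd)]
    essential = genes[: config.n_essential]
    nonessential = genes[config.n_essential: config.n_essential + config.n_nonessential]
    other = genes[config.n_essential + config.n_nonessential:]

    # cell-line metadata
    institute = rng.choice(INSTITUTES, size=nc, p=[2 / 3, 1 / 3])
    culture = rng.choice(CULTURE_LEVELS, size=nc, p=[0.7, 0.2, 0.1])
    growth = rng.lognormal(mean=0.0, sigma=0.25, size=nc)
    cell_meta = pd.DataFrame(
        {"institute": institute, "culture": culture, "growth_rate": growth},
        index=pd.Index(cells, name="cell_line"),
    )

    # lineage latent factors shared by fitness and response
    loadings = rng.standard_normal((nc, config.n_latent))
    gene_factors = rng.standard_normal((ng, config.n_latent))
    gene_factors *= config.latent_scale / np.sqrt(config.n_latent)

    baseline = np.empty(ng)
    baseline[: config.n_essential] = rng.normal(-2.0, 0.2, config.n_essential)
    baseline[config.n_essential: config.n_essential + config.n_nonessential] = (
        rng.normal(0.0, 0.1, config.n_nonessential)
    )
    baseline[config.n_essential + config.n_nonessential:] = (
        rng.normal(-0.3, 0.4, len(other))
    )

    fitness = (
        baseline[:, None]
        + gene_factors @ loadings.T
        + rng.normal(0.0, config.noise_sd, (ng, nc))
    )

    # planted targets (distinct, drawn from the unconstrained gene pool)
    pool = other if len(other) >= nd else genes
    if len(pool) < nd:
        raise ValueError("n_genes too small to assign a distinct target per drug")
    target_genes = [str(g) for g in rng.choice(pool, size=nd, replace=False)]
    targets = dict(zip(drugs, target_genes))

    # planted biomarkers: one per drug, alternating genomic / expression;
    # each shifts both the drug response and the target gene's raw fitness
    bm_rows, bm_values = [], {}
    fitness_df = pd.DataFrame(fitness, index=genes, columns=cells)
    for i, drug in enumerate(drugs):
        gene = targets[drug]
        if i % 2 == 0:
            fid = f"mut_{gene}"
            vec = (rng.random(nc) < 0.3).astype(float)
            fclass = "genomic"
        else:
            fid = f"gexp_{gene}"
            vec = rng.standard_normal(nc)
            fclass = "expression"
        bm_rows.append((fid, drug, gene, fclass, config.biomarker_effect))
        bm_values[fid] = vec
        fitness_df.loc[gene] = fitness_df.loc[gene] - config.biomarker_effect * vec
    biomarkers = pd.DataFrame(
        bm_rows, columns=["feature_id", "drug_id", "gene_id", "feature_class", "effect"]
    )

    gene_sets = EssentialGeneSets(essential=essential, nonessential=nonessential)
    raw = FoldChangeMatrix(values=fitness_df, stage="raw")
    scaled = scale_fold_changes(raw, gene_sets)

    # drug response
    intercept = rng.normal(2.0, 1.0, nd)
    inst_coef = rng.normal(0.0, config.covariate_sd, nd)
    growth_coef = rng.normal(0.0, config.covariate_sd, nd)
    culture_coef = rng.normal(0.0, config.covariate_sd, (nd, 2))  # suspension, semi
    drug_factors = rng.standard_normal((nd, config.n_latent))
    drug_factors *= config.latent_scale / np.sqrt(config.n_latent)

    is_broad = (institute == "Broad").astype(float)
    growth_z = (growth - growth.mean()) / growth.std() if growth.std() > 0 else growth * 0
    is_susp = (culture == "suspension").astype(float)
    is_semi = (culture == "semi-adherent").astype(float)

    response = (
        intercept[:, None]
        + inst_coef[:, None] * is_broad[None, :]
        + growth_coef[:, None] * growth_z[None, :]
        + culture_coef[:, [0]] * is_susp[None, :]
        + culture_coef[:, [1]] * is_semi[None, :]
        + drug_factors @ loadings.T
        + rng.normal(0.0, config.noise_sd, (nd, nc))
    )
    # biomarker sign convention: an altered feature deepens the target's
    # loss-of-fitness (shift applied above) and, coherently, sensitizes the
    # cell line to the drug (lower ln IC50)
    for i, drug in enumerate(drugs):
        response[i] += config.target_effect * scaled.values.loc[targets[drug]].to_numpy()
        fid = biomarkers.loc[biomarkers["drug_id"] == drug, "feature_id"].iloc[0]
        response[i] -= config.biomarker_effect * bm_values[fid]

    response_df = pd.DataFrame(response, index=drugs, columns=cells)

    # mask exactly round(missing_rate * n_drugs * n_cell_lines) entries
    n_mask = int(round(config.missing_rate * nd * nc))
    if n_mask:
        flat = rng.choice(nd * nc, size=n_mask, replace=False)
        arr = response_df.to_numpy()
        arr[np.unravel_index(flat, arr.shape)] = np.nan
        response_df = pd.DataFrame(arr, index=drugs, columns=cells)

    max_conc = pd.Series(np.exp(intercept + 1.0), index=drugs, name="max_conc_uM")
    batch = pd.Series(
        rng.choice(["GDSC1", "GDSC2"], size=nd), index=drugs, name="batch"
    )
    drm = DrugResponseMatrix(
        values=response_df,
        max_conc=max_conc,
        batch=batch,
        targets={d: {targets[d]} for d in drugs},
    )

    truth = GroundTruth(
        targets=targets,
        betas={d: config.target_effect for d in drugs},
        biomarkers=biomarkers,
        biomarker_values=bm_values,
        latent_loadings=pd.DataFrame(
            loadings, index=cells,
            columns=[f"LF{i + 1}" for i in range(config.n_latent)],
        ),
        essential=list(essential),
        nonessential=list(nonessential),
    )
    return SyntheticPanel(
        config=config,
        fold_changes=raw,
        drug_response=drm,
        cell_meta=cell_meta,
        gene_sets=gene_sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# protein-interaction network
# ---------------------------------------------------------------------------

def generate_ppi_network(
    config: PanelConfig, truth: GroundTruth
) -> tuple[nx.Graph, pd.DataFrame]:
    """Protein network with designated genes at known distances from targets.

    Each planted target anchors a path of panel genes at shortest-path
    distances 1, 2, 3 and 4; one two-node decoy component is unreachable
    from every target.  Returns the graph together with the true distance
    table (``target``, ``gene``, ``distance``) for oracle tests.
    """
    rng = _rng(config, _STREAM_PPI)
    targets = list(dict.fromkeys(truth.targets.values()))
    reserved = set(targets) | set(truth.essential) | set(truth.nonessential)
    free = [g for g in _panel_genes(config) if g not in reserved]
    needed = 4 * len(targets) + 2
    if len(free) < needed:
        raise ValueError(
            f"cannot place designated distances: need {needed} free genes, "
            f"have {len(free)}"
        )
    rng.shuffle(free)

    graph = nx.Graph()
    rows = []
    cursor = 0
    for t in targets:
        chain = free[cursor: cursor + 4]
        cursor += 4
        path = [t, *chain]
        nx.add_path(graph, path)
        for d, gene in enumerate(chain, start=1):
            rows.append((t, gene, d))
        rows.append((t, t, 0))
    # unreachable decoy component
    decoy = free[cursor: cursor + 2]
    graph.add_edge(*decoy)
    for t in targets:
        for gene in decoy:
            rows.append((t, gene, -1))  # -1 encodes "unreachable"

    nx.set_edge_attributes(graph, 999, "combined_score")
    table = pd.DataFrame(rows, columns=["target", "gene", "distance"])
    return graph, table


def _panel_genes(config: PanelConfig) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(config.n_genes)]


# ---------------------------------------------------------------------------
# molecular feature matrices
# ---------------------------------------------------------------------------

def generate_molecular_features(
    config: PanelConfig, truth: GroundTruth, panel: SyntheticPanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary genomic and continuous expression feature matrices.

    The planted biomarker vectors (already wired into the panel's outcomes
    by `generate_panel`) become feature rows, padded with decoy features
    drawn independently of every outcome.  The genomic matrix is strictly
    0/1.
    """
    rng = _rng(config, _STREAM_FEATURES)
    cells = list(panel.cell_meta.index)
    nc = len(cells)

    genomic_rows, expression_rows = {}, {}
    for _, row in truth.biomarkers.iterrows():
        vec = truth.biomarker_values[row.feature_id]
        if row.feature_class == "genomic":
            genomic_rows[row.feature_id] = vec.astype(int)
        else:
            expression_rows[row.feature_id] = vec
    for i in range(config.n_decoy_features):
        genomic_rows[f"mut_decoy{i + 1:03d}"] = (rng.random(nc) < 0.25).astype(int)
        expression_rows[f"gexp_decoy{i + 1:03d}"] = rng.standard_normal(nc)

    genomic = pd.DataFrame.from_dict(genomic_rows, orient="index", columns=cells)
    expression = pd.DataFrame.from_dict(expression_rows, orient="index", columns=cells)
    genomic.index.name = expression.index.name = "feature_id"
    return genomic, expression


# ---------------------------------------------------------------------------
# bioactivity records
# ---------------------------------------------------------------------------

def generate_bioactivity_table(
    config: PanelConfig,
) -> tuple[pd.DataFrame, dict]:
    """ChEMBL-style bioactivity records plus the expected active-target truth.

    Emits a mixture of eligible records (pChEMBL present, relation '=',
    human, protein-type target) spanning the family activity thresholds, and
    ineligible decoys (missing pChEMBL, inequality relations, non-human
    organisms, non-protein target types).  The truth dict carries the
    per-drug active target sets and a per-record eligibility flag, both
    computed by direct enumeration.
    """
    rng = _rng(config, _STREAM_BIOACTIVITY)
    drugs = [f"D{i + 1:03d}" for i in range(config.n_drugs)]
    families = list(_FAMILY_THRESHOLDS_M)

    rows = []
    for drug in drugs:
        n_records = int(rng.integers(3, 8))
        for r in range(n_records):
            family = families[int(rng.integers(len(families)))]
            threshold = _FAMILY_THRESHOLDS_M[family]
            # pChEMBL drawn around the family threshold so both sides occur
            pchembl = -np.log10(threshold) + rng.normal(0.0, 1.0)
            record = {
                "drug_id": drug,
                "target_id": f"T{int(rng.integers(1, 200)):04d}",
                "family": family,
                "target_type": "single protein",
                "organism": "Homo sapiens",
                "relation": "=",
                "pchembl": round(float(pchembl), 2),
            }
            kind = rng.random()
            if kind < 0.10:
                record["pchembl"] = np.nan
            elif kind < 0.18:
                record["relation"] = ">"
            elif kind < 0.24:
                record["organism"] = "Rattus norvegicus"
            elif kind < 0.30:
                record["target_type"] = "cell-line"
            rows.append(record)
    records = pd.DataFrame(rows)

    eligible = (
        records["pchembl"].notna()
        & (records["relation"] == "=")
        & (records["organism"] == "Homo sapiens")
        & records["target_type"].isin(
            ["single protein", "protein complex", "protein complex group",
             "protein-protein interaction", "protein family"]
        )
    )
    active_sets: dict[str, set] = {d: set() for d in drugs}
    for _, rec in records[eligible].iterrows():
        conc = 10.0 ** (-rec.pchembl)
        if conc <= _FAMILY_THRESHOLDS_M[rec.family]:
            active_sets[rec.drug_id].add(rec.target_id)
    truth = {
        "active_sets": {d: frozenset(s) for d, s in active_sets.items()},
        "record_eligible": eligible,
    }
    return records, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_panel(panel: SyntheticPanel, outdir: str | Path) -> dict:
    """Write a panel as the delimited-text layouts the pipeline reads.

    Matrices carry the identifier in the first column and cell lines as the
    header; the ground truth is serialized as a plain key-value YAML
    document.  Returns the mapping of logical names to written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fitness": outdir / "fitness_raw.tsv",
        "drug_response": outdir / "drug_response.tsv",
        "drug_meta": outdir / "drug_meta.tsv",
        "cell_meta": outdir / "cell_meta.tsv",
        "essential": outdir / "essential_genes.txt",
        "nonessential": outdir / "nonessential_genes.txt",
        "truth": outdir / "truth.yaml",
    }
    panel.fold_changes.values.to_csv(paths["fitness"], sep="\t", index_label="gene")
    panel.drug_response.values.to_csv(paths["drug_response"], sep="\t", index_label="drug_id")
    drm = panel.drug_response
    meta = pd.DataFrame({
        "drug_id": drm.drugs,
        "name": drm.drugs,
        "targets": [";".join(sorted(drm.targets[d])) for d in drm.drugs],
        "max_conc_uM": drm.max_conc.to_numpy(),
        "batch": drm.batch.to_numpy(),
    })
    meta.to_csv(paths["drug_meta"], sep="\t", index=False)
    panel.cell_meta.to_csv(paths["cell_meta"], sep="\t", index_label="cell_line")
    paths["essential"].write_text("\n".join(panel.truth.essential) + "\n")
    paths["nonessential"].write_text("\n".join(panel.truth.nonessential) + "\n")
    truth_doc = {
        "targets": dict(panel.truth.targets),
        "betas": {k: float(v) for k, v in panel.truth.betas.items()},
        "biomarkers": panel.truth.biomarkers.to_dict(orient="records"),
    }
    paths["truth"].write_text(yaml.safe_dump(truth_doc, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
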