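"""End-to-end orchestration: preprocess -> scan -> annotate -> robust -> models.

The pipeline is configured by a plain YAML document (paths plus thresholds),
logs row counts in and out of every filter, and writes every result table as
delimited text together with a manifest recording the configuration hash and
seed, so a rerun with an identical configuration reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lmm, models, ppi, preprocess, robust

logger = logging.getLogger("moascan")

STAGE_OUTPUTS = [
    "scaled_fitness.tsv",
    "drug_response_filtered.tsv",
    "associations.tsv",
    "volcano.tsv",
    "drug_summary.tsv",
    "robust_associations.tsv",
    "model_reports.tsv",
]


@dataclass
class PipelineConfig:
    """Paths and thresholds steering one pipeline run."""

    fitness: str
    drug_response: str
    drug_meta: str
    cell_meta: str
    essential: str
    nonessential: str
    network: str | None = None
    genomic: str | None = None
    expression: str | None = None
    outdir: str = "moascan_out"
    fdr_threshold: float = 0.10
    scan_mode: str = "fast"
    min_obs: int = 15
    r2_threshold: float = 0.3
    n_model_splits: int = 100
    train_fraction: float = 0.7
    model_drugs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in [0, 1]")
        if self.scan_mode not in ("fast", "exact"):
            raise ValueError(f"unknown scan_mode {self.scan_mode!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.min_obs < 3:
            raise ValueError("min_obs must be at least 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def validate_paths(self) -> None:
        """All referenced input paths must be readable before any stage runs."""
        for name in ("fitness", "drug_response", "drug_meta", "cell_meta",
                     "essential", "nonessential", "network", "genomic", "expression"):
            value = getattr(self, name)
            if value is not None and not Path(value).is_file():
                raise FileNotFoundError(f"config path {name!r} not readable: {value}")

    def content_hash(self) -> str:
        doc = dataclasses.asdict(self)
        return hashlib.sha256(
            yaml.safe_dump(doc, sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers (delimited-text layouts: first column identifier, header cell lines)
# ---------------------------------------------------------------------------

def load_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def load_fitness_matrix(path: str | Path) -> preprocess.FoldChangeMatrix:
    return preprocess.FoldChangeMatrix(values=load_matrix(path), stage="raw")


def load_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def load_drug_response(values_path: str | Path, meta_path: str | Path) -> preprocess.DrugResponseMatrix:
    values = load_matrix(values_path)
    meta = pd.read_csv(meta_path, sep="\t", index_col="drug_id")
    targets = {
        d: set(str(t).split(";")) if pd.notna(t) and str(t) else set()
        for d, t in meta["targets"].items()
    }
    return preprocess.DrugResponseMatrix(
        values=values,
        max_conc=meta["max_conc_uM"],
        batch=meta["batch"],
        targets=targets,
    )


# ---------------------------------------------------------------------------
# report exports
# ---------------------------------------------------------------------------

def export_volcano(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-association volcano table: effect size, -log10 p, q, distance category."""
    out = pd.DataFrame({
        "drug_id": annotated["drug_id"],
        "predictor_id": annotated["predictor_id"],
        "beta": annotated["beta"],
        "minus_log10_pval": -np.log10(annotated["pval"].clip(lower=1e-300)),
        "qval": annotated["qval"],
        "ppi_category": annotated.get("ppi_category", "-"),
    })
    out.loc[annotated["pval"] >= 1.0, "minus_log10_pval"] = 0.0
    return out


_CATEGORY_ORDER = {"T": 0, "1": 1, "2": 2, "3": 3}


def summarize_drugs(
    annotated: pd.DataFrame,
    drug_targets: dict,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-drug classification by the best (smallest-distance) significant hit.

    Categories: "T" when a drug has a significant association with one of its
    nominal targets, "1"/"2"/"3" when the closest significant hit sits that
    many interactions from a target, "-" when significant hits exist but none
    is network-linked within three steps, and "X" for drugs with no
    significant association at all.  Drugs without target annotation are
    reported with ``annotated=False``.
    """
    rows = []
    for drug, block in annotated.groupby("drug_id", sort=False):
        has_targets = bool(drug_targets.get(drug))
        hits = block[block["qval"] < fdr_threshold]
        if hits.empty:
            label = "X"
        else:
            label = min(
                (c for c in hits["ppi_category"] if c in _CATEGORY_ORDER),
                key=_CATEGORY_ORDER.get,
                default="-",
            )
        rows.append({
            "drug_id": drug,
            "category": label,
            "n_significant": int((block["qval"] < fdr_threshold).sum()),
            "annotated": has_targets,
        })
    return pd.DataFrame(rows)


def category_percentages(summary: pd.DataFrame) -> pd.Series:
    """Category counts as percentages of the annotated drug universe."""
    annotated = summary[summary["annotated"]]
    counts = annotated["category"].value_counts()
    return 100.0 * counts / len(annotated)


def target_or_related_percentage(
    n_target: int, n_related: int, n_annotated: int
) -> float:
    """Percentage of annotated drugs hitting their target or a protein within
    three interactions of it."""
    if n_annotated <= 0:
        raise ValueError("n_annotated must be positive")
    return 100.0 * (n_target + n_related) / n_annotated


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the results bundle under ``outdir``.

    Stage order: preprocessing (scaling + drug filter), kinship/covariates,
    association scan with per-drug FDR, PPI distance annotation, volcano and
    per-drug summary exports, robust-biomarker testing of the significant
    pairs, and repeated-split response models.  Stage failures abort with
    the stage name attached.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    stage = _stage("preprocess")
    try:
        fc = load_fitness_matrix(config.fitness)
        sets = preprocess.EssentialGeneSets(
            essential=load_gene_list(config.essential),
            nonessential=load_gene_list(config.nonessential),
        )
        sfm = preprocess.scale_fold_changes(fc, sets)
        drm = load_drug_response(config.drug_response, config.drug_meta)
        n_before = len(drm.drugs)
        drm = preprocess.filter_drugs(drm)
        logger.info("filter_drugs: %d -> %d drugs", n_before, len(drm.drugs))
        cell_meta = pd.read_csv(config.cell_meta, sep="\t", index_col=0)

        path = outdir / "scaled_fitness.tsv"
        sfm.values.to_csv(path, sep="\t", index_label="gene")
        written["scaled_fitness"] = str(path)
        path = outdir / "drug_response_filtered.tsv"
        drm.values.to_csv(path, sep="\t", index_label="drug_id")
        written["drug_response_filtered"] = str(path)

        stage = _stage("kinship_covariates")
        kinship = lmm.build_kinship(sfm)
        pca = preprocess.pca_with_imputation(
            drm.values, n_components=min(10, min(drm.values.shape)),
            growth=cell_meta.get("growth_rate"),
        )
        covariates = lmm.build_covariates(
            sfm.cell_lines,
            institute=cell_meta.get("institute"),
            culture=cell_meta.get("culture"),
            drug_pc1=pca.scores["PC1"],
        )

        stage = _stage("scan")
        results = lmm.scan(
            drm, sfm.values, covariates, kinship,
            mode=config.scan_mode, min_obs=config.min_obs,
            fdr_threshold=config.fdr_threshold,
        )

        stage = _stage("ppi_annotation")
        if config.network is not None:
            net = ppi.simplify_network(ppi.load_string_network(config.network))
            annotated = ppi.annotate_target_distance(results, net, drm.targets)
        else:
            annotated = results.copy()
            annotated["ppi_distance"] = -1
            annotated["ppi_category"] = "-"
            annotated["ppi_reason"] = "no_network_supplied"
        path = outdir / "associations.tsv"
        annotated.to_csv(path, sep="\t", index=False)
        written["associations"] = str(path)

        stage = _stage("reports")
        volcano = export_volcano(annotated)
        path = outdir / "volcano.tsv"
        volcano.to_csv(path, sep="\t", index=False)
        written["volcano"] = str(path)
        summary = summarize_drugs(annotated, drm.targets, config.fdr_threshold)
        path = outdir / "drug_summary.tsv"
        summary.to_csv(path, sep="\t", index=False)
        written["drug_summary"] = str(path)

        stage = _stage("robust_biomarkers")
        genomic = load_matrix(config.genomic) if config.genomic else None
        expression = load_matrix(config.expression) if config.expression else None
        robust_rows = []
        if genomic is not None or expression is not None:
            significant = annotated[annotated["significant"]]
            for drug, gene in significant[["drug_id", "predictor_id"]].itertuples(index=False):
                rows = robust.test_pair_features(
                    (drug, gene), genomic, expression, drm, sfm, covariates, kinship,
                )
                if not rows.empty:
                    robust_rows.append(rows)
        if robust_rows:
            tested = pd.concat(robust_rows, ignore_index=True)
            flagged = robust.flag_robust(
                robust.adjust_per_pair(tested), fdr_threshold=config.fdr_threshold
            )
        else:
            flagged = pd.DataFrame(columns=robust.ROBUST_COLUMNS)
        path = outdir / "robust_associations.tsv"
        flagged.to_csv(path, sep="\t", index=False)
        written["robust_associations"] = str(path)

        stage = _stage("response_models")
        model_drugs = config.model_drugs or list(drm.drugs[:1])
        reports = []
        for drug in model_drugs:
            feature_genes = sorted(drm.targets.get(drug, set()))
            feature_genes = [g for g in feature_genes if g in sfm.values.index]
            sets_for_drug = {}
            if feature_genes:
                sets_for_drug["fitness"] = sfm.values.loc[feature_genes]
            if expression is not None and not expression.empty:
                sets_for_drug["expression"] = expression
                if feature_genes:
                    both = pd.concat([sfm.values.loc[feature_genes], expression])
                    sets_for_drug["both"] = both
            if not sets_for_drug:
                continue
            result = models.compare_feature_sets(
                drm.values.loc[drug], sets_for_drug, drug_id=drug,
                n_splits=config.n_model_splits,
                train_frac=config.train_fraction, seed=config.seed,
            )
            reports.extend(result.values())
        model_table = models.reports_to_frame(reports)
        path = outdir / "model_reports.tsv"
        model_table.to_csv(path, sep="\t", index=False)
        written["model_reports"] = str(path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "outputs": [written[k] for k in (
            "scaled_fitness", "drug_response_filtered", "associations",
            "volcano", "drug_summary", "robust_associations", "model_reports",
        )],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = str(manifest_path)
    return written
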