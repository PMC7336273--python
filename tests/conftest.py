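"""Shared fixtures: synthetic panels at two scales plus derived scan inputs.

The default-scale panel (484 cell lines, 1,000 genes, 20 drugs) and the
matching null panel are expensive enough to build once per session; the
small panel is cheap and rebuilt per module where mutation is a risk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import moascan as m
from moascan import lmm, preprocess


def build_scan_inputs(panel):
    """Scaled fitness, kinship and covariates for a generated panel."""
    sfm = preprocess.scale_fold_changes(panel.fold_changes, panel.gene_sets)
    kinship = lmm.build_kinship(sfm)
    pca = preprocess.pca_with_imputation(
        panel.drug_response.values,
        n_components=min(5, min(panel.drug_response.values.shape)),
        growth=panel.cell_meta["growth_rate"],
    )
    covariates = lmm.build_covariates(
        sfm.cell_lines,
        institute=panel.cell_meta["institute"],
        culture=panel.cell_meta["culture"],
        drug_pc1=pca.scores["PC1"],
    )
    return sfm, kinship, covariates


@pytest.fixture(scope="session")
def small_config():
    return m.PanelConfig(
        n_cell_lines=60, n_genes=150, n_drugs=6,
        n_essential=20, n_nonessential=20, seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return m.generate_panel(small_config)


@pytest.fixture(scope="session")
def default_panel():
    """Default study conditions, the recovery-experiment panel."""
    return m.generate_panel(m.PanelConfig(seed=1))


@pytest.fixture(scope="session")
def default_scan(default_panel):
    """Full association scan of the default panel."""
    sfm, kinship, covariates = build_scan_inputs(default_panel)
    results = m.scan(default_panel.drug_response, sfm.values, covariates, kinship)
    return {
        "panel": default_panel,
        "sfm": sfm,
        "kinship": kinship,
        "covariates": covariates,
        "results": results,
    }


@pytest.fixture(scope="session")
def null_scan():
    """Scan of a panel with no planted effects: kinship confounding only."""
    config = m.PanelConfig(
        n_drugs=10, n_genes=1000, target_effect=0.0, biomarker_effect=0.0, seed=11,
    )
    panel = m.generate_panel(config)
    sfm, kinship, covariates = build_scan_inputs(panel)
    results = m.scan(panel.drug_response, sfm.values, covariates, kinship)
    return {"panel": panel, "results": results}


@pytest.fixture
def toy_results():
    """Hand-written association table spanning the distance categories."""
    return pd.DataFrame({
        "drug_id": ["d1"] * 3 + ["d2"] * 3,
        "predictor_id": ["A", "B", "C"] * 2,
        "beta": [1.0, -0.5, 0.2, 0.8, 0.1, -0.3],
        "lrt_stat": [30.0, 8.0, 0.5, 25.0, 1.0, 0.2],
        "pval": [1e-8, 0.004, 0.5, 1e-6, 0.3, 1.0],
        "n_obs": [50] * 6,
        "predictor_class": ["fitness"] * 6,
        "flagged": [False] * 6,
    })


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
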