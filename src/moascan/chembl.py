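"""Unsupervised drug-target annotation from bioactivity records.

Bioactivity records (ChEMBL-style: one half-maximal activity measurement per
row, harmonized as pChEMBL = -log10 of the molar activity) are filtered to
assay situations that support a defined, exact, human, protein-level
measurement, and a target is called active for a drug when any qualifying
record reaches the activity threshold of the target's protein family
(Illuminating the Druggable Genome conventions): kinases <= 30 nM, GPCRs and
nuclear receptors <= 100 nM, ion channels <= 10 uM, everything else <= 1 uM.
The per-drug active-target count quantifies putative polypharmacology.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("moascan")

#: family activity thresholds, molar concentration, inclusive comparison
FAMILY_THRESHOLDS_M = {
    "Kinase": 30e-9,
    "GPCR": 100e-9,
    "NuclearReceptor": 100e-9,
    "IonChannel": 10e-6,
    "Other": 1e-6,
}

ALLOWED_TARGET_TYPES = frozenset(
    {
        "single protein",
        "protein complex",
        "protein complex group",
        "protein-protein interaction",
        "protein family",
    }
)

REQUIRED_COLUMNS = [
    "drug_id", "target_id", "family", "target_type", "organism",
    "relation", "pchembl",
]


def filter_bioactivities(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records eligible for activity calling.

    A record qualifies when (i) a pChEMBL value is defined, (ii) the assay's
    standard relation is exactly "=", (iii) the target type is one of the
    protein-level descriptions, and (iv) the target organism is Homo
    sapiens.  Unknown family labels are mapped to ``Other`` with a warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"bioactivity table missing columns: {missing}")
    pchembl = pd.to_numeric(records["pchembl"], errors="coerce")
    present = pchembl.dropna()
    if ((present <= 0) | np.isinf(present)).any():
        raise ValueError("pChEMBL values must be finite and positive when present")

    keep = (
        pchembl.notna()
        & (records["relation"] == "=")
        & records["target_type"].str.lower().isin(ALLOWED_TARGET_TYPES)
        & (records["organism"] == "Homo sapiens")
    )
    out = records[keep].copy()
    out["pchembl"] = pchembl[keep]

    unknown = ~out["family"].isin(FAMILY_THRESHOLDS_M)
    if unknown.any():
        logger.warning(
            "filter_bioactivities: %d records with unknown family mapped to Other",
            unknown.sum(),
        )
        out.loc[unknown, "family"] = "Other"
    return out


def call_active_targets(filtered: pd.DataFrame) -> tuple[dict, pd.Series]:
    """Per-drug active target sets and counts from filtered records.

    The activity concentration is ``10 ** (-pChEMBL)`` molar; a target is
    active for a drug iff any of its records reaches the family threshold
    (inclusive).
    """
    conc = 10.0 ** (-filtered["pchembl"].astype(float))
    threshold = filtered["family"].map(FAMILY_THRESHOLDS_M)
    # inclusive boundary, with a relative guard so a pChEMBL stated exactly at
    # a threshold (e.g. -log10(30 nM)) is not lost to floating-point round-off
    active = filtered[conc <= threshold * (1 + 1e-9)]
    sets = {
        drug: frozenset(block["target_id"])
        for drug, block in active.groupby("drug_id")
    }
    for drug in filtered["drug_id"].unique():
        sets.setdefault(drug, frozenset())
    counts = pd.Series({d: len(s) for d, s in sets.items()}, name="n_active_targets")
    return sets, counts.sort_index()
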