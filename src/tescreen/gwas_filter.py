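"""GWAS-catalog filtering and intersection with TE linkage output.

A catalog-style table (snp_id, chrom, pos, trait, mapped_gene, p_value,
risk_allele, effect_direction) is filtered at a genome-wide threshold
(strictly P < 1e-5 by default) and intersected with linked-SNP records
to yield disease-linked TEs: a TE qualifies iff at least one of its
linked SNPs is a retained GWAS hit. All supporting (snp, trait, gene)
triples are kept for the downstream direction-consistency stage.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GWAS_COLUMNS = [
    "snp_id", "chrom", "pos", "trait", "mapped_gene",
    "p_value", "risk_allele", "effect_direction",
]


def load_gwas(tsv_path: str | Path, p_threshold: float = 1e-5) -> pd.DataFrame:
    """Load a GWAS association table, keeping rows with P strictly < threshold.

    Rows whose P value does not parse are rejected with a logged line
    number. Duplicate (snp_id, trait) pairs are deduplicated keeping
    the smallest P.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table {tsv_path} lacks columns {missing}")
    p = pd.to_numeric(df["p_value"], errors="coerce")
    bad = np.flatnonzero(p.isna().to_numpy())
    for i in bad:
        # +2: one for the header line, one for 1-based numbering
        log.warning("GWAS table %s line %d: unparseable P %r, row rejected",
                    tsv_path, i + 2, df["p_value"].iloc[i])
    df = df.assign(p_value=p).dropna(subset=["p_value"])
    df = df[df["p_value"] < p_threshold]
    df = (
        df.sort_values(["snp_id", "trait", "p_value"], kind="mergesort")
        .drop_duplicates(subset=["snp_id", "trait"], keep="first")
        .reset_index(drop=True)
    )
    df["pos"] = df["pos"].astype(np.int64)
    return df


def disease_linked_tes(
    linkage_records: pd.DataFrame, gwas_records: pd.DataFrame
) -> pd.DataFrame:
    """Intersect linked-SNP records with retained GWAS hits.

    Returns one row per supporting (TE, SNP, trait) triple with the
    linkage statistics and GWAS annotation carried along. The distinct
    te_id set is the disease-linked TE set.
    """
    if linkage_records.empty or gwas_records.empty:
        return pd.DataFrame(
            columns=[
                "te_id", "snp_id", "r", "p_link", "distance_bp",
                "trait", "mapped_gene", "gwas_p", "risk_allele", "effect_direction",
            ]
        )
    merged = linkage_records.merge(
        gwas_records[
            ["snp_id", "trait", "mapped_gene", "p_value", "risk_allele", "effect_direction"]
        ],
        on="snp_id",
        how="inner",
    )
    merged = merged.rename(columns={"p": "p_link", "p_value": "gwas_p"})
    cols = [
        "te_id", "snp_id", "r", "p_link", "distance_bp",
        "trait", "mapped_gene", "gwas_p", "risk_allele", "effect_direction",
    ]
    return (
        merged[cols]
        .sort_values(["te_id", "snp_id", "trait"], kind="mergesort")
        .reset_index(drop=True)
    )
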