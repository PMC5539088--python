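"""Direction-of-effect consistency and final candidate assembly.

The last stage of the screen asks whether the TE's expression effect
points the same way as the published GWAS association once both are
expressed in the risk-allele frame. The TE effect is translated into
that frame via the sign of the TE-SNP linkage correlation: an insertion
positively correlated with the risk allele keeps its effect sign, a
negatively correlated insertion flips it. The pair is consistent iff
the translated sign equals the GWAS effect direction:

    consistent  <=>  sign(beta_TE) * sign(r_TE,SNP) == sign(GWAS direction)

The screen's "functionally related gene" judgment is a curation input,
not code: an optional allow-list of (trait, gene) pairs restricts the
final table, and pairs with unknown GWAS direction are routed to a
needs-curation list instead of being silently dropped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_SIGNS = {"+": 1, "-": -1, "−": -1, 1: 1, -1: -1, 1.0: 1, -1.0: -1}

CANDIDATE_COLUMNS = [
    "te_id", "te_family", "chrom", "pos", "gwas_snp_id", "gwas_phenotype",
    "gwas_genes", "gwas_p", "n_enhancer_overlaps", "e_gene", "eqtl_beta",
    "eqtl_p", "eqtl_q", "eqtl_type", "te_beta_sign", "te_snp_r_sign",
    "gwas_direction", "consistent",
]


def _sign(value, what: str) -> int:
    if isinstance(value, str):
        value = value.strip()
    if value in _SIGNS:
        return _SIGNS[value]
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"unrecognized {what} sign {value!r}") from None
    if v == 0:
        raise ValueError(f"{what} sign must be nonzero")
    return 1 if v > 0 else -1


def direction_consistent(te_beta_sign, te_snp_r_sign, gwas_direction) -> bool:
    """Sign algebra of the consistency filter (see module docstring).

    All three arguments may be '+'/'-' strings or signed numbers; an
    unknown GWAS direction is a ValueError (callers route such pairs to
    curation before getting here).
    """
    if isinstance(gwas_direction, str) and gwas_direction.strip().lower() == "unknown":
        raise ValueError("gwas_direction is unknown; route pair to curation")
    b = _sign(te_beta_sign, "te_beta")
    r = _sign(te_snp_r_sign, "te_snp_r")
    g = _sign(gwas_direction, "gwas_direction")
    return b * r == g


@dataclass
class CandidateTables:
    """Final-stage outputs: retained candidates, the full assessed
    table (with the consistency flag for every supported pair), and the
    pairs needing manual curation (unknown GWAS direction)."""

    candidates: pd.DataFrame
    assessed: pd.DataFrame
    needs_curation: pd.DataFrame


def assemble_candidates(
    eqtl_strongest: pd.DataFrame,
    disease_links: pd.DataFrame,
    enhancer_counts: pd.DataFrame,
    te_variants: pd.DataFrame,
    allow_list: Iterable[tuple[str, str]] | None = None,
) -> CandidateTables:
    """Join the screen's stage outputs into the final candidate table.

    One row per (TE, GWAS support) pair in long format; the distinct
    te_id count is the funnel's final number. ``allow_list``, when
    given, is the set of (gwas trait, eQTL gene) pairs judged
    functionally related; rows outside it are excluded from
    ``candidates`` but kept in ``assessed``. Unresolvable ids are a
    hard error naming the id.
    """
    if eqtl_strongest.empty:
        empty = pd.DataFrame(columns=CANDIDATE_COLUMNS)
        return CandidateTables(empty, empty.copy(), empty.copy())

    te_meta = te_variants.set_index("id")
    enh = enhancer_counts.set_index("te_id")["n_enhancer_overlaps"]
    allow = {(t, g) for t, g in allow_list} if allow_list is not None else None

    rows, curation = [], []
    for eq in eqtl_strongest.itertuples():
        if eq.te_id not in te_meta.index:
            raise KeyError(f"te_id {eq.te_id!r} absent from TE variant metadata")
        if eq.te_id not in enh.index:
            raise KeyError(f"te_id {eq.te_id!r} absent from enhancer overlap counts")
        meta = te_meta.loc[eq.te_id]
        supports = disease_links[disease_links["te_id"] == eq.te_id]
        if supports.empty:
            raise KeyError(f"te_id {eq.te_id!r} has no GWAS support records")
        for sup in supports.itertuples():
            base = dict(
                te_id=eq.te_id, te_family=meta["te_family"], chrom=meta["chrom"],
                pos=int(meta["pos"]), gwas_snp_id=sup.snp_id,
                gwas_phenotype=sup.trait, gwas_genes=sup.mapped_gene,
                gwas_p=sup.gwas_p, n_enhancer_overlaps=int(enh.loc[eq.te_id]),
                e_gene=eq.gene_id, eqtl_beta=eq.beta, eqtl_p=eq.p, eqtl_q=eq.q,
                eqtl_type=eq.cis_trans,
                te_beta_sign="+" if eq.beta > 0 else "-",
                te_snp_r_sign="+" if sup.r > 0 else "-",
                gwas_direction=str(sup.effect_direction),
            )
            direction = str(sup.effect_direction).strip().lower()
            if direction in ("unknown", "", "nan"):
                curation.append({**base, "consistent": None})
                continue
            base["consistent"] = direction_consistent(
                base["te_beta_sign"], base["te_snp_r_sign"], sup.effect_direction
            )
            rows.append(base)

    assessed = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    needs_curation = pd.DataFrame(curation, columns=CANDIDATE_COLUMNS)
    keep = assessed["consistent"] == True  # noqa: E712  (column may be object)
    if allow is not None:
        keep &= np.array([
            (t, g) in allow
            for t, g in zip(assessed["gwas_phenotype"], assessed["e_gene"])
        ], dtype=bool)
    candidates = assessed[keep].reset_index(drop=True)
    log.info(
        "consistency stage: %d supported pairs assessed, %d consistent rows, "
        "%d distinct candidate TEs, %d pairs need curation",
        len(assessed), len(candidates), candidates["te_id"].nunique(),
        len(needs_curation),
    )
    return CandidateTables(candidates, assessed, needs_curation)


def funnel_report(stage_counts: Mapping[str, int]) -> pd.DataFrame:
    """Per-stage TE survivor counts as an ordered two-column table."""
    return pd.DataFrame(
        {"stage": list(stage_counts.keys()), "n_te": list(stage_counts.values())}
    )
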