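"""Pairwise TE-SNP linkage disequilibrium on genotype dosages.

LD between a polyTE insertion and nearby SNPs is measured as the
Pearson correlation r of the two dosage vectors across samples, with a
two-sided significance from the exact t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom.
Missing genotypes are handled pairwise-complete. SNPs with p below the
screening alpha (default 0.05, uncorrected by design: this is a
deliberately lenient screening stage) are "linked" to the TE.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

LINKAGE_COLUMNS = [
    "te_id", "snp_id", "r", "p", "n_used", "distance_bp", "snp_is_gwas",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r of two dosage vectors with its exact-t significance.

    ``reason`` is set (and r/p are None) when the pair is untestable:
    fewer than 3 pairwise-complete samples, or a constant vector.
    """

    r: float | None
    p: float | None
    n_used: int
    reason: str | None = None

    @property
    def testable(self) -> bool:
        return self.reason is None


def pairwise_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation on pairwise-complete samples with exact-t p.

    Never propagates NaN: degenerate inputs yield an untestable result
    carrying the reason. p is floored at the smallest positive float
    when the correlation is numerically perfect.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        return CorrelationResult(None, None, n, f"only {n} complete samples (< 3)")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return CorrelationResult(None, None, n, "constant vector on complete samples")
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if 1.0 - r * r <= 0.0:
        p = float(np.finfo(float).tiny)  # numerically perfect correlation
    else:
        t = abs(r) * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(t, df))
        p = max(p, float(np.finfo(float).tiny))
    return CorrelationResult(r, min(p, 1.0), n)


def linked_snps(
    te_id: str,
    te_chrom: str,
    te_pos: int,
    te_dosages: np.ndarray,
    snps,
    alpha: float = 0.05,
    window_bp: int = 1_000_000,
    gwas_snp_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """SNPs within ``window_bp`` of the TE whose correlation p < alpha.

    ``snps`` is a :class:`~tescreen.genotype_io.GenotypeMatrix` of SNP
    records. Returns one row per linked SNP with r, p, n_used, the
    base-pair distance and a GWAS flag.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    gwas_ids = set(gwas_snp_ids)
    vmeta = snps.variants
    sel = (
        (vmeta["chrom"] == te_chrom)
        & ((vmeta["pos"] - te_pos).abs() <= window_bp)
    ).to_numpy()
    rows = []
    for i in np.flatnonzero(sel):
        res = pairwise_r(te_dosages, snps.dosages[i])
        if not res.testable:
            continue
        if res.p < alpha:
            snp = vmeta.iloc[i]
            rows.append(
                (
                    te_id, snp["id"], res.r, res.p, res.n_used,
                    int(abs(int(snp["pos"]) - te_pos)), snp["id"] in gwas_ids,
                )
            )
    return pd.DataFrame(rows, columns=LINKAGE_COLUMNS)


def linkage_table(
    tes,
    snps,
    alpha: float = 0.05,
    window_bp: int = 1_000_000,
    gwas_snp_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Linked-SNP records for every TE in a genotype matrix."""
    parts = []
    for i, te in tes.variants.iterrows():
        parts.append(
            linked_snps(
                te["id"], te["chrom"], int(te["pos"]), tes.dosages[i],
                snps, alpha=alpha, window_bp=window_bp, gwas_snp_ids=gwas_snp_ids,
            )
        )
    if not parts:
        return pd.DataFrame(columns=LINKAGE_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def nearest_gwas_distance(
    te_pos: int,
    gwas_positions: Sequence[int],
    gwas_ids: Sequence[str] | None = None,
) -> tuple[int, str | None] | None:
    """Distance to the nearest GWAS SNP on the TE's chromosome.

    Returns ``(distance_bp, snp_id)`` or None when no GWAS SNP exists
    on the chromosome (the TE is then excluded from density exports).
    Ties are broken toward the smaller coordinate for determinism.
    """
    positions = np.asarray(gwas_positions, dtype=np.int64)
    if positions.size == 0:
        return None
    d = np.abs(positions - int(te_pos))
    best = int(d.min())
    cand = np.flatnonzero(d == best)
    pick = cand[np.argmin(positions[cand])]
    snp_id = gwas_ids[int(pick)] if gwas_ids is not None else None
    return best, snp_id


def compare_r_distributions(
    r_gwas_linked: Sequence[float], r_non_gwas_linked: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on two LD correlation samples."""
    a = np.asarray(r_gwas_linked, dtype=float)
    b = np.asarray(r_non_gwas_linked, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both r samples must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
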