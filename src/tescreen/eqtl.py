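"""Additive linear TE-eQTL screen with covariates and BH FDR control.

For every candidate TE x gene pair, expression is regressed on the TE
insertion dosage with an intercept, a sex indicator and reference-coded
population indicators as covariates (the additive least-squares model
of standard eQTL mappers, re-implemented here so the statistical
surface is self-contained). The dosage coefficient is tested two-sided
against the t distribution on the residual degrees of freedom.
q-values are Benjamini-Hochberg over all testable pairs of a group's
run; the screen is run separately per continental group, and the
realized p threshold corresponding to q < 0.05 is reported alongside.

Cis vs trans: a pair is cis iff the TE position lies within 1 Mb of the
gene boundaries on the same chromosome (inclusive at exactly 1 Mb),
trans otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

EQTL_COLUMNS = [
    "te_id", "gene_id", "beta", "se", "t_stat", "p", "q",
    "n_used", "cis_trans", "reason",
]

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class FitResult:
    """OLS dosage-coefficient estimate for one TE-gene pair.

    ``reason`` is set (and the statistics are None) when the pair is
    untestable: constant dosage, rank-deficient design, or too few
    complete samples.
    """

    beta: float | None
    se: float | None
    t_stat: float | None
    p: float | None
    n_used: int
    reason: str | None = None

    @property
    def testable(self) -> bool:
        return self.reason is None


def design_matrix(
    sex: Sequence[str] | np.ndarray, population: Sequence[str] | np.ndarray
) -> np.ndarray:
    """Covariate design: intercept, sex indicator, population dummies.

    Populations are reference-coded against the lexicographically first
    label; with a single population the covariate drops out entirely
    (as in a one-population group), and likewise for sex.
    """
    sex = np.asarray(sex)
    population = np.asarray(population)
    n = len(sex)
    cols = [np.ones(n)]
    sex_levels = sorted(set(sex.tolist()))
    for lev in sex_levels[1:]:
        cols.append((sex == lev).astype(float))
    pop_levels = sorted(set(population.tolist()))
    for lev in pop_levels[1:]:
        cols.append((population == lev).astype(float))
    return np.column_stack(cols)


def _ols_last_coef(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """beta, se, t, p for the last column of X by normal equations."""
    n, k = X.shape
    xtx = X.T @ X
    beta_hat = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta_hat
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov_last = np.linalg.inv(xtx)[-1, -1]
    beta = float(beta_hat[-1])
    se = float(np.sqrt(sigma2 * cov_last))
    if se == 0.0:
        # exact fit: p numerically floored
        return beta, se, np.inf, _P_FLOOR
    t = beta / se
    p = max(float(2.0 * stats.t.sf(abs(t), df)), _P_FLOOR)
    return beta, se, float(t), p


def fit_additive(
    expression_vector: Sequence[float],
    te_dosages: Sequence[float],
    sex_covariate: Sequence[str],
    population_covariates: Sequence[str],
) -> FitResult:
    """OLS of expression on TE dosage + intercept + sex + population.

    Missing dosages or expression values are dropped complete-case. A
    rank-deficient design or a constant dosage marks the pair
    untestable with a reason rather than raising or returning NaN.
    """
    y = np.asarray(expression_vector, dtype=float)
    g = np.asarray(te_dosages, dtype=float)
    sex = np.asarray(sex_covariate)
    pop = np.asarray(population_covariates)
    if not (len(y) == len(g) == len(sex) == len(pop)):
        raise ValueError("all inputs must have equal length")
    mask = ~(np.isnan(y) | np.isnan(g))
    n = int(mask.sum())
    Xcov = design_matrix(sex[mask], pop[mask])
    k = Xcov.shape[1] + 1
    if n < k + 1:
        return FitResult(None, None, None, None, n,
                         f"{n} complete samples < {k + 1} required")
    gs = g[mask]
    if np.ptp(gs) == 0:
        return FitResult(None, None, None, None, n, "constant dosage")
    X = np.column_stack([Xcov, gs])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return FitResult(None, None, None, None, n, "rank-deficient design")
    beta, se, t, p = _ols_last_coef(X, y[mask])
    return FitResult(beta, se, t, p, n)


def bh_qvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_cis_trans(
    te_chrom: str,
    te_pos: int,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    window_bp: int = 1_000_000,
) -> str:
    """"cis" iff the TE is within ``window_bp`` of the gene boundaries.

    The boundary is inclusive: a TE exactly 1 Mb from a gene edge is
    cis. Different chromosomes are always trans.
    """
    if te_chrom != gene_chrom:
        return "trans"
    if gene_start - window_bp <= te_pos <= gene_end + window_bp:
        return "cis"
    return "trans"


def run_screen(
    candidate_tes,
    expression: pd.DataFrame,
    gene_models: pd.DataFrame,
    cohort: pd.DataFrame,
    group: str,
    cis_window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """All-pairs TE-eQTL screen within one continental group.

    ``candidate_tes`` is a GenotypeMatrix of candidate TE insertions;
    ``expression`` is genes x samples; ``gene_models`` has columns
    gene_id, chrom, start, end; ``cohort`` has sample_id, population,
    group, sex. Only the samples of ``group`` (shared by the genotype
    matrix and the expression matrix) are used, so the other group's
    data cannot influence the result. Returns one row per pair, with
    untestable pairs carried with a reason and NaN statistics; BH
    q-values are computed over the testable pairs only. Genes with zero
    expression variance in the group are skipped with a logged count
    (they reduce m for BH).
    """
    members = cohort.loc[cohort["group"] == group, "sample_id"].tolist()
    samples = [s for s in members if s in candidate_tes.samples and s in expression.columns]
    if not samples:
        raise ValueError(f"no samples of group {group!r} shared by inputs")
    tes = candidate_tes.subset_samples(samples)
    expr = expression[samples]
    meta = cohort.set_index("sample_id").loc[samples]
    sex = meta["sex"].to_numpy()
    pop = meta["population"].to_numpy()
    Xcov = design_matrix(sex, pop)

    gene_range = expr.max(axis=1) - expr.min(axis=1)  # exact zero for constants
    zero_var = gene_range[gene_range == 0.0].index
    if len(zero_var):
        log.info("group %s: skipping %d zero-variance genes", group, len(zero_var))
    genes = [gid for gid in expr.index if gid not in set(zero_var)]
    Y = expr.loc[genes].to_numpy(dtype=float)  # genes x n

    gm = gene_models.set_index("gene_id")
    rows: list[tuple] = []
    if tes.n_variants == 0:
        log.info("group %s: empty candidate TE set; no eQTL tests run", group)
    for i, te in tes.variants.iterrows():
        g = tes.dosages[i]
        mask = ~np.isnan(g)
        n = int(mask.sum())
        k = Xcov.shape[1] + 1
        reason = None
        if n < k + 1:
            reason = f"{n} complete samples < {k + 1} required"
        elif np.ptp(g[mask]) == 0:
            reason = "constant dosage"
        if reason is not None:
            for gid in genes:
                rows.append((te["id"], gid, np.nan, np.nan, np.nan, np.nan,
                             n, _label(te, gm, gid, cis_window_bp), reason))
            continue
        X = np.column_stack([Xcov[mask], g[mask]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            for gid in genes:
                rows.append((te["id"], gid, np.nan, np.nan, np.nan, np.nan,
                             n, _label(te, gm, gid, cis_window_bp), "rank-deficient design"))
            continue
        Ym = Y[:, mask]  # genes x n_complete
        xtx = X.T @ X
        xtx_inv = np.linalg.inv(xtx)
        B = xtx_inv @ (X.T @ Ym.T)  # k x genes
        resid = Ym.T - X @ B
        df = n - X.shape[1]
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        se = np.sqrt(sigma2 * xtx_inv[-1, -1])
        beta = B[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf)
        p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), _P_FLOOR)
        for j, gid in enumerate(genes):
            rows.append((te["id"], gid, float(beta[j]), float(se[j]),
                         float(t[j]), float(p[j]), n,
                         _label(te, gm, gid, cis_window_bp), None))

    out = pd.DataFrame(
        rows,
        columns=["te_id", "gene_id", "beta", "se", "t_stat", "p",
                 "n_used", "cis_trans", "reason"],
    )
    out["q"] = np.nan
    testable = out["reason"].isna()
    if testable.any():
        out.loc[testable, "q"] = bh_qvalues(out.loc[testable, "p"].to_numpy())
    return out[EQTL_COLUMNS]


def _label(te: pd.Series, gene_models: pd.DataFrame, gene_id: str,
           window_bp: int) -> str:
    if gene_id not in gene_models.index:
        raise KeyError(f"gene {gene_id!r} absent from gene models")
    gmrow = gene_models.loc[gene_id]
    return classify_cis_trans(
        te["chrom"], int(te["pos"]), str(gmrow["chrom"]),
        int(gmrow["start"]), int(gmrow["end"]), window_bp,
    )


def strongest_per_te(records: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Minimum-p record per TE among records with q < threshold.

    Ties at identical p are broken by larger |t|, then lexicographic
    gene_id, so the choice is deterministic under input reordering.
    """
    sig = records[records["q"] < q_threshold].copy()
    if sig.empty:
        return sig
    sig["_neg_abs_t"] = -sig["t_stat"].abs()
    sig = sig.sort_values(["te_id", "p", "_neg_abs_t", "gene_id"], kind="mergesort")
    out = sig.groupby("te_id", sort=True).head(1).drop(columns="_neg_abs_t")
    return out.reset_index(drop=True)


def realized_p_threshold(records: pd.DataFrame, q_threshold: float = 0.05) -> float:
    """Largest p among tests called significant at q < threshold.

    This is the run's data-dependent analogue of a fixed genome-wide p
    cutoff; NaN when nothing is significant.
    """
    sig = records.loc[records["q"] < q_threshold, "p"]
    return float(sig.max()) if len(sig) else float("nan")


def qq_export(records: pd.DataFrame) -> pd.DataFrame:
    """Expected vs observed -log10 p quantiles for Q-Q plotting."""
    p = np.sort(records.loc[records["reason"].isna(), "p"].to_numpy())
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(p)}
    )


def manhattan_export(records: pd.DataFrame, te_variants: pd.DataFrame) -> pd.DataFrame:
    """Per-test chromosome/position/-log10 p table for Manhattan plotting."""
    meta = te_variants.set_index("id")[["chrom", "pos"]]
    ok = records[records["reason"].isna()]
    return pd.DataFrame(
        {
            "te_id": ok["te_id"].to_numpy(),
            "chrom": meta.loc[ok["te_id"], "chrom"].to_numpy(),
            "pos": meta.loc[ok["te_id"], "pos"].to_numpy(),
            "gene_id": ok["gene_id"].to_numpy(),
            "neglog10_p": -np.log10(ok["p"].to_numpy()),
        }
    )
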