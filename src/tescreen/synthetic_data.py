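"""Synthetic inputs with planted, recoverable structure for the screen.

Every input the screen consumes — TE and SNP genotypes, a GWAS
association table, per-epigenome enhancer intervals and a normalized
expression matrix — can be generated here with known ground truth, so
each downstream stage is verifiable without external downloads.

Key constructions
-----------------
* LD is planted at the haplotype level: the TE haplotype allele is
  Bernoulli(p) and each SNP allele is drawn conditionally on it with
  P(snp=1 | te=1) = q + D/p and P(snp=1 | te=0) = q - D/(1-p), where
  D = r * sqrt(p(1-p) q(1-q)). Diploid dosages are the sums of two
  independent haplotypes, and the dosage correlation has the same
  expectation r as the haplotype correlation (both covariance and the
  two variances double). Negative r is allowed — an insertion may be
  anti-correlated with a risk allele — but is bounded by the allele
  frequencies: D must keep all four conditional probabilities in
  [0, 1], and a requested r outside that bound is an error naming it.
* Expression is generated already "normalized" (units arbitrary):
  y = mu + beta * dosage + sex/population offsets + N(0, sigma^2),
  with beta = 0 for null genes, and gene coordinates placed to realize
  each planted pair's cis/trans status under the 1 Mb rule.
* Each TE gets its own LD block; blocks are mutually independent, which
  keeps the planted truth exactly recoverable.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import genotype_io
from .enhancer import EnhancerSet, write_bed
from .eqtl import classify_cis_trans
from .genotype_io import GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cohort

@dataclass(frozen=True)
class CohortSpec:
    """Sample layout: per-population counts, continental groups, sex mix."""

    n_per_population: Mapping[str, int]
    population_groups: Mapping[str, str]  # population -> {"AFR", "EUR"}
    sex_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, n in self.n_per_population.items():
            if n < 1:
                raise ValueError(f"population {pop!r} has non-positive count {n}")
            if pop not in self.population_groups:
                raise ValueError(f"population {pop!r} has no group assignment")
        if not 0.0 <= self.sex_fraction <= 1.0:
            raise ValueError("sex_fraction must be in [0, 1]")

    @property
    def n_total(self) -> int:
        return sum(self.n_per_population.values())


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample table (sample_id, population, group, sex); deterministic."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for pop, n in spec.n_per_population.items():
        group = spec.population_groups[pop]
        sexes = np.where(rng.random(n) < spec.sex_fraction, "female", "male")
        for i in range(n):
            rows.append((f"{pop}_{i:04d}", pop, group, sexes[i]))
    return pd.DataFrame(rows, columns=["sample_id", "population", "group", "sex"])


# ---------------------------------------------------------------------------
# LD blocks

def ld_bounds(p: float, q: float) -> tuple[float, float]:
    """Attainable (r_min, r_max) for two loci at allele frequencies p, q."""
    denom = np.sqrt(p * (1 - p) * q * (1 - q))
    d_max = min(p * (1 - q), q * (1 - p))
    d_min = max(-p * q, -(1 - p) * (1 - q))
    return d_min / denom, d_max / denom


@dataclass(frozen=True)
class LdBlockSpec:
    """One TE with its LD-block SNPs and target signed correlations."""

    te_id: str
    te_family: str
    chrom: str
    te_position: int
    te_allele_freq: float
    snp_ids: tuple[str, ...]
    snp_positions: tuple[int, ...]
    snp_allele_freqs: tuple[float, ...]
    target_r: tuple[float, ...]
    block_span_bp: int = 500_000

    def __post_init__(self) -> None:
        if not 0.0 < self.te_allele_freq < 1.0:
            raise ValueError("te_allele_freq must be in (0, 1)")
        k = len(self.snp_ids)
        if not (len(self.snp_positions) == len(self.snp_allele_freqs)
                == len(self.target_r) == k):
            raise ValueError("SNP field lengths are inconsistent")
        for pos in self.snp_positions:
            if abs(pos - self.te_position) > self.block_span_bp:
                raise ValueError(
                    f"SNP position {pos} outside block span "
                    f"{self.block_span_bp} of TE at {self.te_position}"
                )
        p = self.te_allele_freq
        for snp_id, q, r in zip(self.snp_ids, self.snp_allele_freqs, self.target_r):
            if not 0.0 < q < 1.0:
                raise ValueError(f"SNP {snp_id}: allele frequency must be in (0, 1)")
            r_lo, r_hi = ld_bounds(p, q)
            if not r_lo - 1e-12 <= r <= r_hi + 1e-12:
                raise ValueError(
                    f"SNP {snp_id}: target_r={r} outside the attainable bound "
                    f"[{r_lo:.6f}, {r_hi:.6f}] for p={p}, q={q}"
                )


def generate_ld_block(
    spec: LdBlockSpec, n_samples: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample one block: (te_dosages, snp_dosage_matrix, haplotype_table).

    The haplotype table has 2*n_samples rows and 1 + n_snps columns
    (TE first), from which the dosages are the sums of consecutive
    haplotype pairs.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p = spec.te_allele_freq
    n_hap = 2 * n_samples
    hap_te = (rng.random(n_hap) < p).astype(np.int8)
    haps = [hap_te]
    for q, r in zip(spec.snp_allele_freqs, spec.target_r):
        d = r * np.sqrt(p * (1 - p) * q * (1 - q))
        prob = np.where(hap_te == 1, q + d / p, q - d / (1 - p))
        haps.append((rng.random(n_hap) < prob).astype(np.int8))
    table = np.column_stack(haps)
    dosages = table.reshape(n_samples, 2, -1).sum(axis=1).astype(float)
    return dosages[:, 0], dosages[:, 1:].T.copy(), table


# ---------------------------------------------------------------------------
# GWAS table

@dataclass(frozen=True)
class GwasHit:
    """A planted GWAS association (P below the genome-wide threshold)."""

    snp_id: str
    trait: str
    mapped_gene: str
    risk_allele: str = "A"
    effect_direction: str = "+"  # "+", "-" or "unknown"
    p_value: float | None = None  # None -> drawn below 1e-5


GWAS_COLUMNS = [
    "snp_id", "chrom", "pos", "trait", "mapped_gene",
    "p_value", "risk_allele", "effect_direction",
]


def generate_gwas_table(
    hits: Sequence[GwasHit],
    decoy_snp_ids: Sequence[str],
    snp_metadata: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Catalog-style table: hits get P < 1e-5, decoys get P >= 1e-5.

    ``snp_metadata`` (columns id, chrom, pos) must resolve every SNP id.
    """
    rng = np.random.default_rng(seed)
    meta = snp_metadata.set_index("id")
    rows = []
    for h in hits:
        if h.snp_id not in meta.index:
            raise KeyError(f"GWAS hit SNP {h.snp_id!r} not in SNP metadata")
        p = h.p_value if h.p_value is not None else 10 ** rng.uniform(-12, -6)
        if not p < 1e-5:
            raise ValueError(f"hit {h.snp_id}: p_value {p} is not < 1e-5")
        m = meta.loc[h.snp_id]
        rows.append((h.snp_id, m["chrom"], int(m["pos"]), h.trait, h.mapped_gene,
                     p, h.risk_allele, h.effect_direction))
    for sid in decoy_snp_ids:
        if sid not in meta.index:
            raise KeyError(f"decoy SNP {sid!r} not in SNP metadata")
        m = meta.loc[sid]
        p = 10 ** rng.uniform(-4, -0.1)
        rows.append((sid, m["chrom"], int(m["pos"]), "decoy trait", "NONE",
                     p, "A", "unknown"))
    return pd.DataFrame(rows, columns=GWAS_COLUMNS)


# ---------------------------------------------------------------------------
# enhancers

def generate_enhancers(
    variant_points: Mapping[str, tuple[str, int]],
    n_epigenomes: int,
    blood_immune_ids: Iterable[str],
    overlap_plan: Mapping[str, Iterable[str]],
    seed: int,
    tissue_labels: Mapping[str, str] | None = None,
    n_background: int = 5,
) -> tuple[list[EnhancerSet], pd.DataFrame]:
    """Per-epigenome enhancer intervals realizing an overlap plan.

    ``variant_points`` maps variant ids to (chrom, 1-based pos);
    ``overlap_plan`` maps epigenome ids ("E001"...) to the variant ids
    that must fall inside one of that epigenome's enhancers. All other
    variants are guaranteed outside every interval of that epigenome,
    and intervals within an epigenome are non-overlapping. Two distinct
    variants at the same position with conflicting plan membership are
    an unsatisfiable plan and raise. ``n_background`` decoy intervals
    per epigenome are placed beyond all variants.
    """
    rng = np.random.default_rng(seed)
    epigenome_ids = [f"E{i + 1:03d}" for i in range(n_epigenomes)]
    blood = set(blood_immune_ids)
    unknown = (set(overlap_plan) | blood) - set(epigenome_ids)
    if unknown:
        raise ValueError(f"plan/flag ids outside the manifest: {sorted(unknown)}")

    # per-chromosome sorted variant positions, for exclusion clearance
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for vid, (chrom, pos) in variant_points.items():
        by_chrom.setdefault(chrom, []).append((pos, vid))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    max_pos = {c: v[-1][0] for c, v in by_chrom.items()}

    sets = []
    for eid in epigenome_ids:
        planned = set(overlap_plan.get(eid, ()))
        missing = planned - set(variant_points)
        if missing:
            raise KeyError(f"plan for {eid} names unknown variants: {sorted(missing)}")
        intervals: dict[str, list[tuple[int, int]]] = {}
        for vid in sorted(planned):
            chrom, pos = variant_points[vid]
            positions = by_chrom[chrom]
            idx = positions.index((pos, vid))
            conflict = [
                other for p2, other in positions
                if p2 == pos and other != vid and other not in planned
            ]
            if conflict:
                raise ValueError(
                    f"plan for {eid} is unsatisfiable: variant {vid} at "
                    f"{chrom}:{pos} must overlap but co-located "
                    f"{conflict} must not"
                )
            # clearance to the nearest differently-positioned neighbour
            left_gap = pos - positions[idx - 1][0] if idx > 0 else pos
            right_gap = (positions[idx + 1][0] - pos
                         if idx + 1 < len(positions) else 10_000)
            wl = int(rng.integers(10, max(11, min(150, left_gap // 2))))
            wr = int(rng.integers(10, max(11, min(150, right_gap // 2))))
            p0 = pos - 1  # BED frame
            start = max(0, p0 - wl)
            end = p0 + 1 + wr
            intervals.setdefault(chrom, []).append((start, end))
        for chrom, top in max_pos.items():
            base = top + 1_000_000
            for b in range(n_background):
                s = base + b * 1_000 + int(rng.integers(0, 500))
                intervals.setdefault(chrom, []).append((s, s + 200))
        sets.append(
            EnhancerSet(
                epigenome_id=eid,
                tissue_label=(tissue_labels or {}).get(eid, f"tissue_{eid}"),
                blood_immune=eid in blood,
                intervals={c: np.array(v, dtype=np.int64) for c, v in intervals.items()},
            )
        )
    manifest = pd.DataFrame(
        {
            "epigenome_id": epigenome_ids,
            "tissue_label": [s.tissue_label for s in sets],
            "blood_immune": [int(s.blood_immune) for s in sets],
        }
    )
    return sets, manifest


# ---------------------------------------------------------------------------
# expression

@dataclass(frozen=True)
class PlantedEqtl:
    """A planted TE-gene expression effect (beta per insertion allele)."""

    te_id: str
    gene_id: str
    beta: float
    sigma: float = 1.0
    cis_flag: bool = True
    gene_chrom: str | None = None
    gene_start: int | None = None
    gene_end: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def _place_gene(eq: PlantedEqtl, te_chrom: str, te_pos: int,
                cis_window_bp: int) -> tuple[str, int, int]:
    if eq.gene_chrom is not None:
        label = classify_cis_trans(
            te_chrom, te_pos, eq.gene_chrom, eq.gene_start, eq.gene_end,
            cis_window_bp,
        )
        if (label == "cis") != eq.cis_flag:
            raise ValueError(
                f"planted pair {eq.te_id}/{eq.gene_id}: explicit gene "
                f"coordinates give {label}, contradicting cis_flag={eq.cis_flag}"
            )
        return eq.gene_chrom, eq.gene_start, eq.gene_end
    if eq.cis_flag:
        start = te_pos + 200_000
        return te_chrom, start, start + 20_000
    # trans: different chromosome is trans on any assembly
    other = "X" if te_chrom != "X" else "1"
    return other, 1_000_000, 1_020_000


def generate_expression(
    cohort: pd.DataFrame,
    te_genotypes: GenotypeMatrix,
    planted_eqtls: Sequence[PlantedEqtl],
    n_null_genes: int,
    seed: int,
    sex_effect: float = 0.0,
    population_effects: Mapping[str, float] | None = None,
    sigma_null: float = 1.0,
    cis_window_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) and gene-model table.

    Planted genes follow y = mu + beta * dosage + covariate offsets +
    N(0, sigma^2); null genes have beta = 0 and the same covariate
    structure. Gene coordinates realize each planted cis/trans flag
    under the 1 Mb rule; an explicit coordinate contradicting the flag
    raises.
    """
    rng = np.random.default_rng(seed)
    samples = cohort["sample_id"].tolist()
    tes = te_genotypes.subset_samples(samples)
    pop_eff = dict(population_effects or {})
    offsets = (
        np.where(cohort["sex"].to_numpy() == "female", sex_effect, 0.0)
        + np.array([pop_eff.get(p, 0.0) for p in cohort["population"]])
    )

    te_meta = tes.variants.set_index("id")
    rows, models = [], []
    seen = set()
    for eq in planted_eqtls:
        if eq.te_id not in te_meta.index:
            raise KeyError(f"planted eQTL references unknown TE {eq.te_id!r}")
        if eq.gene_id in seen:
            raise ValueError(f"duplicate planted gene {eq.gene_id!r}")
        seen.add(eq.gene_id)
        meta = te_meta.loc[eq.te_id]
        chrom, start, end = _place_gene(eq, meta["chrom"], int(meta["pos"]),
                                        cis_window_bp)
        g = np.nan_to_num(tes.dosages_for(eq.te_id), nan=0.0)
        mu = rng.normal(5.0, 1.0)
        y = mu + eq.beta * g + offsets + rng.normal(0.0, eq.sigma, len(samples))
        rows.append(pd.Series(y, index=samples, name=eq.gene_id))
        models.append((eq.gene_id, chrom, start, end))

    chroms = list(pd.unique(tes.variants["chrom"])) or ["1"]
    for k in range(n_null_genes):
        gid = f"NULL_{k:04d}"
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(1, 50_000_000))
        mu = rng.normal(5.0, 1.0)
        y = mu + offsets + rng.normal(0.0, sigma_null, len(samples))
        rows.append(pd.Series(y, index=samples, name=gid))
        models.append((gid, chrom, start, start + 20_000))

    expression = pd.DataFrame(rows)
    expression.index.name = "gene_id"
    gene_models = pd.DataFrame(models, columns=["gene_id", "chrom", "start", "end"])
    return expression, gene_models


# ---------------------------------------------------------------------------
# ground truth container

@dataclass
class SyntheticTruth:
    """Planted parameters and expected per-stage survivor sets."""

    ld_blocks: list[LdBlockSpec] = field(default_factory=list)
    planted_eqtls: list[PlantedEqtl] = field(default_factory=list)
    gwas_hits: list[GwasHit] = field(default_factory=list)
    enhancer_plan: dict[str, list[str]] = field(default_factory=dict)
    te_classes: dict[str, str] = field(default_factory=dict)
    expected_stages: dict[str, list[str]] = field(default_factory=dict)
    allow_list: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "ld_blocks": [dataclasses.asdict(b) for b in self.ld_blocks],
            "planted_eqtls": [dataclasses.asdict(e) for e in self.planted_eqtls],
            "gwas_hits": [dataclasses.asdict(h) for h in self.gwas_hits],
            "enhancer_plan": {k: sorted(v) for k, v in self.enhancer_plan.items()},
            "te_classes": self.te_classes,
            "expected_stages": self.expected_stages,
            "allow_list": [list(t) for t in self.allow_list],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            ld_blocks=[
                LdBlockSpec(**{**b, "snp_ids": tuple(b["snp_ids"]),
                               "snp_positions": tuple(b["snp_positions"]),
                               "snp_allele_freqs": tuple(b["snp_allele_freqs"]),
                               "target_r": tuple(b["target_r"])})
                for b in doc["ld_blocks"]
            ],
            planted_eqtls=[PlantedEqtl(**e) for e in doc["planted_eqtls"]],
            gwas_hits=[GwasHit(**h) for h in doc["gwas_hits"]],
            enhancer_plan={k: list(v) for k, v in doc["enhancer_plan"].items()},
            te_classes=doc["te_classes"],
            expected_stages={k: list(v) for k, v in doc["expected_stages"].items()},
            allow_list=[tuple(t) for t in doc["allow_list"]],
        )


# ---------------------------------------------------------------------------
# full scenario

#: cohort matching the study conditions: 445 individuals, one African
#: population (87) and four European populations (358 total)
DEFAULT_COHORT = CohortSpec(
    n_per_population={"YRI": 87, "CEU": 89, "FIN": 93, "GBR": 88, "TSI": 88},
    population_groups={"YRI": "AFR", "CEU": "EUR", "FIN": "EUR",
                       "GBR": "EUR", "TSI": "EUR"},
)

# flavor for the fully-planted candidate TEs: family, trait, GWAS gene,
# GWAS P, blood-epigenome overlap count, eQTL gene, cis flag
_CANDIDATE_FLAVOR = [
    ("Alu", "Diabetic retinopathy", "LINC00881, CCNL1", 7.00e-7, 1, "LILRA1", False),
    ("Alu", "Lymphoma", "TRNAI25", 2.00e-8, 20, "HLA-DRB5", True),
    ("Alu", "Nodular sclerosis Hodgkin lymphoma", "TRNAI25", 8.00e-18, 15,
     "HLA-DQB1-AS1", True),
    ("SVA", "Chronic hepatitis B infection", "HLA-DPA1", 5.00e-39, 6,
     "HLA-DPB2", True),
    ("SVA", "IgG glycosylation", "B4GALT1", 2.00e-6, 4, "B4GALT1", True),
    ("SVA", "Glucose homeostasis traits", "ST8SIA6-AS1, PRPF38AP2", 5.00e-6, 7,
     "TMEM236", True),
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Scale and planted structure of the bundled end-to-end scenario.

    Defaults are the screen's study conditions: a 445-sample two-group
    cohort, planted LD at |r| = 0.9 for tag SNPs (where the linkage
    stage has power ~1 at these sample sizes), TE insertion frequencies
    straddling the 0.05 MAF cutoff, planted expression effects of two
    residual standard deviations, and 27 of 127 epigenomes flagged
    blood/immune.
    """

    cohort: CohortSpec = DEFAULT_COHORT
    n_candidates: int = 6         # pass every stage
    n_low_maf: int = 3            # fail the MAF screen (freq 0.02)
    n_no_gwas: int = 4            # linked only to non-GWAS SNPs
    n_no_enhancer: int = 3        # disease-linked, no enhancer overlap
    n_non_blood: int = 3          # overlap only non-flagged epigenomes
    n_null_expression: int = 3    # through the enhancer filter, beta = 0
    n_inconsistent: int = 3       # significant eQTL, wrong direction
    snps_per_block: int = 8
    n_null_genes: int = 300
    n_epigenomes: int = 127
    n_blood_immune: int = 27
    tag_r: float = 0.9
    te_freq: float = 0.3
    low_maf_freq: float = 0.02
    eqtl_beta: float = 2.0        # in units of sigma = 1
    sex_effect: float = 0.4
    population_effects: tuple[tuple[str, float], ...] = (
        ("YRI", 0.0), ("CEU", 0.2), ("FIN", -0.3), ("GBR", 0.1), ("TSI", 0.0))
    snp_overlap_fraction: float = 0.05


def _block_spec(te_id, family, chrom, te_pos, te_freq, tag_r, n_snps, rng,
                tag_is_negative=False) -> LdBlockSpec:
    """One TE block: a tag SNP at the target r plus independent fillers."""
    p = te_freq
    snp_ids, positions, freqs, rs = [], [], [], []
    offsets = rng.choice(np.arange(2, 400) * 1_000, size=n_snps, replace=False)
    signs = rng.choice([-1, 1], size=n_snps)
    # tag SNP: q = p (positive r attains 1) or q = 1 - p (negative r attains -1)
    snp_ids.append(f"{te_id}_tag")
    positions.append(te_pos + int(signs[0]) * int(offsets[0]))
    freqs.append(1 - p if tag_is_negative else p)
    rs.append(-tag_r if tag_is_negative else tag_r)
    for j in range(1, n_snps):
        snp_ids.append(f"{te_id}_s{j}")
        positions.append(te_pos + int(signs[j]) * int(offsets[j]))
        # one low-frequency filler per block exercises the SNP MAF screen
        freqs.append(0.03 if j == n_snps - 1 else float(rng.uniform(0.1, 0.5)))
        rs.append(0.0)
    return LdBlockSpec(
        te_id=te_id, te_family=family, chrom=chrom, te_position=te_pos,
        te_allele_freq=p, snp_ids=tuple(snp_ids),
        snp_positions=tuple(int(x) for x in positions),
        snp_allele_freqs=tuple(freqs), target_r=tuple(rs),
    )


def generate_scenario(
    out_dir: str | Path, seed: int, spec: ScenarioSpec | None = None
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write a complete synthetic input set and its ground truth.

    Returns (paths, truth). The planted design includes one TE class
    per screening stage so that the funnel's survivor sets are known in
    advance; the fully-planted candidates mirror the flavor of the
    screen's published candidate table (traits, genes, overlap counts,
    one trans pair among six).
    """
    spec = spec or ScenarioSpec()
    out = Path(out_dir)
    (out / "enhancers").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    cohort = generate_cohort(
        CohortSpec(
            spec.cohort.n_per_population, spec.cohort.population_groups,
            spec.cohort.sex_fraction, seed=int(rng.integers(2**31)),
        )
    )
    samples = cohort["sample_id"].tolist()
    n = len(samples)

    # --- plant the TE classes -------------------------------------------
    classes = (
        ["candidate"] * spec.n_candidates + ["low_maf"] * spec.n_low_maf
        + ["no_gwas_link"] * spec.n_no_gwas + ["no_enhancer"] * spec.n_no_enhancer
        + ["non_blood_enhancer"] * spec.n_non_blood
        + ["null_expression"] * spec.n_null_expression
        + ["inconsistent"] * spec.n_inconsistent
    )
    families = ["Alu", "L1", "SVA"]
    blocks: list[LdBlockSpec] = []
    te_classes: dict[str, str] = {}
    cand_idx = 0
    for i, cls in enumerate(classes):
        if cls == "candidate":
            family = _CANDIDATE_FLAVOR[cand_idx % len(_CANDIDATE_FLAVOR)][0]
            cand_idx += 1
        else:
            family = families[i % 3]
        te_id = f"{family}-{i + 101}"
        chrom = str(i % 10 + 1)
        te_pos = 20_000_000 + (i // 10) * 30_000_000
        freq = spec.low_maf_freq if cls == "low_maf" else spec.te_freq
        negative = cls in ("candidate", "inconsistent") and i % 3 == 0
        blocks.append(
            _block_spec(te_id, family, chrom, te_pos, freq, spec.tag_r,
                        spec.snps_per_block, rng, tag_is_negative=negative)
        )
        te_classes[te_id] = cls

    # --- genotypes -------------------------------------------------------
    te_rows, snp_rows, te_meta, snp_meta = [], [], [], []
    for b in blocks:
        te_d, snp_d, _ = generate_ld_block(b, n, rng)
        te_rows.append(te_d)
        te_meta.append((b.te_id, b.chrom, b.te_position, "TE", b.te_family,
                        "N", f"<INS:ME:{b.te_family}>"))
        for j, sid in enumerate(b.snp_ids):
            snp_rows.append(snp_d[j])
            snp_meta.append((sid, b.chrom, b.snp_positions[j], "SNP", None,
                             "A", "G"))
    te_matrix = GenotypeMatrix(
        pd.DataFrame(te_meta, columns=genotype_io.VARIANT_COLUMNS),
        samples, np.vstack(te_rows),
    )
    snp_matrix = GenotypeMatrix(
        pd.DataFrame(snp_meta, columns=genotype_io.VARIANT_COLUMNS),
        samples, np.vstack(snp_rows),
    )

    # --- GWAS table ------------------------------------------------------
    hits, decoys = [], []
    cand_idx = 0
    eqtls: list[PlantedEqtl] = []
    allow: list[tuple[str, str]] = []
    for b in blocks:
        cls = te_classes[b.te_id]
        tag = b.snp_ids[0]
        r_sign = 1 if b.target_r[0] > 0 else -1
        if cls == "candidate":
            fam, trait, gene, gwas_p, n_enh, e_gene, cis = \
                _CANDIDATE_FLAVOR[cand_idx % len(_CANDIDATE_FLAVOR)]
            cand_idx += 1
            beta = spec.eqtl_beta * (1 if cand_idx % 2 else -1)
            direction = "+" if (1 if beta > 0 else -1) * r_sign > 0 else "-"
            hits.append(GwasHit(tag, trait, gene, "A", direction, gwas_p))
            eqtls.append(PlantedEqtl(b.te_id, e_gene, beta, 1.0, cis_flag=cis))
            allow.append((trait, e_gene))
        elif cls == "inconsistent":
            beta = spec.eqtl_beta
            trait, e_gene = f"trait_{b.te_id}", f"GENE_{b.te_id}"
            direction = "-" if r_sign > 0 else "+"  # opposite of sign(beta)*sign(r)
            hits.append(GwasHit(tag, trait, f"MAPPED_{b.te_id}", "A",
                                direction))
            eqtls.append(PlantedEqtl(b.te_id, e_gene, beta, 1.0, cis_flag=True))
            allow.append((trait, e_gene))
        elif cls in ("no_enhancer", "non_blood_enhancer", "null_expression"):
            hits.append(GwasHit(tag, f"trait_{b.te_id}", f"MAPPED_{b.te_id}",
                                "A", "+"))
        elif cls == "no_gwas_link":
            decoys.append(tag)
    gwas = generate_gwas_table(hits, decoys, snp_matrix.variants,
                               int(rng.integers(2**31)))

    # --- enhancers -------------------------------------------------------
    epigenome_ids = [f"E{i + 1:03d}" for i in range(spec.n_epigenomes)]
    blood_ids = epigenome_ids[: spec.n_blood_immune]
    other_ids = epigenome_ids[spec.n_blood_immune:]
    plan: dict[str, set[str]] = {eid: set() for eid in epigenome_ids}
    cand_idx = 0
    for b in blocks:
        cls = te_classes[b.te_id]
        if cls == "candidate":
            n_enh = _CANDIDATE_FLAVOR[cand_idx % len(_CANDIDATE_FLAVOR)][4]
            cand_idx += 1
            for eid in blood_ids[:n_enh]:
                plan[eid].add(b.te_id)
        elif cls in ("null_expression", "inconsistent"):
            for eid in blood_ids[:3]:
                plan[eid].add(b.te_id)
        elif cls == "non_blood_enhancer":
            for eid in other_ids[:2]:
                plan[eid].add(b.te_id)
    # SNP overlaps provide the s_i denominator of the potential statistic
    all_snp_ids = list(snp_matrix.variants["id"])
    for eid in epigenome_ids:
        k = max(1, int(spec.snp_overlap_fraction * len(all_snp_ids)))
        picks = rng.choice(len(all_snp_ids), size=k, replace=False)
        plan[eid].update(all_snp_ids[int(j)] for j in picks)
    points = {
        v["id"]: (v["chrom"], int(v["pos"]))
        for _, v in pd.concat([te_matrix.variants, snp_matrix.variants]).iterrows()
    }
    enhancer_sets, manifest = generate_enhancers(
        points, spec.n_epigenomes, blood_ids, plan, int(rng.integers(2**31)),
    )

    # --- expression ------------------------------------------------------
    expression, gene_models = generate_expression(
        cohort, te_matrix, eqtls, spec.n_null_genes,
        int(rng.integers(2**31)), sex_effect=spec.sex_effect,
        population_effects=dict(spec.population_effects),
    )

    # --- expected per-stage survivor sets -------------------------------
    def _of(*cls: str) -> list[str]:
        return sorted(t for t, c in te_classes.items() if c in cls)

    expected = {
        "input": sorted(te_classes),
        "maf_pass": _of("candidate", "no_gwas_link", "no_enhancer",
                        "non_blood_enhancer", "null_expression", "inconsistent"),
        "disease_linked": _of("candidate", "no_enhancer", "non_blood_enhancer",
                              "null_expression", "inconsistent"),
        "enhancer_colocated": _of("candidate", "non_blood_enhancer",
                                  "null_expression", "inconsistent"),
        "blood_immune": _of("candidate", "null_expression", "inconsistent"),
        "eqtl_planted": _of("candidate", "inconsistent"),
        "final_candidates": _of("candidate"),
    }
    truth = SyntheticTruth(
        ld_blocks=blocks, planted_eqtls=eqtls, gwas_hits=hits,
        enhancer_plan={k: sorted(v) for k, v in plan.items()},
        te_classes=te_classes, expected_stages=expected, allow_list=allow,
    )

    # --- write everything ------------------------------------------------
    paths = {
        "te_vcf": out / "te_genotypes.vcf",
        "snp_vcf": out / "snp_genotypes.vcf",
        "cohort": out / "cohort.tsv",
        "gwas": out / "gwas.tsv",
        "manifest": out / "enhancers" / "manifest.tsv",
        "enhancer_dir": out / "enhancers",
        "expression": out / "expression.tsv",
        "gene_models": out / "gene_models.bed",
        "allow_list": out / "allow_list.tsv",
        "truth": out / "truth.json",
    }
    genotype_io.write_genotypes(te_matrix, paths["te_vcf"])
    genotype_io.write_genotypes(snp_matrix, paths["snp_vcf"])
    cohort.to_csv(paths["cohort"], sep="\t", index=False)
    gwas.to_csv(paths["gwas"], sep="\t", index=False)
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    for es in enhancer_sets:
        write_bed(es, out / "enhancers" / f"{es.epigenome_id}.bed")
    expression.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    gm_bed = gene_models.assign(start0=gene_models["start"] - 1)
    gm_bed[["chrom", "start0", "end", "gene_id"]].to_csv(
        paths["gene_models"], sep="\t", header=False, index=False
    )
    pd.DataFrame(allow, columns=["trait", "gene"]).to_csv(
        paths["allow_list"], sep="\t", index=False
    )
    truth.to_json(paths["truth"])
    log.info("synthetic scenario written to %s (%d TEs, %d SNPs, %d genes)",
             out, te_matrix.n_variants, snp_matrix.n_variants, len(expression))
    return paths, truth
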