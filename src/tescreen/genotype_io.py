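"""Read and write TE / SNP genotype matrices and apply the MAF screen.

Genotypes are diploid dosages of the ALT allele. For a polymorphic TE
(polyTE) insertion the ALT allele is the insertion-present allele, so a
dosage of 0 means no insertion on either haplotype, 1 a heterozygous
insertion and 2 a homozygous insertion.

Allele-frequency convention: for SNPs the minor allele frequency is the
folded frequency min(f, 1 - f). For TEs the reported frequency is the
*unfolded* insertion-allele frequency f, because the ancestral state at
any polyTE locus is absence of the insertion and the insertion allele is
taken to be the minor allele by convention. A TE whose insertion
frequency is 0.96 therefore passes a 0.05 screen even though its folded
frequency would not; this asymmetry is deliberate and logged.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

#: symbolic ALT id component -> family label used in reports
TE_ALT_FAMILIES = {"ALU": "Alu", "LINE1": "L1", "SVA": "SVA"}
_FAMILY_TO_ALT = {v: k for k, v in TE_ALT_FAMILIES.items()}

VARIANT_COLUMNS = ["id", "chrom", "pos", "kind", "te_family", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Variants x samples dosage matrix with per-variant metadata.

    ``variants`` is a DataFrame with columns ``id, chrom, pos, kind,
    te_family, ref, alt`` (``kind`` in {"SNP", "TE"}; ``te_family`` is
    None for SNPs). ``dosages`` is a float array of shape
    ``(n_variants, n_samples)`` with values in {0, 1, 2} and NaN for
    missing calls.
    """

    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)
    dosages: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        missing = [s for s in sample_ids if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            self.variants.copy(), list(sample_ids), self.dosages[:, idx]
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            keep = np.flatnonzero(mask)
        else:
            keep = mask
        return GenotypeMatrix(
            self.variants.iloc[keep].reset_index(drop=True),
            list(self.samples),
            self.dosages[keep],
        )

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if not hits.size:
            raise KeyError(f"variant {variant_id!r} not in matrix")
        return int(hits[0])

    def dosages_for(self, variant_id: str) -> np.ndarray:
        return self.dosages[self.variant_index(variant_id)]


def _classify_alt(alt: str) -> tuple[str, str | None]:
    """Map a VCF ALT string to (kind, te_family)."""
    if alt.startswith("<INS:ME:") and alt.endswith(">"):
        token = alt[len("<INS:ME:"):-1].upper()
        family = TE_ALT_FAMILIES.get(token)
        if family is None:
            raise ValueError(f"unknown mobile-element ALT {alt!r}")
        return "TE", family
    return "SNP", None


def read_genotypes(
    vcf_path: str | Path, sample_subset: Sequence[str] | None = None
) -> GenotypeMatrix:
    """Load a VCF of biallelic TE and/or SNP records into a GenotypeMatrix.

    Diploid GT fields are mapped to the dosage of the ALT allele (for
    TEs, the insertion allele); a GT with any missing allele becomes
    NaN. Non-diploid GT fields are an error naming the record.
    """
    vf = pysam.VariantFile(str(vcf_path))
    all_samples = list(vf.header.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in all_samples]
        if missing:
            raise KeyError(f"samples absent from {vcf_path}: {missing}")
        samples = list(sample_subset)
    else:
        samples = all_samples

    meta: list[tuple] = []
    rows: list[np.ndarray] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"record {rec.id or rec.pos} is not biallelic")
        alt = rec.alts[0]
        kind, family = _classify_alt(alt)
        row = np.empty(len(samples))
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or len(gt) != 2:
                raise ValueError(
                    f"non-diploid GT for sample {s} at record "
                    f"{rec.id or f'{rec.chrom}:{rec.pos}'}"
                )
            if gt[0] is None or gt[1] is None:
                row[j] = np.nan
            else:
                row[j] = sum(1 for a in gt if a == 1)
        meta.append((rec.id, rec.chrom, rec.pos, kind, family, rec.ref, alt))
        rows.append(row)
    vf.close()

    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    dosages = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(variants, samples, dosages)


def write_genotypes(matrix: GenotypeMatrix, vcf_path: str | Path) -> Path:
    """Write a GenotypeMatrix as VCF 4.2 (GT subfield only).

    TE records get the symbolic mobile-element ALT of their family;
    SNPs keep their literal alleles.
    """
    header = pysam.VariantHeader()
    for chrom in pd.unique(matrix.variants["chrom"]):
        header.add_line(f"##contig=<ID={chrom}>")
    for token, family in TE_ALT_FAMILIES.items():
        header.add_line(
            f'##ALT=<ID=INS:ME:{token},Description="{family} mobile element insertion">'
        )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in matrix.samples:
        header.add_sample(s)

    vf = pysam.VariantFile(str(vcf_path), "w", header=header)
    for i, v in matrix.variants.iterrows():
        if v["kind"] == "TE":
            alleles = (v["ref"] or "N", f"<INS:ME:{_FAMILY_TO_ALT[v['te_family']]}>")
        else:
            alleles = (v["ref"], v["alt"])
        rec = vf.new_record(
            contig=v["chrom"], start=int(v["pos"]) - 1, stop=int(v["pos"]),
            alleles=alleles, id=v["id"],
        )
        for j, s in enumerate(matrix.samples):
            d = matrix.dosages[i, j]
            if np.isnan(d):
                rec.samples[s]["GT"] = (None, None)
            else:
                d = int(d)
                rec.samples[s]["GT"] = (0, 1) if d == 1 else (d // 2, d // 2)
        vf.write(rec)
    vf.close()
    return Path(vcf_path)


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-variant allele frequency under the screen's convention.

    SNPs: folded MAF = min(f, 1-f) with f the ALT-allele frequency.
    TEs: the unfolded insertion-allele frequency f itself.
    All-missing variants get NaN and a warning; they are dropped by
    :func:`filter_maf`.
    """
    n_called = np.sum(~np.isnan(matrix.dosages), axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(matrix.dosages, axis=1) / (2.0 * n_called)
    f[n_called == 0] = np.nan
    if (n_called == 0).any():
        bad = matrix.variants.loc[n_called == 0, "id"].tolist()
        log.warning("variants with no called genotypes (excluded downstream): %s", bad)
    is_snp = (matrix.variants["kind"] == "SNP").to_numpy()
    out = f.copy()
    out[is_snp] = np.minimum(f[is_snp], 1.0 - f[is_snp])
    return out


def filter_maf(matrix: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain variants with frequency strictly greater than ``threshold``.

    The screen uses strict ">" at the cutoff ("greater than 5%"). TEs
    use the unfolded insertion frequency (see module docstring), so a
    high-frequency insertion is retained rather than folded out.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    freq = minor_allele_frequency(matrix)
    with np.errstate(invalid="ignore"):
        keep = freq > threshold
    keep &= ~np.isnan(freq)
    unfolded_high = keep & (freq > 0.5)
    if unfolded_high.any():
        log.info(
            "%d TE variants retained with unfolded insertion frequency > 0.5",
            int(unfolded_high.sum()),
        )
    return matrix.subset_variants(keep)


def maf_report(
    matrix: GenotypeMatrix, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-group allele-frequency table (one row per variant per group)."""
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    out = []
    for group in sorted(groups.unique()):
        ids = [s for s in matrix.samples if groups.get(s) == group]
        sub = matrix.subset_samples(ids)
        freq = minor_allele_frequency(sub)
        out.append(
            pd.DataFrame(
                {
                    "variant_id": sub.variants["id"],
                    "kind": sub.variants["kind"],
                    "group": group,
                    "n_samples": len(ids),
                    "frequency": freq,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
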