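"""Enhancer-interval overlap and the relative regulatory-potential statistic.

Enhancer calls are per-epigenome BED intervals (0-based half-open).
Variants are point coordinates in the 1-based VCF frame; the conversion
between the two frames happens in exactly one function
(:func:`point_to_bed`), so a 1-based position p lies inside BED
interval [start, end) iff start <= p - 1 < end, i.e. start < p <= end.

The relative regulatory potential of TE insertions in epigenome i is
r_i = t_i / s_i, where t_i is the proportion of disease-linked TEs
co-located with an enhancer of epigenome i and s_i is the proportion of
SNPs from those TEs' LD blocks overlapping an enhancer of the same
epigenome. r_i > 1 indicates TE enrichment in that epigenome's
enhancers; r_i is undefined (NaN) when s_i = 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Point = tuple[str, int]  # (chrom, 1-based position)


def point_to_bed(pos: int) -> int:
    """Convert a 1-based point coordinate to the 0-based BED frame."""
    if pos < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos}")
    return pos - 1


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or abutting half-open intervals."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.size == 0:
        return iv
    if (iv[:, 0] >= iv[:, 1]).any():
        raise ValueError("intervals must satisfy start < end")
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


@dataclass
class EnhancerSet:
    """Merged, sorted enhancer intervals of one epigenome."""

    epigenome_id: str
    tissue_label: str = ""
    blood_immune: bool = False
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {
            chrom: merge_intervals(iv) for chrom, iv in self.intervals.items()
        }

    def contains(self, chrom: str, pos: int) -> tuple[bool, tuple[int, int] | None]:
        """Point-in-interval query for a 1-based position.

        Unknown chromosomes return False (enhancer maps are sparse;
        this is logged at debug level, not an error).
        """
        iv = self.intervals.get(chrom)
        if iv is None or iv.size == 0:
            log.debug("epigenome %s has no intervals on chromosome %s",
                      self.epigenome_id, chrom)
            return False, None
        p0 = point_to_bed(pos)
        k = int(np.searchsorted(iv[:, 0], p0, side="right")) - 1
        if k >= 0 and p0 < iv[k, 1]:
            return True, (int(iv[k, 0]), int(iv[k, 1]))
        return False, None


def overlaps(position: Point, enhancer_set: EnhancerSet) -> bool:
    chrom, pos = position
    return enhancer_set.contains(chrom, pos)[0]


def read_bed(
    path: str | Path,
    epigenome_id: str,
    tissue_label: str = "",
    blood_immune: bool = False,
) -> EnhancerSet:
    """Read a 3+ column BED file into an EnhancerSet (merge-first)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
        comment="#",
    )
    intervals = {
        chrom: grp[["start", "end"]].to_numpy(dtype=np.int64)
        for chrom, grp in df.groupby("chrom", sort=True)
    }
    return EnhancerSet(epigenome_id, tissue_label, blood_immune, intervals)


def write_bed(enhancer_set: EnhancerSet, path: str | Path) -> Path:
    rows = []
    for chrom in sorted(enhancer_set.intervals):
        for s, e in enhancer_set.intervals[chrom]:
            rows.append((chrom, int(s), int(e)))
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False
    )
    return Path(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Epigenome manifest: epigenome_id, tissue_label, blood_immune (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"epigenome_id": str})
    need = {"epigenome_id", "tissue_label", "blood_immune"}
    if not need.issubset(df.columns):
        raise ValueError(f"manifest {path} must have columns {sorted(need)}")
    df["blood_immune"] = df["blood_immune"].astype(int).astype(bool)
    return df


def load_enhancer_sets(manifest_path: str | Path, bed_dir: str | Path) -> list[EnhancerSet]:
    """Load one BED per manifest row (``<bed_dir>/<epigenome_id>.bed``)."""
    manifest = read_manifest(manifest_path)
    bed_dir = Path(bed_dir)
    return [
        read_bed(
            bed_dir / f"{row.epigenome_id}.bed",
            row.epigenome_id, row.tissue_label, bool(row.blood_immune),
        )
        for row in manifest.itertuples()
    ]


def overlap_matrix(
    points: Mapping[str, Point], enhancer_sets: Sequence[EnhancerSet]
) -> pd.DataFrame:
    """Boolean variant x epigenome co-location matrix (heatmap export)."""
    data = {
        es.epigenome_id: [overlaps(pt, es) for pt in points.values()]
        for es in enhancer_sets
    }
    return pd.DataFrame(data, index=list(points.keys()))


def regulatory_potential(
    disease_linked_tes: Mapping[str, Point],
    block_snps: Mapping[str, Point],
    enhancer_sets: Sequence[EnhancerSet],
) -> pd.DataFrame:
    """Per-epigenome t_i, s_i and r_i = t_i / s_i.

    ``disease_linked_tes`` and ``block_snps`` map variant ids to
    (chrom, 1-based pos) points. The SNP universe is the LD-block SNPs
    of the disease-linked TEs. Epigenomes with s_i = 0 get NaN r_i.
    """
    if not disease_linked_tes:
        raise ValueError("disease-linked TE set must be non-empty")
    if not block_snps:
        raise ValueError("block SNP set must be non-empty")
    rows = []
    for es in enhancer_sets:
        t_i = np.mean([overlaps(pt, es) for pt in disease_linked_tes.values()])
        s_i = np.mean([overlaps(pt, es) for pt in block_snps.values()])
        r_i = t_i / s_i if s_i > 0 else np.nan
        if s_i == 0 and t_i > 0:
            log.warning("epigenome %s: t=%.3g with s=0; r_i undefined",
                        es.epigenome_id, t_i)
        rows.append((es.epigenome_id, es.tissue_label, es.blood_immune,
                     float(t_i), float(s_i), float(r_i)))
    return pd.DataFrame(
        rows, columns=["epigenome_id", "tissue_label", "blood_immune", "t", "s", "r"]
    )


def mean_relative_potential(potentials: pd.DataFrame) -> tuple[float, float]:
    """(mean r_i over blood/immune epigenomes, mean over the others).

    Only epigenomes with defined r_i contribute; a class with none
    yields NaN.
    """
    def _mean(sub: pd.DataFrame) -> float:
        vals = sub["r"].dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    return (
        _mean(potentials[potentials["blood_immune"]]),
        _mean(potentials[~potentials["blood_immune"]]),
    )


def overlap_counts(
    points: Mapping[str, Point],
    enhancer_sets: Sequence[EnhancerSet],
    flagged_only: bool = False,
) -> pd.Series:
    """Per-variant count of epigenomes whose enhancers contain the point.

    Counts epigenomes, not intervals, matching the screen's
    "#Enhancer Overlaps" semantics.
    """
    sets = [es for es in enhancer_sets if es.blood_immune or not flagged_only]
    return pd.Series(
        {vid: sum(overlaps(pt, es) for es in sets) for vid, pt in points.items()},
        dtype=int,
    )


def filter_blood_immune(
    disease_linked_tes: Mapping[str, Point],
    enhancer_sets: Sequence[EnhancerSet],
) -> pd.DataFrame:
    """TEs overlapping >= 1 enhancer of >= 1 blood/immune epigenome.

    Returns a table with the all-epigenome overlap count (the
    "#Enhancer Overlaps" column) and the flagged-epigenome count; rows
    are the TEs whose flagged count is >= 1.
    """
    if not any(es.blood_immune for es in enhancer_sets):
        raise ValueError(
            "no blood/immune-flagged epigenomes in the manifest; "
            "the enhancer filter cannot proceed"
        )
    total = overlap_counts(disease_linked_tes, enhancer_sets)
    flagged = overlap_counts(disease_linked_tes, enhancer_sets, flagged_only=True)
    df = pd.DataFrame(
        {"te_id": total.index, "n_enhancer_overlaps": total.to_numpy(),
         "n_blood_immune_overlaps": flagged.reindex(total.index).to_numpy()}
    )
    return df[df["n_blood_immune_overlaps"] >= 1].reset_index(drop=True)
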