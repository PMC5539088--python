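# Methods

`tescreen` implements a genome-wide screening cascade that starts from
polymorphic transposable-element (polyTE) insertion genotypes and
converges on a short list of candidate insertions that are (i) in
linkage disequilibrium with published GWAS disease associations,
(ii) located inside blood/immune enhancer elements, (iii) associated
with gene-expression changes in B-cells, and (iv) directionally
consistent with the GWAS association. This note records the model, the
parameter choices, the synthetic-data design, and the numerical
decisions that were genuinely open.

## The screening model

**Genotypes.** TE insertions and SNPs are diploid dosages in {0, 1, 2}
of the ALT allele; for a TE the ALT allele is the insertion-present
allele (0 = homozygous absent, 1 = heterozygous, 2 = homozygous
present). Missing calls are NaN and handled pairwise-complete
downstream; nothing is imputed — the simplest defensible contract for
a screen whose statistics all tolerate per-pair sample loss.

**MAF filter.** Variants are retained when their allele frequency is
*strictly greater* than the threshold (default 0.05), separately per
continental group. For SNPs the frequency is folded, `min(f, 1-f)`.
For TEs the *unfolded* insertion-allele frequency is used, because the
ancestral state at a polyTE locus is absence of the insertion and the
insertion allele is taken as the minor allele by convention. The
asymmetry is deliberate and logged: a TE at insertion frequency 0.96
passes the filter even though its folded frequency would not. A
dedicated test documents the unfolded choice against the folded
alternative.

**Linkage (LD) stage.** For each TE, all SNPs within a symmetric
window (default ±1 Mb — the same scale as the cis window; the
operational definition of an "LD block" is otherwise open, so the
window is an explicit configuration value echoed into the run log) are
correlated with the TE dosage using Pearson r on pairwise-complete
samples. Significance uses the exact t transform
`t = r sqrt((n-2)/(1-r^2))` on n−2 degrees of freedom, two-sided. SNPs
with p < 0.05 are "linked". No multiple-testing correction is applied
at this stage: it is a deliberately lenient screening filter, and the
stringency lives downstream. Untestable pairs (constant vectors, fewer
than 3 complete samples) are reported with a reason, never as NaN.

**GWAS stage.** A catalog-style table is filtered at strictly
P < 1e-5. Duplicate (SNP, trait) pairs keep the smallest P. A TE is
disease-linked iff at least one of its linked SNPs is a retained hit;
all supporting (SNP, trait, gene) triples are kept because the final
direction check is per support, not per TE. Traits are opaque strings
— no ontology mapping.

**Enhancer stage.** Enhancer calls are per-epigenome BED intervals
(0-based half-open), merged on load; TE insertions are *points* (the
breakpoint coordinate reported in the genotype VCF). The single
coordinate conversion in the package maps 1-based point p to BED frame
p−1, so p is inside [start, end) iff start < p ≤ end. The relative
regulatory potential of epigenome i is r_i = t_i/s_i, with t_i the
proportion of disease-linked TEs inside that epigenome's enhancers and
s_i the same proportion for the SNPs of those TEs' LD blocks (the SNP
universe is the linked SNPs of the disease-linked TEs; using all SNPs
genome-wide would be an alternative reading and is trivially obtained
by passing a different SNP set). r_i is undefined when s_i = 0 and is
excluded from class means. The blood/immune filter keeps TEs
overlapping at least one enhancer of at least one flagged epigenome;
the exported "#Enhancer Overlaps" count is per epigenome, not per
interval.

**eQTL stage.** For every candidate TE × gene pair within a group,
expression is regressed on dosage with an intercept, a sex indicator
and reference-coded population indicators (within a one-population
group the population covariate drops out). The additive least-squares
model is implemented directly by normal equations — vectorized across
genes for a fixed TE design — rather than wrapping an external eQTL
tool, so the statistical surface is self-contained and testable; the
test suite cross-checks it against an independent OLS implementation.
The dosage coefficient is tested two-sided on the residual degrees of
freedom. Benjamini–Hochberg q-values are computed over all testable
pairs of the group's run (pooled across cis and trans; correcting
within the candidate set only is a configuration away since q-values
are recomputed from the exported p column). The significance contract
is q < 0.05; the realized p threshold that this induces is
data-dependent and is reported in the run log rather than fixed.
Zero-variance genes are skipped with a logged count (reducing m).
A pair is cis iff the TE lies within 1 Mb of the gene boundaries on
the same chromosome, inclusive at exactly 1 Mb. Per TE, the
minimum-p significant record is kept; ties break by larger |t|, then
lexicographic gene id, so selection is deterministic under reordering.

**Consistency stage.** The TE expression-effect sign is translated
into the risk-allele frame via the sign of the TE–SNP correlation
(insertion positively linked to the risk allele keeps its sign;
negatively linked flips it), then compared with the GWAS effect
direction: consistent iff `sign(beta)·sign(r) == direction`. This sign
algebra is the package's formalization of "same direction of
association"; it is invariant under a coherent flip of the linkage
frame, verified by enumerating all eight sign combinations against a
truth table written before implementation. The "functionally related
gene" judgment is not code: it enters as an optional allow-list of
(trait, gene) pairs, and supports with unknown GWAS direction go to a
needs-curation table instead of being dropped. Output is long format
(one row per TE–trait support) with the distinct-TE count reported
alongside.

## Synthetic data: what it emulates, what it does not

The generator produces all four inputs with planted, recoverable
structure.

* **LD planting.** TE haplotype alleles are Bernoulli(p); each SNP
  haplotype allele is drawn conditionally with
  P(snp=1|te=1) = q + D/p and P(snp=1|te=0) = q − D/(1−p), where
  D = r·sqrt(p(1−p)q(1−q)). This makes the haplotype covariance
  exactly D, and dosage r (what the screen measures) converges to the
  same r since summing two independent haplotypes doubles both the
  covariance and the variances. Requested r outside the
  frequency-determined bound (all four conditional probabilities in
  [0,1]) is an error naming the bound. Negative r is supported and
  used, since an insertion may be anti-correlated with a risk allele
  and the direction filter must be exercised both ways; note that
  strong negative r requires q ≈ 1−p.
* **Expression.** y = μ + β·g + sex/population offsets + N(0, σ²);
  null genes have β = 0. Values are generated already "normalized"
  (the upstream RPKM/PEER normalization of real expression data is an
  input to this package, not part of it); units are arbitrary.
* **Enhancers.** Intervals are placed to strictly contain planned
  variants and exclude all others, clipped to half the distance to the
  nearest neighbouring variant; decoy intervals are placed beyond all
  variants so BED files are non-trivial.
* **Default scenario.** The bundled end-to-end scenario uses the
  study-scale conditions: 445 samples (one African population of 87,
  four European populations totalling 358), tag SNPs planted at
  |r| = 0.9 (where linkage power is ≈ 1 at both group sizes), TE
  insertion frequencies of 0.30 against a 0.05 cutoff (with a low-MAF
  class at 0.02), planted expression effects of 2σ, 127 epigenomes
  with 27 flagged blood/immune, and one planted TE class per funnel
  stage (6 full candidates — five cis, one trans — plus classes
  failing exactly one filter each: MAF, GWAS linkage, enhancer
  overlap, blood/immune flag, expression effect, direction
  consistency). Funnel survivor sets are therefore known in advance:
  25 → 22 → 18 → 15 → 12 → 9 → 6 per group.

What the generator does *not* emulate: recombination-map realism
(each TE has an independent LD block), population structure beyond
discrete labels, genotype-calling error, expression batch effects, or
read-level data. Passing tests therefore demonstrate the correctness
and calibration of the screen's statistics and plumbing under the
stated model — not robustness to the failure modes of real consortium
data, whose headline counts depend on those external datasets and are
out of reach at this scale.

## Numerical choices and edge cases

* p-values from perfect correlations or exact fits are floored at the
  smallest positive double rather than returned as 0, keeping them in
  (0, 1].
* Correlation r is clipped into [−1, 1] before the t transform.
* BH q-values come from `statsmodels.stats.multitest.multipletests`;
  hand-computed vectors are frozen in tests.
* Rank-deficient eQTL designs (e.g. sex aliasing population) and
  constant dosages mark the pair untestable with a reason; untestable
  pairs stay in the output table and are excluded from m.
* Nearest-GWAS-SNP distance ties break toward the smaller coordinate.
* Gene coordinates are 1-based inclusive internally; BED conversion
  happens only at I/O boundaries.
* Reruns are byte-identical: the screen itself contains no randomness,
  and all TSV output uses fixed float formatting.

## Test and acceptance problem sizes

The statistical validation uses: 1000 random vector pairs against a
definitional-sums correlation oracle; 100 seeds × n = 10 000 per
planted LD target in {0, 0.3, 0.6, 0.9} (tolerance ±0.02 on the mean);
1000 null SNPs at n = 445 for type-I calibration (±3 binomial SE); 500
random small designs against an independent OLS; 100 seeds of 5
planted effects among 500 null genes for power/FDR; 10 000 points ×
1000 intervals against an exhaustive overlap scan; and the full
end-to-end scenario run twice for byte-identical determinism. These
sizes make every check decisive (Monte-Carlo error well inside each
tolerance) while the whole suite runs in well under a minute.

## Known limitations

* The screen treats TE insertions as points; a configuration padding
  could be added where breakpoint uncertainty matters.
* Effect directions for real GWAS catalogs are not uniformly reported;
  real-data use requires the user to supply the direction column
  (the synthetic table always carries it).
* The published analogue of this screen reports both "seven
  high-confidence" candidates and a six-row candidate table; since
  long-format rows and distinct TEs can legitimately differ, both
  counts are always reported.
* BH controls the *expected* false-discovery proportion, so the eQTL
  stage may admit occasional null discoveries by design; exactness in
  the end-to-end test is asserted where the stages are deterministic
  and at the final allow-list-protected candidate set.
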