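# tescreen

A genome-wide screen for **polymorphic transposable-element (polyTE)
insertions that plausibly cause disease through gene-regulatory
effects**. Active human retrotransposon families (Alu, L1, SVA) keep
generating presence/absence insertion polymorphisms; because GWAS
panels genotype SNPs rather than structural variants, a disease signal
tagged by a SNP may actually be driven by a linked TE insertion sitting
inside a regulatory element. `tescreen` is for population/statistical
geneticists who want to run — or validate end to end — the
successive-filter cascade that turns thousands of polyTE genotypes into
a handful of high-confidence, mechanistically interpretable candidates.

## The screen

Per continental population group (AFR, EUR), five filters are applied
in order; each stage's survivor set is a subset of the previous one
(the "funnel"):

1. **MAF** — keep variants with allele frequency > 0.05 (TEs use the
   *unfolded* insertion-allele frequency, the insertion being the minor
   allele by convention).
2. **GWAS linkage** — for each TE, Pearson correlation *r* of dosage
   vectors with every SNP within ±1 Mb; significance from the exact
   transform *t = r√((n−2)/(1−r²))*; a TE is disease-linked iff a
   linked SNP (p < 0.05) is a GWAS hit at P < 10⁻⁵.
3. **Enhancer overlap** — keep TEs whose insertion point falls inside
   an enhancer of ≥ 1 blood/immune-flagged epigenome. The per-epigenome
   enrichment statistic is *rᵢ = tᵢ/sᵢ* (TE overlap proportion over
   LD-block-SNP overlap proportion).
4. **eQTL** — ordinary least squares of expression on TE dosage with
   sex and population covariates, for all TE × gene pairs;
   Benjamini–Hochberg FDR q < 0.05; cis iff the TE is within 1 Mb of
   the gene boundaries; strongest association kept per TE.
5. **Direction consistency** — the TE effect sign, translated into the
   risk-allele frame through sign(*r*), must equal the GWAS effect
   direction: `sign(β)·sign(r) == direction`. An optional (trait, gene)
   allow-list carries the functional-relatedness judgment.

A synthetic-data module plants every layer of structure (haplotype-
level LD at a target *r*, GWAS hits with known directions, enhancer
overlaps by plan, expression effects with known β), so the whole
cascade is testable with exact ground truth. See `docs/methods.md`.

## Worked example

Generate the bundled synthetic scenario (445 samples: 87 AFR + 358
EUR; 25 planted TEs; 127 epigenomes, 27 blood/immune) and run the
screen:

```sh
tescreen simulate --out demo --seed 7
tescreen run --config demo/run_config.yaml
```

which prints

```
[AFR] funnel: {'input': 25, 'maf_pass': 22, 'disease_linked': 18,
 'enhancer_colocated': 15, 'blood_immune': 12, 'eqtl_significant': 9,
 'strongest_per_te': 9, 'final_candidates': 6, 'final_candidate_rows': 6}
[EUR] funnel: {'input': 25, 'maf_pass': 22, ... 'final_candidates': 6, ...}
```

Reading the funnel: of 25 TEs, 3 fail the MAF filter (insertion
frequency 0.02), 4 are linked only to non-GWAS SNPs, 3 have no
enhancer overlap and 3 overlap only non-blood epigenomes, 3 have no
expression effect, and 3 have a significant eQTL whose direction
contradicts the GWAS association — leaving exactly the 6 planted
candidates. `demo/screen_out/EUR/candidates.tsv` holds the final
table, e.g.:

```
te_id    chrom  pos       gwas_phenotype        n_enhancer_overlaps  e_gene    eqtl_beta  eqtl_p       eqtl_type
Alu-101  1      20000000  Diabetic retinopathy  1                    LILRA1     1.99      1.8e-83      trans
Alu-102  2      20000000  Lymphoma              20                   HLA-DRB5  -2.03      6.1e-77      cis
```

Here `eqtl_beta` is the expression change per insertion allele (the
planted effects are ±2 residual SDs, recovered accurately), and every
row's direction is consistent with its GWAS support. Per-stage exports
(linkage table, regulatory potentials, Q–Q and Manhattan data, the
needs-curation list and funnel report) land next to it.

The same screen runs on real inputs — TE/SNP VCFs (symbolic
`<INS:ME:*>` ALT alleles for TEs), a GWAS table TSV, per-epigenome
enhancer BEDs with a manifest, and a normalized expression matrix —
via the same YAML config; `tescreen stage <name> --config ...` stops
after any single stage.

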