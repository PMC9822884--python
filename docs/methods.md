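# Methods

This document states the models, parameters and numerical choices
implemented in `triodx`. All genomic coordinates are 1-based inclusive
(VCF convention); BED input is converted at the reading boundary.

## Small-variant triage (`trio_snv`)

**Genotype QC.** A variant passes when the child has depth ≥ 10 and an alt
allele fraction inside [0.25, 0.75] for heterozygous calls or ≥ 0.90 for
homozygous/hemizygous calls. De novo candidates (child carries, both
parents called homozygous reference) additionally require each parent to
have depth ≥ 10 and alt fraction < 0.05, guarding against parental allele
dropout. Failures carry machine-readable reason codes
(`missing_data`, `low_depth`, `allele_fraction`, `parental_support`).

**Interpretation scope.** The "exome from genome": a position is in scope
when it overlaps an exon (non-coding exons and UTRs included) or lies
within 8 bp of an exon boundary (splice window, configurable). Widening the
window is monotone — it can only add positions.

**Segregation.** Autosomal rules over called trio genotypes: a child het is
*de novo* iff both parents are homozygous reference; a child homozygote is
*homozygous* iff both parents carry the allele; impossible configurations
(child het with both parents homozygous alt; child homozygote with a
non-carrying parent) are flagged `mendelian_inconsistent` and receive no
mode. Missing parental genotypes suppress the modes that need that parent
and flag `incomplete_segregation`. Inherited heterozygous variants are
retained only as dominant candidates when already classified P/LP (a
configuration switch). On male X outside the GRCh37 pseudoautosomal regions
(X:60,001–2,699,520 and X:154,931,044–155,260,560, packaged), child calls
are coerced hemizygous; only the mother informs de novo status because a
father's X is not transmitted to a son.

**Compound heterozygotes.** Child-het variants of one gene are paired when
their parental origins are one paternal plus one maternal, or one de novo
plus one inherited. Ambiguous phasing (both parents carry) never forms a
pair, so no emitted pair can sit on one haplotype.

**Prioritization.** Tier 1 = NDD-panel genes, tier 2 = other established
disease genes, tier 3 = candidate genes; variants in unlisted genes are
dropped. Rarity gates are per mode: population/in-house allele frequency
≤ 0.001 for dominant modes (de novo, inherited dominant), ≤ 0.01 for
recessive modes with zero tolerated population homozygotes when a count is
available. Within a tier, ordering is clinical classification
(P < LP < VUS < unlabeled < LB < B), then frequency, then position.

## CNV triage (`cnv_triage`)

Child-carried DEL/DUP events are kept when de novo, homozygous (copy
number 0 with both parents carrying) or hemizygous (male X non-PAR).
Parental carrier status uses joint genotypes when present, otherwise a
≥ 50% reciprocal-overlap match (same SV type) against the parent's own call
list. Duplicate calls from different callers merge at ≥ 80% reciprocal
overlap, keeping the higher-quality record and pooling caller evidence.
Reciprocal overlap is the minimum of the two per-interval overlap
fractions.

Kept events fall into the highest-priority satisfied category:

1. any overlap (one base pair suffices, intronic included) with an
   NDD-panel gene — a switch can require exon overlap instead;
2. exon overlap with an established disease gene;
3. exon overlap with any gene, for events strictly larger than 10 kb.

Single-allele deletions over autosomal-recessive genes are additionally
paired with child-het small variants in trans (deletion de novo, or the
small variant inherited from the parent not carrying the deletion); a
variant physically inside the deletion on the same parental haplotype is
never paired.

Reported event sizes round half-up to the nearest kb below 100 kb and to
0.1 Mb at or above — the convention that matches published clinical CNV
tables (e.g. a 608,343 bp deletion prints as "0.6 Mb", a 5,335 bp deletion
as "5 kb"). Copy-number strings in cytogenetic `band(start-end)xN` notation
are parsed in both printed copy-number dialects (`…x1` and `…3x`).

## STR triage (`str_triage`)

Repeat genotypes are classified by the larger allele against locus
thresholds packaged for the six NDD loci: FMR1 (premutation ≥ 55, full
mutation ≥ 200), AFF2 (≥ 200), DMPK (≥ 50), CSTB (≥ 30), ARX (≥ 20),
EIF4A3 (≥ 14). Classification is monotone in allele size. Any allele at or
above a premutation threshold is flagged for orthogonal confirmation. A
pipeline option (`premutation_is_diagnostic`, default on) reports a
confirmed premutation-range FMR1 allele as diagnostic; with the option off
it contributes a VUS. Loci without thresholds pass through unevaluated.

## ROH and mitochondrial DNA (`roh_mito`)

ROH detection follows the PLINK sliding-window scheme with the three
published overrides (window het allowance 3, minimum 50 SNPs per segment,
minimum 300 kb) on top of PLINK defaults for unstated parameters (window
size 50 SNPs, per-SNP hit proportion 0.05, missing-call allowance 5). A
window is homozygous when it contains at most 3 het and 5 missing calls; a
SNP supports an ROH when ≥ 5% of the windows covering it are homozygous;
maximal runs of supporting SNPs become segments, filtered by SNP count and
physical length. ROH output is annotative only: a homozygous candidate
inside a segment is tagged as consistent with identity by descent, but an
ROH never constitutes a diagnosis by itself.

Mitochondrial variants match the catalog on exact (position, reference,
alternate); the child's alt read fraction is carried as a heteroplasmy
proxy. The packaged catalog is an explicitly synthetic stand-in holding a
handful of well-known confirmed pathogenic mutations and is
user-replaceable.

## Outcome classification and concordance (`diagnosis`)

Per patient: *conclusive* when some candidate is P/LP in an established
disease gene (panel or otherwise) with a phenotype match — and, for genes
annotated autosomal recessive, biallelic support (homozygous, compound
heterozygous, or an in-trans partner); *possible* when some candidate is a
VUS in a disease gene with a phenotype match, or P/LP in a candidate gene;
otherwise *none*. Conclusive dominates possible. Phenotype match is an
input flag per (patient, gene) — it encodes expert clinical judgment and
is supplied as data, never computed. A pathogenic-but-monoallelic
recessive finding yields outcome none with rationale
`monoallelic_recessive`.

Two pathways are compared as a 3×3 concordance matrix over the shared
patient set, with a named list of discordant patients. For patients with
several findings, the primary variant (the one counted in per-type
tallies) is the highest-tier candidate, then the rarest, then input order.

Fisher's exact test is computed with exact big-integer rational
arithmetic (no floating-point hypergeometrics); the two-sided p-value uses
the point-probability rule, summing all tables with the observed margins
whose probability does not exceed the observed table's. An all-zero table
returns p = 1 by convention. `scipy.stats.fisher_exact` serves as an
independent cross-check in the test suite, never as the implementation.

## Synthetic cohorts (`synthetic_cohort`)

Defaults are study conditions, not tuning knobs: 150 trios, 101 male
children, outcome fractions 45/150 conclusive, 35/150 possible, 70/150
none; conclusive type weights 26 SNV : 13 indel : 5 CNV : 1 STR; small
variant mode weights 36 de novo : 1 homozygous : 3 hemizygous (of 40);
2 of the 5 conclusive CNVs and 4 possible-outcome CNVs are visible to GS
only. Counts are apportioned by largest remainder, so configured fractions
are met exactly and the realized counts are seed-independent; all
stochastic detail (positions, alleles, depths, noise) flows from one
seeded NumPy generator, making bundles byte-identical for a fixed
configuration.

The simulated genome is 23 uniform 50 Mb contigs (1–22, X) plus mtDNA;
the fixed gene set has three genes per chromosome, each with ten 150 bp
exons spaced 5 kb apart, the last exon non-coding. Monoallelic plants
(single-allele CNVs, de novo VUS) draw only from autosomal-dominant gene
pools, since triage rightly demands a second allele in recessive genes.
Background variants are Mendelian-consistent exonic polymorphisms
(Hardy-Weinberg parents, allele frequency 0.02–0.5, benign labels) that
the frequency gates and classification rules exclude from diagnoses.
Depths are negative-binomial (mean 50, dispersion 10); het allele
fractions are Beta-distributed around 0.5. Optional noise: parental
genotype dropout and genotype errors injected as guaranteed
Mendelian-inconsistent configurations at configured rates (default 0).

Both pathway views derive from one cohort: the SOC structural-variant
files omit CNVs smaller than 10 kb and CNVs touching only non-coding
exons — the two ways small pathogenic CNVs historically escaped
exome-based work-ups.

## Reference tables (`reference_cohort`)

The packaged diagnosis tables (conclusive small-variant and CNV/STR
diagnoses from a published 150-trio two-pathway comparison) are fixtures,
not computations. From them the module recomputes: distinct diagnosed
patients per pathway (rows marked concordant are SOC-and-GS; `GS+` rows
are GS-only), per-type tallies via the primary-variant rule, CNV size
labels from the printed coordinates, and the FMR1 repeat allele from
repeat notation.

## Limitations

- Variant calling itself is out of scope; inputs are call sets.
- Phenotype matching is supplied as data, not computed from HPO terms.
- The published possible-diagnosis patient lists are not available, so
  possible-outcome cells of the published concordance table are
  reproduced only on synthetic cohorts, never recomputed from fixtures.
- The published yield-comparison p-value of 1.0 is not recoverable from
  the public counts (the unpaired two-sided construction gives ≈ 0.90);
  both constructions are computed and reported by
  `analysis/04_statistics.py`.
- The mitochondrial catalog is synthetic; results on real data depend on
  supplying a current curated catalog.
- STR calling QC (coverage/mapping flags) is passed through, not derived
  from reads; heteroplasmy is approximated by the alt read fraction.
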