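# triodx

Trio genome-sequencing variant triage and diagnostic-yield concordance for
neurodevelopmental disorders (NDD).

## The problem

For patients with unexplained neurodevelopmental disorders, the
standard-of-care (SOC) diagnostic work-up has historically been exome
sequencing plus ancillary assays (chromosomal microarray, repeat-PCR,
mitochondrial panels). Genome sequencing (GS) of the patient-parent trio can
in principle replace that entire battery with one test: it covers small
variants, copy-number variants (CNVs), short-tandem-repeat (STR) expansions,
runs of homozygosity and the mitochondrial genome in a single assay. The
question a diagnostic laboratory has to answer before switching is
*concordance*: does a GS-first pathway find everything the SOC pathway finds,
and what does it add?

`triodx` implements the interpretation pathway downstream of variant calling
needed to answer that question for patient-parent trios:

- **Small variants** — trio genotype QC, an "exome-from-genome"
  interpretation scope (exonic plus splice-region positions, non-coding
  exons included), segregation into de novo / homozygous / compound
  heterozygous / hemizygous modes, and tiered prioritization against a gene
  panel (`triodx.trio_snv`).
- **CNVs** — inheritance filtering with reciprocal-overlap matching against
  parental calls, a three-category triage (NDD-panel gene overlap; exonic
  disease-gene overlap; exonic overlap of any gene for events > 10 kb), and
  CNV+SNV compound-heterozygote detection in recessive genes
  (`triodx.cnv_triage`).
- **STR expansions** — premutation / full-mutation thresholds at six NDD
  loci (AFF2, ARX, CSTB, EIF4A3, DMPK, FMR1) (`triodx.str_triage`).
- **ROH and mtDNA** — PLINK-style sliding-window run-of-homozygosity
  detection (annotative support for identity by descent) and exact catalog
  matching of confirmed pathogenic mitochondrial mutations
  (`triodx.roh_mito`).
- **Outcomes and concordance** — collapse of each patient's candidates into
  *conclusive* / *possible* / *none*, 3×3 cross-pathway concordance, exact
  Fisher tests, and per-variant-type diagnosis tallies (`triodx.diagnosis`).
- **Synthetic cohorts** — a deterministic trio-cohort simulator with a truth
  table, emulating both pathway views from one cohort (the SOC view lacks
  sub-10 kb and non-coding-exon-only CNVs), used for end-to-end parameter
  recovery (`triodx.synthetic_cohort`).
- **Reference tables** — published conclusive-diagnosis tables from a
  150-trio comparison study, packaged as machine-readable fixtures so the
  cohort-level numbers can be recomputed from them (`triodx.reference_cohort`).

## Worked example

Simulate a small cohort, triage it under both pathway views, and compare:

```console
$ triodx simulate --out demo --n-trios 12 --seed 3 --background 60
wrote cohort of 12 trios to demo
$ triodx triage --cohort demo --pathway GS --out gs.tsv
GS: 4/12 conclusive; wrote gs.tsv
$ triodx triage --cohort demo --pathway SOC --out soc.tsv
SOC: 3/12 conclusive; wrote soc.tsv
$ triodx compare --a soc.tsv --b gs.tsv
rows: SOC, cols: GS
        conclusive      possible        none    total
conclusive      3       0       0       3
possible        0       0       0       0
none    1       3       5       9
total   4       3       5       12
discordant P001: none vs possible (cnv)
discordant P002: none vs possible (cnv)
discordant P003: none vs possible (cnv)
discordant P012: none vs conclusive (cnv)
$ triodx report --outcomes gs.tsv
snv     2
indel   1
cnv     1
str     0
mito    0
```

The four discordant patients all carry planted CNVs that the SOC view
cannot see: three small variants of unknown significance and one conclusive
two-exon deletion below the SOC detectability floor.

The same machinery is available as a library:

```python
from triodx import pipeline, diagnosis
gs = pipeline.run_cohort("demo", "GS")
soc = pipeline.run_cohort("demo", "SOC")
matrix, discordant = diagnosis.compare_pathways(soc, gs)
print(matrix.to_text())
```

## Repository layout

- `src/triodx/` — the library (modules listed above, plus `formats_io` for
  VCF/PED/BED/TSV/ISCN parsing and `cli.py`).
- `src/triodx/data/` — packaged fixtures: the reference diagnosis tables,
  STR locus catalog, GRCh37 pseudoautosomal regions, and a synthetic
  mitochondrial catalog stand-in.
- `analysis/` — numbered, thin analysis scripts (see below).
- `scripts/acceptance.py` — computes the headline quantities as JSON.
- `tests/` — unit, property (hypothesis) and acceptance tests.
- `docs/methods.md` — model, parameters and numerical choices.
- `results/` — small text outputs of the analysis scripts.
- `scratch/` — large generated data (simulated cohorts); disposable.

## Reproduction

Everything is deterministic given a seed. From a fresh checkout:

```sh
pip install --no-build-isolation -e .[test]
python -m pytest -q                       # full test suite
python analysis/01_reference_tables.py    # recompute published-table numbers
python analysis/02_simulate_cohort.py     # 150-trio cohort -> scratch/
python analysis/03_triage_concordance.py  # both pathways + concordance
python analysis/04_statistics.py          # exact tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Expected headline numbers (independent of the seed, because outcome counts
are apportioned deterministically): 43 SOC / 45 GS conclusively diagnosed
patients from the reference tables; tallies 26 SNV / 13 indel / 3 CNV /
1 STR (SOC) and 5 CNV (GS); all six printed CNV size labels reproduced; the
94-unit FMR1 allele; and, on the simulated 150-trio cohort, 100% recovery
of planted diagnoses with concordance off-diagonal cells
(SOC none, GS conclusive) = 2 and (SOC none, GS possible) = 4.
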