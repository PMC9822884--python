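"""End-to-end triage: from one trio's call files to a diagnostic outcome,
and from a cohort bundle to per-pathway outcome lists with recovery
statistics against the truth table.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from . import cnv_triage, diagnosis, roh_mito, str_triage, trio_snv
from .formats_io import read_gene_models, read_ped, read_str_calls, read_sv_calls, read_trio_vcf
from .records import CHILD, HET, HOM_ALT, GeneModel, Pedigree, StrGenotype, TrioGenotype
from .synthetic_cohort import GS_ONLY, TruthRecord

GS = "GS"
SOC = "SOC"


@dataclass
class PipelineOptions:
    qc: trio_snv.QcThresholds = field(default_factory=trio_snv.QcThresholds)
    scope: trio_snv.ScopeConfig = field(default_factory=trio_snv.ScopeConfig)
    gates: trio_snv.FrequencyGates = field(default_factory=trio_snv.FrequencyGates)
    roh: roh_mito.RohParams = field(default_factory=roh_mito.RohParams)
    # a premutation-range allele with confirmatory follow-up can be
    # reported as diagnostic (fragile X anticipation); switchable
    premutation_is_diagnostic: bool = True
    str_catalog: dict[str, str_triage.StrLocus] = field(
        default_factory=str_triage.load_str_catalog
    )
    mito_catalog: list[roh_mito.MitoCatalogEntry] = field(
        default_factory=roh_mito.load_mito_catalog
    )


_MODE_PRIORITY = (trio_snv.DE_NOVO, trio_snv.HOMOZYGOUS, trio_snv.HEMIZYGOUS)


def triage_trio(
    ped: Pedigree,
    small_vcf: str | Path,
    sv_vcf: str | Path,
    str_genotypes: list[StrGenotype],
    models: list[GeneModel],
    phenotype_match: set[tuple[str, str]],
    options: PipelineOptions | None = None,
    pathway: str = GS,
) -> tuple[diagnosis.PatientOutcome, list[diagnosis.SupportingVariant]]:
    """Run the full triage for one trio and classify the patient."""
    opt = options or PipelineOptions()
    pid = ped.child_id
    model_by_gene = {m.gene: m for m in models}

    def matches(gene: str) -> bool:
        return (pid, gene) in phenotype_match

    variants = list(read_trio_vcf(small_vcf, ped))
    mito_vars = [v for v in variants if v.chrom in roh_mito.MITO_CHROMS]
    nuclear = [v for v in variants if v.chrom not in roh_mito.MITO_CHROMS]

    scoped = [
        v for v in nuclear
        if trio_snv.genotype_qc(v, opt.qc).passed
        and trio_snv.in_scope(v, models, opt.scope)
    ]

    # ROH segments (annotative): per-chromosome child genotype sequences
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for v in sorted(nuclear, key=lambda v: (v.chrom, v.pos)):
        code = roh_mito.HET if v.genotypes[CHILD] == HET else roh_mito.HOM
        by_chrom.setdefault(v.chrom, []).append((v.pos, code))
    roh_segments = {
        c: roh_mito.detect_roh(c, sites, opt.roh) for c, sites in by_chrom.items()
    }

    # segregation + compound hets
    mode_calls: list[tuple[TrioGenotype, trio_snv.InheritanceCall]] = []
    for v in scoped:
        for call in trio_snv.segregate(v, ped).calls:
            mode_calls.append((v, call))
    by_gene: dict[str, list[TrioGenotype]] = {}
    for v in scoped:
        if v.gene:
            by_gene.setdefault(v.gene, []).append(v)
    for gene, vs in by_gene.items():
        for a, b in trio_snv.find_compound_hets(vs, ped):
            mode_calls.append(
                (a, trio_snv.InheritanceCall(trio_snv.COMPOUND_HET, partner=b.key))
            )
            mode_calls.append(
                (b, trio_snv.InheritanceCall(trio_snv.COMPOUND_HET, partner=a.key))
            )

    prioritized = trio_snv.prioritize_small_variants(mode_calls, models, opt.gates)

    candidates: list[diagnosis.SupportingVariant] = []
    for p in prioritized:
        v = p.variant
        model = model_by_gene.get(v.gene or "")
        detail = "roh_supported" if (
            p.call.mode == trio_snv.HOMOZYGOUS
            and roh_mito.in_roh(v.chrom, v.pos, roh_segments.get(v.chrom, []))
        ) else ""
        candidates.append(
            diagnosis.SupportingVariant(
                vtype="indel" if v.is_indel else "snv",
                gene=v.gene or "",
                gene_class=model.gene_class if model else "other",
                mode=p.call.mode,
                pathogenicity=v.pathogenicity,
                phenotype_match=matches(v.gene or ""),
                moi=model.moi if model else "unknown",
                has_partner=p.call.mode == trio_snv.COMPOUND_HET,
                tier=p.tier,
                pop_af=v.pop_af,
                detail=detail,
            )
        )

    # CNVs
    index = cnv_triage.GeneModelIndex(models)
    cnv_calls = cnv_triage.merge_caller_calls(list(read_sv_calls(sv_vcf, ped)))
    kept_cnvs: list[tuple[cnv_triage.CnvCall, cnv_triage.CnvSegregation]] = []
    for call in cnv_calls:
        seg = cnv_triage.segregate_cnv(call, ped)
        if not seg.modes & {trio_snv.DE_NOVO, trio_snv.HOMOZYGOUS, trio_snv.HEMIZYGOUS}:
            continue
        kept_cnvs.append((call, seg))
        cat = cnv_triage.categorize_cnv(call, index)
        if cat.category == cnv_triage.CATEGORY_NONE:
            continue
        gene = next((g for g in cat.genes if matches(g)), cat.genes[0])
        model = model_by_gene.get(gene)
        mode = next(m for m in _MODE_PRIORITY if m in seg.modes)
        candidates.append(
            diagnosis.SupportingVariant(
                vtype="cnv",
                gene=gene,
                gene_class=model.gene_class if model else "other",
                mode=mode,
                pathogenicity=call.pathogenicity,
                phenotype_match=matches(gene),
                moi=model.moi if model else "unknown",
                tier={"panel_gene": 1, "exonic_disease_gene": 2}.get(cat.category, 3),
                detail=cnv_triage.cnv_report_size(call),
            )
        )
    for call, v, gene in cnv_triage.find_cnv_snv_compound_het(
        kept_cnvs, scoped, models, ped
    ):
        model = model_by_gene[gene]
        candidates.append(
            diagnosis.SupportingVariant(
                vtype="indel" if v.is_indel else "snv",
                gene=gene,
                gene_class=model.gene_class,
                mode=trio_snv.COMPOUND_HET,
                pathogenicity=v.pathogenicity,
                phenotype_match=matches(gene),
                moi=model.moi,
                has_partner=True,
                tier={"ndd_panel": 1, "disease_gene": 2}.get(model.gene_class, 3),
                pop_af=v.pop_af,
                detail=f"in_trans_with_{call.svtype}",
            )
        )

    # STR expansions at the six NDD loci
    for g in str_genotypes:
        locus = opt.str_catalog.get(g.locus)
        cls = str_triage.classify_str(g, locus)
        if cls.status == str_triage.EXPANDED:
            label = "P"
        elif cls.status == str_triage.PREMUTATION and opt.premutation_is_diagnostic:
            label = "P"
        elif cls.status == str_triage.PREMUTATION:
            label = "VUS"
        else:
            continue
        candidates.append(
            diagnosis.SupportingVariant(
                vtype="str",
                gene=g.locus,
                gene_class="disease_gene",
                mode="expansion",
                pathogenicity=label,
                phenotype_match=matches(g.locus),
                tier=1,
                detail=f"{g.max_allele}_repeat_units",
            )
        )

    # mitochondrial catalog matches
    for m in roh_mito.match_mito(mito_vars, opt.mito_catalog):
        candidates.append(
            diagnosis.SupportingVariant(
                vtype="mito",
                gene="MT",
                gene_class="disease_gene",
                mode="maternal",
                pathogenicity="P",
                phenotype_match=matches("MT"),
                tier=1,
                detail=m.entry.phenotype,
            )
        )

    outcome = diagnosis.classify_patient(pid, candidates, pathway)
    return outcome, candidates


# --------------------------------------------------------------------------
# Cohort-level drivers
# --------------------------------------------------------------------------

def load_truth(root: str | Path) -> list[TruthRecord]:
    out = []
    with (Path(root) / "truth.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthRecord(
                    trio_id=row["trio_id"], vtype=row["vtype"], gene=row["gene"],
                    chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
                    mode=row["mode"], outcome=row["outcome"],
                    visibility=row["visibility"],
                )
            )
    return out


def load_phenotype_match(root: str | Path) -> set[tuple[str, str]]:
    out = set()
    with (Path(root) / "phenotype_match.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["match"] == "1":
                out.add((row["patient"], row["gene"]))
    return out


def run_cohort(
    root: str | Path,
    pathway: str = GS,
    options: PipelineOptions | None = None,
) -> list[diagnosis.PatientOutcome]:
    """Triage every trio of a cohort bundle under one pathway view."""
    root = Path(root)
    opt = options or PipelineOptions()
    pedigrees = read_ped(root / "pedigree.ped")
    models = read_gene_models(root / "gene_models.tsv")
    pheno = load_phenotype_match(root)
    strs_by_sample: dict[str, list[StrGenotype]] = {}
    for sample, g in read_str_calls(root / "strs.tsv"):
        strs_by_sample.setdefault(sample, []).append(g)

    sv_name = "sv_gs.vcf" if pathway == GS else "sv_soc.vcf"
    outcomes = []
    for ped in pedigrees:
        tdir = root / "trios" / ped.child_id
        outcome, _ = triage_trio(
            ped,
            tdir / "small_variants.vcf",
            tdir / sv_name,
            strs_by_sample.get(ped.child_id, []),
            models,
            pheno,
            opt,
            pathway,
        )
        outcomes.append(outcome)
    return outcomes


@dataclass
class RecoveryReport:
    n_expected: int
    n_recovered: int
    missed: list[str]

    @property
    def fraction(self) -> float:
        return 1.0 if self.n_expected == 0 else self.n_recovered / self.n_expected


def score_recovery(
    outcomes: list[diagnosis.PatientOutcome],
    truth: list[TruthRecord],
    pathway: str = GS,
) -> RecoveryReport:
    """Fraction of planted diagnoses recovered with the intended outcome
    class, gene, variant type — and inheritance mode for small variants.

    Plants invisible to the pathway (gs_only under SOC) are excluded from
    the denominator.
    """
    by_pid = {o.patient_id: o for o in outcomes}
    n_expected = 0
    n_recovered = 0
    missed = []
    for t in truth:
        if pathway == SOC and t.visibility == GS_ONLY:
            continue
        n_expected += 1
        o = by_pid.get(t.trio_id)
        ok = (
            o is not None
            and o.outcome == t.outcome
            and any(
                s.gene == t.gene
                and s.vtype == t.vtype
                and (t.vtype not in ("snv", "indel") or s.mode == t.mode)
                for s in o.supporting
            )
        )
        if ok:
            n_recovered += 1
        else:
            missed.append(f"{t.trio_id}:{t.vtype}:{t.gene}:{t.mode}")
    return RecoveryReport(n_expected, n_recovered, missed)
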