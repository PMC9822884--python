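"""Synthetic trio-cohort generator with a truth table.

Generates patient-parent trio call sets with the statistical structure the
triage pipeline assumes: Mendelian-consistent background variation in
exonic space, plus planted causal variants of every type (SNV, indel,
CNV, STR expansion, mitochondrial) and inheritance mode (de novo,
homozygous, compound heterozygous, hemizygous), together with a TSV truth
table describing every plant.

Two pathway views are emulated from one cohort: the GS view (all files)
and a standard-of-care (SOC) view whose CNV call set lacks events below a
10 kb detectability floor and events touching only non-coding exons —
the two ways small pathogenic CNVs historically escaped exome-based
work-ups. The default configuration reproduces the published cohort's
conditions: 150 trios at roughly 2:1 male:female, 45 conclusive outcomes
(26 SNV, 13 indel, 5 CNV of which 2 GS-only, 1 FMR1 repeat expansion),
35 possible outcomes of which 4 are GS-only CNVs, and 70 undiagnosed.

Outcome and type counts are apportioned deterministically (largest
remainder), so configured fractions are met exactly; all stochastic
detail (positions, alleles, depths, noise) flows from one seeded
generator, making output byte-identical for a fixed config.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .formats_io import write_gene_models, write_ped, write_str_table, write_vcf
from .records import (
    CHILD,
    FATHER,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MOTHER,
    GeneModel,
    GenomicInterval,
    Pedigree,
    StrGenotype,
)

DE_NOVO = "de_novo"
HOMOZYGOUS = "homozygous"
COMPOUND_HET = "compound_het"
HEMIZYGOUS = "hemizygous"

CONCLUSIVE = "conclusive"
POSSIBLE = "possible"
NONE = "none"

BOTH = "both"
GS_ONLY = "gs_only"

# simulated mini-genome: uniform 50 Mb nuclear contigs + mtDNA
SIM_CONTIGS: dict[str, int] = {str(c): 50_000_000 for c in range(1, 23)}
SIM_CONTIGS["X"] = 50_000_000
SIM_CONTIGS["MT"] = 16_569

_BASES = ("A", "C", "G", "T")


class ConfigError(ValueError):
    """Impossible or inconsistent cohort configuration."""


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort (defaults mirror the
    published 150-trio cohort)."""

    n_trios: int = 150
    background_variants_per_trio: int = 300
    male_fraction: float = 101 / 150
    outcome_fractions: dict[str, float] = field(
        default_factory=lambda: {CONCLUSIVE: 45 / 150, POSSIBLE: 35 / 150, NONE: 70 / 150}
    )
    conclusive_type_weights: dict[str, float] = field(
        default_factory=lambda: {"snv": 26 / 45, "indel": 13 / 45, "cnv": 5 / 45,
                                 "str": 1 / 45, "mito": 0.0}
    )
    small_variant_mode_weights: dict[str, float] = field(
        default_factory=lambda: {DE_NOVO: 36 / 40, HOMOZYGOUS: 1 / 40,
                                 COMPOUND_HET: 0.0, HEMIZYGOUS: 3 / 40}
    )
    n_gs_only_conclusive_cnvs: int = 2
    n_gs_only_possible_cnvs: int = 4
    soc_min_cnv_bp: int = 10_000
    # QC noise model
    depth_mean: float = 50.0
    depth_dispersion: float = 10.0   # negative-binomial size parameter
    het_af_concentration: float = 40.0  # Beta(c/2, c/2) for het allele fraction
    parental_dropout_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trios < 0:
            raise ConfigError("n_trios must be >= 0")
        for name, d in (
            ("outcome_fractions", self.outcome_fractions),
            ("conclusive_type_weights", self.conclusive_type_weights),
            ("small_variant_mode_weights", self.small_variant_mode_weights),
        ):
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigError("male_fraction must be in [0,1]")
        for r in (self.parental_dropout_rate, self.genotype_error_rate):
            if not 0 <= r <= 1:
                raise ConfigError("rates must be in [0,1]")


@dataclass(frozen=True)
class TruthRecord:
    """One planted causal variant and its intended interpretation."""

    trio_id: str
    vtype: str  # snv | indel | cnv | str | mito
    gene: str
    chrom: str
    start: int
    end: int
    mode: str
    outcome: str  # conclusive | possible
    visibility: str = BOTH  # both | gs_only (cnv only)

    def __post_init__(self) -> None:
        if self.visibility == GS_ONLY and self.vtype != "cnv":
            raise ValueError("gs_only visibility is reserved for CNV plants")


@dataclass
class CohortBundle:
    root: Path
    pedigrees: list[Pedigree]
    models: list[GeneModel]
    truth: list[TruthRecord]
    phenotype_match: set[tuple[str, str]]  # (patient id, gene)

    def trio_dir(self, child_id: str) -> Path:
        return self.root / "trios" / child_id

    def small_variant_vcf(self, child_id: str) -> Path:
        return self.trio_dir(child_id) / "small_variants.vcf"

    def sv_vcf(self, child_id: str, pathway: str) -> Path:
        name = "sv_gs.vcf" if pathway.upper() == "GS" else "sv_soc.vcf"
        return self.trio_dir(child_id) / name

    @property
    def str_table(self) -> Path:
        return self.root / "strs.tsv"


# --------------------------------------------------------------------------
# Deterministic gene models
# --------------------------------------------------------------------------

N_EXONS = 10
EXON_LEN = 150
EXON_SPACING = 5_000  # exon start-to-start distance


def build_gene_models() -> list[GeneModel]:
    """Fixed synthetic gene set: three genes per autosome plus three
    X-linked genes. Each gene has 10 exons of 150 bp spaced 5 kb apart;
    the last exon is non-coding (3'UTR)."""
    models: list[GeneModel] = []
    idx = 0
    chroms = [str(c) for c in range(1, 23)] + ["X"]
    for chrom in chroms:
        for slot in range(3):
            start = 5_000_000 + slot * 10_000_000
            exons = [
                GenomicInterval(chrom, start + i * EXON_SPACING,
                                start + i * EXON_SPACING + EXON_LEN - 1)
                for i in range(N_EXONS)
            ]
            if chrom == "X":
                gene_class = "ndd_panel" if slot == 0 else "disease_gene"
                moi = "XL"
            else:
                r = idx % 10
                if r < 4:
                    gene_class = "ndd_panel"
                elif r < 7:
                    gene_class = "disease_gene"
                elif r < 9:
                    gene_class = "candidate_gene"
                else:
                    gene_class = "other"
                if gene_class in ("ndd_panel", "disease_gene"):
                    moi = "AR" if idx % 5 == 0 else "AD"
                else:
                    moi = "AD" if gene_class == "candidate_gene" else "unknown"
            models.append(
                GeneModel(
                    gene=f"SYNG{idx + 1:03d}",
                    chrom=chrom,
                    exons=exons,
                    gene_class=gene_class,
                    moi=moi,
                    coding_exons=exons[:-1],
                )
            )
            idx += 1
    return models


def apportion(weights: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder apportionment of `total` over weighted keys;
    deterministic (ties broken by key order)."""
    raw = {k: w * total for k, w in weights.items()}
    counts = {k: int(v) for k, v in raw.items()}
    leftover = total - sum(counts.values())
    by_rem = sorted(weights, key=lambda k: -(raw[k] - counts[k]))
    for k in by_rem[:leftover]:
        counts[k] += 1
    return counts


# --------------------------------------------------------------------------
# Mendelian helpers
# --------------------------------------------------------------------------

_GAMETES = {HOM_REF: {0}, HET: {0, 1}, HOM_ALT: {1}}
_FROM_COUNT = {0: HOM_REF, 1: HET, 2: HOM_ALT}


def mendelian_consistent(child: str, father: str, mother: str) -> bool:
    """Autosomal biallelic transmission check (missing is never an error)."""
    if MISSING in (child, father, mother):
        return True
    possible = {
        _FROM_COUNT[a + b] for a in _GAMETES[father] for b in _GAMETES[mother]
    }
    return child in possible


# --------------------------------------------------------------------------
# Plant plan
# --------------------------------------------------------------------------

@dataclass
class _Plant:
    trio_index: int
    vtype: str
    mode: str
    outcome: str
    gene: str
    visibility: str = BOTH
    pathogenicity: str = "P"
    needs_male: bool = False
    cnv_spec: tuple[int, int, str, int] | None = None  # start_off, length, svtype, cn


def _build_plan(config: CohortConfig, models: list[GeneModel]) -> tuple[list[str], list[_Plant]]:
    """Decide each trio's sex and the full plant list; raises ConfigError
    before any file is written if the plan is impossible."""
    n = config.n_trios
    n_male = apportion({"male": config.male_fraction,
                        "female": 1 - config.male_fraction}, n)["male"]
    outcome_counts = apportion(config.outcome_fractions, n)
    n_conc, n_poss = outcome_counts[CONCLUSIVE], outcome_counts[POSSIBLE]
    type_counts = apportion(config.conclusive_type_weights, n_conc)
    n_small = type_counts["snv"] + type_counts["indel"]
    mode_counts = apportion(config.small_variant_mode_weights, n_small)

    ad_genes = [m for m in models
                if m.gene_class in ("ndd_panel", "disease_gene")
                and m.moi == "AD"]
    ar_genes = [m for m in models
                if m.gene_class in ("ndd_panel", "disease_gene") and m.moi == "AR"]
    xl_genes = [m for m in models if m.moi == "XL"]
    # monoallelic plants (single-allele CNVs, de novo VUS) must not land in
    # recessive genes, where triage rightly demands a second allele
    panel_genes = [m for m in models
                   if m.gene_class == "ndd_panel" and m.chrom != "X"
                   and m.moi == "AD"]
    disease_genes = [m for m in models
                     if m.gene_class == "disease_gene" and m.chrom != "X"
                     and m.moi == "AD"]

    plants: list[_Plant] = []

    # conclusive small variants: modes drawn hemizygous first (they
    # constrain trio sex), then homozygous / compound het, then de novo
    vtypes = ["snv"] * type_counts["snv"] + ["indel"] * type_counts["indel"]
    modes = (
        [HEMIZYGOUS] * mode_counts[HEMIZYGOUS]
        + [HOMOZYGOUS] * mode_counts[HOMOZYGOUS]
        + [COMPOUND_HET] * mode_counts[COMPOUND_HET]
        + [DE_NOVO] * mode_counts[DE_NOVO]
    )
    cyc = {"ad": 0, "ar": 0, "xl": 0}
    for vtype, mode in zip(vtypes, modes):
        if mode == HEMIZYGOUS:
            if not xl_genes:
                raise ConfigError("hemizygous plant requires an X-linked gene")
            gene = xl_genes[cyc["xl"] % len(xl_genes)]
            cyc["xl"] += 1
            needs_male = True
        elif mode in (HOMOZYGOUS, COMPOUND_HET):
            if not ar_genes:
                raise ConfigError("recessive plant requires an AR gene")
            gene = ar_genes[cyc["ar"] % len(ar_genes)]
            cyc["ar"] += 1
            needs_male = False
        else:
            gene = ad_genes[cyc["ad"] % len(ad_genes)]
            cyc["ad"] += 1
            needs_male = False
        plants.append(_Plant(-1, vtype, mode, CONCLUSIVE, gene.gene,
                             needs_male=needs_male))

    # conclusive CNVs
    n_cnv = type_counts["cnv"]
    n_gs_only = min(config.n_gs_only_conclusive_cnvs, n_cnv)
    if n_cnv and not panel_genes:
        raise ConfigError("CNV plants require autosomal panel genes")
    for i in range(n_cnv):
        if i == 0 and n_gs_only >= 1:
            # small two-exon deletion, below the SOC detectability floor
            gene = panel_genes[0]
            spec = (EXON_SPACING * 3 - 120, 5_335, "DEL", 1)
            plants.append(_Plant(-1, "cnv", DE_NOVO, CONCLUSIVE, gene.gene,
                                 visibility=GS_ONLY, cnv_spec=spec))
        elif i == 1 and n_gs_only >= 2:
            # deletion touching only the terminal non-coding exon
            if not disease_genes:
                raise ConfigError("non-coding-exon CNV plant requires a disease gene")
            gene = disease_genes[0]
            spec = (EXON_SPACING * (N_EXONS - 1) - 100, 36_232, "DEL", 1)
            plants.append(_Plant(-1, "cnv", DE_NOVO, CONCLUSIVE, gene.gene,
                                 visibility=GS_ONLY, cnv_spec=spec))
        else:
            gene = panel_genes[1 + (i % max(1, len(panel_genes) - 1))]
            svtype, cn = ("DUP", 3) if i % 3 == 2 else ("DEL", 1)
            spec = (-50_000, 200_000 + 50_000 * i, svtype, cn)
            plants.append(_Plant(-1, "cnv", DE_NOVO, CONCLUSIVE, gene.gene,
                                 cnv_spec=spec))

    # conclusive STR expansions (FMR1, male carriers)
    for _ in range(type_counts["str"]):
        plants.append(_Plant(-1, "str", HEMIZYGOUS, CONCLUSIVE, "FMR1",
                             needs_male=True))

    # conclusive mitochondrial matches
    for _ in range(type_counts["mito"]):
        plants.append(_Plant(-1, "mito", "maternal", CONCLUSIVE, "MT"))

    # possible diagnoses: GS-only small VUS CNVs first, then de novo VUS
    # small variants in disease genes
    n_poss_cnv = min(config.n_gs_only_possible_cnvs, n_poss)
    for i in range(n_poss_cnv):
        gene = disease_genes[(1 + i) % len(disease_genes)]
        spec = (EXON_SPACING * (2 + i % 3) - 120, 6_000 + 500 * i, "DEL", 1)
        plants.append(_Plant(-1, "cnv", DE_NOVO, POSSIBLE, gene.gene,
                             visibility=GS_ONLY, pathogenicity="VUS", cnv_spec=spec))
    for i in range(n_poss - n_poss_cnv):
        gene = disease_genes[i % len(disease_genes)]
        plants.append(_Plant(-1, "snv", DE_NOVO, POSSIBLE, gene.gene,
                             pathogenicity="VUS"))

    # trio sexes: males first, then assign plants to trios (one plant per
    # trio; male-requiring plants claim male trios)
    sexes = ["male"] * n_male + ["female"] * (n - n_male)
    male_pool = list(range(n_male))
    female_pool = list(range(n_male, n))
    for p in sorted(plants, key=lambda p: not p.needs_male):
        if p.needs_male:
            if not male_pool:
                raise ConfigError(
                    "plant requires a male child but no male trio remains"
                )
            p.trio_index = male_pool.pop(0)
        else:
            if female_pool:
                p.trio_index = female_pool.pop(0)
            elif male_pool:
                p.trio_index = male_pool.pop(0)
            else:
                raise ConfigError("more planted outcomes than trios")
    return sexes, plants


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _child_id(i: int) -> str:
    return f"P{i + 1:03d}"


def _gt_str(code: str, haploid: bool = False) -> str:
    if code == MISSING:
        return "." if haploid else "./."
    if haploid:
        return "1" if code in (HET, HOM_ALT) else "0"
    return {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}[code]


class _TrioSimulator:
    """Accumulates one trio's small-variant records and formats VCF rows."""

    def __init__(self, ped: Pedigree, config: CohortConfig, rng: np.random.Generator):
        self.ped = ped
        self.config = config
        self.rng = rng
        # (chrom, pos) -> row dict
        self.sites: dict[tuple[str, int], dict] = {}

    def _depth(self) -> int:
        c = self.config
        p = c.depth_dispersion / (c.depth_dispersion + c.depth_mean)
        return max(1, int(self.rng.negative_binomial(c.depth_dispersion, p)))

    def _af_for(self, code: str, haploid: bool) -> float:
        c = self.config.het_af_concentration
        if code == HET:
            return float(self.rng.beta(c / 2, c / 2))
        if code in (HOM_ALT,) or (haploid and code in (HET, HOM_ALT)):
            return float(min(1.0, 1.0 - self.rng.beta(1, 49) * 0.1))
        return 0.0

    def add_site(
        self,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        genotypes: dict[str, str],
        gene: str | None,
        csq: str,
        cls: str,
        pop_af: float,
        clean: bool = False,
        pop_hom: int | None = None,
    ) -> None:
        haploid_members = set()
        if chrom == "X":
            if self.ped.child_sex == "male":
                haploid_members.add(CHILD)
            haploid_members.add(FATHER)
        if chrom == "MT":
            haploid_members = set(MEMBER_ALL)
        fields = {}
        for m in MEMBER_ALL:
            code = genotypes[m]
            hap = m in haploid_members
            if clean:
                dp = 50
                af = 0.5 if (code == HET and not hap) else (
                    1.0 if code in (HET, HOM_ALT) and hap or code == HOM_ALT else 0.0
                )
            else:
                dp = self._depth()
                af = self._af_for(code, hap)
            if code == MISSING:
                fields[m] = ("./." if not hap else ".", ".", ".")
            else:
                alt_reads = int(round(dp * af))
                alt_reads = min(alt_reads, dp)
                fields[m] = (
                    _gt_str(code, hap),
                    str(dp),
                    f"{dp - alt_reads},{alt_reads}",
                )
        self.sites[(chrom, pos)] = {
            "ref": ref,
            "alt": alt,
            "gene": gene,
            "csq": csq,
            "cls": cls,
            "pop_af": pop_af,
            "pop_hom": pop_hom,
            "fields": fields,
        }

    def rows(self) -> list[str]:
        def chrom_key(c: str):
            return (0, int(c)) if c.isdigit() else (1, c)

        out = []
        for (chrom, pos) in sorted(self.sites, key=lambda k: (chrom_key(k[0]), k[1])):
            s = self.sites[(chrom, pos)]
            info = [
                f"GENE={s['gene']}" if s["gene"] else None,
                f"CSQ={s['csq']}",
                f"CLS={s['cls']}",
                f"POPAF={s['pop_af']:.6g}",
                f"IHAF={s['pop_af']:.6g}",
                f"POPHOM={s['pop_hom']}" if s["pop_hom"] is not None else None,
            ]
            info_s = ";".join(x for x in info if x)
            cols = [chrom, str(pos), ".", s["ref"], s["alt"], "100", "PASS",
                    info_s, "GT:DP:AD"]
            for m in MEMBER_ALL:
                gt, dp, ad = s["fields"][m]
                cols.append(f"{gt}:{dp}:{ad}" if dp != "." else gt)
            out.append("\t".join(cols))
        return out


MEMBER_ALL = (CHILD, FATHER, MOTHER)


def _draw_background_site(
    sim: _TrioSimulator, models: list[GeneModel], rng: np.random.Generator,
    config: CohortConfig,
) -> None:
    autosomal = [m for m in models if m.chrom != "X"]
    g = autosomal[rng.integers(len(autosomal))]
    exon = g.exons[rng.integers(len(g.exons))]
    pos = int(exon.start + rng.integers(exon.length))
    ref, alt = _BASES[rng.integers(4)], None
    alt = _BASES[(rng.integers(3) + _BASES.index(ref) + 1) % 4]
    af = float(rng.uniform(0.02, 0.5))

    def parent_code() -> str:
        return _FROM_COUNT[int(rng.binomial(1, af) + rng.binomial(1, af))]

    father, mother = parent_code(), parent_code()

    def gamete(code: str) -> int:
        if code == HOM_REF:
            return 0
        if code == HOM_ALT:
            return 1
        return int(rng.integers(2))

    child = _FROM_COUNT[gamete(father) + gamete(mother)]

    # injected genotype-error noise: overwrite with a clearly
    # non-Mendelian configuration at the configured rate
    if config.genotype_error_rate and rng.random() < config.genotype_error_rate:
        father, mother, child = HOM_REF, HOM_REF, HOM_ALT
    genotypes = {CHILD: child, FATHER: father, MOTHER: mother}
    for parent in (FATHER, MOTHER):
        if config.parental_dropout_rate and rng.random() < config.parental_dropout_rate:
            genotypes[parent] = MISSING
    sim.add_site(g.chrom, pos, ref, alt, genotypes, g.gene,
                 csq="synonymous_variant", cls="B", pop_af=af)


_NORMAL_STRS = {
    "FMR1": (20, 23), "AFF2": (15, 16), "ARX": (13, 13),
    "CSTB": (3, 3), "EIF4A3": (8, 8), "DMPK": (5, 12),
}
_X_STR_LOCI = {"FMR1", "AFF2", "ARX"}
_STR_MOTIFS = {
    "FMR1": "CGG", "AFF2": "GCC", "ARX": "GCN", "CSTB": "CCCCGCCCCGCG",
    "EIF4A3": "CCTCGCTGTGCCGCTGCCGA", "DMPK": "CTG",
}


def simulate_cohort(config: CohortConfig, out_dir: str | Path) -> CohortBundle:
    """Generate the full cohort bundle under ``out_dir``.

    Layout: pedigree.ped, gene_models.tsv, phenotype_match.tsv, truth.tsv,
    strs.tsv, config.yaml and per-trio VCFs under trios/<child>/
    (small_variants.vcf, sv_gs.vcf, sv_soc.vcf).
    """
    config.validate()
    models = build_gene_models()
    sexes, plants = _build_plan(config, models)  # raises before any write
    rng = np.random.default_rng(config.seed)

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)

    pedigrees = [
        Pedigree(
            child_id=_child_id(i),
            father_id=f"F{i + 1:03d}",
            mother_id=f"M{i + 1:03d}",
            child_sex=sexes[i],
            affected=(_child_id(i),),
        )
        for i in range(config.n_trios)
    ]
    plants_by_trio: dict[int, list[_Plant]] = {}
    for p in plants:
        plants_by_trio.setdefault(p.trio_index, []).append(p)

    truth: list[TruthRecord] = []
    pheno: set[tuple[str, str]] = set()
    str_rows: list[tuple[str, StrGenotype]] = []
    model_by_gene = {m.gene: m for m in models}

    for i, ped in enumerate(pedigrees):
        sim = _TrioSimulator(ped, config, rng)
        sv_gs_rows: list[str] = []
        sv_soc_rows: list[str] = []

        for _ in range(config.background_variants_per_trio):
            _draw_background_site(sim, models, rng, config)

        # default-normal STR genotypes at the six loci
        planted_str_genes = {
            p.gene for p in plants_by_trio.get(i, []) if p.vtype == "str"
        }
        for locus, (a1, a2) in _NORMAL_STRS.items():
            if locus in planted_str_genes:
                continue
            hemi = locus in _X_STR_LOCI and ped.child_sex == "male"
            alleles = (a1,) if hemi else (a1, a2)
            str_rows.append(
                (ped.child_id,
                 StrGenotype(locus=locus, motif=_STR_MOTIFS[locus], alleles=alleles))
            )

        for plant in plants_by_trio.get(i, []):
            truth_rec, sv_lines = _apply_plant(plant, ped, sim, model_by_gene, rng)
            truth.append(truth_rec)
            pheno.add((ped.child_id, plant.gene))
            if plant.vtype == "cnv":
                sv_gs_rows.extend(sv_lines)
                if plant.visibility == BOTH:
                    sv_soc_rows.extend(sv_lines)
            elif plant.vtype == "str":
                str_rows.append(
                    (ped.child_id,
                     StrGenotype(locus=plant.gene, motif=_STR_MOTIFS[plant.gene],
                                 alleles=(94,) if ped.child_sex == "male" else (23, 94)))
                )

        tdir = root / "trios" / ped.child_id
        tdir.mkdir(parents=True, exist_ok=True)
        write_vcf(tdir / "small_variants.vcf", ped, sim.rows(), SIM_CONTIGS)
        write_vcf(tdir / "sv_gs.vcf", ped, sv_gs_rows, SIM_CONTIGS, sv=True)
        write_vcf(tdir / "sv_soc.vcf", ped, sv_soc_rows, SIM_CONTIGS, sv=True)

    write_ped(root / "pedigree.ped", pedigrees)
    write_gene_models(root / "gene_models.tsv", models)
    write_str_table(root / "strs.tsv", sorted(str_rows, key=lambda r: (r[0], r[1].locus)))
    with (root / "truth.tsv").open("w") as fh:
        fh.write("trio_id\tvtype\tgene\tchrom\tstart\tend\tmode\toutcome\tvisibility\n")
        for t in sorted(truth, key=lambda t: (t.trio_id, t.chrom, t.start)):
            fh.write(
                f"{t.trio_id}\t{t.vtype}\t{t.gene}\t{t.chrom}\t{t.start}\t{t.end}"
                f"\t{t.mode}\t{t.outcome}\t{t.visibility}\n"
            )
    with (root / "phenotype_match.tsv").open("w") as fh:
        fh.write("patient\tgene\tmatch\n")
        for pid, gene in sorted(pheno):
            fh.write(f"{pid}\t{gene}\t1\n")
    (root / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))

    return CohortBundle(root=root, pedigrees=pedigrees, models=models,
                        truth=truth, phenotype_match=pheno)


def _apply_plant(
    plant: _Plant,
    ped: Pedigree,
    sim: _TrioSimulator,
    model_by_gene: dict[str, GeneModel],
    rng: np.random.Generator,
) -> tuple[TruthRecord, list[str]]:
    gene = model_by_gene.get(plant.gene)
    if gene is None and plant.vtype not in ("str", "mito"):
        raise ConfigError(f"plant targets unknown gene {plant.gene}")

    sv_lines: list[str] = []
    if plant.vtype in ("snv", "indel"):
        exon = gene.exons[2]
        pos = exon.start + 75
        if plant.vtype == "snv":
            ref, alt, csq = "C", "T", "stop_gained"
        else:
            ref, alt, csq = "CTG", "C", "frameshift_variant"
        if plant.mode == DE_NOVO:
            gts = {CHILD: HET, FATHER: HOM_REF, MOTHER: HOM_REF}
        elif plant.mode == HOMOZYGOUS:
            gts = {CHILD: HOM_ALT, FATHER: HET, MOTHER: HET}
        elif plant.mode == HEMIZYGOUS:
            gts = {CHILD: HOM_ALT, FATHER: HOM_REF, MOTHER: HET}
        else:  # compound het: paternal member here, maternal partner below
            gts = {CHILD: HET, FATHER: HET, MOTHER: HOM_REF}
        sim.add_site(gene.chrom, pos, ref, alt, gts, gene.gene, csq,
                     plant.pathogenicity, pop_af=0.0, clean=True, pop_hom=0)
        end = pos + len(ref) - 1
        if plant.mode == COMPOUND_HET:
            exon2 = gene.exons[4]
            pos2 = exon2.start + 40
            sim.add_site(gene.chrom, pos2, "G", "A",
                         {CHILD: HET, FATHER: HOM_REF, MOTHER: HET},
                         gene.gene, "stop_gained", plant.pathogenicity,
                         pop_af=0.0, clean=True, pop_hom=0)
            end = pos2
        return (
            TruthRecord(ped.child_id, plant.vtype, plant.gene, gene.chrom,
                        pos, end, plant.mode, plant.outcome),
            sv_lines,
        )

    if plant.vtype == "cnv":
        start_off, length, svtype, cn = plant.cnv_spec
        start = gene.exons[0].start + start_off
        end = start + length - 1
        info = f"SVTYPE={svtype};END={end};CN={cn};CALLER=depth_based;CLS={plant.pathogenicity}"
        cols = [gene.chrom, str(start), ".", "N", f"<{svtype}>", "60", "PASS",
                info, "GT", "0/1", "0/0", "0/0"]
        sv_lines.append("\t".join(cols))
        return (
            TruthRecord(ped.child_id, "cnv", plant.gene, gene.chrom, start, end,
                        plant.mode, plant.outcome, plant.visibility),
            sv_lines,
        )

    if plant.vtype == "str":
        # written by the caller into the cohort STR table
        return (
            TruthRecord(ped.child_id, "str", plant.gene, "X", 146_993_568,
                        146_993_628, plant.mode, plant.outcome),
            sv_lines,
        )

    # mitochondrial: a confirmed-pathogenic catalog hit, maternally shared
    sim.add_site("MT", 3243, "A", "G",
                 {CHILD: HOM_ALT, FATHER: HOM_REF, MOTHER: HOM_ALT},
                 None, "non_coding_transcript_variant", plant.pathogenicity,
                 pop_af=0.0, clean=True)
    return (
        TruthRecord(ped.child_id, "mito", plant.gene, "MT", 3243, 3243,
                    plant.mode, plant.outcome),
        sv_lines,
    )


def bundle_hash(root: str | Path) -> str:
    """SHA-256 over every file in a bundle (deterministic order); equal
    configs and seeds must produce equal hashes."""
    if isinstance(root, CohortBundle):
        root = root.root
    h = hashlib.sha256()
    root = Path(root)
    for f in sorted(root.rglob("*")):
        if f.is_file():
            h.update(str(f.relative_to(root)).encode())
            h.update(f.read_bytes())
    return h.hexdigest()
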