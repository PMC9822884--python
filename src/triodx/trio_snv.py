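"""Small-variant triage: genotype QC, interpretation scope, trio
segregation by mode of inheritance, compound-heterozygote pairing and
tiered prioritization.

The interpretation scope is the "exome from genome": exonic positions
(coding and non-coding exons, UTRs included) plus splice-site positions up
to a configurable number of base pairs (default 8) into the intron. Modes
of inheritance considered are de novo, homozygous, compound heterozygous
and hemizygous; inherited heterozygous variants are retained only as
dominant candidates when already classified (likely) pathogenic and the
corresponding switch is on.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from .records import (
    CHILD,
    FATHER,
    HEMI,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MOTHER,
    GeneModel,
    GenomicInterval,
    Pedigree,
    TrioGenotype,
)

# inheritance modes
DE_NOVO = "de_novo"
HOMOZYGOUS = "homozygous"
COMPOUND_HET = "compound_het"
HEMIZYGOUS = "hemizygous"
INHERITED_DOMINANT = "inherited_dominant_candidate"

# parental origins of a child-het allele
PATERNAL = "paternal"
MATERNAL = "maternal"
ORIGIN_DE_NOVO = "de_novo"
AMBIGUOUS = "ambiguous"
ORIGIN_UNKNOWN = "unknown"


@dataclass(frozen=True)
class InheritanceCall:
    mode: str
    supporting: tuple[str, ...] = ()
    partner: tuple[str, int, str, str] | None = None  # key of the in-trans variant

    def __post_init__(self) -> None:
        if self.mode == COMPOUND_HET and self.partner is None:
            raise ValueError("compound_het calls must reference a partner variant")


@dataclass
class SegregationResult:
    calls: tuple[InheritanceCall, ...]
    flags: tuple[str, ...] = ()

    @property
    def modes(self) -> set[str]:
        return {c.mode for c in self.calls}


@dataclass(frozen=True)
class QcThresholds:
    """Trio genotype quality gates (community-standard defaults)."""

    min_depth: int = 10
    het_af_min: float = 0.25
    het_af_max: float = 0.75
    hom_af_min: float = 0.90
    denovo_parent_max_af: float = 0.05
    denovo_parent_min_depth: int = 10


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScopeConfig:
    splice_window: int = 8
    include_noncoding: bool = True

    def __post_init__(self) -> None:
        if self.splice_window < 0:
            raise ValueError("splice window must be >= 0")


@dataclass(frozen=True)
class FrequencyGates:
    """Per-mode rarity gates on population / in-house allele frequency."""

    dominant_max_af: float = 0.001  # de novo, inherited dominant
    recessive_max_af: float = 0.01  # homozygous, compound het, hemizygous
    recessive_max_pop_hom: int = 0  # applied only when a count is supplied


# --------------------------------------------------------------------------
# Pseudoautosomal regions
# --------------------------------------------------------------------------

def load_par_regions(path: str | Path | None = None) -> list[GenomicInterval]:
    """Load pseudoautosomal regions (chrom, start, end TSV; packaged
    GRCh37 table by default). Positions inside a PAR are treated as
    autosomal."""
    if path is None:
        ref = importlib.resources.files("triodx.data") / "par_regions_grch37.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    out = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append(GenomicInterval(chrom, int(start), int(end)))
    return out


def is_x_nonpar(chrom: str, pos: int, par_regions: list[GenomicInterval]) -> bool:
    if chrom.removeprefix("chr") != "X":
        return False
    norm = chrom.removeprefix("chr")
    return not any(
        p.contains(norm, pos) or p.contains(chrom, pos) for p in par_regions
    )


def _effective_genotype(
    gt: str, member: str, v: TrioGenotype, ped: Pedigree, par: list[GenomicInterval]
) -> str:
    """Coerce diploid calls to hemizygous for males on X non-PAR."""
    if gt == MISSING or not is_x_nonpar(v.chrom, v.pos, par):
        return gt
    male = (member == FATHER) or (member == CHILD and ped.child_sex == "male")
    if male and gt in (HET, HOM_ALT, HEMI):
        return HEMI
    if male and gt == HOM_REF:
        return HOM_REF
    return gt


def _carries_alt(gt: str) -> bool:
    return gt in (HET, HOM_ALT, HEMI)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def genotype_qc(v: TrioGenotype, thresholds: QcThresholds | None = None) -> QcResult:
    """Deterministic pass/fail with machine-readable reason codes.

    De novo candidates (child carries, neither parent's genotype does)
    additionally require parental depth and near-zero parental alt
    fraction, guarding against parental allele dropout.
    """
    t = thresholds or QcThresholds()
    reasons: list[str] = []

    child_gt = v.genotypes[CHILD]
    child_dp = v.depths.get(CHILD)
    child_af = v.alt_fractions.get(CHILD)
    if child_dp is None or child_af is None:
        reasons.append("missing_data")
    else:
        if child_dp < t.min_depth:
            reasons.append("low_depth")
        if child_gt == HET and not (t.het_af_min <= child_af <= t.het_af_max):
            reasons.append("allele_fraction")
        if child_gt in (HOM_ALT, HEMI) and child_af < t.hom_af_min:
            reasons.append("allele_fraction")

    father_gt = v.genotypes.get(FATHER, MISSING)
    mother_gt = v.genotypes.get(MOTHER, MISSING)
    denovo_candidate = (
        _carries_alt(child_gt)
        and father_gt == HOM_REF
        and mother_gt == HOM_REF
    )
    if denovo_candidate:
        for parent in (FATHER, MOTHER):
            dp = v.depths.get(parent)
            af = v.alt_fractions.get(parent)
            if dp is None or af is None:
                if "missing_data" not in reasons:
                    reasons.append("missing_data")
                continue
            if dp < t.denovo_parent_min_depth:
                reasons.append("low_depth")
            if af >= t.denovo_parent_max_af:
                reasons.append("parental_support")

    # stable unique order
    uniq = tuple(dict.fromkeys(reasons))
    return QcResult(passed=not uniq, reasons=uniq)


def in_scope(
    v: TrioGenotype,
    models: list[GeneModel],
    scope: ScopeConfig | None = None,
) -> bool:
    """True iff the position overlaps an exon or lies within the splice
    window of an exon boundary. Widening the window is monotone: it can
    only add positions to scope."""
    scope = scope or ScopeConfig()
    w = scope.splice_window
    for m in models:
        if m.chrom != v.chrom:
            continue
        exons = m.exons
        if not scope.include_noncoding and m.coding_exons is not None:
            exons = m.coding_exons
        for e in exons:
            if e.start - w <= v.pos <= e.end + w:
                return True
    return False


def segregate(
    v: TrioGenotype,
    ped: Pedigree,
    par_regions: list[GenomicInterval] | None = None,
    report_inherited_dominant: bool = True,
) -> SegregationResult:
    """Assign inheritance modes (excluding compound het) purely from the
    trio genotypes, child sex and chromosome.

    Missing parental genotypes suppress modes that need that parent and
    flag the variant ``incomplete_segregation``. Genotype configurations
    impossible under Mendelian transmission yield no mode and the flag
    ``mendelian_inconsistent``.
    """
    par = par_regions if par_regions is not None else _DEFAULT_PAR
    child = _effective_genotype(v.genotypes[CHILD], CHILD, v, ped, par)
    father = _effective_genotype(v.genotypes.get(FATHER, MISSING), FATHER, v, ped, par)
    mother = _effective_genotype(v.genotypes.get(MOTHER, MISSING), MOTHER, v, ped, par)

    calls: list[InheritanceCall] = []
    flags: list[str] = []
    if father == MISSING or mother == MISSING:
        flags.append("incomplete_segregation")

    male_x = ped.child_sex == "male" and is_x_nonpar(v.chrom, v.pos, par)

    if child == MISSING or not _carries_alt(child):
        return SegregationResult(tuple(calls), tuple(flags))

    if male_x:
        # child is hemizygous for any carried alt; father's X is not
        # transmitted to a son, so only the mother informs de novo status
        calls.append(InheritanceCall(HEMIZYGOUS, supporting=(MOTHER,)))
        if mother == MISSING:
            pass  # de novo status unresolvable
        elif not _carries_alt(mother):
            calls.append(InheritanceCall(DE_NOVO, supporting=(MOTHER,)))
        return SegregationResult(tuple(calls), tuple(flags))

    f_carries = _carries_alt(father)
    m_carries = _carries_alt(mother)

    if child == HET:
        if father == MISSING or mother == MISSING:
            pass  # de novo unresolvable; inherited-het carries no mode anyway
        elif father == HOM_ALT and mother == HOM_ALT:
            flags.append("mendelian_inconsistent")
        elif not f_carries and not m_carries:
            calls.append(InheritanceCall(DE_NOVO, supporting=(FATHER, MOTHER)))
        elif report_inherited_dominant and v.pathogenicity in ("P", "LP"):
            src = tuple(
                p for p, c in ((FATHER, f_carries), (MOTHER, m_carries)) if c
            )
            calls.append(InheritanceCall(INHERITED_DOMINANT, supporting=src))
    elif child in (HOM_ALT, HEMI):
        if father == MISSING or mother == MISSING:
            pass
        elif f_carries and m_carries:
            calls.append(InheritanceCall(HOMOZYGOUS, supporting=(FATHER, MOTHER)))
        else:
            flags.append("mendelian_inconsistent")

    return SegregationResult(tuple(calls), tuple(flags))


_DEFAULT_PAR = load_par_regions()


def parental_origin(v: TrioGenotype, ped: Pedigree,
                    par_regions: list[GenomicInterval] | None = None) -> str:
    """Phase a child-het allele by parental genotypes."""
    par = par_regions if par_regions is not None else _DEFAULT_PAR
    father = _effective_genotype(v.genotypes.get(FATHER, MISSING), FATHER, v, ped, par)
    mother = _effective_genotype(v.genotypes.get(MOTHER, MISSING), MOTHER, v, ped, par)
    if father == MISSING or mother == MISSING:
        return ORIGIN_UNKNOWN
    f, m = _carries_alt(father), _carries_alt(mother)
    if f and m:
        return AMBIGUOUS
    if f:
        return PATERNAL
    if m:
        return MATERNAL
    return ORIGIN_DE_NOVO


def find_compound_hets(
    variants: list[TrioGenotype],
    ped: Pedigree,
    par_regions: list[GenomicInterval] | None = None,
) -> list[tuple[TrioGenotype, TrioGenotype]]:
    """Pair child-het variants of one gene that are in trans.

    A valid pair has one paternal- and one maternal-origin member, or one
    de novo member with one inherited-het member. Ambiguous phasing (both
    parents carry) or missing parents never form a pair, so no emitted
    pair can have both members from the same parent.
    """
    hets = [v for v in variants if v.genotypes[CHILD] == HET]
    origins = {v.key: parental_origin(v, ped, par_regions) for v in hets}
    pairs = []
    for i in range(len(hets)):
        for j in range(i + 1, len(hets)):
            a, b = hets[i], hets[j]
            oa, ob = origins[a.key], origins[b.key]
            ok = {oa, ob} == {PATERNAL, MATERNAL} or (
                ORIGIN_DE_NOVO in (oa, ob)
                and (oa in (PATERNAL, MATERNAL) or ob in (PATERNAL, MATERNAL))
            )
            if ok:
                pairs.append((a, b) if a.key <= b.key else (b, a))
    return sorted(pairs, key=lambda p: (p[0].key, p[1].key))


# --------------------------------------------------------------------------
# Prioritization
# --------------------------------------------------------------------------

_PATH_RANK = {"P": 0, "LP": 1, "VUS": 2, "U": 3, "LB": 4, "B": 5}
_TIER_BY_CLASS = {"ndd_panel": 1, "disease_gene": 2, "candidate_gene": 3}


@dataclass(frozen=True)
class PrioritizedVariant:
    variant: TrioGenotype
    call: InheritanceCall
    tier: int

    @property
    def sort_key(self):
        v = self.variant
        af = max(v.pop_af or 0.0, v.inhouse_af or 0.0)
        return (self.tier, _PATH_RANK.get(v.pathogenicity, 3), af,
                v.chrom, v.pos, v.alt)


def _max_af(v: TrioGenotype) -> float:
    return max(v.pop_af or 0.0, v.inhouse_af or 0.0)


def passes_frequency_gate(
    v: TrioGenotype, mode: str, gates: FrequencyGates | None = None
) -> bool:
    g = gates or FrequencyGates()
    af = _max_af(v)
    if mode in (DE_NOVO, INHERITED_DOMINANT):
        return af <= g.dominant_max_af
    if mode in (HOMOZYGOUS, COMPOUND_HET, HEMIZYGOUS):
        if af > g.recessive_max_af:
            return False
        if v.pop_hom_count is not None and v.pop_hom_count > g.recessive_max_pop_hom:
            return False
    return True


def prioritize_small_variants(
    calls: list[tuple[TrioGenotype, InheritanceCall]],
    models: list[GeneModel],
    gates: FrequencyGates | None = None,
) -> list[PrioritizedVariant]:
    """Tier candidates by gene class and order them for review.

    Tier 1: genes on the NDD panel; tier 2: other established disease
    genes; tier 3: candidate disease genes. Within a tier, ordering is by
    clinical classification, then rarity, with a positional tie-break for
    reproducibility. Variants in genes of class ``other`` and variants
    failing their mode's frequency gate are dropped.
    """
    class_by_gene = {m.gene: m.gene_class for m in models}
    out = []
    for v, call in calls:
        tier = _TIER_BY_CLASS.get(class_by_gene.get(v.gene or "", "other"))
        if tier is None:
            continue
        if not passes_frequency_gate(v, call.mode, gates):
            continue
        out.append(PrioritizedVariant(variant=v, call=call, tier=tier))
    return sorted(out, key=lambda p: p.sort_key)
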