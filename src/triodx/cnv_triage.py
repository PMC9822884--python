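"""CNV inheritance filtering and three-category triage.

Deletions and duplications are filtered for de novo, homozygous and
hemizygous events, then assessed in three priority-ordered categories:

1. any overlap with a gene on the NDD panel (exonic or not),
2. exon overlap with any established disease gene,
3. exon overlap with any gene for events larger than 10 kb (strict).

Heterozygous or de novo deletions over autosomal-recessive genes are
additionally checked for compound heterozygosity with small variants in
trans.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from intervaltree import IntervalTree

from .records import (
    ABSENT,
    CHILD,
    FATHER,
    HET,
    MOTHER,
    PRESENT,
    UNKNOWN,
    CnvCall,
    GeneModel,
    GenomicInterval,
    Pedigree,
    TrioGenotype,
)
from .trio_snv import (
    AMBIGUOUS,
    DE_NOVO,
    HEMIZYGOUS,
    HOMOZYGOUS,
    MATERNAL,
    ORIGIN_DE_NOVO,
    ORIGIN_UNKNOWN,
    PATERNAL,
    is_x_nonpar,
    load_par_regions,
    parental_origin,
)

INHERITED = "inherited"

CATEGORY_PANEL = "panel_gene"
CATEGORY_EXONIC_DISEASE = "exonic_disease_gene"
CATEGORY_EXONIC_LARGE = "exonic_large"
CATEGORY_NONE = "none"

_PAR = load_par_regions()


@dataclass
class CnvCategory:
    category: str
    genes: list[str] = field(default_factory=list)
    exon_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class CnvSegregation:
    modes: set[str]
    origin: str  # paternal / maternal / de_novo / unknown
    flags: tuple[str, ...] = ()


def _parent_carries(
    call: CnvCall,
    parent: str,
    parent_calls: list[CnvCall] | None,
    min_reciprocal_overlap: float,
) -> str:
    """Resolve a parent's carrier status, preferring joint-genotyped
    status on the call itself, else matching against the parent's own
    call list at the reciprocal-overlap threshold."""
    status = call.carriers.get(parent, UNKNOWN)
    if status != UNKNOWN:
        return status
    if parent_calls is None:
        return UNKNOWN
    for pc in parent_calls:
        if (
            pc.svtype == call.svtype
            and pc.interval.reciprocal_overlap(call.interval) >= min_reciprocal_overlap
        ):
            return PRESENT
    return ABSENT


def segregate_cnv(
    call: CnvCall,
    ped: Pedigree,
    father_calls: list[CnvCall] | None = None,
    mother_calls: list[CnvCall] | None = None,
    min_reciprocal_overlap: float = 0.5,
) -> CnvSegregation:
    """Assign inheritance modes to a child-carried CNV.

    De novo requires neither parent to carry an overlapping event of the
    same type (same-record genotypes or >= 50% reciprocal overlap against
    the parents' call lists). A copy-number-0 deletion with both parents
    carrying is homozygous; male X non-PAR events are hemizygous.
    """
    if call.carriers.get(CHILD, PRESENT) == ABSENT:
        return CnvSegregation(modes=set(), origin=ORIGIN_UNKNOWN)

    f = _parent_carries(call, FATHER, father_calls, min_reciprocal_overlap)
    m = _parent_carries(call, MOTHER, mother_calls, min_reciprocal_overlap)

    modes: set[str] = set()
    flags: list[str] = []
    origin = ORIGIN_UNKNOWN

    male_x = ped.child_sex == "male" and is_x_nonpar(
        call.interval.chrom, call.interval.start, _PAR
    )
    if male_x:
        modes.add(HEMIZYGOUS)

    if f == UNKNOWN or m == UNKNOWN:
        flags.append("unknown_parental_status")
    elif f == ABSENT and m == ABSENT:
        modes.add(DE_NOVO)
        origin = ORIGIN_DE_NOVO
    else:
        modes.add(INHERITED)
        if f == PRESENT and m == PRESENT:
            origin = AMBIGUOUS
        elif f == PRESENT:
            origin = PATERNAL
        else:
            origin = MATERNAL

    if (
        call.svtype == "DEL"
        and call.copy_number == 0
        and f == PRESENT
        and m == PRESENT
    ):
        modes.add(HOMOZYGOUS)

    return CnvSegregation(modes=modes, origin=origin, flags=tuple(flags))


# --------------------------------------------------------------------------
# Categorization
# --------------------------------------------------------------------------

class GeneModelIndex:
    """Interval-tree index over gene spans and exons for fast CNV overlap."""

    def __init__(self, models: list[GeneModel]):
        self.models = models
        self._span_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for model in models:
            span = model.span
            self._span_trees.setdefault(model.chrom, IntervalTree()).addi(
                span.start, span.end + 1, model
            )
            tree = self._exon_trees.setdefault(model.chrom, IntervalTree())
            for exon in model.exons:
                tree.addi(exon.start, exon.end + 1, model)

    def genes_overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self._span_trees.get(iv.chrom)
        if tree is None:
            return []
        hits = {h.data.gene: h.data for h in tree.overlap(iv.start, iv.end + 1)}
        return [hits[g] for g in sorted(hits)]

    def exon_overlap_counts(self, iv: GenomicInterval) -> dict[str, int]:
        tree = self._exon_trees.get(iv.chrom)
        if tree is None:
            return {}
        counts: dict[str, int] = {}
        for h in tree.overlap(iv.start, iv.end + 1):
            counts[h.data.gene] = counts.get(h.data.gene, 0) + 1
        return counts


def categorize_cnv(
    call: CnvCall,
    index: GeneModelIndex,
    large_threshold_bp: int = 10_000,
    panel_requires_exon: bool = False,
) -> CnvCategory:
    """Assign the highest-priority satisfied category.

    A single base pair of overlap counts; category 1 fires on any overlap
    with an NDD-panel gene (a config switch can require exon overlap),
    category 2 on exon overlap with a disease gene, category 3 on exon
    overlap with any gene when the event is strictly larger than 10 kb.
    """
    iv = call.interval
    genes = index.genes_overlapping(iv)
    exon_counts = index.exon_overlap_counts(iv)

    panel = [
        g for g in genes
        if g.gene_class == "ndd_panel"
        and (not panel_requires_exon or exon_counts.get(g.gene, 0) > 0)
    ]
    if panel:
        names = [g.gene for g in panel]
        return CnvCategory(CATEGORY_PANEL, names,
                           {n: exon_counts.get(n, 0) for n in names})

    disease_exonic = [
        g for g in genes
        if g.gene_class == "disease_gene" and exon_counts.get(g.gene, 0) > 0
    ]
    if disease_exonic:
        names = [g.gene for g in disease_exonic]
        return CnvCategory(CATEGORY_EXONIC_DISEASE, names,
                           {n: exon_counts[n] for n in names})

    if iv.length > large_threshold_bp and exon_counts:
        names = sorted(exon_counts)
        return CnvCategory(CATEGORY_EXONIC_LARGE, names, dict(exon_counts))

    return CnvCategory(CATEGORY_NONE)


# --------------------------------------------------------------------------
# CNV + SNV compound heterozygotes in recessive genes
# --------------------------------------------------------------------------

def find_cnv_snv_compound_het(
    cnvs: list[tuple[CnvCall, CnvSegregation]],
    small_variants: list[TrioGenotype],
    models: list[GeneModel],
    ped: Pedigree,
) -> list[tuple[CnvCall, TrioGenotype, str]]:
    """Pair single-allele deletions over autosomal-recessive genes with
    child-het small variants in trans.

    A pair is reported when the deletion is de novo, or the small variant
    is inherited from the parent not carrying the deletion. A variant
    physically inside a deletion on the same parental haplotype is never
    paired (it would sit on the deleted copy).
    """
    ar_genes = {m.gene: m for m in models if m.moi == "AR"}
    out = []
    for call, seg in cnvs:
        if call.svtype != "DEL":
            continue
        if call.copy_number is not None and call.copy_number == 0:
            continue  # biallelic loss already stands alone
        for gene_name, model in ar_genes.items():
            if not call.interval.overlaps(model.span):
                continue
            for v in small_variants:
                if v.gene != gene_name or v.genotypes[CHILD] != HET:
                    continue
                v_origin = parental_origin(v, ped)
                inside = call.interval.contains(v.chrom, v.pos)
                if seg.origin == ORIGIN_DE_NOVO:
                    if v_origin in (PATERNAL, MATERNAL):
                        out.append((call, v, gene_name))
                elif seg.origin in (PATERNAL, MATERNAL):
                    trans = {PATERNAL: MATERNAL, MATERNAL: PATERNAL}[seg.origin]
                    if v_origin == trans:
                        out.append((call, v, gene_name))
                    elif v_origin == seg.origin and inside:
                        continue  # same haplotype as the deletion
    return out


# --------------------------------------------------------------------------
# Reporting helpers
# --------------------------------------------------------------------------

def cnv_report_size(call_or_interval) -> str:
    """Human-readable event size: half-up to the nearest kb below 100 kb,
    to 0.1 Mb at or above (the convention of clinical CNV reports)."""
    iv = call_or_interval.interval if hasattr(call_or_interval, "interval") else call_or_interval
    length = iv.end - iv.start + 1
    if length < 100_000:
        kb = (Decimal(length) / Decimal(1000)).quantize(
            Decimal(1), rounding=ROUND_HALF_UP
        )
        return f"{kb} kb"
    mb = (Decimal(length) / Decimal(1_000_000)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return f"{mb} Mb"


def merge_caller_calls(
    calls: list[CnvCall], min_reciprocal_overlap: float = 0.8
) -> list[CnvCall]:
    """Collapse duplicate DEL/DUP calls from different callers at >= 80%
    reciprocal overlap, keeping the higher-quality record and pooling the
    caller evidence."""
    kept: list[CnvCall] = []
    for call in sorted(
        calls, key=lambda c: -(c.quality if c.quality is not None else 0.0)
    ):
        merged = False
        for i, existing in enumerate(kept):
            if (
                existing.svtype == call.svtype
                and existing.interval.reciprocal_overlap(call.interval)
                >= min_reciprocal_overlap
            ):
                kept[i] = CnvCall(
                    interval=existing.interval,
                    svtype=existing.svtype,
                    copy_number=existing.copy_number,
                    carriers=existing.carriers,
                    quality=existing.quality,
                    callers=existing.callers | call.callers,
                )
                merged = True
                break
        if not merged:
            kept.append(call)
    return sorted(kept, key=lambda c: (c.interval.chrom, c.interval.start))
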