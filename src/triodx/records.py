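"""Core domain records shared across the triage pipeline.

All genomic coordinates are 1-based inclusive (the VCF convention).
BED-style 0-based half-open input is converted at the reading boundary,
never stored.
"""
from __future__ import annotations

from dataclasses import dataclass, field

# genotype codes for one trio member at one site
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
HEMI = "hemi"  # single-copy alt (male X non-PAR)
MISSING = "missing"

GENOTYPES = (HOM_REF, HET, HOM_ALT, HEMI, MISSING)

CHILD = "child"
FATHER = "father"
MOTHER = "mother"
MEMBERS = (CHILD, FATHER, MOTHER)

# clinical classification labels; "U" = unclassified
PATHOGENICITY_LABELS = ("P", "LP", "VUS", "LB", "B", "U")

GENE_CLASSES = ("ndd_panel", "disease_gene", "candidate_gene", "other")
MOI_VALUES = ("AD", "AR", "XL", "unknown")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Overlap fraction relative to the *larger* requirement: the
        minimum of the two per-interval fractions."""
        ov = self.overlap_bp(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class IscnCnv:
    """A copy-number segment in cytogenetic band(start-end)xN notation."""

    band: str
    interval: GenomicInterval
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy number must be non-negative")

    @property
    def svtype(self) -> str:
        return "DEL" if self.copy_number < 2 else "DUP"


@dataclass(frozen=True)
class Pedigree:
    """One patient-parent trio."""

    child_id: str
    father_id: str
    mother_id: str
    child_sex: str  # "male" | "female"
    affected: tuple[str, ...] = ()  # sample ids flagged affected

    def __post_init__(self) -> None:
        ids = {self.child_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise ValueError("trio requires three distinct sample ids")
        if self.child_sex not in ("male", "female"):
            raise ValueError(f"child_sex must be male/female, got {self.child_sex!r}")

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.child_id, self.father_id, self.mother_id)


@dataclass
class GeneModel:
    """A gene with its (merged, sorted) exon intervals and diagnostic class.

    Exons include non-coding exons and UTRs; `span` is the min..max exon
    footprint used for whole-gene overlap tests.
    """

    gene: str
    chrom: str
    exons: list[GenomicInterval]
    gene_class: str = "other"
    moi: str = "unknown"
    # optional subset of `exons` that carry coding sequence; None means
    # the coding/non-coding split is unannotated and all exons are used
    coding_exons: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        if self.moi not in MOI_VALUES:
            raise ValueError(f"unknown moi {self.moi!r}")
        self.exons = merge_intervals(self.exons)
        if not self.exons:
            raise ValueError(f"gene {self.gene} has no exons")
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError("exon chromosome mismatch")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or bookended intervals."""
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + 1:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class TrioGenotype:
    """One child-carried ALT allele at one site, with trio genotypes and QC.

    Genotypes are stored as called (diploid codes); hemizygous coercion for
    male X non-PAR happens in the segregation layer, which knows the
    pedigree sex.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, str]  # member -> genotype code
    depths: dict[str, int | None] = field(default_factory=dict)
    alt_fractions: dict[str, float | None] = field(default_factory=dict)
    quality: float | None = None
    gene: str | None = None
    consequence: str | None = None
    pop_af: float | None = None
    inhouse_af: float | None = None
    pop_hom_count: int | None = None
    pathogenicity: str = "U"

    def __post_init__(self) -> None:
        if CHILD not in self.genotypes:
            raise ValueError("child genotype is required")
        for m, g in self.genotypes.items():
            if g not in GENOTYPES:
                raise ValueError(f"bad genotype {g!r} for {m}")
        for m, f in self.alt_fractions.items():
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError(f"alt fraction out of [0,1] for {m}: {f}")
        if self.pathogenicity not in PATHOGENICITY_LABELS:
            raise ValueError(f"bad pathogenicity label {self.pathogenicity!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"


@dataclass
class CnvCall:
    """A DEL/DUP segment with per-trio-member carrier status."""

    interval: GenomicInterval
    svtype: str  # "DEL" | "DUP"
    copy_number: int | None = None
    carriers: dict[str, str] = field(default_factory=dict)  # member -> status
    quality: float | None = None
    callers: frozenset[str] = frozenset()
    pathogenicity: str = "U"  # clinical classification label

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "DUP"):
            raise ValueError(f"svtype must be DEL or DUP, got {self.svtype!r}")
        if self.svtype == "DEL" and self.copy_number is not None and self.copy_number >= 2:
            raise ValueError("DEL implies copy number < 2 when known")
        for m, s in self.carriers.items():
            if s not in (PRESENT, ABSENT, UNKNOWN):
                raise ValueError(f"bad carrier status {s!r} for {m}")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class StrGenotype:
    """Repeat-unit genotype at one short-tandem-repeat locus for one sample.

    `alleles` holds one count for a hemizygous male X locus, two otherwise.
    """

    locus: str  # gene symbol of the locus
    motif: str | None
    alleles: tuple[int, ...]
    region: GenomicInterval | None = None
    coverage_flag: str = "ok"  # "ok" | "review"
    mapping_flag: str = "ok"

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("one or two alleles expected")
        if any(a < 0 for a in self.alleles):
            raise ValueError("allele repeat counts must be >= 0")

    @property
    def max_allele(self) -> int:
        return max(self.alleles)

    @property
    def flagged(self) -> bool:
        return self.coverage_flag != "ok" or self.mapping_flag != "ok"
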