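"""Diagnostic outcome classification and two-pathway concordance.

Each patient's prioritized candidates collapse into one of three outcome
classes, following clinical reporting practice:

* conclusive — a (likely) pathogenic variant in an established disease
  gene matching the phenotype (biallelic support required for recessive
  inheritance);
* possible — a variant of unknown significance in a disease gene matching
  the phenotype, or a (likely) pathogenic variant in a candidate gene;
* none — neither of the above.

Phenotype match is an input flag per (patient, gene): it encodes expert
clinical judgment and is supplied as data, never computed here.

Cohort-level machinery cross-tabulates two diagnostic pathways' outcomes
into a 3x3 concordance matrix, lists discordant patients, tallies
diagnoses by variant type, and provides an exact Fisher test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

CONCLUSIVE = "conclusive"
POSSIBLE = "possible"
NONE = "none"
OUTCOMES = (CONCLUSIVE, POSSIBLE, NONE)

VARIANT_TYPES = ("snv", "indel", "cnv", "str", "mito")

_PATH_RANK = {"P": 0, "LP": 1, "VUS": 2, "U": 3, "LB": 4, "B": 5}


@dataclass(frozen=True)
class SupportingVariant:
    """One candidate variant feeding a patient's outcome."""

    vtype: str  # snv | indel | cnv | str | mito
    gene: str
    gene_class: str  # ndd_panel | disease_gene | candidate_gene | other
    mode: str  # inheritance mode
    pathogenicity: str  # P | LP | VUS | LB | B | U
    phenotype_match: bool
    moi: str = "unknown"  # gene mode of inheritance annotation
    has_partner: bool = False  # in-trans partner present (biallelic support)
    tier: int | None = None
    pop_af: float | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.vtype not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.vtype!r}")


@dataclass(frozen=True)
class PatientOutcome:
    patient_id: str
    pathway: str
    outcome: str
    supporting: tuple[SupportingVariant, ...] = ()
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == NONE and self.supporting:
            raise ValueError("outcome none implies no supporting variants")
        if self.outcome != NONE and not self.supporting:
            raise ValueError(f"outcome {self.outcome} requires supporting variants")


def _biallelic_ok(c: SupportingVariant) -> bool:
    """Recessive genes need both alleles hit before a variant explains
    disease; dominant and X-linked hemizygous findings stand alone."""
    if c.moi != "AR":
        return True
    return c.mode in ("homozygous", "compound_het") or c.has_partner


def classify_patient(
    patient_id: str,
    candidates: list[SupportingVariant],
    pathway: str = "GS",
) -> PatientOutcome:
    """Collapse a patient's candidates into one outcome class.

    Conclusive dominates possible. Candidates without a classification
    label are treated as unclassified and can never trigger a conclusive
    outcome.
    """
    conclusive = [
        c for c in candidates
        if c.pathogenicity in ("P", "LP")
        and c.gene_class in ("ndd_panel", "disease_gene")
        and c.phenotype_match
        and _biallelic_ok(c)
    ]
    if conclusive:
        return PatientOutcome(patient_id, pathway, CONCLUSIVE,
                              tuple(conclusive), rationale="pathogenic_disease_gene")

    possible = [
        c for c in candidates
        if (
            c.pathogenicity == "VUS"
            and c.gene_class in ("ndd_panel", "disease_gene")
            and c.phenotype_match
        )
        or (c.pathogenicity in ("P", "LP") and c.gene_class == "candidate_gene")
    ]
    if possible:
        return PatientOutcome(patient_id, pathway, POSSIBLE,
                              tuple(possible), rationale="vus_or_candidate_gene")

    rationale = ""
    if any(
        c.pathogenicity in ("P", "LP")
        and c.gene_class in ("ndd_panel", "disease_gene")
        and c.phenotype_match
        and not _biallelic_ok(c)
        for c in candidates
    ):
        rationale = "monoallelic_recessive"
    return PatientOutcome(patient_id, pathway, NONE, (), rationale=rationale)


# --------------------------------------------------------------------------
# Concordance
# --------------------------------------------------------------------------

@dataclass
class ConcordanceMatrix:
    """3x3 cross-tabulation of outcomes from pathway A (rows) vs B (cols)."""

    pathway_a: str
    pathway_b: str
    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {(a, b): 0 for a in OUTCOMES for b in OUTCOMES}
    )

    @property
    def cohort_size(self) -> int:
        return sum(self.counts.values())

    def row_total(self, a: str) -> int:
        return sum(self.counts[(a, b)] for b in OUTCOMES)

    def col_total(self, b: str) -> int:
        return sum(self.counts[(a, b)] for a in OUTCOMES)

    @property
    def diagonal(self) -> int:
        return sum(self.counts[(o, o)] for o in OUTCOMES)

    def to_text(self) -> str:
        lines = [f"rows: {self.pathway_a}, cols: {self.pathway_b}"]
        header = "\t" + "\t".join(OUTCOMES) + "\ttotal"
        lines.append(header)
        for a in OUTCOMES:
            row = [a] + [str(self.counts[(a, b)]) for b in OUTCOMES]
            row.append(str(self.row_total(a)))
            lines.append("\t".join(row))
        lines.append(
            "total\t" + "\t".join(str(self.col_total(b)) for b in OUTCOMES)
            + f"\t{self.cohort_size}"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class Discordance:
    patient_id: str
    outcome_a: str
    outcome_b: str
    types_a: tuple[str, ...]
    types_b: tuple[str, ...]


def compare_pathways(
    outcomes_a: list[PatientOutcome], outcomes_b: list[PatientOutcome]
) -> tuple[ConcordanceMatrix, list[Discordance]]:
    """Cross-tabulate two pathways over the same patient set.

    Patient order is irrelevant; mismatched id sets raise with the
    symmetric difference listed.
    """
    by_a = {o.patient_id: o for o in outcomes_a}
    by_b = {o.patient_id: o for o in outcomes_b}
    if set(by_a) != set(by_b):
        diff = sorted(set(by_a) ^ set(by_b))
        raise ValueError(f"patient id sets differ: {diff}")

    pa = outcomes_a[0].pathway if outcomes_a else "A"
    pb = outcomes_b[0].pathway if outcomes_b else "B"
    matrix = ConcordanceMatrix(pathway_a=pa, pathway_b=pb)
    discordant = []
    for pid in sorted(by_a):
        a, b = by_a[pid], by_b[pid]
        matrix.counts[(a.outcome, b.outcome)] += 1
        if a.outcome != b.outcome:
            discordant.append(
                Discordance(
                    patient_id=pid,
                    outcome_a=a.outcome,
                    outcome_b=b.outcome,
                    types_a=tuple(s.vtype for s in a.supporting),
                    types_b=tuple(s.vtype for s in b.supporting),
                )
            )
    return matrix, discordant


# --------------------------------------------------------------------------
# Fisher's exact test (exact rational arithmetic)
# --------------------------------------------------------------------------

def fisher_exact(table: tuple[tuple[int, int], tuple[int, int]],
                 alternative: str = "two-sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    Two-sided uses the point-probability rule: sum over all tables with
    the observed margins whose probability does not exceed the observed
    table's. Computed with exact big-integer rationals, so enumeration is
    exact for any margins. An all-zero table returns 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), comb(n, c1))

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = prob(a)
    if alternative == "two-sided":
        total = sum((p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs),
                    Fraction(0))
    elif alternative == "greater":
        total = sum((prob(x) for x in range(a, hi + 1)), Fraction(0))
    elif alternative == "less":
        total = sum((prob(x) for x in range(lo, a + 1)), Fraction(0))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(total, Fraction(1)))


# --------------------------------------------------------------------------
# Variant-type tallies
# --------------------------------------------------------------------------

def primary_variant(supporting: tuple[SupportingVariant, ...]) -> SupportingVariant:
    """The variant counted for a patient with more than one finding:
    highest tier, then lowest population frequency, then input order."""
    return min(
        enumerate(supporting),
        key=lambda iv: (
            iv[1].tier if iv[1].tier is not None else 4,
            _PATH_RANK.get(iv[1].pathogenicity, 3),
            iv[1].pop_af if iv[1].pop_af is not None else 0.0,
            iv[0],
        ),
    )[1]


def tally_diagnoses(
    outcomes: list[PatientOutcome], outcome_class: str = CONCLUSIVE
) -> dict[str, int]:
    """Count diagnosed patients by the variant type of their primary
    finding; counts sum to the number of patients in the outcome class."""
    tally = {t: 0 for t in VARIANT_TYPES}
    for o in outcomes:
        if o.outcome != outcome_class:
            continue
        tally[primary_variant(o.supporting).vtype] += 1
    return tally
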