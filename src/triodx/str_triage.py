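"""Short-tandem-repeat expansion triage at the six NDD loci.

Repeat genotypes (repeat-unit counts per allele) are compared against
locus-specific premutation and full-mutation thresholds. Clinical
interpretation is restricted to AFF2, ARX, CSTB, EIF4A3, DMPK and FMR1;
genotypes at other loci pass through unevaluated. Any allele at or above
the premutation threshold raises a confirmation flag for orthogonal
follow-up (PCR / fragment analysis in practice).
"""
from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass
from pathlib import Path

from .formats_io import FormatError
from .records import GenomicInterval, StrGenotype

log = logging.getLogger(__name__)

NDD_STR_GENES = ("AFF2", "ARX", "CSTB", "EIF4A3", "DMPK", "FMR1")

NORMAL = "normal"
PREMUTATION = "intermediate_or_premutation"
EXPANDED = "expanded"
UNEVALUATED = "unevaluated"


@dataclass(frozen=True)
class StrLocus:
    gene: str
    region: GenomicInterval
    motif: str
    premutation_threshold: int | None
    pathogenic_threshold: int | None

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if (
            self.premutation_threshold is not None
            and self.pathogenic_threshold is not None
            and self.pathogenic_threshold <= self.premutation_threshold
        ):
            raise ValueError("pathogenic threshold must exceed premutation threshold")


@dataclass(frozen=True)
class StrClassification:
    status: str
    flagged: bool  # needs orthogonal confirmation / manual curation


def load_str_catalog(path: str | Path | None = None) -> dict[str, StrLocus]:
    """Load the locus catalog TSV (gene, chrom, start, end, motif,
    premutation_threshold, pathogenic_threshold; '.' = unset).

    A region whose length is not a whole number of motif units draws a
    warning only — published locus definitions are not always exact
    multiples.
    """
    if path is None:
        text = (importlib.resources.files("triodx.data") / "str_loci.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = text.splitlines()
    catalog: dict[str, StrLocus] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        gene, chrom, start, end, motif, pre, path_thr = line.split("\t")
        region = GenomicInterval(chrom, int(start), int(end))
        if region.length % len(motif) != 0:
            log.warning(
                "locus %s: region length %d is not a multiple of the %d bp motif",
                gene, region.length, len(motif),
            )
        catalog[gene] = StrLocus(
            gene=gene,
            region=region,
            motif=motif,
            premutation_threshold=None if pre in (".", "") else int(pre),
            pathogenic_threshold=None if path_thr in (".", "") else int(path_thr),
        )
    return catalog


def classify_str(g: StrGenotype, locus: StrLocus | None) -> StrClassification:
    """Classify by the larger allele; monotone in allele size.

    Unknown loci (no thresholds) are returned unevaluated and flagged.
    """
    if locus is None or locus.pathogenic_threshold is None:
        return StrClassification(UNEVALUATED, flagged=True)
    top = g.max_allele
    if top >= locus.pathogenic_threshold:
        return StrClassification(EXPANDED, flagged=True)
    if locus.premutation_threshold is not None and top >= locus.premutation_threshold:
        return StrClassification(PREMUTATION, flagged=True)
    return StrClassification(NORMAL, flagged=g.flagged)


_STR_NOTATION_RE = re.compile(
    r"^\s*(?P<chrom>[0-9XYM]+):(?P<start>\d+)_(?P<end>\d+)"
    r"(?P<motif>[ACGTN]+)\[(?P<n>\d+)\]\s*$"
)


def parse_str_notation(text: str) -> StrGenotype:
    """Parse ``chrom:start_end MOTIF[n]`` repeat notation into a
    single-allele StrGenotype fragment."""
    m = _STR_NOTATION_RE.match(text)
    if not m:
        raise FormatError(f"unparseable repeat notation: {text!r}")
    region = GenomicInterval(m.group("chrom"), int(m.group("start")), int(m.group("end")))
    return StrGenotype(
        locus="",
        motif=m.group("motif"),
        alleles=(int(m.group("n")),),
        region=region,
    )
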