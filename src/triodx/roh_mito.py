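"""Run-of-homozygosity detection and mitochondrial catalog matching.

ROH detection follows the PLINK sliding-window scheme: windows of a fixed
number of SNPs are scored homozygous when they contain at most a small
number of heterozygous (and missing) calls; a SNP supports an ROH when a
sufficient fraction of the windows covering it are homozygous; maximal
runs of supporting SNPs become segments, filtered by minimum SNP count
and minimum physical length. Defaults carry the three published overrides
(window het allowance 3, minimum 50 SNPs, minimum 300 kb) on top of PLINK
defaults for the rest.

ROH output is annotative only: a homozygous candidate inside a segment is
tagged as consistent with identity by descent, but an ROH by itself never
constitutes a diagnosis.

Mitochondrial variants are matched exactly (position, ref, alt) against a
catalog of confirmed pathogenic mutations; a small synthetic stand-in
catalog is packaged and user-replaceable.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

from .records import CHILD, GenomicInterval, TrioGenotype

HOM = "hom"
HET = "het"
MISS = "missing"

MITO_CHROMS = {"MT", "M", "chrM", "chrMT"}


@dataclass(frozen=True)
class RohParams:
    window_het: int = 3           # max het calls per homozygous window
    min_snps: int = 50            # minimum SNPs per reported segment
    min_kb: float = 300.0         # minimum segment length
    window_snps: int = 50         # SNPs per sliding window
    hit_proportion: float = 0.05  # min fraction of homozygous windows per SNP
    window_missing: int = 5       # max missing calls per homozygous window

    def __post_init__(self) -> None:
        if min(self.window_het, self.min_snps, self.window_snps) < 0:
            raise ValueError("counts must be non-negative")
        if self.min_kb <= 0 or not (0 < self.hit_proportion <= 1):
            raise ValueError("invalid ROH parameters")


@dataclass(frozen=True)
class RohSegment:
    interval: GenomicInterval
    snp_count: int
    het_count: int


def detect_roh(
    chrom: str,
    sites: list[tuple[int, str]],
    params: RohParams | None = None,
) -> list[RohSegment]:
    """Detect ROH segments on one chromosome.

    ``sites`` is a position-sorted list of (position, call) with call one
    of ``hom``/``het``/``missing`` for the child's biallelic genotypes.
    """
    p = params or RohParams()
    n = len(sites)
    positions = [s[0] for s in sites]
    if any(positions[i] > positions[i + 1] for i in range(n - 1)):
        raise ValueError("sites must be sorted by position")

    w = p.window_snps
    if n < w:
        return []

    # score each window of w consecutive SNPs
    n_windows = n - w + 1
    window_hom = [False] * n_windows
    hets = sum(1 for _, c in sites[:w] if c == HET)
    miss = sum(1 for _, c in sites[:w] if c == MISS)
    for i in range(n_windows):
        if i > 0:
            out_c, in_c = sites[i - 1][1], sites[i + w - 1][1]
            hets += (in_c == HET) - (out_c == HET)
            miss += (in_c == MISS) - (out_c == MISS)
        window_hom[i] = hets <= p.window_het and miss <= p.window_missing

    # per-SNP support: fraction of covering windows that are homozygous
    supporting = [False] * n
    for j in range(n):
        lo = max(0, j - w + 1)
        hi = min(j, n_windows - 1)
        if hi < lo:
            continue
        covering = hi - lo + 1
        hom_cov = sum(1 for i in range(lo, hi + 1) if window_hom[i])
        supporting[j] = hom_cov / covering >= p.hit_proportion

    # maximal runs of supporting SNPs -> candidate segments
    segments: list[RohSegment] = []
    j = 0
    while j < n:
        if not supporting[j]:
            j += 1
            continue
        k = j
        while k + 1 < n and supporting[k + 1]:
            k += 1
        seg_sites = sites[j:k + 1]
        length = seg_sites[-1][0] - seg_sites[0][0] + 1
        if len(seg_sites) >= p.min_snps and length >= p.min_kb * 1000:
            segments.append(
                RohSegment(
                    interval=GenomicInterval(chrom, seg_sites[0][0], seg_sites[-1][0]),
                    snp_count=len(seg_sites),
                    het_count=sum(1 for _, c in seg_sites if c == HET),
                )
            )
        j = k + 1
    return segments


def in_roh(chrom: str, pos: int, segments: list[RohSegment]) -> bool:
    return any(s.interval.contains(chrom, pos) for s in segments)


# --------------------------------------------------------------------------
# Mitochondrial DNA
# --------------------------------------------------------------------------

MT_LENGTH = 16569


@dataclass(frozen=True)
class MitoCatalogEntry:
    position: int
    ref: str
    alt: str
    phenotype: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise ValueError(f"mitochondrial position out of range: {self.position}")


def load_mito_catalog(path: str | Path | None = None) -> list[MitoCatalogEntry]:
    """Load a confirmed-pathogenic mtDNA catalog TSV (position, ref, alt,
    phenotype). The packaged default is a synthetic stand-in listing a
    handful of well-known confirmed mutations."""
    if path is None:
        text = (
            importlib.resources.files("triodx.data") / "synthetic_mito_catalog.tsv"
        ).read_text()
    else:
        text = Path(path).read_text()
    out = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        pos, ref, alt, phen = line.split("\t")
        out.append(MitoCatalogEntry(int(pos), ref, alt, phen))
    return out


@dataclass(frozen=True)
class MitoMatch:
    variant: TrioGenotype
    entry: MitoCatalogEntry
    heteroplasmy: float | None  # child alt fraction as a proxy


def match_mito(
    variants: list[TrioGenotype], catalog: list[MitoCatalogEntry]
) -> list[MitoMatch]:
    """Exact (position, ref, alt) matches of mitochondrial-contig variants
    against the catalog."""
    by_key = {(e.position, e.ref, e.alt): e for e in catalog}
    matches = []
    for v in variants:
        if v.chrom not in MITO_CHROMS:
            continue
        entry = by_key.get((v.pos, v.ref, v.alt))
        if entry is not None:
            matches.append(
                MitoMatch(variant=v, entry=entry,
                          heteroplasmy=v.alt_fractions.get(CHILD))
            )
    return matches
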