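"""Readers and writers for every external format the pipeline touches.

Small variants and SVs travel as VCF 4.2 (read through cyvcf2), pedigrees
as 6-column PED, gene models as a 1-based TSV (or BED, converted on read),
repeat genotypes as TSV. Copy-number segments printed in cytogenetic
``band(start-end)xN`` notation are parsed so published variant tables are
machine-usable.
"""
from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable, Iterator

from cyvcf2 import VCF

from .records import (
    ABSENT,
    CHILD,
    FATHER,
    HEMI,
    HET,
    HOM_ALT,
    HOM_REF,
    MEMBERS,
    MISSING,
    MOTHER,
    PRESENT,
    UNKNOWN,
    CnvCall,
    GeneModel,
    GenomicInterval,
    IscnCnv,
    Pedigree,
    StrGenotype,
    TrioGenotype,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input data."""


class ConfigurationError(ValueError):
    """Input inconsistent with the run configuration (e.g. missing sample)."""


# --------------------------------------------------------------------------
# ISCN-like CNV strings
# --------------------------------------------------------------------------

# both copy-number dialects occur in published tables: "...x1" and "...3x"
_ISCN_RE = re.compile(
    r"^\s*(?P<band>[0-9XY]+[pq][0-9.]+)"
    r"\((?P<coords>[^)]*)\)"
    r"(?:x(?P<cn_post>\d+)|(?P<cn_pre>\d+)x)\s*$"
)
_COORD_RE = re.compile(r"^(?P<start>\d+)-(?P<end>\d+)$")


def parse_iscn_cnv(text: str) -> IscnCnv:
    """Parse ``band(start-end)xN`` (or ``band(start-end)Nx``) into an IscnCnv.

    The chromosome is taken from the leading digits/X/Y of the band.
    """
    m = _ISCN_RE.match(text)
    if not m:
        raise FormatError(f"unparseable copy-number string: {text!r}")
    coords = _COORD_RE.match(m.group("coords"))
    if not coords:
        raise FormatError(
            f"bad coordinate token {m.group('coords')!r} in {text!r} "
            "(expected start-end)"
        )
    start, end = int(coords.group("start")), int(coords.group("end"))
    if start > end:
        raise FormatError(f"start > end in {text!r}")
    band = m.group("band")
    chrom = re.match(r"^([0-9]+|X|Y)", band).group(1)
    cn = int(m.group("cn_post") or m.group("cn_pre"))
    return IscnCnv(band=band, interval=GenomicInterval(chrom, start, end), copy_number=cn)


# --------------------------------------------------------------------------
# PED
# --------------------------------------------------------------------------

def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a 6-column PED file and return one Pedigree per complete trio.

    Columns: family, individual, father, mother, sex (1=male, 2=female),
    phenotype (2=affected).
    """
    rows: dict[str, tuple[str, str, str, str, str]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 PED columns")
        rows[f[1]] = (f[0], f[2], f[3], f[4], f[5])
        order.append(f[1])
    trios = []
    for ind in order:
        fam, father, mother, sex, pheno = rows[ind]
        if father in ("0", "") or mother in ("0", ""):
            continue
        if father not in rows or mother not in rows:
            raise FormatError(f"parents of {ind} not present in PED")
        affected = tuple(
            s for s in (ind, father, mother)
            if (rows[s][4] if s != ind else pheno) == "2"
        )
        trios.append(
            Pedigree(
                child_id=ind,
                father_id=father,
                mother_id=mother,
                child_sex="male" if sex == "1" else "female",
                affected=affected,
            )
        )
    return trios


def write_ped(path: str | Path, trios: Iterable[Pedigree]) -> None:
    lines = []
    for t in trios:
        sex = "1" if t.child_sex == "male" else "2"
        fam = t.child_id
        lines.append(f"{fam}\t{t.father_id}\t0\t0\t1\t1")
        lines.append(f"{fam}\t{t.mother_id}\t0\t0\t2\t1")
        child_aff = "2" if t.child_id in t.affected else "1"
        lines.append(f"{fam}\t{t.child_id}\t{t.father_id}\t{t.mother_id}\t{sex}\t{child_aff}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# --------------------------------------------------------------------------
# Gene models
# --------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from TSV (1-based inclusive) or BED (0-based
    half-open, converted on read).

    TSV columns: gene, chrom, exon_starts, exon_ends (comma lists),
    gene_class, moi.
    BED columns: chrom, start, end, gene[, gene_class[, moi]] — one exon
    per row, grouped by gene.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_gene_models_bed(path)
    models = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            starts = [int(x) for x in row["exon_starts"].split(",") if x]
            ends = [int(x) for x in row["exon_ends"].split(",") if x]
            if len(starts) != len(ends):
                raise FormatError(f"exon_starts/exon_ends length mismatch for {row['gene']}")
            exons = [GenomicInterval(row["chrom"], s, e) for s, e in zip(starts, ends)]
            models.append(
                GeneModel(
                    gene=row["gene"],
                    chrom=row["chrom"],
                    exons=exons,
                    gene_class=row.get("gene_class", "other"),
                    moi=row.get("moi", "unknown"),
                )
            )
    return models


def _read_gene_models_bed(path: Path) -> list[GeneModel]:
    by_gene: dict[str, dict] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns")
        chrom, start0, end0, gene = f[0], int(f[1]), int(f[2]), f[3]
        rec = by_gene.setdefault(
            gene,
            {
                "chrom": chrom,
                "exons": [],
                "gene_class": f[4] if len(f) > 4 else "other",
                "moi": f[5] if len(f) > 5 else "unknown",
            },
        )
        rec["exons"].append(GenomicInterval(chrom, start0 + 1, end0))
    return [
        GeneModel(gene=g, chrom=r["chrom"], exons=r["exons"],
                  gene_class=r["gene_class"], moi=r["moi"])
        for g, r in by_gene.items()
    ]


def write_gene_models(path: str | Path, models: Iterable[GeneModel]) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tchrom\texon_starts\texon_ends\tgene_class\tmoi\n")
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.gene,
                        m.chrom,
                        ",".join(str(e.start) for e in m.exons),
                        ",".join(str(e.end) for e in m.exons),
                        m.gene_class,
                        m.moi,
                    ]
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# Trio small-variant VCF
# --------------------------------------------------------------------------

def _genotype_code(alleles: list[int], alt_index: int) -> str:
    """Map a genotype's allele list to a code relative to one ALT."""
    called = [a for a in alleles if a >= 0]
    if not called:
        return MISSING
    n_alt = sum(1 for a in called if a == alt_index)
    if len(called) == 1:
        return HEMI if n_alt == 1 else HOM_REF
    if n_alt == 0:
        return HOM_REF
    if n_alt == len(called):
        return HOM_ALT
    return HET


def _per_alt_info(value, alt_idx: int, n_alt: int):
    """INFO fields annotated per-ALT arrive as scalars (biallelic) or
    comma tuples (multi-allelic)."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[alt_idx] if alt_idx < len(value) else None
    if isinstance(value, (bytes, str)):
        s = value.decode() if isinstance(value, bytes) else value
        parts = s.split(",")
        if n_alt > 1 and len(parts) == n_alt:
            return parts[alt_idx]
        return s
    return value


def read_trio_vcf(path: str | Path, pedigree: Pedigree) -> Iterator[TrioGenotype]:
    """Stream TrioGenotype records: one per child-carried ALT allele.

    Multi-allelic sites are decomposed, one record per ALT. Missing
    parental genotypes are retained and flagged as ``missing``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx = {}
    for member, sid in zip(MEMBERS, pedigree.sample_ids):
        if sid not in samples:
            raise ConfigurationError(f"sample {sid!r} ({member}) absent from VCF header")
        idx[member] = samples.index(sid)

    for v in vcf:
        gts = v.genotypes  # per-sample [allele, allele, ..., phased]
        try:
            depths = v.format("DP")
        except Exception:
            depths = None
        try:
            ads = v.format("AD")
        except Exception:
            ads = None
        for alt_i, alt in enumerate(v.ALT):
            alt_code = alt_i + 1
            member_gt = {
                m: _genotype_code(list(gts[idx[m]][:-1]), alt_code) for m in MEMBERS
            }
            if member_gt[CHILD] not in (HET, HOM_ALT, HEMI):
                continue
            member_dp: dict[str, int | None] = {}
            member_af: dict[str, float | None] = {}
            for m in MEMBERS:
                i = idx[m]
                dp = int(depths[i][0]) if depths is not None and depths[i][0] >= 0 else None
                af = None
                if ads is not None:
                    ad = ads[i]
                    total = sum(int(x) for x in ad if x >= 0)
                    if total > 0 and alt_code < len(ad) and ad[alt_code] >= 0:
                        af = float(ad[alt_code]) / total
                    if dp is None and total > 0:
                        dp = total
                member_dp[m] = dp
                member_af[m] = af

            def _f(key):
                raw = _per_alt_info(v.INFO.get(key), alt_i, len(v.ALT))
                if raw in (None, "", "."):
                    return None
                return float(raw)

            gene = _per_alt_info(v.INFO.get("GENE"), alt_i, len(v.ALT))
            csq = _per_alt_info(v.INFO.get("CSQ"), alt_i, len(v.ALT))
            cls = _per_alt_info(v.INFO.get("CLS"), alt_i, len(v.ALT)) or "U"
            hom = _f("POPHOM")
            yield TrioGenotype(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                genotypes=member_gt,
                depths=member_dp,
                alt_fractions=member_af,
                quality=v.QUAL,
                gene=gene,
                consequence=csq,
                pop_af=_f("POPAF"),
                inhouse_af=_f("IHAF"),
                pop_hom_count=int(hom) if hom is not None else None,
                pathogenicity=str(cls),
            )


# --------------------------------------------------------------------------
# SV / CNV VCF
# --------------------------------------------------------------------------

def read_sv_calls(
    path: str | Path, pedigree: Pedigree, skipped: list | None = None
) -> Iterator[CnvCall]:
    """Stream DEL/DUP calls from a VCF-style SV file.

    Records without a resolvable end coordinate and non-CNV types (BND,
    INV, ...) are skipped with a warning; pass ``skipped`` to collect them.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx = {}
    for member, sid in zip(MEMBERS, pedigree.sample_ids):
        idx[member] = samples.index(sid) if sid in samples else None

    for v in vcf:
        svtype = v.INFO.get("SVTYPE")
        if svtype not in ("DEL", "DUP"):
            log.warning("skipping non-CNV record %s:%s type=%s", v.CHROM, v.POS, svtype)
            if skipped is not None:
                skipped.append((v.CHROM, v.POS, svtype))
            continue
        end = v.INFO.get("END")
        if end is None:
            svlen = v.INFO.get("SVLEN")
            if svlen is None:
                log.warning("skipping %s:%s: no END or SVLEN", v.CHROM, v.POS)
                if skipped is not None:
                    skipped.append((v.CHROM, v.POS, svtype))
                continue
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            end = v.POS + abs(int(svlen)) - 1
        cn = v.INFO.get("CN")
        carriers = {}
        gts = v.genotypes
        for m in MEMBERS:
            i = idx[m]
            if i is None:
                carriers[m] = UNKNOWN
                continue
            alleles = [a for a in gts[i][:-1] if a >= 0]
            if not alleles:
                carriers[m] = UNKNOWN
            elif any(a > 0 for a in alleles):
                carriers[m] = PRESENT
            else:
                carriers[m] = ABSENT
        callers = frozenset((v.INFO.get("CALLER") or "").split(",")) - {""}
        yield CnvCall(
            interval=GenomicInterval(v.CHROM, v.POS, int(end)),
            svtype=svtype,
            copy_number=int(cn) if cn is not None else None,
            carriers=carriers,
            quality=v.QUAL,
            callers=callers,
            pathogenicity=str(v.INFO.get("CLS") or "U"),
        )


# --------------------------------------------------------------------------
# STR genotype tables
# --------------------------------------------------------------------------

def read_str_calls(path: str | Path) -> Iterator[tuple[str, StrGenotype]]:
    """Read a repeat-genotype TSV: sample, locus, motif, allele1[, allele2].

    Rows missing a motif are retained with a review flag; locus threshold
    lookup happens downstream against the locus catalog.
    """
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            alleles = [int(row["allele1"])]
            a2 = row.get("allele2", "")
            if a2 not in ("", ".", None):
                alleles.append(int(a2))
            motif = row.get("motif") or None
            yield row["sample"], StrGenotype(
                locus=row["locus"],
                motif=motif,
                alleles=tuple(alleles),
                coverage_flag="review" if motif is None else row.get("coverage_flag", "ok"),
                mapping_flag=row.get("mapping_flag", "ok"),
            )


def write_str_table(path: str | Path, rows: Iterable[tuple[str, StrGenotype]]) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tlocus\tmotif\tallele1\tallele2\tcoverage_flag\tmapping_flag\n")
        for sample, g in rows:
            a2 = str(g.alleles[1]) if len(g.alleles) == 2 else "."
            fh.write(
                f"{sample}\t{g.locus}\t{g.motif or ''}\t{g.alleles[0]}\t{a2}"
                f"\t{g.coverage_flag}\t{g.mapping_flag}\n"
            )


# --------------------------------------------------------------------------
# VCF writers (used by the synthetic cohort generator; round-trips through
# the cyvcf2 readers above)
# --------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol per ALT">
##INFO=<ID=CSQ,Number=A,Type=String,Description="Consequence per ALT">
##INFO=<ID=CLS,Number=A,Type=String,Description="Clinical classification per ALT (P/LP/VUS/LB/B/U)">
##INFO=<ID=POPAF,Number=A,Type=Float,Description="Population allele frequency per ALT">
##INFO=<ID=IHAF,Number=A,Type=Float,Description="In-house allele frequency per ALT">
##INFO=<ID=POPHOM,Number=A,Type=Integer,Description="Population homozygote count per ALT">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_SV_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=CN,Number=1,Type=Integer,Description="Child copy number">
##INFO=<ID=CALLER,Number=1,Type=String,Description="Calling evidence (comma list)">
##INFO=<ID=CLS,Number=1,Type=String,Description="Clinical classification (P/LP/VUS/LB/B/U)">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _contig_lines(contigs: dict[str, int]) -> str:
    return "".join(f"##contig=<ID={c},length={n}>\n" for c, n in contigs.items())


def write_vcf(
    path: str | Path,
    pedigree: Pedigree,
    rows: Iterable[str],
    contigs: dict[str, int],
    sv: bool = False,
) -> None:
    """Write a 3-sample VCF. ``rows`` are pre-formatted body lines
    (CHROM..sample columns, tab-separated, child/father/mother order)."""
    header = _SV_HEADER if sv else _VCF_HEADER
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(
        pedigree.sample_ids
    )
    with Path(path).open("w") as fh:
        fh.write(header)
        fh.write(_contig_lines(contigs))
        fh.write(cols + "\n")
        for r in rows:
            fh.write(r + "\n")
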