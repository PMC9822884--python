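"""formats_io: ISCN strings, PED, gene models, trio and SV VCF round-trips."""
from __future__ import annotations

import pytest

from triodx import formats_io as fio
from triodx.records import (
    CHILD,
    FATHER,
    MOTHER,
    GeneModel,
    GenomicInterval,
    Pedigree,
)

# --------------------------------------------------------------------------
# ISCN-like CNV strings (both printed copy-number dialects)
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,chrom,start,end,cn,svtype",
    [
        ("15q11.2(22833529-23093519)x1", "15", 22833529, 23093519, 1, "DEL"),
        ("2p16.3(50822408-50828236)x1", "2", 50822408, 50828236, 1, "DEL"),
        ("16p13.11(15058820-16294898)3x", "16", 15058820, 16294898, 3, "DUP"),
        ("Xp21.1(31854743-31888617)1x", "X", 31854743, 31888617, 1, "DEL"),
        ("7q11.23(72701098-74305338)x3", "7", 72701098, 74305338, 3, "DUP"),
    ],
)
def test_parse_iscn_both_dialects(text, chrom, start, end, cn, svtype):
    cnv = fio.parse_iscn_cnv(text)
    assert cnv.interval == GenomicInterval(chrom, start, end)
    assert cnv.copy_number == cn
    assert cnv.svtype == svtype


@pytest.mark.parametrize(
    "bad",
    [
        "15q11.2(22833529-23093519)",  # no copy number
        "15q11.2(22833529)x1",  # single coordinate
        "notaband(1-2)x1",
        "15q11.2(23093519-22833529)x1",  # start > end
        "",
    ],
)
def test_parse_iscn_rejects_malformed(bad):
    with pytest.raises(fio.FormatError):
        fio.parse_iscn_cnv(bad)


# --------------------------------------------------------------------------
# PED round-trip
# --------------------------------------------------------------------------

def test_ped_roundtrip(tmp_path):
    trios = [
        Pedigree("P001", "F001", "M001", "male", affected=("P001",)),
        Pedigree("P002", "F002", "M002", "female", affected=("P002",)),
    ]
    path = tmp_path / "t.ped"
    fio.write_ped(path, trios)
    back = fio.read_ped(path)
    assert [(t.child_id, t.father_id, t.mother_id, t.child_sex) for t in back] == [
        (t.child_id, t.father_id, t.mother_id, t.child_sex) for t in trios
    ]


def test_ped_missing_parent_row_raises(tmp_path):
    path = tmp_path / "t.ped"
    path.write_text("FAM\tP001\tF001\tM001\t1\t2\n")
    with pytest.raises(fio.FormatError):
        fio.read_ped(path)


def test_ped_too_few_columns_raises(tmp_path):
    path = tmp_path / "t.ped"
    path.write_text("FAM\tP001\tF001\n")
    with pytest.raises(fio.FormatError):
        fio.read_ped(path)


# --------------------------------------------------------------------------
# Gene models: TSV round-trip and BED coordinate conversion
# --------------------------------------------------------------------------

def test_gene_models_tsv_roundtrip(tmp_path, simple_models):
    path = tmp_path / "genes.tsv"
    fio.write_gene_models(path, simple_models)
    back = fio.read_gene_models(path)
    assert [(m.gene, m.chrom, m.exons, m.gene_class, m.moi) for m in back] == [
        (m.gene, m.chrom, m.exons, m.gene_class, m.moi) for m in simple_models
    ]


def test_gene_models_bed_converts_coordinates(tmp_path):
    # BED 0-based half-open [99, 200) == 1-based inclusive 100..200
    path = tmp_path / "genes.bed"
    path.write_text("1\t99\t200\tGENEA\tndd_panel\tAD\n1\t299\t400\tGENEA\n")
    (model,) = fio.read_gene_models(path)
    assert model.exons == [GenomicInterval("1", 100, 200), GenomicInterval("1", 300, 400)]
    assert model.gene_class == "ndd_panel" and model.moi == "AD"


# --------------------------------------------------------------------------
# Trio small-variant VCF
# --------------------------------------------------------------------------

def _write_small_vcf(path, ped, body_lines):
    fio.write_vcf(path, ped, body_lines, contigs={"1": 1_000_000, "X": 1_000_000})


def test_trio_vcf_roundtrip(tmp_path, trio_ped):
    path = tmp_path / "t.vcf"
    _write_small_vcf(
        path,
        trio_ped,
        [
            "1\t1000\t.\tA\tT\t100\tPASS\t"
            "GENE=GENEA;CSQ=missense_variant;CLS=P;POPAF=0.0001;IHAF=0.0002;POPHOM=0"
            "\tGT:DP:AD\t0/1:52:26,26\t0/0:48:48,0\t0/0:50:50,0",
        ],
    )
    (v,) = list(fio.read_trio_vcf(path, trio_ped))
    assert (v.chrom, v.pos, v.ref, v.alt) == ("1", 1000, "A", "T")
    assert v.genotypes == {CHILD: "het", FATHER: "hom_ref", MOTHER: "hom_ref"}
    assert v.depths[CHILD] == 52
    assert v.alt_fractions[CHILD] == pytest.approx(0.5)
    assert v.gene == "GENEA" and v.pathogenicity == "P"
    assert v.pop_af == pytest.approx(0.0001)
    assert v.inhouse_af == pytest.approx(0.0002)
    assert v.pop_hom_count == 0


def test_trio_vcf_multiallelic_decomposition(tmp_path, trio_ped):
    path = tmp_path / "t.vcf"
    _write_small_vcf(
        path,
        trio_ped,
        [
            "1\t1000\t.\tA\tT,G\t100\tPASS\t"
            "GENE=GENEA,GENEA;CSQ=mis,syn;CLS=P,B;POPAF=0.001,0.2"
            "\tGT:DP:AD\t1/2:60:0,30,30\t0/1:50:25,25,0\t0/2:50:25,0,25",
        ],
    )
    recs = list(fio.read_trio_vcf(path, trio_ped))
    assert [r.alt for r in recs] == ["T", "G"]
    # child 1/2 is het for each ALT separately
    assert all(r.genotypes[CHILD] == "het" for r in recs)
    assert recs[0].pathogenicity == "P" and recs[1].pathogenicity == "B"
    assert recs[0].genotypes[FATHER] == "het" and recs[0].genotypes[MOTHER] == "hom_ref"
    assert recs[1].genotypes[FATHER] == "hom_ref" and recs[1].genotypes[MOTHER] == "het"


def test_trio_vcf_skips_child_hom_ref_alts(tmp_path, trio_ped):
    path = tmp_path / "t.vcf"
    _write_small_vcf(
        path,
        trio_ped,
        ["1\t1000\t.\tA\tT\t100\tPASS\tCLS=P\tGT:DP:AD\t0/0:50:50,0\t0/1:50:25,25\t0/0:50:50,0"],
    )
    assert list(fio.read_trio_vcf(path, trio_ped)) == []


def test_trio_vcf_missing_sample_raises(tmp_path, trio_ped):
    path = tmp_path / "t.vcf"
    _write_small_vcf(path, trio_ped, [])
    other = Pedigree("childX", "father1", "mother1", "male")
    with pytest.raises(fio.ConfigurationError):
        list(fio.read_trio_vcf(path, other))


def test_trio_vcf_missing_parent_genotype(tmp_path, trio_ped):
    path = tmp_path / "t.vcf"
    _write_small_vcf(
        path,
        trio_ped,
        ["1\t1000\t.\tA\tT\t100\tPASS\tCLS=U\tGT:DP:AD\t0/1:50:25,25\t./.\t0/0:50:50,0"],
    )
    (v,) = list(fio.read_trio_vcf(path, trio_ped))
    assert v.genotypes[FATHER] == "missing"
    assert v.depths[FATHER] is None


def test_trio_vcf_haploid_male_x(tmp_path, male_ped):
    path = tmp_path / "t.vcf"
    _write_small_vcf(
        path,
        male_ped,
        ["X\t5000000\t.\tC\tT\t100\tPASS\tCLS=P\tGT:DP:AD\t1:50:0,50\t0:50:50,0\t0/1:50:25,25"],
    )
    (v,) = list(fio.read_trio_vcf(path, male_ped))
    assert v.genotypes[CHILD] == "hemi"
    assert v.genotypes[FATHER] == "hom_ref"
    assert v.genotypes[MOTHER] == "het"


# --------------------------------------------------------------------------
# SV VCF
# --------------------------------------------------------------------------

def _write_sv_vcf(path, ped, body_lines):
    fio.write_vcf(path, ped, body_lines, contigs={"1": 50_000_000}, sv=True)


def test_sv_reader_del_dup_and_skips(tmp_path, trio_ped):
    path = tmp_path / "sv.vcf"
    _write_sv_vcf(
        path,
        trio_ped,
        [
            "1\t10000\t.\tN\t<DEL>\t99\tPASS\tSVTYPE=DEL;END=30000;CN=1;CALLER=a,b;CLS=P"
            "\tGT\t0/1\t0/0\t0/0",
            "1\t40000\t.\tN\t<DUP>\t99\tPASS\tSVTYPE=DUP;SVLEN=5000;CN=3\tGT\t0/1\t0/1\t0/0",
            "1\t50000\t.\tN\t<INV>\t99\tPASS\tSVTYPE=INV;END=60000\tGT\t0/1\t0/0\t0/0",
            "1\t70000\t.\tN\t<DEL>\t99\tPASS\tSVTYPE=DEL\tGT\t0/1\t0/0\t0/0",
        ],
    )
    skipped = []
    calls = list(fio.read_sv_calls(path, trio_ped, skipped=skipped))
    assert len(calls) == 2
    dele, dup = calls
    assert dele.interval == GenomicInterval("1", 10000, 30000)
    assert dele.copy_number == 1 and dele.callers == {"a", "b"}
    assert dele.pathogenicity == "P"
    assert dele.carriers == {CHILD: "present", FATHER: "absent", MOTHER: "absent"}
    # END from SVLEN: pos + |SVLEN| - 1
    assert dup.interval == GenomicInterval("1", 40000, 44999)
    # INV and the END-less DEL are both skipped and collected
    assert len(skipped) == 2


# --------------------------------------------------------------------------
# STR tables
# --------------------------------------------------------------------------

def test_str_table_roundtrip(tmp_path):
    from triodx.records import StrGenotype

    rows = [
        ("P001", StrGenotype("FMR1", "CGG", (20, 94))),
        ("P002", StrGenotype("DMPK", "CTG", (5,))),
    ]
    path = tmp_path / "strs.tsv"
    fio.write_str_table(path, rows)
    back = list(fio.read_str_calls(path))
    assert [(s, g.locus, g.alleles) for s, g in back] == [
        ("P001", "FMR1", (20, 94)),
        ("P002", "DMPK", (5,)),
    ]


def test_str_table_missing_motif_flags_review(tmp_path):
    path = tmp_path / "strs.tsv"
    path.write_text("sample\tlocus\tmotif\tallele1\tallele2\nP001\tFMR1\t\t30\t.\n")
    ((_, g),) = list(fio.read_str_calls(path))
    assert g.motif is None and g.coverage_flag == "review"
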