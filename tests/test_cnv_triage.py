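"""cnv_triage: segregation, three-category triage vs a brute-force interval
oracle, CNV+SNV compound hets, size labels, caller merging."""
from __future__ import annotations

import numpy as np
import pytest

from triodx import cnv_triage
from triodx.records import (
    CHILD,
    FATHER,
    MOTHER,
    CnvCall,
    GeneModel,
    GenomicInterval,
    Pedigree,
)
from conftest import make_variant


def _call(start, end, svtype="DEL", cn=1, carriers=None, chrom="1", **kw):
    return CnvCall(
        interval=GenomicInterval(chrom, start, end),
        svtype=svtype,
        copy_number=cn,
        carriers=carriers or {CHILD: "present", FATHER: "absent", MOTHER: "absent"},
        **kw,
    )


# --------------------------------------------------------------------------
# Segregation
# --------------------------------------------------------------------------

def test_cnv_de_novo(trio_ped):
    seg = cnv_triage.segregate_cnv(_call(10_000, 30_000), trio_ped)
    assert seg.modes == {"de_novo"} and seg.origin == "de_novo"


def test_cnv_inherited_paternal(trio_ped):
    seg = cnv_triage.segregate_cnv(
        _call(10_000, 30_000, carriers={CHILD: "present", FATHER: "present", MOTHER: "absent"}),
        trio_ped,
    )
    assert seg.modes == {"inherited"} and seg.origin == "paternal"


def test_cnv_homozygous_deletion(trio_ped):
    seg = cnv_triage.segregate_cnv(
        _call(10_000, 30_000, cn=0,
              carriers={CHILD: "present", FATHER: "present", MOTHER: "present"}),
        trio_ped,
    )
    assert "homozygous" in seg.modes


def test_cnv_parent_matching_by_reciprocal_overlap(trio_ped):
    child = _call(10_000, 20_000, carriers={CHILD: "present"})
    # 50% reciprocal overlap boundary: parent event 15000..25000 overlaps
    # 5001/10001 ~ 0.50005 -> counts as carried
    father_hit = [_call(15_000, 25_000, carriers={FATHER: "present"})]
    seg = cnv_triage.segregate_cnv(child, trio_ped, father_calls=father_hit,
                                   mother_calls=[])
    assert seg.origin == "paternal"
    # below threshold -> de novo
    father_miss = [_call(16_000, 26_000, carriers={FATHER: "present"})]
    seg2 = cnv_triage.segregate_cnv(child, trio_ped, father_calls=father_miss,
                                    mother_calls=[])
    assert seg2.origin == "de_novo"


def test_cnv_parent_type_mismatch_not_carrier(trio_ped):
    child = _call(10_000, 20_000, carriers={CHILD: "present"})
    father = [_call(10_000, 20_000, svtype="DUP", cn=3, carriers={FATHER: "present"})]
    seg = cnv_triage.segregate_cnv(child, trio_ped, father_calls=father, mother_calls=[])
    assert seg.origin == "de_novo"


def test_cnv_unknown_parent_flags(trio_ped):
    seg = cnv_triage.segregate_cnv(
        _call(10_000, 30_000, carriers={CHILD: "present"}), trio_ped
    )
    assert "unknown_parental_status" in seg.flags and seg.modes == set()


def test_cnv_male_x_hemizygous(male_ped):
    seg = cnv_triage.segregate_cnv(_call(5_000_000, 5_050_000, chrom="X"), male_ped)
    assert seg.modes == {"hemizygous", "de_novo"}


# --------------------------------------------------------------------------
# Categorization vs brute-force oracle
# --------------------------------------------------------------------------

def _random_models(rng, n=12):
    models = []
    classes = ["ndd_panel", "disease_gene", "candidate_gene", "other"]
    for i in range(n):
        start = int(rng.integers(1, 900_000))
        exons = []
        pos = start
        for _ in range(int(rng.integers(1, 6))):
            length = int(rng.integers(50, 300))
            exons.append(GenomicInterval("1", pos, pos + length - 1))
            pos += length + int(rng.integers(100, 3000))
        models.append(
            GeneModel(gene=f"G{i}", chrom="1", exons=exons,
                      gene_class=classes[int(rng.integers(4))])
        )
    return models


def _oracle_category(call, models, large=10_000):
    """Naive restatement of the three-category priority rule."""
    iv = call.interval

    def span_overlap(m):
        return iv.overlaps(m.span)

    def exon_overlap(m):
        return any(iv.overlaps(e) for e in m.exons)

    if any(m.gene_class == "ndd_panel" and span_overlap(m) for m in models):
        return "panel_gene"
    if any(m.gene_class == "disease_gene" and exon_overlap(m) for m in models):
        return "exonic_disease_gene"
    if iv.length > large and any(exon_overlap(m) for m in models):
        return "exonic_large"
    return "none"


def test_categorize_matches_oracle_on_random_instances():
    rng = np.random.default_rng(11)
    for trial in range(300):
        models = _random_models(rng)
        index = cnv_triage.GeneModelIndex(models)
        for _ in range(5):
            start = int(rng.integers(1, 950_000))
            length = int(rng.integers(100, 60_000))
            call = _call(start, start + length - 1)
            got = cnv_triage.categorize_cnv(call, index).category
            assert got == _oracle_category(call, models), (trial, call.interval)


def test_large_threshold_is_strict():
    m = GeneModel(gene="G", chrom="1", exons=[GenomicInterval("1", 5_000, 5_100)],
                  gene_class="other")
    index = cnv_triage.GeneModelIndex([m])
    exactly = _call(5_000, 15_000 - 1)  # length 10,000: not > 10 kb
    above = _call(5_000, 15_000)  # length 10,001
    assert cnv_triage.categorize_cnv(exactly, index).category == "none"
    assert cnv_triage.categorize_cnv(above, index).category == "exonic_large"


def test_panel_gene_any_overlap_even_intronic():
    m = GeneModel(gene="G", chrom="1",
                  exons=[GenomicInterval("1", 1_000, 1_100),
                         GenomicInterval("1", 9_000, 9_100)],
                  gene_class="ndd_panel")
    index = cnv_triage.GeneModelIndex([m])
    intronic = _call(2_000, 3_000)
    assert cnv_triage.categorize_cnv(intronic, index).category == "panel_gene"
    # with the exon-required switch the same event drops out entirely
    assert cnv_triage.categorize_cnv(
        intronic, index, panel_requires_exon=True
    ).category == "none"


# --------------------------------------------------------------------------
# CNV + SNV compound het
# --------------------------------------------------------------------------

@pytest.fixture
def ar_model():
    return GeneModel(gene="GENEB", chrom="1",
                     exons=[GenomicInterval("1", 50_000, 50_500),
                            GenomicInterval("1", 60_000, 60_500)],
                     gene_class="disease_gene", moi="AR")


def test_cnv_snv_comphet_trans(trio_ped, ar_model):
    dele = _call(49_000, 51_000,
                 carriers={CHILD: "present", FATHER: "present", MOTHER: "absent"})
    seg = cnv_triage.segregate_cnv(dele, trio_ped)
    snv = make_variant(pos=60_100, mother="het", gene="GENEB", pathogenicity="P")
    out = cnv_triage.find_cnv_snv_compound_het(
        [(dele, seg)], [snv], [ar_model], trio_ped
    )
    assert [(c.interval.start, v.pos, g) for c, v, g in out] == [(49_000, 60_100, "GENEB")]


def test_cnv_snv_comphet_cis_rejected(trio_ped, ar_model):
    dele = _call(49_000, 51_000,
                 carriers={CHILD: "present", FATHER: "present", MOTHER: "absent"})
    seg = cnv_triage.segregate_cnv(dele, trio_ped)
    # same-parent origin: not in trans
    snv = make_variant(pos=60_100, father="het", gene="GENEB", pathogenicity="P")
    assert cnv_triage.find_cnv_snv_compound_het(
        [(dele, seg)], [snv], [ar_model], trio_ped
    ) == []


def test_cnv_snv_comphet_de_novo_del(trio_ped, ar_model):
    dele = _call(49_000, 51_000)
    seg = cnv_triage.segregate_cnv(dele, trio_ped)
    snv = make_variant(pos=60_100, mother="het", gene="GENEB", pathogenicity="P")
    assert len(cnv_triage.find_cnv_snv_compound_het(
        [(dele, seg)], [snv], [ar_model], trio_ped
    )) == 1


def test_cnv_snv_comphet_ignores_biallelic_del(trio_ped, ar_model):
    dele = _call(49_000, 51_000, cn=0,
                 carriers={CHILD: "present", FATHER: "present", MOTHER: "present"})
    seg = cnv_triage.segregate_cnv(dele, trio_ped)
    snv = make_variant(pos=60_100, mother="het", gene="GENEB", pathogenicity="P")
    assert cnv_triage.find_cnv_snv_compound_het(
        [(dele, seg)], [snv], [ar_model], trio_ped
    ) == []


# --------------------------------------------------------------------------
# Size labels
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "start,end,label",
    [
        (1, 5_335, "5 kb"),
        (1, 36_232, "36 kb"),
        (1, 32_450, "32 kb"),
        (1, 1_296_865, "1.3 Mb"),
        (1, 908_597, "0.9 Mb"),
        (1, 608_343, "0.6 Mb"),
        (1, 1_499, "1 kb"),  # 1,499 rounds half-up to 1 kb
        (1, 1_500, "2 kb"),  # half-up at .5
        (1, 99_999, "100 kb"),  # just below the unit cutover
        (1, 100_000, "0.1 Mb"),  # at the cutover

    ],
)
def test_cnv_report_size(start, end, label):
    assert cnv_triage.cnv_report_size(GenomicInterval("1", start, end)) == label


# --------------------------------------------------------------------------
# Caller merging
# --------------------------------------------------------------------------

def test_merge_caller_calls_pools_evidence():
    a = _call(10_000, 20_000, quality=50.0, callers=frozenset({"cA"}))
    b = _call(10_100, 20_100, quality=90.0, callers=frozenset({"cB"}))
    (merged,) = cnv_triage.merge_caller_calls([a, b])
    assert merged.callers == {"cA", "cB"}
    assert merged.interval.start == 10_100  # higher-quality record kept


def test_merge_respects_80_percent_threshold():
    a = _call(10_000, 20_000, quality=50.0)
    b = _call(17_000, 27_000, quality=90.0)  # ~30% reciprocal overlap
    assert len(cnv_triage.merge_caller_calls([a, b])) == 2


def test_merge_keeps_del_dup_separate():
    a = _call(10_000, 20_000)
    b = _call(10_000, 20_000, svtype="DUP", cn=3)
    assert len(cnv_triage.merge_caller_calls([a, b])) == 2
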