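"""trio_snv: QC, scope, segregation (27-state oracle), compound hets,
prioritization."""
from __future__ import annotations

import itertools

import pytest
from hypothesis import given, strategies as st

from triodx import trio_snv
from triodx.records import CHILD, FATHER, MOTHER, GeneModel, GenomicInterval, Pedigree
from conftest import make_variant

DIPLOID = ("hom_ref", "het", "hom_alt")


# --------------------------------------------------------------------------
# Genotype QC
# --------------------------------------------------------------------------

def test_qc_passes_clean_het():
    assert trio_snv.genotype_qc(make_variant()).passed


def test_qc_low_depth():
    r = trio_snv.genotype_qc(make_variant(dp=5))
    assert not r.passed and "low_depth" in r.reasons


def test_qc_het_allele_fraction_out_of_band():
    r = trio_snv.genotype_qc(make_variant(child_af=0.1))
    assert not r.passed and "allele_fraction" in r.reasons


def test_qc_hom_allele_fraction():
    r = trio_snv.genotype_qc(make_variant(child="hom_alt", child_af=0.7))
    assert not r.passed and "allele_fraction" in r.reasons


def test_qc_denovo_parental_support():
    v = make_variant()
    v.alt_fractions[FATHER] = 0.10  # alt reads in a hom_ref parent
    r = trio_snv.genotype_qc(v)
    assert not r.passed and "parental_support" in r.reasons


def test_qc_missing_child_data():
    v = make_variant()
    v.depths[CHILD] = None
    r = trio_snv.genotype_qc(v)
    assert not r.passed and "missing_data" in r.reasons


def test_qc_inherited_het_ignores_parental_alt_reads():
    # parental alt-fraction guard applies only to de novo candidates
    v = make_variant(father="het")
    v.alt_fractions[FATHER] = 0.5
    assert trio_snv.genotype_qc(v).passed


# --------------------------------------------------------------------------
# Interpretation scope: exon +/- splice window
# --------------------------------------------------------------------------

def test_scope_boundaries(simple_models):
    # exon GENEA: 900..1100; window 8 -> in scope within 892..1108
    for pos, expected in [(892, True), (891, False), (1108, True), (1109, False), (1000, True)]:
        assert trio_snv.in_scope(make_variant(pos=pos), simple_models) is expected


def test_scope_includes_noncoding_exons():
    m = GeneModel(
        gene="G",
        chrom="1",
        exons=[GenomicInterval("1", 100, 200), GenomicInterval("1", 1000, 1100)],
        coding_exons=[GenomicInterval("1", 100, 200)],
    )
    v = make_variant(pos=1050)
    assert trio_snv.in_scope(v, [m], trio_snv.ScopeConfig(include_noncoding=True))
    assert not trio_snv.in_scope(v, [m], trio_snv.ScopeConfig(include_noncoding=False))


@given(pos=st.integers(800, 1300), w1=st.integers(0, 20), w2=st.integers(0, 20))
def test_scope_monotone_in_window(simple_models, pos, w1, w2):
    """Widening the splice window never removes a position from scope."""
    lo, hi = sorted((w1, w2))
    v = make_variant(pos=pos)
    narrow = trio_snv.in_scope(v, simple_models, trio_snv.ScopeConfig(splice_window=lo))
    wide = trio_snv.in_scope(v, simple_models, trio_snv.ScopeConfig(splice_window=hi))
    assert wide or not narrow


def test_scope_negative_window_rejected():
    with pytest.raises(ValueError):
        trio_snv.ScopeConfig(splice_window=-1)


# --------------------------------------------------------------------------
# Autosomal segregation vs 27-state brute-force truth table
# --------------------------------------------------------------------------

def _oracle_modes(child, father, mother, pathogenic):
    """Independent statement of the autosomal segregation rules."""
    modes, flags = set(), set()
    if child == "het":
        if father == "hom_alt" and mother == "hom_alt":
            flags.add("mendelian_inconsistent")
        elif father == "hom_ref" and mother == "hom_ref":
            modes.add("de_novo")
        elif pathogenic:
            modes.add("inherited_dominant_candidate")
    elif child == "hom_alt":
        if father != "hom_ref" and mother != "hom_ref":
            modes.add("homozygous")
        else:
            flags.add("mendelian_inconsistent")
    return modes, flags


@pytest.mark.parametrize("pathogenicity", ["P", "U"])
def test_segregate_matches_27_state_oracle(trio_ped, pathogenicity):
    for child, father, mother in itertools.product(DIPLOID, repeat=3):
        v = make_variant(
            child=child, father=father, mother=mother, pathogenicity=pathogenicity
        )
        res = trio_snv.segregate(v, trio_ped)
        want_modes, want_flags = _oracle_modes(
            child, father, mother, pathogenicity in ("P", "LP")
        )
        assert res.modes == want_modes, (child, father, mother)
        assert set(res.flags) == want_flags, (child, father, mother)


def test_segregate_missing_parent_flags_incomplete(trio_ped):
    v = make_variant(father="missing")
    res = trio_snv.segregate(v, trio_ped)
    assert "incomplete_segregation" in res.flags
    assert res.modes == set()  # de novo unresolvable


def test_segregate_male_x_hemizygous(male_ped):
    v = make_variant(chrom="X", pos=5_000_000, child="het", mother="hom_ref")
    res = trio_snv.segregate(v, male_ped)
    assert res.modes == {"hemizygous", "de_novo"}
    v2 = make_variant(chrom="X", pos=5_000_000, child="het", mother="het")
    assert trio_snv.segregate(v2, male_ped).modes == {"hemizygous"}


def test_segregate_female_x_is_autosomal_like(trio_ped):
    v = make_variant(chrom="X", pos=5_000_000, child="het")
    assert trio_snv.segregate(v, trio_ped).modes == {"de_novo"}


def test_segregate_x_par_treated_autosomal(male_ped):
    # GRCh37 PAR1 starts at X:60001
    v = make_variant(chrom="X", pos=60_100, child="het")
    assert trio_snv.segregate(v, male_ped).modes == {"de_novo"}


# --------------------------------------------------------------------------
# Parental origin and compound heterozygotes vs enumeration oracle
# --------------------------------------------------------------------------

def _oracle_origin(father, mother):
    if father == "missing" or mother == "missing":
        return "unknown"
    f = father in ("het", "hom_alt")
    m = mother in ("het", "hom_alt")
    if f and m:
        return "ambiguous"
    if f:
        return "paternal"
    if m:
        return "maternal"
    return "de_novo"


def test_parental_origin_all_states(trio_ped):
    for father, mother in itertools.product(DIPLOID + ("missing",), repeat=2):
        v = make_variant(father=father, mother=mother)
        assert trio_snv.parental_origin(v, trio_ped) == _oracle_origin(father, mother)


@given(
    parent_states=st.lists(
        st.tuples(st.sampled_from(DIPLOID), st.sampled_from(DIPLOID)),
        min_size=0,
        max_size=6,
    )
)
def test_compound_het_matches_enumeration_oracle(parent_states):
    ped = Pedigree("child1", "father1", "mother1", "female")
    variants = [
        make_variant(pos=1000 + 10 * i, father=f, mother=m, gene="G")
        for i, (f, m) in enumerate(parent_states)
    ]
    got = {
        (a.key, b.key) for a, b in trio_snv.find_compound_hets(variants, ped)
    }
    want = set()
    for a, b in itertools.combinations(variants, 2):
        oa = _oracle_origin(a.genotypes[FATHER], a.genotypes[MOTHER])
        ob = _oracle_origin(b.genotypes[FATHER], b.genotypes[MOTHER])
        trans = {oa, ob} == {"paternal", "maternal"} or (
            "de_novo" in (oa, ob) and ({oa, ob} & {"paternal", "maternal"})
        )
        if trans:
            want.add(tuple(sorted((a.key, b.key))))
    assert got == want


def test_compound_het_never_same_parent(trio_ped):
    # two maternal hets cannot be in trans
    variants = [
        make_variant(pos=1000, mother="het", gene="G"),
        make_variant(pos=1010, mother="het", gene="G"),
    ]
    assert trio_snv.find_compound_hets(variants, trio_ped) == []


def test_compound_het_requires_child_het(trio_ped):
    variants = [
        make_variant(pos=1000, child="hom_alt", father="het", mother="het", gene="G"),
        make_variant(pos=1010, mother="het", gene="G"),
    ]
    assert trio_snv.find_compound_hets(variants, trio_ped) == []


# --------------------------------------------------------------------------
# Prioritization: tiers, frequency gates, ordering
# --------------------------------------------------------------------------

def _call(mode="de_novo"):
    return trio_snv.InheritanceCall(mode)


def test_prioritize_tiers_and_drops_other(simple_models):
    models = simple_models + [
        GeneModel(gene="GENEC", chrom="1", exons=[GenomicInterval("1", 1, 10)],
                  gene_class="candidate_gene", moi="AD"),
        GeneModel(gene="GENED", chrom="1", exons=[GenomicInterval("1", 20, 30)],
                  gene_class="other"),
    ]
    calls = [
        (make_variant(pos=1, gene="GENED", pathogenicity="P"), _call()),
        (make_variant(pos=2, gene="GENEC", pathogenicity="P"), _call()),
        (make_variant(pos=3, gene="GENEB", pathogenicity="P"), _call()),
        (make_variant(pos=4, gene="GENEA", pathogenicity="P"), _call()),
    ]
    out = trio_snv.prioritize_small_variants(calls, models)
    assert [(p.variant.gene, p.tier) for p in out] == [
        ("GENEA", 1), ("GENEB", 2), ("GENEC", 3)
    ]


def test_frequency_gates_per_mode():
    gates = trio_snv.FrequencyGates()
    common = make_variant(pop_af=0.005)
    assert not trio_snv.passes_frequency_gate(common, "de_novo", gates)
    assert trio_snv.passes_frequency_gate(common, "homozygous", gates)
    too_common = make_variant(pop_af=0.05)
    assert not trio_snv.passes_frequency_gate(too_common, "homozygous", gates)
    hom_seen = make_variant(pop_af=0.001, pop_hom_count=2)
    assert not trio_snv.passes_frequency_gate(hom_seen, "homozygous", gates)
    assert trio_snv.passes_frequency_gate(hom_seen, "de_novo", gates)


def test_prioritize_orders_by_pathogenicity_then_af(simple_models):
    calls = [
        (make_variant(pos=1, gene="GENEA", pathogenicity="VUS", pop_af=0.0), _call()),
        (make_variant(pos=2, gene="GENEA", pathogenicity="P", pop_af=0.0005), _call()),
        (make_variant(pos=3, gene="GENEA", pathogenicity="P", pop_af=0.0001), _call()),
    ]
    out = trio_snv.prioritize_small_variants(calls, simple_models)
    assert [p.variant.pos for p in out] == [3, 2, 1]


def test_compound_het_call_requires_partner():
    with pytest.raises(ValueError):
        trio_snv.InheritanceCall("compound_het")
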