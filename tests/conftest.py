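"""Shared fixtures and hypothesis configuration for the test suite."""
from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from triodx.records import (
    CHILD,
    FATHER,
    MOTHER,
    GeneModel,
    GenomicInterval,
    Pedigree,
    TrioGenotype,
)

# deterministic property tests: derandomized, generous deadline
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def trio_ped() -> Pedigree:
    return Pedigree("child1", "father1", "mother1", "female")


@pytest.fixture
def male_ped() -> Pedigree:
    return Pedigree("child1", "father1", "mother1", "male")


def make_variant(
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    child="het",
    father="hom_ref",
    mother="hom_ref",
    gene=None,
    pathogenicity="U",
    pop_af=None,
    dp=50,
    child_af=None,
    **kw,
) -> TrioGenotype:
    """Compact TrioGenotype factory with clean QC defaults."""
    if child_af is None:
        child_af = 0.5 if child == "het" else (1.0 if child in ("hom_alt", "hemi") else 0.0)
    afs = {
        CHILD: child_af,
        FATHER: 0.5 if father == "het" else (1.0 if father == "hom_alt" else 0.0),
        MOTHER: 0.5 if mother == "het" else (1.0 if mother == "hom_alt" else 0.0),
    }
    return TrioGenotype(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes={CHILD: child, FATHER: father, MOTHER: mother},
        depths={CHILD: dp, FATHER: dp, MOTHER: dp},
        alt_fractions=afs,
        gene=gene,
        pathogenicity=pathogenicity,
        pop_af=pop_af,
        **kw,
    )


@pytest.fixture
def simple_models() -> list[GeneModel]:
    """Two-gene toy model set on chromosome 1."""
    return [
        GeneModel(
            gene="GENEA",
            chrom="1",
            exons=[GenomicInterval("1", 900, 1100), GenomicInterval("1", 2000, 2200)],
            gene_class="ndd_panel",
            moi="AD",
        ),
        GeneModel(
            gene="GENEB",
            chrom="1",
            exons=[GenomicInterval("1", 50_000, 50_500)],
            gene_class="disease_gene",
            moi="AR",
        ),
    ]


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory) -> Path:
    """A 12-trio noise-free cohort bundle shared across pipeline tests."""
    from triodx.synthetic_cohort import CohortConfig, simulate_cohort

    root = tmp_path_factory.mktemp("cohort12")
    simulate_cohort(CohortConfig(n_trios=12, seed=3, background_variants_per_trio=60), root)
    return root
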