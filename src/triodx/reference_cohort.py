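"""Published-cohort diagnosis tables as machine-usable fixtures.

A prospective study of 150 NDD patient-parent trios ran two diagnostic
pathways in parallel — an exome-based standard-of-care (SOC) work-up and
genome sequencing (GS) — and published its conclusive diagnoses as two
variant tables (small variants; CNV/STR). This module loads those tables
and recomputes cohort-level quantities from them: distinct diagnosed
patients per pathway, variant-type tallies, CNV size labels and the
fragile-X repeat allele.

Rows with concordance ``yes`` were found by both pathways; ``GS+`` marks
diagnoses made by genome sequencing only.
"""
from __future__ import annotations

import importlib.resources
import io
import re

import pandas as pd

from .cnv_triage import cnv_report_size
from .formats_io import parse_iscn_cnv
from .str_triage import parse_str_notation
from .diagnosis import (
    CONCLUSIVE,
    PatientOutcome,
    SupportingVariant,
    tally_diagnoses,
)

SOC = "SOC"
GS = "GS"

_ISCN_HINT = re.compile(r"\(\d+-\d+\)")
_REPEAT_HINT = re.compile(r"\[\d+\]")


def _read_packaged(name: str) -> pd.DataFrame:
    text = (importlib.resources.files("triodx.data") / name).read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", dtype={"patient": str})


def load_small_variant_table() -> pd.DataFrame:
    """Conclusive SNV/indel diagnoses (one row per reported variant)."""
    df = _read_packaged("conclusive_small_variant_diagnoses.tsv")
    df["variant_type"] = df["genomic_mutation"].map(classify_mutation_string)
    return df


def load_cnv_str_table() -> pd.DataFrame:
    """Conclusive CNV and repeat-expansion diagnoses."""
    df = _read_packaged("conclusive_cnv_str_diagnoses.tsv")
    df["variant_type"] = df["genomic_mutation"].map(classify_mutation_string)
    return df


def classify_mutation_string(text: str) -> str:
    """Derive the variant type from a printed mutation description."""
    if _REPEAT_HINT.search(text):
        return "str"
    if _ISCN_HINT.search(text):
        return "cnv"
    if re.search(r"(del|dup|ins)", text):
        return "indel"
    if ">" in text:
        return "snv"
    raise ValueError(f"cannot classify mutation string {text!r}")


def conclusive_patients(pathway: str) -> set[str]:
    """Distinct patients with a conclusive diagnosis in the pathway."""
    frames = [load_small_variant_table(), load_cnv_str_table()]
    patients: set[str] = set()
    for df in frames:
        if pathway == SOC:
            df = df[df["concordance"] == "yes"]
        elif pathway != GS:
            raise ValueError(f"unknown pathway {pathway!r}")
        patients |= set(df["patient"])
    return patients


def conclusive_outcomes(pathway: str) -> list[PatientOutcome]:
    """Per-patient conclusive outcomes rebuilt from the variant tables.

    Supporting variants keep table (input) order, which breaks primary-
    variant ties for dual-finding patients.
    """
    frames = pd.concat(
        [load_small_variant_table(), load_cnv_str_table()], ignore_index=True
    )
    if pathway == SOC:
        frames = frames[frames["concordance"] == "yes"]
    by_patient: dict[str, list[SupportingVariant]] = {}
    for _, row in frames.iterrows():
        by_patient.setdefault(row["patient"], []).append(
            SupportingVariant(
                vtype=row["variant_type"],
                gene=row["gene"],
                gene_class="disease_gene",
                mode=row["inheritance"].replace(" ", "_"),
                pathogenicity="P",
                phenotype_match=True,
                tier=1,
                detail=row["genomic_mutation"],
            )
        )
    return [
        PatientOutcome(pid, pathway, CONCLUSIVE, tuple(vs))
        for pid, vs in sorted(by_patient.items())
    ]


def conclusive_tally(pathway: str) -> dict[str, int]:
    """Variant-type counts over conclusively diagnosed patients (one
    primary variant per patient)."""
    return tally_diagnoses(conclusive_outcomes(pathway), CONCLUSIVE)


def cnv_size_labels() -> list[tuple[str, str, str]]:
    """(genomic mutation, printed size, recomputed size) per CNV row."""
    df = load_cnv_str_table()
    out = []
    for _, row in df.iterrows():
        if row["variant_type"] != "cnv":
            continue
        cnv = parse_iscn_cnv(row["genomic_mutation"])
        out.append((row["genomic_mutation"], row["size"], cnv_report_size(cnv.interval)))
    return out


def fmr1_repeat_allele() -> int:
    """Repeat-unit count of the reported fragile-X expansion allele."""
    df = load_cnv_str_table()
    row = df[df["variant_type"] == "str"].iloc[0]
    return parse_str_notation(row["genomic_mutation"]).max_allele
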