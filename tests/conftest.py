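"""Shared builders for the test suite.

Fixtures are generated programmatically; no data files are stored.
"""

from __future__ import annotations

import math

import pytest

from phosphorescue.tables_io import (
    CHANNELS,
    PLACEHOLDER,
    ProteinRecord,
    SiteRecord,
    SiteTableDialect,
)

NAN5 = (math.nan,) * 5


def make_window(before: str, after: str, center: str = "S") -> str:
    """A 31-residue window centered on ``center`` with the given context.

    ``before``/``after`` are the residues immediately flanking the
    phosphoacceptor; termini are padded with the placeholder, exactly as
    MaxQuant pads windows near protein ends.
    """
    half = 15
    left = (PLACEHOLDER * (half - len(before))) + before
    right = after + (PLACEHOLDER * (half - len(after)))
    window = left + center + right
    assert len(window) == 31
    return window


def make_site(
    site_id: str = "S1",
    ratios: dict | None = None,
    localization_prob: float = 0.99,
    is_reverse: bool = False,
    is_contaminant: bool = False,
    multiplicity: int = 1,
    protein: str = "P00001",
    position: int = 10,
    sequence_window: str | None = None,
    amino_acid: str = "S",
) -> SiteRecord:
    if ratios is None:
        ratios = {ch: NAN5 for ch in CHANNELS}
    return SiteRecord(
        site_id=site_id,
        protein_ids=(protein,),
        gene_names=("GENE1",),
        position=position,
        amino_acid=amino_acid,
        localization_prob=localization_prob,
        multiplicity=multiplicity,
        sequence_window=sequence_window or make_window("AAAAA", "EEEEE", amino_acid),
        is_reverse=is_reverse,
        is_contaminant=is_contaminant,
        ratios=ratios,
    )


def make_protein(
    protein: str = "P00001",
    ratios: dict | None = None,
    is_reverse: bool = False,
    is_contaminant: bool = False,
) -> ProteinRecord:
    if ratios is None:
        ratios = {ch: NAN5 for ch in CHANNELS}
    return ProteinRecord(
        protein_ids=(protein,),
        gene_names=("GENE1",),
        is_reverse=is_reverse,
        is_contaminant=is_contaminant,
        ratios=ratios,
    )


def values_equal(a: float, b: float) -> bool:
    if math.isnan(a) and math.isnan(b):
        return True
    return a == b


def ratios_equal(r1: dict, r2: dict) -> bool:
    if set(r1) != set(r2):
        return False
    return all(
        len(r1[ch]) == len(r2[ch])
        and all(values_equal(a, b) for a, b in zip(r1[ch], r2[ch]))
        for ch in r1
    )


def site_records_equal(a: SiteRecord, b: SiteRecord) -> bool:
    plain = (
        a.site_id == b.site_id
        and a.protein_ids == b.protein_ids
        and a.gene_names == b.gene_names
        and a.position == b.position
        and a.amino_acid == b.amino_acid
        and a.localization_prob == b.localization_prob
        and a.multiplicity == b.multiplicity
        and a.sequence_window == b.sequence_window
        and a.is_reverse == b.is_reverse
        and a.is_contaminant == b.is_contaminant
    )
    return plain and ratios_equal(dict(a.ratios), dict(b.ratios))


def protein_records_equal(a: ProteinRecord, b: ProteinRecord) -> bool:
    plain = (
        a.protein_ids == b.protein_ids
        and a.gene_names == b.gene_names
        and a.is_reverse == b.is_reverse
        and a.is_contaminant == b.is_contaminant
    )
    return plain and ratios_equal(dict(a.ratios), dict(b.ratios))


def blank_site_row(dialect: SiteTableDialect) -> dict[str, str]:
    """An all-empty row dict covering every mandatory column."""
    row = {c: "" for c in dialect.mandatory_columns()}
    row[dialect.site_id] = "S1"
    row[dialect.proteins] = "P00001"
    row[dialect.gene_names] = "GENE1"
    row[dialect.position] = "10"
    row[dialect.amino_acid] = "S"
    row[dialect.localization_prob] = "0.99"
    row[dialect.sequence_window] = make_window("AAAAA", "EEEEE")
    return row


@pytest.fixture
def site_dialect() -> SiteTableDialect:
    return SiteTableDialect()
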