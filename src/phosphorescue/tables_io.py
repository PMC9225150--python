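"""Reading and writing MaxQuant-dialect tab-delimited tables.

Quantitative input comes as two wide, tab-separated tables following the
MaxQuant output conventions: a phosphosite table (``Phospho (STY)Sites.txt``
layout, one row per site with per-multiplicity ratio columns suffixed
``___1/___2/___3``) and a protein-group table (``proteinGroups.txt`` layout).
Column names are configurable through a *dialect* so simplified fixtures need
not reproduce every MaxQuant column.

Phosphosite rows are expanded to one :class:`SiteRecord` per site ×
multiplicity state carrying any non-missing ratio, mirroring the Perseus
"expand site table" convention: downstream statistics are computed per
phosphopeptide multiplicity state, not per site row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import math

import pandas as pd

#: The three SILAC ratio channels: M/L compares inhibitor-treated wild-type
#: kinase cells to vehicle-treated wild-type cells; H/L compares
#: inhibitor-treated resistant-mutant cells to the same control; H/M is the
#: within-treatment mutant/wild-type contrast used to test rescue.
CHANNELS: tuple[str, ...] = ("M/L", "H/L", "H/M")

#: Placeholder used by MaxQuant to pad sequence windows at protein termini.
PLACEHOLDER = "_"

#: Cell contents that parse as a missing ratio.
MISSING_TOKENS = frozenset({"", "NaN", "nan"})


class TableFormatError(ValueError):
    """A mandatory column is absent or the table layout is unusable."""


class TableParseError(ValueError):
    """A cell could not be parsed; carries the offending row number."""


@dataclass(frozen=True)
class SiteRecord:
    """One phosphosite × multiplicity state with per-replicate channel ratios.

    ``ratios`` maps each channel in :data:`CHANNELS` to an ordered list of
    per-replicate normalized ratio values on the linear (not log) scale;
    missing replicates are ``nan``. ``position`` is the 1-based residue index
    within the protein (MaxQuant convention).
    """

    site_id: str
    protein_ids: tuple[str, ...]
    gene_names: tuple[str, ...]
    position: int
    amino_acid: str
    localization_prob: float
    multiplicity: int
    sequence_window: str
    is_reverse: bool
    is_contaminant: bool
    ratios: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if len(self.sequence_window) % 2 == 0:
            raise ValueError(
                f"{self.site_id}: sequence window length must be odd, "
                f"got {len(self.sequence_window)}"
            )
        center = self.sequence_window[len(self.sequence_window) // 2]
        if center not in (self.amino_acid, PLACEHOLDER):
            raise ValueError(
                f"{self.site_id}: window center {center!r} does not match "
                f"amino acid {self.amino_acid!r}"
            )
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError(
                f"{self.site_id}: localization probability "
                f"{self.localization_prob} outside [0, 1]"
            )
        if self.multiplicity not in (1, 2, 3):
            raise ValueError(f"{self.site_id}: multiplicity {self.multiplicity}")
        lengths = {len(v) for v in self.ratios.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.site_id}: unequal replicate counts {lengths}")

    @property
    def n_replicates(self) -> int:
        return len(next(iter(self.ratios.values())))

    @property
    def leading_protein(self) -> str:
        return self.protein_ids[0] if self.protein_ids else ""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein group with per-replicate channel ratios."""

    protein_ids: tuple[str, ...]
    gene_names: tuple[str, ...]
    is_reverse: bool
    is_contaminant: bool
    ratios: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.ratios.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.leading_protein}: unequal replicate counts {lengths}"
            )

    @property
    def n_replicates(self) -> int:
        return len(next(iter(self.ratios.values())))

    @property
    def leading_protein(self) -> str:
        return self.protein_ids[0] if self.protein_ids else ""


@dataclass(frozen=True)
class SiteTableDialect:
    """Column-name mapping for the phosphosite table."""

    site_id: str = "id"
    proteins: str = "Proteins"
    gene_names: str = "Gene names"
    position: str = "Position"
    amino_acid: str = "Amino acid"
    localization_prob: str = "Localization prob"
    sequence_window: str = "Sequence window"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    ratio_template: str = "Ratio {channel} normalized {replicate}___{multiplicity}"
    replicates: tuple[str, ...] = ("1", "2", "3", "4", "5")
    channels: tuple[str, ...] = CHANNELS
    multiplicities: tuple[int, ...] = (1, 2, 3)

    def ratio_column(self, channel: str, replicate: str, multiplicity: int) -> str:
        return self.ratio_template.format(
            channel=channel, replicate=replicate, multiplicity=multiplicity
        )

    def mandatory_columns(self) -> list[str]:
        cols = [
            self.site_id,
            self.proteins,
            self.gene_names,
            self.position,
            self.amino_acid,
            self.localization_prob,
            self.sequence_window,
            self.reverse,
            self.contaminant,
        ]
        cols += [
            self.ratio_column(c, r, m)
            for c in self.channels
            for r in self.replicates
            for m in self.multiplicities
        ]
        return cols


@dataclass(frozen=True)
class ProteinTableDialect:
    """Column-name mapping for the protein-group table."""

    proteins: str = "Protein IDs"
    gene_names: str = "Gene names"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    ratio_template: str = "Ratio {channel} normalized {replicate}"
    replicates: tuple[str, ...] = ("1", "2", "3", "4", "5")
    channels: tuple[str, ...] = CHANNELS

    def ratio_column(self, channel: str, replicate: str) -> str:
        return self.ratio_template.format(channel=channel, replicate=replicate)

    def mandatory_columns(self) -> list[str]:
        cols = [self.proteins, self.gene_names, self.reverse, self.contaminant]
        cols += [
            self.ratio_column(c, r) for c in self.channels for r in self.replicates
        ]
        return cols


def _read_raw(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _check_columns(df: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing mandatory column(s): {', '.join(missing)}")


def _parse_ratio(cell: str, row_number: int, column: str) -> float:
    if cell.strip() in MISSING_TOKENS:
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise TableParseError(
            f"row {row_number}: cannot parse ratio cell {cell!r} "
            f"in column {column!r}"
        ) from None


def _split_ids(cell: str) -> tuple[str, ...]:
    return tuple(p for p in cell.split(";") if p)


def read_site_table(
    path: str | Path, dialect: SiteTableDialect | None = None
) -> list[SiteRecord]:
    """Read a phosphosite table, expanding multiplicity columns.

    Returns one :class:`SiteRecord` per site × multiplicity state that carries
    at least one non-missing ratio value. Row numbers in errors are 1-based
    data rows (header excluded).
    """
    dialect = dialect or SiteTableDialect()
    df = _read_raw(path)
    _check_columns(df, dialect.mandatory_columns())
    records: list[SiteRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        for m in dialect.multiplicities:
            ratios = {
                ch: tuple(
                    _parse_ratio(
                        row_d[dialect.ratio_column(ch, rep, m)],
                        i,
                        dialect.ratio_column(ch, rep, m),
                    )
                    for rep in dialect.replicates
                )
                for ch in dialect.channels
            }
            if not any(
                not math.isnan(v) for vals in ratios.values() for v in vals
            ):
                continue
            records.append(
                SiteRecord(
                    site_id=row_d[dialect.site_id],
                    protein_ids=_split_ids(row_d[dialect.proteins]),
                    gene_names=_split_ids(row_d[dialect.gene_names]),
                    position=int(row_d[dialect.position]),
                    amino_acid=row_d[dialect.amino_acid],
                    localization_prob=float(row_d[dialect.localization_prob]),
                    multiplicity=m,
                    sequence_window=row_d[dialect.sequence_window],
                    is_reverse=row_d[dialect.reverse].strip() == "+",
                    is_contaminant=row_d[dialect.contaminant].strip() == "+",
                    ratios=ratios,
                )
            )
    return records


def read_protein_table(
    path: str | Path, dialect: ProteinTableDialect | None = None
) -> list[ProteinRecord]:
    """Read a protein-group table (no multiplicity expansion)."""
    dialect = dialect or ProteinTableDialect()
    df = _read_raw(path)
    _check_columns(df, dialect.mandatory_columns())
    records: list[ProteinRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        ratios = {
            ch: tuple(
                _parse_ratio(
                    row_d[dialect.ratio_column(ch, rep)],
                    i,
                    dialect.ratio_column(ch, rep),
                )
                for rep in dialect.replicates
            )
            for ch in dialect.channels
        }
        records.append(
            ProteinRecord(
                protein_ids=_split_ids(row_d[dialect.proteins]),
                gene_names=_split_ids(row_d[dialect.gene_names]),
                is_reverse=row_d[dialect.reverse].strip() == "+",
                is_contaminant=row_d[dialect.contaminant].strip() == "+",
                ratios=ratios,
            )
        )
    return records


def _fmt(value: float) -> str:
    # repr of a Python float round-trips exactly through float()
    return "" if (isinstance(value, float) and math.isnan(value)) else repr(float(value))


def write_site_table(
    records: Sequence[SiteRecord],
    path: str | Path,
    dialect: SiteTableDialect | None = None,
) -> None:
    """Write SiteRecords in the wide MaxQuant dialect, one row per record.

    Each record's ratios land in the columns of its own multiplicity; the
    other multiplicity columns stay empty, so :func:`read_site_table` expands
    the file back to the same records.
    """
    dialect = dialect or SiteTableDialect()
    columns = dialect.mandatory_columns()
    rows = []
    for rec in records:
        row = {c: "" for c in columns}
        row[dialect.site_id] = rec.site_id
        row[dialect.proteins] = ";".join(rec.protein_ids)
        row[dialect.gene_names] = ";".join(rec.gene_names)
        row[dialect.position] = str(rec.position)
        row[dialect.amino_acid] = rec.amino_acid
        row[dialect.localization_prob] = repr(float(rec.localization_prob))
        row[dialect.sequence_window] = rec.sequence_window
        row[dialect.reverse] = "+" if rec.is_reverse else ""
        row[dialect.contaminant] = "+" if rec.is_contaminant else ""
        for ch in dialect.channels:
            for rep, value in zip(dialect.replicates, rec.ratios[ch]):
                row[dialect.ratio_column(ch, rep, rec.multiplicity)] = _fmt(value)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_protein_table(
    records: Sequence[ProteinRecord],
    path: str | Path,
    dialect: ProteinTableDialect | None = None,
) -> None:
    dialect = dialect or ProteinTableDialect()
    columns = dialect.mandatory_columns()
    rows = []
    for rec in records:
        row = {c: "" for c in columns}
        row[dialect.proteins] = ";".join(rec.protein_ids)
        row[dialect.gene_names] = ";".join(rec.gene_names)
        row[dialect.reverse] = "+" if rec.is_reverse else ""
        row[dialect.contaminant] = "+" if rec.is_contaminant else ""
        for ch in dialect.channels:
            for rep, value in zip(dialect.replicates, rec.ratios[ch]):
                row[dialect.ratio_column(ch, rep)] = _fmt(value)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a classified-results table as tab-delimited text.

    Missing values render as empty strings; column order is preserved as
    given, so reruns produce byte-identical files.
    """
    table.to_csv(path, sep="\t", index=False, na_rep="")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def replace_ratios(
    record: SiteRecord | ProteinRecord, ratios: Mapping[str, tuple[float, ...]]
):
    """Return a copy of ``record`` with its ratio map replaced."""
    return dataclasses.replace(record, ratios=dict(ratios))
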