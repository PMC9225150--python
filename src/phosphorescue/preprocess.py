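"""Quality-control filtering and log2 transformation of SILAC ratios.

Filtering follows the standard Perseus-style funnel: decoy (reverse) and
contaminant entries are dropped first, then phosphosites whose phosphate
localization probability falls below the class-I threshold (0.75,
inclusive). Ratios are then moved to log2 space, where a symmetric fold
change has symmetric magnitude and the one-sample t-test against zero is
meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence, TypeVar

from .tables_io import ProteinRecord, SiteRecord, replace_ratios

R = TypeVar("R", SiteRecord, ProteinRecord)

DEFAULT_MIN_LOCALIZATION = 0.75


@dataclass(frozen=True)
class FilterReport:
    """Counts surviving each stage of the QC funnel."""

    n_input: int
    n_after_reverse_contaminant: int
    n_after_localization: int
    threshold_localization: float

    def __post_init__(self) -> None:
        if not (
            self.n_input
            >= self.n_after_reverse_contaminant
            >= self.n_after_localization
        ):
            raise ValueError("filter funnel counts must be non-increasing")

    def to_dict(self) -> dict:
        return asdict(self)


def filter_sites(
    records: Sequence[SiteRecord],
    min_localization: float = DEFAULT_MIN_LOCALIZATION,
) -> tuple[list[SiteRecord], FilterReport]:
    """Drop reverse/contaminant records, then poorly localized sites.

    The localization comparison is inclusive: a site at exactly the
    threshold survives.
    """
    if not 0.0 <= min_localization <= 1.0:
        raise ValueError(f"min_localization {min_localization} outside [0, 1]")
    clean = [r for r in records if not (r.is_reverse or r.is_contaminant)]
    localized = [r for r in clean if r.localization_prob >= min_localization]
    report = FilterReport(
        n_input=len(records),
        n_after_reverse_contaminant=len(clean),
        n_after_localization=len(localized),
        threshold_localization=min_localization,
    )
    return localized, report


def filter_proteins(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop reverse/contaminant protein groups (no localization concept)."""
    return [r for r in records if not (r.is_reverse or r.is_contaminant)]


def log2_transform(records: Sequence[R]) -> list[R]:
    """Replace every non-missing ratio with its base-2 logarithm.

    Missing values stay missing. A non-positive ratio is a hard error (it
    cannot arise from intensity ratios and would poison the log transform).
    """
    out: list[R] = []
    for rec in records:
        new_ratios = {}
        for channel, values in rec.ratios.items():
            transformed = []
            for v in values:
                if math.isnan(v):
                    transformed.append(math.nan)
                elif v <= 0:
                    ident = getattr(rec, "site_id", None) or rec.leading_protein
                    raise ValueError(
                        f"non-positive ratio {v} in channel {channel} "
                        f"of record {ident}"
                    )
                else:
                    transformed.append(math.log2(v))
            new_ratios[channel] = tuple(transformed)
        out.append(replace_ratios(rec, new_ratios))
    return out
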