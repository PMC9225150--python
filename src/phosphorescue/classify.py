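"""Inhibition/rescue classification of phosphopeptides and proteins.

The chemical-genetic design behind these rules: L = wild-type kinase +
vehicle, M = wild-type kinase + ATP-competitive inhibitor, H =
inhibitor-resistant mutant kinase + inhibitor. A direct substrate of the
kinase loses phosphorylation under inhibition (mean log2 M/L well below
zero) but keeps it when the resistant mutant carries the activity
(mean log2 H/L back near zero, with a significant H/M contrast). An
off-target effect of the inhibitor is inhibited in both M/L and H/L and is
therefore not rescued.

Classification rules (defaults alpha = 0.05 on BH q-values, fold-change
threshold 0.585 in log2 units, i.e. 1.5-fold):

* downregulated and significant: mean M/L < 0 with M/L q < alpha;
  biologically relevant: mean M/L < −0.585 (strict);
* rescued (down direction): −0.585 < mean H/L < 0.585 and H/M q < alpha;
* partially rescued (down direction): not rescued, mean H/M > 0 and
  H/M q < alpha;
* upregulated records use the mirrored criteria.

Protein-level calls use identical thresholds on protein-group ratios, and
each site is flagged ``protein_confounded`` when its parent protein changes
significantly and relevantly in the same direction — differential protein
abundance, not differential phosphorylation, may then explain the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .stats import DEFAULT_MIN_VALID, RatioStats, compute_stats
from .tables_io import ProteinRecord, SiteRecord

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: Biological-relevance cutoff on |mean log2 M/L|; 0.585 ~ log2(1.5),
#: i.e. 1.5-fold regulation.
DEFAULT_FC_THRESHOLD = 0.585

DIRECTIONS = ("down", "up", "none", "insufficient_data")
RESCUE_LABELS = ("rescued", "partially_rescued", "not_rescued", "not_applicable")


@dataclass(frozen=True)
class RegulationCall:
    """Direction/significance/relevance plus rescue status for one record."""

    direction: str
    significant: bool
    biologically_relevant: bool
    rescue: str = "not_applicable"
    rescue_reason: str | None = None
    protein_confounded: bool = False


@dataclass(frozen=True)
class ClassifiedSite:
    record: SiteRecord
    stats: Mapping[str, RatioStats]
    call: RegulationCall
    motif_adherent: bool | None = None


@dataclass(frozen=True)
class ClassifiedProtein:
    record: ProteinRecord
    stats: Mapping[str, RatioStats]
    call: RegulationCall


@dataclass(frozen=True)
class FunnelSummary:
    """Distinct-entity counts at each stage of the classification funnel.

    Distinct phosphopeptide = unique (sequence window, multiplicity);
    distinct phosphosite = unique (leading protein accession, position);
    distinct protein = unique leading accession. Partial-rescue counts
    include the rescued records (the rescue criteria are strictly stronger
    whenever the three channels are mutually consistent).
    """

    n_down_significant_relevant: int
    n_down_sites: int
    n_rescued_peptides: int
    n_rescued_sites: int
    n_rescued_proteins: int
    n_partial_peptides: int
    n_partial_sites: int
    n_partial_proteins: int
    n_up_significant_relevant: int
    n_up_rescued: int
    n_multiplicity1_rescued: int

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def call_regulation(
    stats: Mapping[str, RatioStats],
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> RegulationCall:
    """Direction, significance and biological relevance from M/L statistics.

    Both boundaries are strict: q must be < alpha, and |mean M/L| must
    exceed (not reach) the fold-change threshold.
    """
    ml = stats.get("M/L")
    if ml is None or ml.mean_log2 is None or ml.q_value is None:
        return RegulationCall("insufficient_data", False, False)
    mean = ml.mean_log2
    if mean < 0:
        direction = "down"
        relevant = mean < -fc_threshold
    elif mean > 0:
        direction = "up"
        relevant = mean > fc_threshold
    else:
        direction = "none"
        relevant = False
    significant = direction != "none" and ml.q_value < alpha
    return RegulationCall(direction, significant, relevant)


def call_rescue(
    stats: Mapping[str, RatioStats],
    call: RegulationCall,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> RegulationCall:
    """Attach the rescue status to a regulation call.

    Rescue is only evaluated for records that are significantly regulated
    to a biologically relevant level; everything else is ``not_applicable``.
    Records whose H/L mean or H/M test is undefined stay ``not_rescued``
    with the reason recorded (conservative: never promoted on missing
    evidence).
    """
    if not (call.significant and call.biologically_relevant):
        return replace(call, rescue="not_applicable")
    hl = stats.get("H/L")
    hm = stats.get("H/M")
    if hl is None or hl.mean_log2 is None:
        return replace(call, rescue="not_rescued", rescue_reason="H/L undefined")
    if hm is None or hm.q_value is None:
        return replace(call, rescue="not_rescued", rescue_reason="H/M test undefined")
    hm_significant = hm.q_value < alpha
    within_interval = -fc_threshold < hl.mean_log2 < fc_threshold
    if call.direction == "down":
        if within_interval and hm_significant:
            return replace(call, rescue="rescued")
        if hm.mean_log2 is not None and hm.mean_log2 > 0 and hm_significant:
            return replace(call, rescue="partially_rescued")
    else:  # up: mirrored criteria
        if within_interval and hm_significant:
            return replace(call, rescue="rescued")
        if hm.mean_log2 is not None and hm.mean_log2 < 0 and hm_significant:
            return replace(call, rescue="partially_rescued")
    return replace(call, rescue="not_rescued")


def cross_reference_proteome(
    sites: Sequence[ClassifiedSite],
    proteins: Sequence[ClassifiedProtein],
) -> list[ClassifiedSite]:
    """Flag sites whose parent protein changes in the same direction.

    A site is confounded when any of its protein accessions matches a
    protein-group record that is significant AND biologically relevant with
    the same direction. Sites without a matching protein record are left
    unflagged (and logged).
    """
    by_accession: dict[str, list[ClassifiedProtein]] = {}
    for prot in proteins:
        for acc in prot.record.protein_ids:
            by_accession.setdefault(acc, []).append(prot)
    out: list[ClassifiedSite] = []
    for site in sites:
        matches = [
            p for acc in site.record.protein_ids for p in by_accession.get(acc, [])
        ]
        if not matches and site.record.protein_ids:
            logger.debug(
                "site %s: no protein record for %s",
                site.record.site_id,
                site.record.protein_ids,
            )
        confounded = any(
            p.call.significant
            and p.call.biologically_relevant
            and p.call.direction == site.call.direction
            for p in matches
        )
        out.append(
            replace(site, call=replace(site.call, protein_confounded=confounded))
        )
    return out


def _peptide_key(rec: SiteRecord) -> tuple[str, int]:
    return (rec.sequence_window, rec.multiplicity)


def _site_key(rec: SiteRecord) -> tuple[str, int]:
    return (rec.leading_protein, rec.position)


def _count(sites: Sequence[ClassifiedSite]) -> tuple[int, int, int]:
    peptides = {_peptide_key(s.record) for s in sites}
    site_keys = {_site_key(s.record) for s in sites}
    proteins = {s.record.leading_protein for s in sites}
    return len(peptides), len(site_keys), len(proteins)


def summarize_funnel(
    sites: Sequence[ClassifiedSite],
    proteins: Sequence[ClassifiedProtein] = (),
) -> FunnelSummary:
    """Distinct phosphopeptide/site/protein counts per classification stage."""
    down = [
        s
        for s in sites
        if s.call.direction == "down"
        and s.call.significant
        and s.call.biologically_relevant
    ]
    up = [
        s
        for s in sites
        if s.call.direction == "up"
        and s.call.significant
        and s.call.biologically_relevant
    ]
    down_rescued = [s for s in down if s.call.rescue == "rescued"]
    # the partial-rescue list contains the rescued records by construction
    down_partial = [
        s for s in down if s.call.rescue in ("rescued", "partially_rescued")
    ]
    up_rescued = [s for s in up if s.call.rescue == "rescued"]

    n_down_pep, n_down_sites, _ = _count(down)
    n_res_pep, n_res_sites, n_res_prot = _count(down_rescued)
    n_par_pep, n_par_sites, n_par_prot = _count(down_partial)
    n_up_pep, _, _ = _count(up)
    n_up_res_pep, _, _ = _count(up_rescued)
    mult1 = {
        _peptide_key(s.record)
        for s in down_rescued
        if s.record.multiplicity == 1
    }
    return FunnelSummary(
        n_down_significant_relevant=n_down_pep,
        n_down_sites=n_down_sites,
        n_rescued_peptides=n_res_pep,
        n_rescued_sites=n_res_sites,
        n_rescued_proteins=n_res_prot,
        n_partial_peptides=n_par_pep,
        n_partial_sites=n_par_sites,
        n_partial_proteins=n_par_prot,
        n_up_significant_relevant=n_up_pep,
        n_up_rescued=n_up_res_pep,
        n_multiplicity1_rescued=len(mult1),
    )


def classify_sites(
    records: Sequence[SiteRecord],
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    min_valid: int = DEFAULT_MIN_VALID,
) -> list[ClassifiedSite]:
    """Statistics + regulation + rescue calls for log2-transformed sites."""
    all_stats = compute_stats(records, min_valid=min_valid)
    out = []
    for rec, stats in zip(records, all_stats):
        call = call_rescue(
            stats, call_regulation(stats, alpha, fc_threshold), alpha, fc_threshold
        )
        out.append(ClassifiedSite(record=rec, stats=stats, call=call))
    return out


def classify_proteins(
    records: Sequence[ProteinRecord],
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    min_valid: int = DEFAULT_MIN_VALID,
) -> list[ClassifiedProtein]:
    """As :func:`classify_sites`, for protein groups (separate BH family)."""
    all_stats = compute_stats(records, min_valid=min_valid)
    out = []
    for rec, stats in zip(records, all_stats):
        call = call_rescue(
            stats, call_regulation(stats, alpha, fc_threshold), alpha, fc_threshold
        )
        out.append(ClassifiedProtein(record=rec, stats=stats, call=call))
    return out
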