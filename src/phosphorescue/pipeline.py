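"""End-to-end orchestration: tables in, classified results and reports out.

``run_pipeline`` composes the stages in analysis order — read, QC filter,
log2 transform, per-channel statistics with BH correction, regulation and
rescue calls, proteome cross-reference, funnel summary, motif profiles —
and writes all artifacts to one output directory. Every threshold is
logged, and the log format carries no timestamps, so a rerun on identical
inputs produces a byte-identical output directory.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classify import (
    ClassifiedProtein,
    ClassifiedSite,
    DEFAULT_ALPHA,
    DEFAULT_FC_THRESHOLD,
    FunnelSummary,
    classify_proteins,
    classify_sites,
    cross_reference_proteome,
    summarize_funnel,
)
from .motif import MotifProfile, adheres_to_motif, build_motif_profile
from .preprocess import (
    DEFAULT_MIN_LOCALIZATION,
    FilterReport,
    filter_proteins,
    filter_sites,
    log2_transform,
)
from .stats import DEFAULT_MIN_VALID, RatioStats
from .tables_io import (
    CHANNELS,
    ProteinTableDialect,
    SiteTableDialect,
    read_protein_table,
    read_site_table,
    write_results,
)

logger = logging.getLogger(__name__)

#: Record-set names for which motif profiles are produced (nested sets).
MOTIF_PROFILE_CLASSES = ("all", "inhibited", "partially_rescued", "rescued")


@dataclass(frozen=True)
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    sites_path: str | Path
    out_dir: str | Path
    proteins_path: str | Path | None = None
    alpha: float = DEFAULT_ALPHA
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    min_localization: float = DEFAULT_MIN_LOCALIZATION
    min_valid: int = DEFAULT_MIN_VALID
    site_dialect: SiteTableDialect = field(default_factory=SiteTableDialect)
    protein_dialect: ProteinTableDialect = field(
        default_factory=ProteinTableDialect
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if not 0.0 <= self.min_localization <= 1.0:
            raise ValueError("min_localization outside [0, 1]")
        if self.min_valid < 2:
            raise ValueError("min_valid must be at least 2")


@dataclass(frozen=True)
class PipelineResult:
    """In-memory view of everything a pipeline run produced."""

    sites: list[ClassifiedSite]
    proteins: list[ClassifiedProtein]
    filter_report: FilterReport
    funnel: FunnelSummary
    motif_profiles: Mapping[str, MotifProfile]
    paths: Mapping[str, Path]


def _stats_columns(stats: Mapping[str, RatioStats]) -> dict:
    cols = {}
    for channel in CHANNELS:
        s = stats[channel]
        tag = channel.replace("/", "").lower()  # M/L -> ml
        cols[f"n_valid_{tag}"] = s.n_valid
        cols[f"mean_log2_{tag}"] = s.mean_log2
        cols[f"sd_log2_{tag}"] = s.sd_log2
        cols[f"t_{tag}"] = s.t_stat
        cols[f"p_{tag}"] = s.p_value
        cols[f"q_{tag}"] = s.q_value
    return cols


def site_results_table(sites: Sequence[ClassifiedSite]) -> pd.DataFrame:
    """Flatten classified sites into one row per record."""
    rows = []
    for s in sites:
        r = s.record
        row = {
            "site_id": r.site_id,
            "proteins": ";".join(r.protein_ids),
            "gene_names": ";".join(r.gene_names),
            "position": r.position,
            "amino_acid": r.amino_acid,
            "multiplicity": r.multiplicity,
            "localization_prob": r.localization_prob,
            "sequence_window": r.sequence_window,
        }
        row.update(_stats_columns(s.stats))
        row.update(
            {
                "direction": s.call.direction,
                "significant": s.call.significant,
                "biologically_relevant": s.call.biologically_relevant,
                "rescue": s.call.rescue,
                "rescue_reason": s.call.rescue_reason,
                "protein_confounded": s.call.protein_confounded,
                "motif_adherent": s.motif_adherent,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def protein_results_table(proteins: Sequence[ClassifiedProtein]) -> pd.DataFrame:
    rows = []
    for p in proteins:
        r = p.record
        row = {
            "proteins": ";".join(r.protein_ids),
            "gene_names": ";".join(r.gene_names),
        }
        row.update(_stats_columns(p.stats))
        row.update(
            {
                "direction": p.call.direction,
                "significant": p.call.significant,
                "biologically_relevant": p.call.biologically_relevant,
                "rescue": p.call.rescue,
                "rescue_reason": p.call.rescue_reason,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def volcano_table(sites: Sequence[ClassifiedSite]) -> pd.DataFrame:
    """Plot-ready export: mean log2 M/L vs −log10 q with a class label."""
    rows = []
    for s in sites:
        ml = s.stats["M/L"]
        if ml.mean_log2 is None or ml.q_value is None:
            continue
        if s.call.rescue in ("rescued", "partially_rescued"):
            label = s.call.rescue
        elif s.call.significant and s.call.biologically_relevant:
            label = "regulated"
        else:
            label = "not_significant"
        q = max(ml.q_value, 1e-300)
        rows.append(
            {
                "site_id": s.record.site_id,
                "mean_log2_ml": ml.mean_log2,
                "neg_log10_q_ml": -math.log10(q),
                "class": label,
            }
        )
    return pd.DataFrame(rows)


def _profile_sets(
    prefilter: Sequence,  # SiteRecords before QC filtering
    sites: Sequence[ClassifiedSite],
) -> dict[str, list[str]]:
    inhibited = [
        s
        for s in sites
        if s.call.direction == "down"
        and s.call.significant
        and s.call.biologically_relevant
    ]
    partial = [
        s for s in inhibited if s.call.rescue in ("rescued", "partially_rescued")
    ]
    rescued = [s for s in inhibited if s.call.rescue == "rescued"]
    return {
        "all": [r.sequence_window for r in prefilter],
        "inhibited": [s.record.sequence_window for s in inhibited],
        "partially_rescued": [s.record.sequence_window for s in partial],
        "rescued": [s.record.sequence_window for s in rescued],
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    A missing protein table degrades gracefully: the cross-reference step
    is skipped with a warning and every ``protein_confounded`` flag stays
    false.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pkg_logger = logging.getLogger("phosphorescue")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger.addHandler(handler)
    prior_level = pkg_logger.level
    pkg_logger.setLevel(logging.INFO)
    try:
        logger.info(
            "thresholds: alpha=%g fc_threshold=%g min_localization=%g min_valid=%d",
            config.alpha, config.fc_threshold, config.min_localization,
            config.min_valid,
        )
        raw_sites = read_site_table(config.sites_path, config.site_dialect)
        logger.info("read %d site records from %s", len(raw_sites), config.sites_path)
        kept, report = filter_sites(raw_sites, config.min_localization)
        logger.info(
            "QC funnel: %d input -> %d after reverse/contaminant -> %d after "
            "localization >= %g",
            report.n_input, report.n_after_reverse_contaminant,
            report.n_after_localization, report.threshold_localization,
        )
        log_sites = log2_transform(kept)
        sites = classify_sites(
            log_sites, config.alpha, config.fc_threshold, config.min_valid
        )

        proteins: list[ClassifiedProtein] = []
        if config.proteins_path is not None:
            raw_proteins = read_protein_table(
                config.proteins_path, config.protein_dialect
            )
            kept_proteins = filter_proteins(raw_proteins)
            logger.info(
                "read %d protein records (%d after reverse/contaminant)",
                len(raw_proteins), len(kept_proteins),
            )
            proteins = classify_proteins(
                log2_transform(kept_proteins), config.alpha,
                config.fc_threshold, config.min_valid,
            )
            sites = cross_reference_proteome(sites, proteins)
        else:
            logger.warning(
                "no protein table given: cross-reference skipped, "
                "protein_confounded all false"
            )

        sites = [
            ClassifiedSite(
                record=s.record,
                stats=s.stats,
                call=s.call,
                motif_adherent=adheres_to_motif(s.record.sequence_window),
            )
            for s in sites
        ]
        funnel = summarize_funnel(sites, proteins)
        logger.info("funnel summary: %s", funnel.to_dict())

        window_sets = _profile_sets(raw_sites, sites)
        profiles = {
            name: build_motif_profile(windows)
            for name, windows in window_sets.items()
        }

        paths: dict[str, Path] = {
            "sites": out / "classified_sites.tsv",
            "proteins": out / "classified_proteins.tsv",
            "funnel": out / "funnel.json",
            "volcano": out / "volcano_sites.tsv",
            "motif_ic": out / "motif_ic.json",
            "log": out / "run.log",
        }
        write_results(site_results_table(sites), paths["sites"])
        write_results(protein_results_table(proteins), paths["proteins"])
        write_results(volcano_table(sites), paths["volcano"])
        summary = {
            "thresholds": {
                "alpha": config.alpha,
                "fc_threshold": config.fc_threshold,
                "min_localization": config.min_localization,
                "min_valid": config.min_valid,
            },
            "filter_report": report.to_dict(),
            "funnel": funnel.to_dict(),
        }
        paths["funnel"].write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        ic_out = {}
        for name, profile in profiles.items():
            path = out / f"motif_counts_{name}.tsv"
            profile.counts.to_csv(path, sep="\t", index_label="residue")
            paths[f"motif_counts_{name}"] = path
            ic_out[name] = {
                "n_windows": profile.n_windows,
                "ic_bits": {
                    str(pos): (None if math.isnan(v) else v)
                    for pos, v in profile.information_content.items()
                },
            }
        paths["motif_ic"].write_text(
            json.dumps(ic_out, indent=2, sort_keys=True) + "\n"
        )
        # output directory deliberately not logged: the run log must be
        # byte-identical across reruns on identical inputs
        logger.info("wrote %d artifacts", len(paths))
        return PipelineResult(
            sites=sites,
            proteins=proteins,
            filter_report=report,
            funnel=funnel,
            motif_profiles=profiles,
            paths=paths,
        )
    finally:
        handler.close()
        pkg_logger.removeHandler(handler)
        pkg_logger.setLevel(prior_level)
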