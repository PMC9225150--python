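"""Regulation and rescue calls, proteome cross-reference, funnel counts."""

from __future__ import annotations

import pytest

from phosphorescue import (
    call_regulation,
    call_rescue,
    classify_proteins,
    classify_sites,
    cross_reference_proteome,
    filter_sites,
    generate_dataset,
    log2_transform,
    summarize_funnel,
    zero_noise_config,
)
from phosphorescue.classify import ClassifiedProtein, ClassifiedSite, RegulationCall
from phosphorescue.simulate import benchmark_config, evaluate_recovery
from phosphorescue.stats import RatioStats

from conftest import make_protein, make_site


def rs(channel, mean, q=None, n=5, sd=0.2):
    p = q  # p <= q always; equal is fine for rule-level tests
    t = None if mean is None else mean / (sd / n**0.5)
    return RatioStats(channel, n, mean, sd, t, p, q_value=q)


def stats_map(ml=(None, None), hl=(None, None), hm=(None, None)):
    return {
        "M/L": rs("M/L", *ml),
        "H/L": rs("H/L", *hl),
        "H/M": rs("H/M", *hm),
    }


class TestCallRegulation:
    def test_down_significant_relevant(self):
        call = call_regulation(stats_map(ml=(-1.0, 0.001)))
        assert call.direction == "down"
        assert call.significant and call.biologically_relevant

    def test_down_significant_but_small_effect(self):
        call = call_regulation(stats_map(ml=(-0.3, 0.001)))
        assert call.direction == "down"
        assert call.significant and not call.biologically_relevant

    def test_down_large_effect_not_significant(self):
        call = call_regulation(stats_map(ml=(-1.0, 0.20)))
        assert call.direction == "down"
        assert not call.significant and call.biologically_relevant

    def test_exact_threshold_is_not_relevant(self):
        """|mean M/L| must strictly exceed 0.585."""
        call = call_regulation(stats_map(ml=(-0.585, 0.001)))
        assert not call.biologically_relevant
        call = call_regulation(stats_map(ml=(0.585, 0.001)))
        assert not call.biologically_relevant

    def test_undefined_ml_is_insufficient_data(self):
        call = call_regulation(stats_map())
        assert call.direction == "insufficient_data"
        assert not call.significant


class TestCallRescue:
    def test_down_rescued(self):
        stats = stats_map(ml=(-1.5, 0.001), hl=(0.10, None), hm=(1.6, 0.01))
        call = call_rescue(stats, call_regulation(stats))
        assert call.rescue == "rescued"

    def test_down_partial_rescue(self):
        stats = stats_map(ml=(-1.5, 0.001), hl=(-0.90, None), hm=(0.60, 0.01))
        call = call_rescue(stats, call_regulation(stats))
        assert call.rescue == "partially_rescued"

    def test_down_not_rescued_when_hm_not_significant(self):
        stats = stats_map(ml=(-1.5, 0.001), hl=(-1.0, None), hm=(0.05, 0.30))
        call = call_rescue(stats, call_regulation(stats))
        assert call.rescue == "not_rescued"

    def test_up_rescued_mirrored(self):
        stats = stats_map(ml=(1.5, 0.001), hl=(-0.10, None), hm=(-1.6, 0.01))
        call = call_rescue(stats, call_regulation(stats))
        assert call.rescue == "rescued"

    def test_up_partial_mirrored(self):
        stats = stats_map(ml=(1.5, 0.001), hl=(0.90, None), hm=(-0.60, 0.01))
        call = call_rescue(stats, call_regulation(stats))
        assert call.rescue == "partially_rescued"

    def test_not_applicable_without_relevance(self):
        stats = stats_map(ml=(-0.3, 0.001))
        call = call_rescue(stats, call_regulation(stats))
        assert call.rescue == "not_applicable"

    def test_undefined_hm_defaults_to_not_rescued(self):
        stats = stats_map(ml=(-1.5, 0.001), hl=(0.0, None))
        call = call_rescue(stats, call_regulation(stats))
        assert call.rescue == "not_rescued"
        assert call.rescue_reason is not None

    def test_hl_boundary_is_strict(self):
        stats = stats_map(ml=(-1.5, 0.001), hl=(0.585, None), hm=(2.0, 0.001))
        call = call_rescue(stats, call_regulation(stats))
        assert call.rescue != "rescued"


class TestNestingProperty:
    def test_rescued_satisfies_partial_criteria(self):
        """On channel-consistent data every rescued record also meets the
        partial-rescue criteria: the rescued list nests inside the partial
        list."""
        for seed in range(3):
            config = benchmark_config(seed=seed, n_sites=1000)
            sites, _, _ = generate_dataset(config)
            kept, _ = filter_sites(sites)
            classified = classify_sites(log2_transform(kept))
            for c in classified:
                if c.call.rescue != "rescued":
                    continue
                hm = c.stats["H/M"]
                assert hm.q_value is not None and hm.q_value < 0.05
                if c.call.direction == "down":
                    assert hm.mean_log2 > 0
                else:
                    assert hm.mean_log2 < 0


class TestCrossReference:
    def _mk_site(self, call, protein="P00001"):
        return ClassifiedSite(record=make_site(protein=protein), stats={}, call=call)

    def _mk_protein(self, call, protein="P00001"):
        return ClassifiedProtein(record=make_protein(protein), stats={}, call=call)

    def test_protein_change_in_same_direction_flags_site(self):
        down = RegulationCall("down", True, True, rescue="rescued")
        out = cross_reference_proteome(
            [self._mk_site(down)], [self._mk_protein(down)]
        )
        assert out[0].call.protein_confounded

    def test_unchanged_protein_does_not_flag(self):
        down = RegulationCall("down", True, True, rescue="rescued")
        flat = RegulationCall("none", False, False)
        out = cross_reference_proteome(
            [self._mk_site(down)], [self._mk_protein(flat)]
        )
        assert not out[0].call.protein_confounded

    def test_direction_mismatch_does_not_flag(self):
        down = RegulationCall("down", True, True, rescue="rescued")
        up = RegulationCall("up", True, True)
        out = cross_reference_proteome([self._mk_site(down)], [self._mk_protein(up)])
        assert not out[0].call.protein_confounded

    def test_missing_protein_record_defaults_false(self):
        down = RegulationCall("down", True, True, rescue="rescued")
        out = cross_reference_proteome(
            [self._mk_site(down, protein="P99999")], []
        )
        assert not out[0].call.protein_confounded

    def test_planted_protein_driven_sites_flagged_exactly(self):
        """Five planted protein-driven sites are the only flagged ones."""
        config = zero_noise_config(n_sites=400, seed=11, n_protein_driven=5)
        sites, proteins, truth = generate_dataset(config)
        kept, _ = filter_sites(sites)
        classified = classify_sites(log2_transform(kept))
        protein_calls = classify_proteins(log2_transform(proteins))
        classified = cross_reference_proteome(classified, protein_calls)
        flagged = {c.record.site_id for c in classified if c.call.protein_confounded}
        planted = set(truth.index[truth["protein_driven"]])
        assert flagged == planted
        assert len(flagged) == 5


class TestFunnelSummary:
    def test_distinct_peptide_vs_site_counting(self):
        """Same protein+position at multiplicities 1 and 2: two distinct
        phosphopeptides, one distinct phosphosite."""
        rescued = RegulationCall("down", True, True, rescue="rescued")
        window = make_site().sequence_window
        sites = [
            ClassifiedSite(
                record=make_site("a", multiplicity=1, sequence_window=window),
                stats={}, call=rescued,
            ),
            ClassifiedSite(
                record=make_site("b", multiplicity=2, sequence_window=window),
                stats={}, call=rescued,
            ),
        ]
        funnel = summarize_funnel(sites)
        assert funnel.n_rescued_peptides == 2
        assert funnel.n_rescued_sites == 1
        assert funnel.n_rescued_proteins == 1
        assert funnel.n_multiplicity1_rescued == 1

    def test_empty_rescued_set(self):
        flat = RegulationCall("none", False, False)
        sites = [ClassifiedSite(record=make_site(), stats={}, call=flat)]
        funnel = summarize_funnel(sites)
        assert funnel.n_rescued_peptides == 0
        assert funnel.n_partial_peptides == 0
        assert funnel.n_down_significant_relevant == 0

    def test_partial_counts_contain_rescued(self):
        config = benchmark_config(seed=2, n_sites=1000)
        sites, _, _ = generate_dataset(config)
        kept, _ = filter_sites(sites)
        funnel = summarize_funnel(classify_sites(log2_transform(kept)))
        assert funnel.n_rescued_peptides <= funnel.n_partial_peptides
        assert funnel.n_partial_peptides <= funnel.n_down_significant_relevant


class TestZeroNoiseRecovery:
    def test_confusion_diagonal_and_funnel_exact(self):
        """At sigma=0 every planted class is recovered exactly and the
        funnel equals the planted counts."""
        config = zero_noise_config(n_sites=500, seed=5)
        sites, _, truth = generate_dataset(config)
        kept, report = filter_sites(sites)
        assert report.n_after_localization == 500
        classified = classify_sites(log2_transform(kept))
        recovery = evaluate_recovery(classified, truth)
        assert recovery.accuracy == 1.0
        counts = truth["class_label"].value_counts()
        funnel = summarize_funnel(classified)
        n_rescued = int(counts.get("substrate_rescued", 0))
        n_partial = int(counts.get("substrate_partial", 0))
        n_off = int(counts.get("off_target", 0))
        n_up = int(counts.get("compensatory_up_rescued", 0))
        assert funnel.n_rescued_peptides == n_rescued
        assert funnel.n_partial_peptides == n_rescued + n_partial
        assert funnel.n_down_significant_relevant == n_rescued + n_partial + n_off
        assert funnel.n_up_significant_relevant == n_up
        assert funnel.n_up_rescued == n_up
        rescued_truth = truth[truth["class_label"] == "substrate_rescued"]
        assert funnel.n_rescued_proteins == rescued_truth["leading_protein"].nunique()
        assert funnel.n_multiplicity1_rescued == int(
            (rescued_truth["multiplicity"] == 1).sum()
        )
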