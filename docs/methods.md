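# Methods

## The rescue model

The analysis assumes a triple-SILAC design in which three cell states are
mixed and quantified together: L (wild-type kinase, vehicle), M (wild-type
kinase + ATP-competitive inhibitor) and H (inhibitor-resistant mutant
kinase + inhibitor). MaxQuant reports normalized intensity ratios M/L, H/L
and H/M per biological replicate; because all three derive from the same
per-channel intensities, log2(H/M) = log2(H/L) − log2(M/L) holds
replicate-wise. The inference exploits this structure: M/L measures the
inhibitor's total effect (on- plus off-target), H/L isolates what the
resistant mutant restores, and H/M is the within-treatment contrast whose
one-sample t-test provides the statistical evidence for rescue.

Classification rules and defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | BH q-value threshold, strict (`q < alpha`) |
| `fc_threshold` | 0.585 | log2 units ≈ log2(1.5); biological relevance is strict (`|x̄| > θ`) |
| `min_localization` | 0.75 | phosphosite localization probability, inclusive (`≥`) |
| `min_valid` | 3 | non-missing replicates (of 5) required per channel to test |

The fold-change threshold is stored as the conventional printed value
0.585 rather than log2(1.5) = 0.58496…, so that "exactly ±0.585" is, by
the strict inequality, *not* biologically relevant.

### Decision order and conventions

1. Reverse/decoy and contaminant records are removed first, then the
   localization filter is applied (order affects only the intermediate
   funnel counts, not the surviving set). Localization filtering applies
   to phosphosites only, never protein groups.
2. MaxQuant's per-multiplicity ratio columns (`___1/___2/___3`) are
   expanded to one record per site × multiplicity state carrying any
   non-missing ratio, since statistics are reported per phosphopeptide
   multiplicity state. How the original Perseus workflow collapsed or
   expanded these columns is not documented; this expansion is our
   convention.
3. Tests are two-sided; direction is imposed separately through the sign
   of the mean, so direction is not double-counted in the p-value.
4. The BH family is one channel across all records of one table; sites
   and protein groups are corrected as separate families (the column-wise
   default of Perseus-style workflows).
5. Rescue is evaluated only for records that are significant AND
   biologically relevant; everything else is `not_applicable`. A record
   whose H/L mean or H/M test is undefined (too few valid replicates) is
   conservatively `not_rescued`, never promoted or dropped. A significant
   H/M test in the *wrong* direction (mean H/M < 0 for a downregulated
   record) is likewise `not_rescued`.
6. Upregulated records use criteria exactly mirrored from the
   downregulated ones, including the H/M q-test requirement.
7. Cross-referencing *flags* protein-confounded sites
   (`protein_confounded=True`) instead of removing them, keeping funnel
   counts comparable with and without the flag. A site with no matching
   protein record is unflagged and logged.
8. "Distinct phosphopeptide" = unique (sequence window, multiplicity);
   "distinct phosphosite" = unique (leading accession, position);
   "distinct protein" = unique leading accession. These entities are not
   formally defined in the source workflow; the definitions are fixed
   here and used consistently in `summarize_funnel`.
9. Partial-rescue counts include the rescued records: whenever the three
   channels are mutually consistent, the rescue criteria strictly imply
   the partial-rescue criteria (if x̄(M/L) < −θ and x̄(H/L) > −θ then
   x̄(H/M) = x̄(H/L) − x̄(M/L) > 0), so the rescued list nests inside the
   partial list.

### Degenerate statistics

A channel with fewer than `min_valid` finite replicates, or with zero
variance around a zero mean, has undefined t/p/q and yields
`insufficient_data` (regulation) or `not_rescued` (rescue). Zero variance
at a *nonzero* mean takes the continuous limit t = ±∞, p = 0 — the same
convention scipy's `ttest_1samp` adopts — so noise-free data classifies
decisively rather than vanishing from the analysis. Consequently p-values
live in [0, 1] and `bh_adjust` accepts p = 0. `bh_adjust` excludes
undefined entries from the family (m counts defined p-values only) and
preserves input order; ties need no special handling under the step-up
rule.

## Motif analysis

Adherence implements the minimal acidophilic consensus only: center
residue ∈ {S, T} and the +3 residue ∈ {D, E}. Tyrosine-centered windows
never adhere; a terminus placeholder (`_`) at +3 means non-adherent;
proline at +1 — prevalent among cellular substrates despite its
reputation as a negative determinant in vitro — is never penalized.
Extended acidic-determinant scoring is out of scope; the downstream
acidic preference is instead visible in the position frequency matrix.
Information content is log2(20) − Shannon entropy per position against a
uniform 20-residue background, with no small-sample correction (plain
WebLogo convention); empty (all-placeholder) columns report NaN.

## Synthetic data generator

The generator emulates the study design: 5 biological replicates, three
channels, and five planted effect classes with log2 effects
(δ_M, δ_H) = (−Δ, 0) rescued substrate, (−Δ, −Δ(1−f)) partial substrate
(f = `partial_fraction_restored`, default 0.5, placing x̄(H/L) at −Δ/2 —
outside the rescue interval for Δ = 1.5 but inside partial rescue),
(−Δ, −Δ) off-target, (0, 0) unaffected, (+Δ, 0) compensatory upregulated.
Noise is drawn per channel *intensity* (log2 scale, SD `sigma`), not per
ratio, so each log2 ratio carries noise σ√2 and the three channels are
correlated exactly as in a real triple-SILAC mix — the dependence the H/M
test relies on. Missingness is applied per intensity cell; a missing
intensity voids both ratios involving that channel in that replicate.
Replicates are modeled as independent beyond the shared channel structure.

Defaults chosen once as realistic study conditions: class proportions
{rescued 0.05, partial 0.05, off-target 0.05, unaffected 0.80,
compensatory 0.05}; Δ = 1.5; σ = 0.3; missing rate 0.1; localization
probability ~ Beta(8, 1) (≈10% of sites fall below the 0.75 filter);
1% decoy and 1% contaminant rows; multiplicity ∈ {1, 2, 3} with
probabilities (0.6, 0.3, 0.1); baseline log2 intensity ~ N(25, 2)
(cancels in every ratio); a fixed human-proteome-like amino-acid
background for sequence windows. Substrate-class windows (including the
compensatory class, whose real counterparts overwhelmingly carried the
motif) are +3-acidic with probability `p_motif` = 0.83 versus a
background rate of 0.12, and motif-carrying windows also receive acidic
+1/+2 residues at rate 0.35, emulating the acidophilic downstream
stretch. Optionally, `n_protein_driven` unaffected sites are given
protein-level effects (δ_M = δ_H = −Δ at both site and protein) to plant
confounders for the cross-reference step.

Two presets document the validation conditions. `zero_noise_config` sets
σ = 0 with complete data: every classification is then forced by the
thresholds, the confusion matrix must be diagonal, and the funnel must
equal the planted counts exactly. `benchmark_config` keeps the planted
effects at σ = 0.3, 2,000 sites, 5 replicates but with complete data (no
missingness, perfect localization, no decoys), so that it measures the
classifier's statistical operating characteristics rather than QC
attrition, which is tested separately. Measured at these conditions over
20 seeds, the rescued class shows specificity ≈ 0.996 and sensitivity
≈ 0.86–0.88: with df = 4 t-tests and ratio noise σ√2 ≈ 0.42, a typical
planted substrate has p(H/M) ≈ 1.4 × 10⁻³, which lands near the BH
threshold across 2,000 tests, so roughly one planted substrate in eight
narrowly misses an FDR gate. This is a power property of the published
decision rules at these noise and replicate levels, not an implementation
artifact (an independent vectorized re-derivation of the rules agrees
call-for-call).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: intensity-dependent missingness, replicate
correlation beyond shared channels, peptide-level ratio compression,
shared peptides across protein groups, arginine-to-proline conversion,
and search-engine identification error beyond uniform decoy flags.

## Problem sizes

The test and acceptance workloads use 300–2,000 sites per dataset, up to
100 seeded datasets for the nesting property, 20 seeds for the
operating-characteristic benchmark, 10,000 null draws for t-test
calibration and 1,000 random vectors for the BH oracle comparison — sizes
at which the targeted statistical tolerances (binomial bands, seed
averages) are already tight.
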