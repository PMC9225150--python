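"""Synthetic triple-SILAC phosphoproteomics data with planted ground truth.

The generator emulates the chemical-genetic rescue design so that every
pipeline stage can be exercised with known answers: three SILAC channels
(L = wild-type kinase + vehicle, M = wild-type + inhibitor, H =
inhibitor-resistant mutant + inhibitor), five biological replicates, and
five planted effect classes:

* ``substrate_rescued``   — inhibited (δ_M = −Δ) and fully rescued (δ_H = 0);
* ``substrate_partial``   — inhibited, only partially restored
  (δ_H = −Δ·(1 − partial_fraction_restored));
* ``off_target``          — inhibited in both channels (δ_M = δ_H = −Δ);
* ``unaffected``          — no effect;
* ``compensatory_up_rescued`` — upregulated under inhibition (δ_M = +Δ)
  and restored by the resistant mutant (δ_H = 0).

Noise is placed on per-channel log2 intensities, not on ratios, so the
three emitted ratios are mutually consistent: log2(H/M) = log2(H/L) −
log2(M/L) holds elementwise (to machine precision) by construction,
exactly the dependence structure the H/M rescue test relies on. A missing
intensity voids both ratios involving that channel for that replicate.

Sequence windows are 31-mers with an S (80%) or T (20%) phosphoacceptor;
substrate-class windows carry an acidic residue at +3 with probability
``p_motif`` (default 0.83), background windows with probability
``background_acidic_rate``; all other positions are drawn from a fixed
human-proteome-like amino-acid composition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClassifiedSite
from .tables_io import (
    ProteinRecord,
    SiteRecord,
    write_protein_table,
    write_site_table,
)

CLASSES = (
    "substrate_rescued",
    "substrate_partial",
    "off_target",
    "unaffected",
    "compensatory_up_rescued",
)

#: Classes whose sequence windows are biased toward the recognition motif.
MOTIF_BIASED_CLASSES = frozenset(
    {"substrate_rescued", "substrate_partial", "compensatory_up_rescued"}
)

#: Approximate human proteome amino-acid frequencies (fixed built-in table).
BACKGROUND_COMPOSITION: dict[str, float] = {
    "A": 0.0702, "R": 0.0564, "N": 0.0359, "D": 0.0473, "C": 0.0230,
    "Q": 0.0477, "E": 0.0710, "G": 0.0657, "H": 0.0263, "I": 0.0433,
    "L": 0.0996, "K": 0.0573, "M": 0.0213, "F": 0.0365, "P": 0.0631,
    "S": 0.0833, "T": 0.0536, "W": 0.0122, "Y": 0.0267, "V": 0.0597,
}

_MULTIPLICITY_PROBS = (0.6, 0.3, 0.1)
WINDOW_LENGTH = 31
_CENTER = WINDOW_LENGTH // 2

#: Acidic probability at +1/+2 in motif-carrying windows: acidophilic
#: kinase substrates show an acidic stretch downstream of the
#: phosphoacceptor, not just the +3 determinant.
FLANK_ACIDIC_RATE = 0.35


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; defaults mirror the study design.

    ``delta`` is the planted inhibition effect in log2 units (1.5 ≈
    2.8-fold); ``sigma`` is the per-channel intensity noise SD in log2
    units; ``localization_beta_params`` of ``None`` makes every site
    perfectly localized.
    """

    n_sites: int = 2000
    n_replicates: int = 5
    class_proportions: dict = field(
        default_factory=lambda: {
            "substrate_rescued": 0.05,
            "substrate_partial": 0.05,
            "off_target": 0.05,
            "unaffected": 0.80,
            "compensatory_up_rescued": 0.05,
        }
    )
    delta: float = 1.5
    partial_fraction_restored: float = 0.5
    sigma: float = 0.3
    missing_rate: float = 0.1
    p_motif: float = 0.83
    background_acidic_rate: float = 0.12
    localization_beta_params: tuple[float, float] | None = (8.0, 1.0)
    contaminant_rate: float = 0.01
    reverse_rate: float = 0.01
    n_proteins: int | None = None
    n_protein_driven: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        for name in (
            "missing_rate", "p_motif", "background_acidic_rate",
            "contaminant_rate", "reverse_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not 0.0 < self.partial_fraction_restored < 1.0:
            raise ValueError("partial_fraction_restored must be in (0, 1)")

    def resolved_n_proteins(self) -> int:
        return self.n_proteins if self.n_proteins is not None else max(
            1, self.n_sites // 2
        )


def zero_noise_config(n_sites: int = 500, seed: int = 0, **overrides) -> SyntheticConfig:
    """Noise-free, complete-data configuration: classification is forced."""
    kwargs = dict(
        n_sites=n_sites,
        sigma=0.0,
        missing_rate=0.0,
        localization_beta_params=None,
        contaminant_rate=0.0,
        reverse_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def benchmark_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Moderate-noise benchmark: σ = 0.3, Δ = 1.5, 2,000 sites, 5 replicates.

    Complete data (no missingness or localization attrition) so the
    benchmark measures the classifier's statistical recovery rather than
    QC attrition, which is exercised separately.
    """
    kwargs = dict(
        n_sites=2000,
        sigma=0.3,
        missing_rate=0.0,
        localization_beta_params=None,
        contaminant_rate=0.0,
        reverse_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def _class_deltas(labels: np.ndarray, delta: float, pf: float) -> tuple[np.ndarray, np.ndarray]:
    table = {
        "substrate_rescued": (-delta, 0.0),
        "substrate_partial": (-delta, -delta * (1.0 - pf)),
        "off_target": (-delta, -delta),
        "unaffected": (0.0, 0.0),
        "compensatory_up_rescued": (delta, 0.0),
    }
    delta_m = np.array([table[c][0] for c in labels])
    delta_h = np.array([table[c][1] for c in labels])
    return delta_m, delta_h


def _ratio_block(
    rng: np.random.Generator,
    delta_m: np.ndarray,
    delta_h: np.ndarray,
    sigma: float,
    n_replicates: int,
    missing_rate: float,
) -> dict[str, np.ndarray]:
    """Linear-scale per-replicate ratios from noisy log2 channel intensities."""
    n = delta_m.size
    beta = rng.normal(25.0, 2.0, size=n)[:, None]
    noise = rng.normal(0.0, 1.0, size=(n, 3, n_replicates)) * sigma
    light = beta + noise[:, 0]
    medium = beta + delta_m[:, None] + noise[:, 1]
    heavy = beta + delta_h[:, None] + noise[:, 2]
    present = rng.random(size=(n, 3, n_replicates)) >= missing_rate
    ml = np.where(present[:, 1] & present[:, 0], medium - light, np.nan)
    hl = np.where(present[:, 2] & present[:, 0], heavy - light, np.nan)
    hm = np.where(present[:, 2] & present[:, 1], heavy - medium, np.nan)
    return {"M/L": np.exp2(ml), "H/L": np.exp2(hl), "H/M": np.exp2(hm)}


def _draw_windows(
    rng: np.random.Generator,
    motif_biased: np.ndarray,
    p_motif: float,
    background_rate: float,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Sequence windows, planted-motif flags, and center residues."""
    n = motif_biased.size
    letters = np.array(list(BACKGROUND_COMPOSITION))
    probs = np.array(list(BACKGROUND_COMPOSITION.values()))
    probs = probs / probs.sum()
    grid = rng.choice(letters, size=(n, WINDOW_LENGTH), p=probs)
    center_is_s = rng.random(n) < 0.8
    p_acidic = np.where(motif_biased, p_motif, background_rate)
    motif_planted = rng.random(n) < p_acidic
    acidic_is_d = rng.random(n) < 0.5
    non_acidic = [a for a in BACKGROUND_COMPOSITION if a not in "DE"]
    na_probs = np.array([BACKGROUND_COMPOSITION[a] for a in non_acidic])
    na_probs = na_probs / na_probs.sum()
    substitutes = rng.choice(np.array(non_acidic), size=n, p=na_probs)
    centers = np.where(center_is_s, "S", "T")
    grid[:, _CENTER] = centers
    grid[:, _CENTER + 3] = np.where(
        motif_planted, np.where(acidic_is_d, "D", "E"), substitutes
    )
    # acidic flank at +1/+2 accompanies a planted motif
    for offset in (1, 2):
        flank = motif_planted & (rng.random(n) < FLANK_ACIDIC_RATE)
        flank_is_d = rng.random(n) < 0.5
        grid[:, _CENTER + offset] = np.where(
            flank, np.where(flank_is_d, "D", "E"), grid[:, _CENTER + offset]
        )
    windows = ["".join(row) for row in grid]
    return windows, motif_planted, centers


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[SiteRecord], list[ProteinRecord], pd.DataFrame]:
    """Generate matched phosphosite and protein tables with ground truth.

    All randomness flows from ``config.seed``; identical configs yield
    identical records. The ground truth is a DataFrame indexed by site id
    with the planted class, effects, motif flag and confounder flag.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    n_proteins = config.resolved_n_proteins()

    counts = rng.multinomial(
        n, [config.class_proportions.get(c, 0.0) for c in CLASSES]
    )
    labels = np.repeat(np.array(CLASSES, dtype=object), counts)
    labels = labels[rng.permutation(n)]

    protein_idx = rng.integers(0, n_proteins, size=n)
    # confounded sites get dedicated proteins carrying the same planted effect
    protein_driven = np.zeros(n, dtype=bool)
    if config.n_protein_driven > 0:
        unaffected_pos = np.flatnonzero(labels == "unaffected")
        if unaffected_pos.size < config.n_protein_driven:
            raise ValueError(
                "not enough unaffected sites to plant the protein-driven subset"
            )
        chosen = rng.choice(
            unaffected_pos, size=config.n_protein_driven, replace=False
        )
        protein_driven[chosen] = True
        for k, pos in enumerate(chosen):
            protein_idx[pos] = n_proteins + k
    total_proteins = n_proteins + config.n_protein_driven

    # unique (protein, position) pairs: sequential slots within each protein
    positions = np.zeros(n, dtype=int)
    next_slot: dict[int, int] = {}
    for i in range(n):
        slot = next_slot.get(protein_idx[i], 0)
        next_slot[protein_idx[i]] = slot + 1
        positions[i] = 5 + 13 * slot

    if config.localization_beta_params is None:
        loc_probs = np.ones(n)
    else:
        a, b = config.localization_beta_params
        loc_probs = rng.beta(a, b, size=n)
    reverse = rng.random(n) < config.reverse_rate
    contaminant = rng.random(n) < config.contaminant_rate
    multiplicities = rng.choice([1, 2, 3], size=n, p=_MULTIPLICITY_PROBS)

    motif_biased = np.array([c in MOTIF_BIASED_CLASSES for c in labels])
    windows, motif_planted, centers = _draw_windows(
        rng, motif_biased, config.p_motif, config.background_acidic_rate
    )

    delta_m, delta_h = _class_deltas(
        labels, config.delta, config.partial_fraction_restored
    )
    delta_m = np.where(protein_driven, -config.delta, delta_m)
    delta_h = np.where(protein_driven, -config.delta, delta_h)
    ratios = _ratio_block(
        rng, delta_m, delta_h, config.sigma, config.n_replicates,
        config.missing_rate,
    )

    site_records: list[SiteRecord] = []
    truth_rows = []
    for i in range(n):
        site_id = f"S{i:05d}"
        accession = f"P{protein_idx[i]:05d}"
        site_records.append(
            SiteRecord(
                site_id=site_id,
                protein_ids=(accession,),
                gene_names=(f"G{protein_idx[i]:05d}",),
                position=int(positions[i]),
                amino_acid=str(centers[i]),
                localization_prob=float(loc_probs[i]),
                multiplicity=int(multiplicities[i]),
                sequence_window=windows[i],
                is_reverse=bool(reverse[i]),
                is_contaminant=bool(contaminant[i]),
                ratios={
                    ch: tuple(float(v) for v in ratios[ch][i]) for ch in ratios
                },
            )
        )
        truth_rows.append(
            {
                "site_id": site_id,
                "class_label": labels[i],
                "delta_m": float(delta_m[i]),
                "delta_h": float(delta_h[i]),
                "motif_planted": bool(motif_planted[i]),
                "protein_driven": bool(protein_driven[i]),
                "leading_protein": accession,
                "multiplicity": int(multiplicities[i]),
            }
        )

    driven_proteins = set(int(j) for j in protein_idx[protein_driven])
    p_delta_m = np.array(
        [-config.delta if j in driven_proteins else 0.0 for j in range(total_proteins)]
    )
    p_delta_h = p_delta_m.copy()
    p_ratios = _ratio_block(
        rng, p_delta_m, p_delta_h, config.sigma, config.n_replicates,
        config.missing_rate,
    )
    protein_records = [
        ProteinRecord(
            protein_ids=(f"P{j:05d}",),
            gene_names=(f"G{j:05d}",),
            is_reverse=False,
            is_contaminant=False,
            ratios={
                ch: tuple(float(v) for v in p_ratios[ch][j]) for ch in p_ratios
            },
        )
        for j in range(total_proteins)
    ]

    truth = pd.DataFrame(truth_rows).set_index("site_id")
    return site_records, protein_records, truth


def emit_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the dataset in the MaxQuant dialect.

    Writes the phosphosite table, the protein-group table, the ground-truth
    TSV and the configuration as JSON; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites, proteins, truth = generate_dataset(config)
    paths = {
        "sites": out / "phospho_sites.tsv",
        "proteins": out / "protein_groups.tsv",
        "truth": out / "ground_truth.tsv",
        "config": out / "synthetic_config.json",
    }
    write_site_table(sites, paths["sites"])
    write_protein_table(proteins, paths["proteins"])
    truth.to_csv(paths["truth"], sep="\t")
    cfg = dataclasses.asdict(config)
    if cfg["localization_beta_params"] is not None:
        cfg["localization_beta_params"] = list(cfg["localization_beta_params"])
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    return paths


#: Expected rescue label for each planted class under correct classification.
EXPECTED_CALL = {
    "substrate_rescued": "rescued",
    "substrate_partial": "partially_rescued",
    "off_target": "not_rescued",
    "unaffected": "none",
    "compensatory_up_rescued": "rescued",
}


@dataclass(frozen=True)
class RecoveryReport:
    """Confusion matrix and per-class operating characteristics."""

    confusion: pd.DataFrame  # planted class (rows) × observed label (cols)
    sensitivity: dict[str, float | None]
    specificity: dict[str, float | None]
    accuracy: float

    def is_diagonal(self) -> bool:
        """True iff every record received exactly its expected label."""
        return self.accuracy == 1.0


def _observed_label(site: ClassifiedSite) -> str:
    return "none" if site.call.rescue == "not_applicable" else site.call.rescue


def evaluate_recovery(
    classified: Sequence[ClassifiedSite], truth: pd.DataFrame
) -> RecoveryReport:
    """Compare rescue calls with the planted ground truth.

    Records present in the truth but absent from ``classified`` (removed by
    QC filtering) are scored as ``filtered``. Sensitivity of a class is the
    fraction of its planted records receiving the expected label;
    specificity of a label is the fraction of records *not* expecting that
    label that did not receive it. Classes with no planted records report
    ``None``.
    """
    observed = {c.record.site_id: _observed_label(c) for c in classified}
    unknown = set(observed) - set(truth.index)
    if unknown:
        raise ValueError(
            f"classified records missing from truth: {sorted(unknown)[:5]}"
        )
    df = pd.DataFrame(
        {
            "class_label": truth["class_label"],
            "observed": [
                observed.get(site_id, "filtered") for site_id in truth.index
            ],
        }
    )
    df["expected"] = df["class_label"].map(EXPECTED_CALL)
    confusion = pd.crosstab(df["class_label"], df["observed"])
    sensitivity: dict[str, float | None] = {}
    for cls in CLASSES:
        sub = df[df["class_label"] == cls]
        sensitivity[cls] = (
            None if sub.empty else float((sub["observed"] == sub["expected"]).mean())
        )
    specificity: dict[str, float | None] = {}
    for label in ("rescued", "partially_rescued", "not_rescued"):
        neg = df[df["expected"] != label]
        specificity[label] = (
            None if neg.empty else float((neg["observed"] != label).mean())
        )
    accuracy = float((df["observed"] == df["expected"]).mean())
    return RecoveryReport(
        confusion=confusion,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
    )
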