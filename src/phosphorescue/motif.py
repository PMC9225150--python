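"""Sequence-context analysis of phosphosite windows.

CSNK2 is an acidophilic Ser/Thr kinase whose minimal recognition motif is
[S/T]-x-x-[D/E]: an acidic residue three positions downstream of the
phosphoacceptor. :func:`adheres_to_motif` applies exactly that minimal
rule; the extended acidic preference (+1, +2 and further downstream) is
visible in the position frequency matrix / information-content profile
produced by :func:`build_motif_profile`, the quantities a WebLogo-style
sequence logo displays.

Proline at +1, reported as a negative determinant in vitro but in fact
prevalent among cellular substrates, is never penalized here: adherence is
decided by the +3 residue alone, and the profile reports +1 composition
faithfully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import PLACEHOLDER

#: The 20 canonical amino acids.
ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")

MAX_IC_BITS = math.log2(20)

DEFAULT_HALFWIDTH = 15  # MaxQuant emits 31-residue windows


@dataclass(frozen=True)
class MotifProfile:
    """Position frequency matrix with per-position information content.

    ``counts`` and ``frequencies`` are residue × position DataFrames with
    positions −halfwidth..+halfwidth (0 = phosphoacceptor); placeholder
    characters from terminus padding are excluded from the tallies.
    ``information_content`` is log2(20) − Shannon entropy per position, in
    bits; positions with no observed residues report NaN.
    """

    window_halfwidth: int
    counts: pd.DataFrame
    frequencies: pd.DataFrame
    information_content: pd.Series
    n_windows: int


def adheres_to_motif(sequence_window: str) -> bool:
    """True iff the window matches the minimal [S/T]-x-x-[D/E] motif.

    The window must be odd-length and centered on the phosphoacceptor.
    Tyrosine-centered windows and windows whose +3 position is padding or
    beyond the window never adhere.
    """
    if len(sequence_window) % 2 == 0:
        raise ValueError(
            f"sequence window length must be odd, got {len(sequence_window)}"
        )
    center = len(sequence_window) // 2
    if sequence_window[center] not in "ST":
        return False
    plus3 = center + 3
    if plus3 >= len(sequence_window):
        return False
    return sequence_window[plus3] in "DE"


def motif_adherence_rate(windows: list[str]) -> tuple[int, float]:
    """Number and fraction of windows matching the minimal motif."""
    if not windows:
        return 0, 0.0
    adherent = sum(adheres_to_motif(w) for w in windows)
    return adherent, adherent / len(windows)


def _fit_window(window: str, width: int) -> str:
    """Center-trim or placeholder-pad a window to the target odd width."""
    if len(window) % 2 == 0:
        raise ValueError(f"sequence window length must be odd, got {len(window)}")
    if len(window) > width:
        excess = (len(window) - width) // 2
        return window[excess : excess + width]
    pad = (width - len(window)) // 2
    return PLACEHOLDER * pad + window + PLACEHOLDER * pad


def build_motif_profile(
    windows: list[str], halfwidth: int = DEFAULT_HALFWIDTH
) -> MotifProfile:
    """Tally aligned windows into a PFM with per-position IC in bits.

    Background is uniform over the 20 residues, without small-sample
    correction (plain WebLogo convention), so IC per position lies in
    [0, log2 20].
    """
    width = 2 * halfwidth + 1
    positions = list(range(-halfwidth, halfwidth + 1))
    counts = np.zeros((len(ALPHABET), width), dtype=int)
    index = {aa: i for i, aa in enumerate(ALPHABET)}
    for window in windows:
        fitted = _fit_window(window, width)
        for j, ch in enumerate(fitted):
            if ch == PLACEHOLDER:
                continue
            try:
                counts[index[ch], j] += 1
            except KeyError:
                raise ValueError(
                    f"residue {ch!r} is not one of the 20 amino acids"
                ) from None
    counts_df = pd.DataFrame(counts, index=list(ALPHABET), columns=positions)
    totals = counts_df.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts_df / totals
    ic = []
    for pos in positions:
        if totals[pos] == 0:
            ic.append(math.nan)
            continue
        f = freqs[pos].to_numpy()
        nz = f[f > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic.append(MAX_IC_BITS - entropy)
    return MotifProfile(
        window_halfwidth=halfwidth,
        counts=counts_df,
        frequencies=freqs.fillna(0.0),
        information_content=pd.Series(ic, index=positions, name="ic_bits"),
        n_windows=len(windows),
    )
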