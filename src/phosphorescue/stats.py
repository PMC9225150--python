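"""Per-channel summary statistics for log2 SILAC ratios.

Each record/channel gets a one-sample Student t-test of the replicate log2
ratios against zero (no regulation), and Benjamini–Hochberg adjusted
q-values computed across the whole test family of a channel. Sites and
protein groups are corrected as separate families, matching column-wise
testing in Perseus.

Degenerate inputs follow the continuous limit: a channel whose replicates
are identical and nonzero has infinite evidence against the null (t = ±inf,
p = 0); identical-and-zero replicates carry no evidence either way and the
statistic is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .tables_io import CHANNELS, ProteinRecord, SiteRecord

DEFAULT_MIN_VALID = 3


@dataclass(frozen=True)
class RatioStats:
    """Summary of one channel's replicate log2 ratios for one record.

    ``t_stat``/``p_value``/``q_value`` are ``None`` when undefined (too few
    valid replicates, or zero variance around zero); ``reason`` records why.
    """

    channel: str
    n_valid: int
    mean_log2: float | None
    sd_log2: float | None
    t_stat: float | None
    p_value: float | None
    q_value: float | None = None
    reason: str | None = None


def one_sample_ttest(values: Sequence[float]) -> tuple[float | None, float | None]:
    """Two-sided one-sample t-test of ``values`` against zero.

    Returns ``(t, p)`` with t = mean / (sd/sqrt(n)) on n−1 degrees of
    freedom, or ``(None, None)`` if fewer than two finite values are given
    or the values are constant at zero. Constant nonzero values return the
    limit ``(±inf, 0.0)``.
    """
    vals = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    n = vals.size
    if n < 2:
        return None, None
    mean = vals.mean()
    sd = vals.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return None, None
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def bh_adjust(p_values: Sequence[float | None]) -> list[float | None]:
    """Benjamini–Hochberg step-up adjustment preserving input order.

    ``None`` entries are excluded from the family and returned as ``None``;
    the family size m is the number of defined p-values. Defined p-values
    must lie in [0, 1].
    """
    defined_idx = [i for i, p in enumerate(p_values) if p is not None]
    defined = [p_values[i] for i in defined_idx]
    for p in defined:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    out: list[float | None] = [None] * len(p_values)
    if defined:
        q = multipletests(defined, method="fdr_bh")[1]
        for i, qi in zip(defined_idx, q):
            out[i] = float(qi)
    return out


def channel_stats(
    record: SiteRecord | ProteinRecord, min_valid: int = DEFAULT_MIN_VALID
) -> dict[str, RatioStats]:
    """Per-channel statistics for one log2-transformed record (no q yet).

    Channels with fewer than ``min_valid`` non-missing replicates get
    undefined test statistics; mean/sd are still reported when at least one
    (resp. two) values exist.
    """
    out: dict[str, RatioStats] = {}
    for channel in CHANNELS:
        values = record.ratios.get(channel, ())
        vals = [v for v in values if not math.isnan(v)]
        n = len(vals)
        mean = float(np.mean(vals)) if n >= 1 else None
        sd = float(np.std(vals, ddof=1)) if n >= 2 else None
        if n < min_valid:
            out[channel] = RatioStats(
                channel, n, mean, sd, None, None,
                reason=f"fewer than {min_valid} valid replicates",
            )
            continue
        t, p = one_sample_ttest(vals)
        reason = "zero variance at zero mean" if t is None else None
        out[channel] = RatioStats(channel, n, mean, sd, t, p, reason=reason)
    return out


def compute_stats(
    records: Sequence[SiteRecord] | Sequence[ProteinRecord],
    min_valid: int = DEFAULT_MIN_VALID,
) -> list[dict[str, RatioStats]]:
    """Channel statistics for every record, with family-wide BH q-values.

    The BH family is one channel across all given records; call this
    separately for sites and for protein groups so they form separate
    correction families.
    """
    per_record = [channel_stats(r, min_valid) for r in records]
    for channel in CHANNELS:
        ps = [s[channel].p_value for s in per_record]
        qs = bh_adjust(ps)
        for stats_map, q in zip(per_record, qs):
            stats_map[channel] = replace(stats_map[channel], q_value=q)
    return per_record
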