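"""Outlier statistics for SILAC log-ratio distributions.

Significance A scores a single log2 ratio against the robust spread of the
ratio distribution it came from: the distribution is summarised by its
15.87th, 50th and 84.13th percentiles (the points that delimit +/- one
standard deviation under normality), the ratio is converted to a one-sided
robust z-score against the spread on its own side of the median, and the
p-value is the Gaussian upper tail ``0.5 * erfc(z / sqrt(2))``.

Significance B is Significance A computed inside bins of proteins with
similar total intensity, so that abundant proteins — whose ratios are
measured more precisely — are judged against their own, tighter noise
level rather than the pooled spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc
from scipy.stats import false_discovery_control

from .errors import StatisticError

#: Percentiles delimiting one robust standard deviation around the median.
PERCENTILE_LOWER = 15.87
PERCENTILE_UPPER = 84.13

#: Default number of proteins per intensity bin.
DEFAULT_BIN_SIZE = 300

#: Minimum number of ratio-bearing records for the statistic to be defined.
MIN_RECORDS = 3


@dataclass(frozen=True)
class RobustQuantiles:
    """15.87 / 50 / 84.13 percentile summary of a log-ratio distribution."""

    r_minus: float
    r_zero: float
    r_plus: float

    def __post_init__(self) -> None:
        if not (self.r_minus <= self.r_zero <= self.r_plus):
            raise StatisticError(
                f"quantiles out of order: {self.r_minus}, {self.r_zero}, {self.r_plus}"
            )


def robust_quantiles(log_ratios: Sequence[float]) -> RobustQuantiles:
    """Percentile summary of a non-empty collection of finite log ratios.

    Percentiles use linear interpolation between order statistics.
    """
    arr = np.asarray(log_ratios, dtype=float)
    if arr.size == 0:
        raise StatisticError("cannot summarise an empty ratio distribution")
    if not np.all(np.isfinite(arr)):
        raise StatisticError("log ratios must be finite")
    lo, med, hi = np.percentile(arr, [PERCENTILE_LOWER, 50.0, PERCENTILE_UPPER])
    return RobustQuantiles(float(lo), float(med), float(hi))


def significance_a(r: float, q: RobustQuantiles) -> tuple[float, str]:
    """Outlier p-value of a single log2 ratio ``r`` against quantiles ``q``.

    Returns ``(p, side)`` with ``p`` in (0, 0.5] and ``side`` one of
    ``"right"`` (above the median), ``"left"`` or ``"center"`` (exactly at
    the median, where p = 0.5 regardless of spread).

    Raises :class:`StatisticError` if the spread on the needed side is zero.
    """
    if r == q.r_zero:
        return 0.5, "center"
    if r > q.r_zero:
        spread = q.r_plus - q.r_zero
        side = "right"
        z = (r - q.r_zero) / spread if spread > 0 else np.inf
    else:
        spread = q.r_zero - q.r_minus
        side = "left"
        z = (q.r_zero - r) / spread if spread > 0 else np.inf
    if spread <= 0:
        raise StatisticError(f"zero spread on the {side} side: degenerate distribution")
    # clamp so p stays strictly positive when erfc underflows at extreme z
    p = max(float(0.5 * erfc(z / np.sqrt(2.0))), np.finfo(float).tiny)
    return p, side


def _significance_a_vector(values: np.ndarray, q: RobustQuantiles) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised significance A over one bin. Same semantics as the scalar."""
    p = np.full(values.shape, 0.5)
    side = np.full(values.shape, "center", dtype=object)
    above = values > q.r_zero
    below = values < q.r_zero
    if above.any():
        spread = q.r_plus - q.r_zero
        if spread <= 0:
            raise StatisticError("zero spread on the right side: degenerate distribution")
        z = (values[above] - q.r_zero) / spread
        p[above] = 0.5 * erfc(z / np.sqrt(2.0))
        side[above] = "right"
    if below.any():
        spread = q.r_zero - q.r_minus
        if spread <= 0:
            raise StatisticError("zero spread on the left side: degenerate distribution")
        z = (q.r_zero - values[below]) / spread
        p[below] = 0.5 * erfc(z / np.sqrt(2.0))
        side[below] = "left"
    np.maximum(p, np.finfo(float).tiny, out=p)
    return p, side


def bin_sizes(n: int, bin_size: int) -> list[int]:
    """Partition ``n`` intensity-sorted records into consecutive bins.

    Bins hold exactly ``bin_size`` records except the last, which absorbs
    any trailing remainder smaller than ``bin_size`` (so every bin has at
    least ``bin_size`` members unless there are fewer than ``bin_size``
    records in total, in which case there is a single bin).
    """
    if n <= 0:
        return []
    k = max(1, n // bin_size)
    sizes = [bin_size] * (k - 1)
    sizes.append(n - bin_size * (k - 1))
    return sizes


def significance_b(
    records: pd.DataFrame,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Intensity-binned outlier p-values for one replicate.

    ``records`` must carry columns ``protein_id``, ``replicate``,
    ``log2_hl_norm`` and ``total_intensity``; rows with a null ratio are
    excluded before binning. Records are sorted by total intensity
    descending (ties broken by protein_id) and partitioned into bins of at
    least ``bin_size``; significance A is applied within each bin against
    that bin's own quantiles.

    Returns a DataFrame with columns ``protein_id``, ``replicate``,
    ``log2_hl_norm``, ``total_intensity``, ``bin_index``, ``side``,
    ``p_sigb``.
    """
    if bin_size < 10:
        raise StatisticError(f"bin_size must be >= 10, got {bin_size}")
    quantified = records.loc[records["log2_hl_norm"].notna()].copy()
    n = len(quantified)
    if n < MIN_RECORDS:
        raise StatisticError(
            f"significance B needs at least {MIN_RECORDS} quantified proteins, got {n}"
        )
    quantified = quantified.sort_values(
        ["total_intensity", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    sizes = bin_sizes(n, bin_size)
    bin_index = np.repeat(np.arange(len(sizes)), sizes)
    quantified["bin_index"] = bin_index

    p = np.empty(n)
    side = np.empty(n, dtype=object)
    values = quantified["log2_hl_norm"].to_numpy(dtype=float)
    start = 0
    for b, size in enumerate(sizes):
        stop = start + size
        q = robust_quantiles(values[start:stop])
        p[start:stop], side[start:stop] = _significance_a_vector(values[start:stop], q)
        start = stop
    quantified["side"] = side
    quantified["p_sigb"] = p
    cols = [
        "protein_id",
        "replicate",
        "log2_hl_norm",
        "total_intensity",
        "bin_index",
        "side",
        "p_sigb",
    ]
    return quantified[cols]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (optional, off by default
    in the pipeline, which thresholds raw p-values)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)):
        raise StatisticError("p-values must lie in (0, 1]")
    return false_discovery_control(arr, method="bh")
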