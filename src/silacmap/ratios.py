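"""Per-replicate H/L ratio processing.

Two stages sit between the raw protein-group tables and the outlier
statistic:

* a manual ratio fallback — proteins whose upstream software computed no
  ratio, but whose combined channel intensity exceeds a floor (default
  1e6), get ``intensity_h / intensity_l`` as a manually calculated ratio,
  so that strongly bait-enriched proteins with few quantified peptides are
  not lost;
* median centering of the log2 ratios within each replicate, a transparent
  surrogate for the upstream tool's proprietary ratio normalization.

Proteins with signal only in the heavy (bait) channel can never receive a
finite ratio; above the intensity floor they are flagged ``ip_specific``
and reported separately instead of being assigned an infinite ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, NormalizationError

DEFAULT_INTENSITY_THRESHOLD = 1e6

#: Columns of a normalized-record frame.
NORMALIZED_COLUMNS = [
    "protein_id",
    "gene_name",
    "replicate",
    "log2_hl_norm",
    "total_intensity",
    "ratio_provenance",
    "ip_specific",
]


def manual_ratio_fill(
    records: pd.DataFrame,
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
) -> pd.DataFrame:
    """Fill missing ratios from raw channel intensities where total
    intensity exceeds the floor.

    A record qualifies when its ratio is null, ``intensity_h + intensity_l``
    strictly exceeds ``intensity_threshold`` and both channels are positive;
    it then gets ``ratio_hl = intensity_h / intensity_l`` with provenance
    ``"manual"``. Computed ratios are never overwritten. Records with a
    null ratio, no light signal and heavy intensity above the floor are
    flagged ``ip_specific`` (their ratio stays null).

    Raises :class:`DataError` on negative intensities.
    """
    if intensity_threshold <= 0:
        raise DataError(f"intensity_threshold must be positive, got {intensity_threshold}")
    out = records.copy()
    h = out["intensity_h"].to_numpy(dtype=float)
    light = out["intensity_l"].to_numpy(dtype=float)
    if (h < 0).any() or (light < 0).any():
        raise DataError("negative channel intensities")
    missing = out["ratio_hl"].isna().to_numpy()
    fill = missing & (h + light > intensity_threshold) & (h > 0) & (light > 0)
    out.loc[fill, "ratio_hl"] = h[fill] / light[fill]
    out.loc[fill, "ratio_provenance"] = "manual"
    out["ip_specific"] = missing & (light == 0) & (h > intensity_threshold)
    return out


def normalize_replicate(
    records: pd.DataFrame,
    include_manual_in_median: bool = True,
    center: bool = True,
) -> pd.DataFrame:
    """Median-center the log2 ratios of one replicate.

    ``log2_hl_norm = log2(ratio_hl) - median`` where the median is taken
    over all non-null log2 ratios of the replicate (after the manual fill;
    set ``include_manual_in_median=False`` to center on computed ratios
    only). Null ratios propagate as nulls. ``center=False`` skips the
    median shift for inputs whose ratios were already normalized upstream.

    Raises :class:`NormalizationError` if the replicate has no usable ratio.
    """
    out = records.copy()
    ratio = out["ratio_hl"].to_numpy(dtype=float)
    log2 = np.where(np.isnan(ratio), np.nan, np.log2(np.where(ratio > 0, ratio, np.nan)))
    if include_manual_in_median:
        in_median = ~np.isnan(log2)
    else:
        in_median = ~np.isnan(log2) & (out["ratio_provenance"] == "computed").to_numpy()
    if not in_median.any():
        replicate = out["replicate"].iloc[0] if len(out) else "?"
        raise NormalizationError(f"replicate {replicate}: no usable ratios to normalize")
    shift = float(np.median(log2[in_median])) if center else 0.0
    out["log2_hl_norm"] = log2 - shift
    out["total_intensity"] = out["intensity_h"] + out["intensity_l"]
    if "ip_specific" not in out.columns:
        out["ip_specific"] = False
    if "gene_name" not in out.columns:
        out["gene_name"] = out["protein_id"]
    return out[NORMALIZED_COLUMNS]


def normalize_all(
    records: pd.DataFrame,
    include_manual_in_median: bool = True,
    center: bool = True,
) -> pd.DataFrame:
    """Apply :func:`normalize_replicate` to every replicate in ``records``."""
    parts = [
        normalize_replicate(group, include_manual_in_median, center)
        for _, group in records.groupby("replicate", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)
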