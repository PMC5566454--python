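"""Rule-based differential protein abundance.

A protein is called differentially abundant between degraded and intact
cartilage when three criteria hold jointly: the absolute median of the
per-patient log2 abundance ratios is at least 0.75, that absolute
median exceeds the sample standard deviation of the ratios, and the
protein was detected in paired samples from at least ``min_paired``
patients. There is no sampling model and hence no p-value for this
layer; the effect is the median log2 ratio.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import SampleSheet
from .methylation import paired_differences

logger = logging.getLogger(__name__)

__all__ = ["compute_ratios", "call_differential"]


def compute_ratios(proteins: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Per-patient log2 abundance ratios (degraded / intact).

    A patient's ratio is missing whenever either member of the pair is
    undetected. Abundances must be positive where present.
    """
    arr = proteins.to_numpy(dtype=float)
    if np.any(arr[~np.isnan(arr)] <= 0):
        i, j = np.argwhere(~np.isnan(arr) & (arr <= 0))[0]
        raise ValueError(
            f"non-positive abundance at {proteins.index[i]!r}, "
            f"sample {proteins.columns[j]!r}"
        )
    return paired_differences(np.log2(proteins), sheet)


def call_differential(
    ratios: pd.DataFrame,
    min_abs_median: float = 0.75,
    min_paired: int = 5,
) -> pd.DataFrame:
    """Apply the three-way differential-abundance rule to a ratio table.

    Returns a table indexed by protein with the summary statistics
    (``median_ratio``, ``sd_ratio``, ``n_paired``), one flag per
    criterion, the conjunction ``differential``, the signed ``effect``
    (median log2 ratio) and ``direction``. Non-differential proteins are
    retained so each failed criterion can be audited.
    """
    values = ratios.to_numpy(dtype=float)
    n_paired = np.sum(~np.isnan(values), axis=1)
    with np.errstate(all="ignore"):
        median = np.nanmedian(np.where(np.isnan(values), np.nan, values), axis=1)
        sd = np.array([
            np.std(row[~np.isnan(row)], ddof=1) if (~np.isnan(row)).sum() >= 2 else np.nan
            for row in values
        ])
    median[n_paired == 0] = np.nan

    pass_median = np.abs(median) >= min_abs_median
    pass_sd = np.abs(median) > sd
    pass_detection = n_paired >= min_paired
    pass_median &= ~np.isnan(median)
    pass_sd = np.where(np.isnan(sd) | np.isnan(median), False, pass_sd)
    differential = pass_median & pass_sd & pass_detection

    direction = np.where(median > 0, "up", np.where(median < 0, "down", "zero"))
    direction = np.where(np.isnan(median), "zero", direction)
    out = pd.DataFrame(
        {
            "effect": median,
            "median_ratio": median,
            "sd_ratio": sd,
            "n_paired": n_paired,
            "pass_median": pass_median,
            "pass_sd": pass_sd,
            "pass_detection": pass_detection,
            "differential": differential,
            "direction": direction,
        },
        index=ratios.index.rename("feature_id"),
    )
    n_up = int(((out["direction"] == "up") & out["differential"]).sum())
    n_down = int(((out["direction"] == "down") & out["differential"]).sum())
    logger.info(
        "proteomics call: %d of %d proteins differential (%d up, %d down)",
        int(differential.sum()), len(out), n_up, n_down,
    )
    return out
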