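"""Discovery-vs-replication concordance summaries.

For the features declared significant in the discovery cohort, the
summary reports the proportion with the same direction of change in the
replication data and, among those same-direction features, the
proportion that also reach nominal significance (replication p <= 0.05),
plus effect-size correlations over all common features and over the
significant ones. Works identically for gene-level expression tables
and probe-level methylation tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ReplicationSummary", "replication_concordance"]


@dataclass
class ReplicationSummary:
    n_features_common: int
    n_discovery_sig: int
    prop_same_direction: float
    prop_same_direction_and_nominal: float
    r_all: float
    r_sig: float


def replication_concordance(
    discovery: pd.DataFrame,
    repl: pd.DataFrame,
    sig_ids,
    nominal_alpha: float = 0.05,
) -> ReplicationSummary:
    """Concordance of discovery-significant features in a replication cohort.

    Features are first restricted to those present in both tables (a
    symmetric QC restriction); ``sig_ids`` must be a subset of the
    discovery features. Zero replication effects have no direction and
    count as discordant (logged).
    """
    sig_ids = set(sig_ids)
    strays = sig_ids - set(discovery.index)
    if strays:
        raise ValueError(f"sig_ids absent from discovery table: {sorted(strays)[:5]}")
    common = discovery.index.intersection(repl.index)
    if len(common) == 0:
        raise ValueError("no features shared between discovery and replication")
    disc = discovery.loc[common]
    rep = repl.loc[common]
    sig = sorted(sig_ids & set(common))
    n_dropped = len(sig_ids) - len(sig)
    if n_dropped:
        logger.info("replication: %d discovery-significant features failed joint QC", n_dropped)

    with np.errstate(invalid="ignore", divide="ignore"):
        r_all = float(np.corrcoef(disc["effect"], rep["effect"])[0, 1])
        if len(sig) >= 2:
            r_sig = float(
                np.corrcoef(disc.loc[sig, "effect"], rep.loc[sig, "effect"])[0, 1]
            )
        else:
            r_sig = float("nan")

    if sig:
        d_eff = disc.loc[sig, "effect"].to_numpy(dtype=float)
        r_eff = rep.loc[sig, "effect"].to_numpy(dtype=float)
        zero = r_eff == 0
        if zero.any():
            logger.info("replication: %d zero replication effects counted discordant",
                        int(zero.sum()))
        same = (np.sign(d_eff) == np.sign(r_eff)) & ~zero
        prop_same = float(same.mean())
        if same.any():
            nominal = rep.loc[sig, "p"].to_numpy(dtype=float)[same] <= nominal_alpha
            prop_nominal = float(nominal.mean())
        else:
            prop_nominal = float("nan")
    else:
        prop_same = float("nan")
        prop_nominal = float("nan")

    summary = ReplicationSummary(
        n_features_common=int(len(common)),
        n_discovery_sig=len(sig),
        prop_same_direction=prop_same,
        prop_same_direction_and_nominal=prop_nominal,
        r_all=r_all,
        r_sig=r_sig,
    )
    logger.info(
        "replication: %d/%d same direction (%.3f); %.3f of those nominal; "
        "r_all %.3f, r_sig %.3f",
        int(round(prop_same * len(sig))) if sig else 0, len(sig),
        prop_same, prop_nominal, r_all, r_sig,
    )
    return summary
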