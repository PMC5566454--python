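"""Cross-omics overlap, concordance, correlation and the evidence table.

Overlap between two differential feature lists is scored with a
one-sided upper-tail hypergeometric test against the universe of
features quantified in both layers; direction agreement among the
overlapping features is scored with a two-sided exact binomial test at
p0 = 0.5 (doubled smaller tail, capped at 1). The evidence table counts,
for every gene, on how many distinct omics levels it shows differential
regulation, counting methylation once whether the evidence comes from a
DMR overlap or from the promoter-level test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import binomial_two_sided, hypergeometric_upper

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "hypergeometric_overlap",
    "direction_concordance",
    "correlate_effects",
    "build_evidence_table",
]


@dataclass
class OverlapResult:
    n_universe: int = 0
    n_setA: int = 0
    n_setB: int = 0
    n_overlap: int = 0
    p_hypergeometric: float = float("nan")
    concordant: int = 0
    discordant: int = 0
    p_binomial: float = float("nan")


def hypergeometric_overlap(setA: set, setB: set, universe: set) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap of two gene sets."""
    setA, setB, universe = set(setA), set(setB), set(universe)
    strays = (setA | setB) - universe
    if strays:
        raise ValueError(f"ids outside the universe: {sorted(strays)[:5]}")
    k = len(setA & setB)
    res = OverlapResult(
        n_universe=len(universe),
        n_setA=len(setA),
        n_setB=len(setB),
        n_overlap=k,
        p_hypergeometric=hypergeometric_upper(k, len(universe), len(setA), len(setB)),
    )
    logger.info(
        "overlap: %d of (%d x %d) in universe %d, hypergeometric p = %.3g",
        k, res.n_setA, res.n_setB, res.n_universe, res.p_hypergeometric,
    )
    return res


def direction_concordance(
    tableA: pd.DataFrame, tableB: pd.DataFrame, ids
) -> OverlapResult:
    """Exact binomial test of direction agreement over shared features.

    Features with a zero effect on either side have no defined sign and
    are excluded with a logged count.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("no shared features for concordance")
    effA = tableA.loc[ids, "effect"].to_numpy(dtype=float)
    effB = tableB.loc[ids, "effect"].to_numpy(dtype=float)
    usable = (effA != 0) & (effB != 0) & ~np.isnan(effA) & ~np.isnan(effB)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("concordance: %d features with zero/missing effect excluded", n_excluded)
    signs = np.sign(effA[usable]) == np.sign(effB[usable])
    k, n = int(signs.sum()), int(usable.sum())
    res = OverlapResult(
        n_overlap=n,
        concordant=k,
        discordant=n - k,
        p_binomial=binomial_two_sided(k, n) if n else float("nan"),
    )
    logger.info("concordance: %d of %d same direction, binomial p = %.3g",
                k, n, res.p_binomial)
    return res


def correlate_effects(
    tableA: pd.DataFrame, tableB: pd.DataFrame, ids, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation of effect sizes over shared feature ids."""
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("need >= 3 shared features to correlate")
    a = tableA.loc[ids, "effect"].to_numpy(dtype=float)
    b = tableB.loc[ids, "effect"].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the effect vectors")
    if method == "pearson":
        r, p = sps.pearsonr(a, b)
    elif method == "spearman":
        r, p = sps.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def build_evidence_table(
    rna: pd.DataFrame,
    dmr_genes: set,
    promoter: pd.DataFrame,
    protein: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene multi-level evidence flags and level counts.

    The methylation level is counted once, whether the gene overlaps a
    DMR or is significant in the promoter-level test (or both). Flags
    are taken directly from the source tables; no thresholds are
    re-derived here beyond reading the ``significant``/``differential``
    columns produced upstream.
    """
    genes = (
        set(rna.index) | set(dmr_genes) | set(promoter.index) | set(protein.index)
    )
    idx = pd.Index(sorted(genes), name="gene_id")
    rna_de = pd.Series(False, index=idx)
    rna_hits = rna.index[rna["significant"]]
    rna_de.loc[rna_de.index.intersection(rna_hits)] = True
    promoter_dm = pd.Series(False, index=idx)
    prom_hits = promoter.index[promoter["significant"]]
    promoter_dm.loc[promoter_dm.index.intersection(prom_hits)] = True
    dmr_overlap = pd.Series(idx.isin(set(dmr_genes)), index=idx)
    protein_da = pd.Series(False, index=idx)
    prot_hits = protein.index[protein["differential"]]
    protein_da.loc[protein_da.index.intersection(prot_hits)] = True

    meth = dmr_overlap | promoter_dm
    n_levels = rna_de.astype(int) + meth.astype(int) + protein_da.astype(int)

    def _dir(table: pd.DataFrame) -> pd.Series:
        return table["direction"].reindex(idx).fillna("")

    table = pd.DataFrame(
        {
            "rna_de": rna_de,
            "dmr_overlap": dmr_overlap,
            "promoter_dm": promoter_dm,
            "protein_da": protein_da,
            "n_levels": n_levels,
            "dir_rna": _dir(rna),
            "dir_promoter": _dir(promoter),
            "dir_protein": _dir(protein),
        }
    )
    logger.info(
        "evidence table: %d genes, %d with >= 2 levels, %d with all 3 levels",
        len(table), int((n_levels >= 2).sum()), int((n_levels == 3).sum()),
    )
    return table
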