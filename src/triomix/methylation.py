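"""Paired differential CpG methylation, DMR calling and promoter analysis.

The per-probe model is a linear model for tissue status with patient
identity as covariate. On a complete paired design (one intact and one
degraded sample per patient) the status coefficient's t-test is
algebraically the paired t-test on per-patient beta differences, which
is how it is computed here (vectorised across probes); the equivalence
is verified against an explicit blocked linear-model fit in the tests.

A differentially methylated region (DMR) is a run of consecutive
manifest probes containing at least ``min_significant`` probes at
FDR <= 5%, at most ``max_nonsignificant`` non-significant probes, with
no more than 1 kb between adjacent member probes, trimmed so that both
endpoints are significant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleSheet
from .stats import benjamini_hochberg, make_diff_table

logger = logging.getLogger(__name__)

__all__ = [
    "paired_differences",
    "test_probes",
    "call_dmrs",
    "map_dmrs_to_genes",
    "promoter_analysis",
]

PROMOTER_FEATURES = ("TSS200", "TSS1500")


def paired_differences(values: pd.DataFrame, sheet: SampleSheet, cohort: str | None = None) -> pd.DataFrame:
    """Per-patient degraded-minus-intact differences (features x patients)."""
    pairs = sheet.pairs(cohort)
    missing = [s for s in pairs["intact"].tolist() + pairs["degraded"].tolist()
               if s not in values.columns]
    if missing:
        raise ValueError(f"samples in sheet absent from matrix: {missing}")
    deg = values[pairs["degraded"].to_numpy()].to_numpy(dtype=float)
    intact = values[pairs["intact"].to_numpy()].to_numpy(dtype=float)
    return pd.DataFrame(deg - intact, index=values.index, columns=pairs["patient_id"])


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised paired t-test per row; zero-variance rows get p = 1."""
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("paired t-test needs >= 2 complete patient pairs")
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    t[degenerate] = 0.0
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    p[degenerate] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return mean, t, p


def test_probes(beta: pd.DataFrame, sheet: SampleSheet, alpha: float = 0.05) -> pd.DataFrame:
    """Per-probe differential methylation between degraded and intact.

    Returns a DataFrame indexed by probe id with columns ``delta_beta``
    (mean degraded minus intact), ``t``, ``p``, ``q`` (BH across all
    probes) and ``significant`` (q <= alpha). Probes that are constant
    within every pair get delta_beta 0 and p = 1 by convention.
    """
    diffs = paired_differences(beta, sheet)
    mean, t, p = _paired_t(diffs.to_numpy())
    n_degenerate = int((diffs.to_numpy().std(axis=1, ddof=1) == 0).sum())
    if n_degenerate:
        logger.info("%d zero-variance probes assigned p = 1", n_degenerate)
    q = benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "delta_beta": mean,
            "t": t,
            "p": p,
            "q": q,
            "significant": q <= alpha,
        },
        index=diffs.index,
    )
    logger.info("probe test: %d probes, %d significant at q <= %g",
                len(out), int(out["significant"].sum()), alpha)
    return out


def _chrom_runs(
    sig: np.ndarray,
    pos: np.ndarray,
    min_significant: int,
    max_nonsignificant: int,
    max_gap: int,
    nonsig_mode: str,
) -> list[tuple[int, int]]:
    """Greedy left-to-right maximal valid windows on one chromosome.

    Candidate windows start and end at significant probes, contain at
    least ``min_significant`` significant probes, at most
    ``max_nonsignificant`` non-significant probes (in total, or as a
    longest consecutive run when ``nonsig_mode='consecutive'``), and
    have every adjacent-probe gap <= ``max_gap``. Of all valid windows
    the leftmost-starting, longest one is kept, then scanning resumes
    after it; this makes the output disjoint and deterministic.
    """
    n = len(sig)
    out = []
    i = 0
    while i < n:
        if not sig[i]:
            i += 1
            continue
        nonsig_total = 0
        nonsig_run = 0
        n_sig = 1
        best_end = i
        best_nsig = 1
        j = i
        while j + 1 < n:
            if pos[j + 1] - pos[j] > max_gap:
                break
            j += 1
            if sig[j]:
                n_sig += 1
                nonsig_run = 0
                budget = nonsig_total if nonsig_mode == "total" else nonsig_run
                if budget <= max_nonsignificant:
                    best_end = j
                    best_nsig = n_sig
            else:
                nonsig_total += 1
                nonsig_run += 1
                if nonsig_mode == "total" and nonsig_total > max_nonsignificant:
                    break
                if nonsig_mode == "consecutive" and nonsig_run > max_nonsignificant:
                    break
        if best_nsig >= min_significant:
            out.append((i, best_end))
            i = best_end + 1
        else:
            i += 1
    return out


def call_dmrs(
    results: pd.DataFrame,
    manifest: pd.DataFrame,
    min_significant: int = 3,
    max_nonsignificant: int = 3,
    max_gap: int = 1000,
    nonsig_mode: str = "total",
) -> pd.DataFrame:
    """Call DMRs from per-probe results over a position-sorted manifest.

    Returns one row per region with chrom, start, end (0-based
    half-open, spanning member probes), the ordered member probe ids,
    significant/non-significant counts, mean delta-beta and an (empty)
    gene set to be filled by :func:`map_dmrs_to_genes`.
    """
    if nonsig_mode not in ("total", "consecutive"):
        raise ValueError("nonsig_mode must be 'total' or 'consecutive'")
    missing = set(manifest["probe_id"]) - set(results.index)
    if missing:
        raise ValueError(f"results missing {len(missing)} manifest probes")
    rows = []
    for chrom, grp in manifest.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"manifest not position-sorted on {chrom}")
        probe_ids = grp["probe_id"].to_numpy()
        sig = results.loc[probe_ids, "significant"].to_numpy(dtype=bool)
        delta = results.loc[probe_ids, "delta_beta"].to_numpy(dtype=float)
        for i, j in _chrom_runs(sig, pos, min_significant, max_nonsignificant,
                                max_gap, nonsig_mode):
            members = probe_ids[i : j + 1]
            n_sig = int(sig[i : j + 1].sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[i]),
                    "end": int(pos[j]) + 1,
                    "probe_ids": list(members),
                    "n_significant": n_sig,
                    "n_nonsignificant": int(len(members) - n_sig),
                    "mean_delta_beta": float(delta[i : j + 1].mean()),
                    "genes": set(),
                }
            )
    dmrs = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "probe_ids", "n_significant",
                 "n_nonsignificant", "mean_delta_beta", "genes"],
    )
    logger.info("called %d DMRs from %d probes", len(dmrs), len(manifest))
    return dmrs


def map_dmrs_to_genes(
    dmrs: pd.DataFrame,
    gene_models: pd.DataFrame,
    promoter_extension: int = 1500,
) -> pd.DataFrame:
    """Assign genes whose promoter-extended span intersects each DMR.

    A gene's interval is extended by ``promoter_extension`` bp upstream
    of its TSS (strand-aware); any overlap with the DMR span assigns the
    gene. A DMR may receive several genes.
    """
    if promoter_extension < 0:
        raise ValueError("promoter_extension must be >= 0")
    dmrs = dmrs.copy()
    gm = gene_models
    ext_start = np.where(gm["strand"] == "+", gm["start"] - promoter_extension, gm["start"])
    ext_end = np.where(gm["strand"] == "-", gm["end"] + promoter_extension, gm["end"])
    genes_by_chrom = {
        chrom: (ext_start[idx], ext_end[idx], gm["gene_id"].to_numpy()[idx])
        for chrom, idx in gm.groupby("chrom").indices.items()
    }
    assigned = []
    for _, row in dmrs.iterrows():
        hit: set[str] = set()
        if row["chrom"] in genes_by_chrom:
            gs, ge, gid = genes_by_chrom[row["chrom"]]
            mask = (gs < row["end"]) & (ge > row["start"])
            hit = set(gid[mask])
        assigned.append(hit)
    dmrs["genes"] = assigned
    n_unique = len(set().union(*assigned)) if assigned else 0
    logger.info("DMR-gene mapping: %d DMRs overlap %d unique genes "
                "(promoter extension %d bp)", len(dmrs), n_unique, promoter_extension)
    return dmrs


def promoter_analysis(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    sheet: SampleSheet,
    promoter_features: tuple[str, ...] = PROMOTER_FEATURES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene paired t-test on mean promoter beta values.

    For every gene with at least one promoter probe present in the beta
    matrix, the promoter methylation of each sample is the mean beta
    over the gene's promoter probes; genes are then tested with a
    two-sided paired t-test on per-patient differences and corrected
    with BH. Genes without usable promoter probes are excluded (logged).
    """
    prom = manifest[manifest["feature"].isin(promoter_features) & (manifest["gene"] != "")]
    usable = prom[prom["probe_id"].isin(beta.index)]
    n_excluded = prom["gene"].nunique() - usable["gene"].nunique()
    if n_excluded:
        logger.info("promoter analysis: %d genes excluded (no promoter probes in matrix)",
                    n_excluded)
    if usable.empty:
        return make_diff_table([], [], [], alpha=alpha)
    gene_means = (
        beta.loc[usable["probe_id"]]
        .groupby(usable["gene"].to_numpy())
        .mean()
    )
    diffs = paired_differences(gene_means, sheet)
    mean, t, p = _paired_t(diffs.to_numpy())
    table = make_diff_table(gene_means.index, mean, p, extra={"t": t}, alpha=alpha)
    logger.info("promoter analysis: %d genes tested, %d significant at q <= %g",
                len(table), int(table["significant"].sum()), alpha)
    return table
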