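"""Paired negative-binomial differential expression.

The model for each gene is the NB log-linear GLM

    log mu_gs = log(effective library size_s) + b0 + patient_i(s) + beta * status_s

with Var(Y) = mu + phi * mu^2 (NB2). Library composition is normalised
with trimmed-mean-of-M (TMM) scaling factors; dispersions are estimated
by Pearson-residual (pseudo-likelihood) moments from the patient+status
mean model and shrunk toward the common value; the status effect is
tested with a likelihood-ratio chi-square test on 1 df. The fitting is
an iteratively reweighted least-squares routine batched across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, xlogy

from .io import SampleSheet
from .stats import make_diff_table

logger = logging.getLogger(__name__)

__all__ = [
    "NormFactors",
    "DispersionEstimates",
    "tmm_factors",
    "estimate_dispersion",
    "test_de",
    "compute_fpkm",
]

LN2 = float(np.log(2.0))


@dataclass
class NormFactors:
    """TMM scaling factors; effective library size = raw size * factor."""

    factors: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


@dataclass
class DispersionEstimates:
    common: float
    genewise: pd.Series  # raw Pearson-moment estimates, floored at 0
    shrunk: pd.Series    # shrunk toward the common value
    prior_df: float = 10.0


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-M normalisation factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction
    is closest to the mean upper quartile. For every other sample the
    factor is 2 to the precision-weighted mean of per-gene log2 count
    ratios (M-values), after trimming ``trim_m`` from each tail of M and
    ``trim_a`` from each tail of the average abundance A; genes with a
    zero count in either sample are excluded.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    Y = counts.to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    if np.any(lib == 0):
        bad = counts.columns[np.argmax(lib == 0)]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    f75 = np.array([np.quantile(Y[:, j] / lib[j], 0.75) for j in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(Y.shape[1])
    yr, nr = Y[:, ref], lib[ref]
    for j in range(Y.shape[1]):
        if j == ref:
            continue
        ys, ns = Y[:, j], lib[j]
        keep = (ys > 0) & (yr > 0)
        if keep.sum() < 10:
            continue
        m = np.log2((ys[keep] / ns) / (yr[keep] / nr))
        a = 0.5 * np.log2((ys[keep] / ns) * (yr[keep] / nr))
        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m), n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a), n - np.floor(n * trim_a)
        rank_m = sps.rankdata(m, method="ordinal")
        rank_a = sps.rankdata(a, method="ordinal")
        trimmed = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
        if not trimmed.any():
            continue
        w = 1.0 / ((ns - ys[keep]) / (ns * ys[keep]) + (nr - yr[keep]) / (nr * yr[keep]))
        factors[j] = 2.0 ** (np.sum(w[trimmed] * m[trimmed]) / np.sum(w[trimmed]))
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        pd.Series(factors, index=counts.columns, name="tmm_factor"),
        pd.Series(lib, index=counts.columns, name="lib_size"),
    )


def _design(sheet: SampleSheet, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    """Full (intercept + patient + status) and null design matrices."""
    t = sheet.table.set_index("sample_id").loc[list(sample_ids)]
    patients = pd.unique(t["patient_id"])
    n = len(t)
    cols = [np.ones(n)]
    for pat in patients[1:]:
        cols.append((t["patient_id"] == pat).to_numpy(dtype=float))
    x0 = np.column_stack(cols)
    status = (t["status"] == "degraded").to_numpy(dtype=float)
    x1 = np.column_stack([x0, status])
    return x1, x0


def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for the NB (or Poisson when phi=0) log-linear model.

    Returns (beta, mu, loglik, converged) with shapes (g,p), (g,s), (g,), (g,).
    """
    g, s = Y.shape
    p = X.shape[1]
    eta = np.log(Y + 0.5) - offset
    beta = np.zeros((g, p))
    converged = np.zeros(g, dtype=bool)
    ridge = 1e-10 * np.eye(p)
    phi_col = phi[:, None]

    active = np.arange(g)
    for _ in range(max_iter):
        if active.size == 0:
            break
        eta_a = eta[active]
        mu = np.exp(np.clip(eta_a + offset, -30.0, 30.0))
        w = mu / (1.0 + phi_col[active] * mu)
        z = eta_a + (Y[active] - mu) / mu
        A = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True) + ridge
        b = np.einsum("sp,gs->gp", X, w * z, optimize=True)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta[active]), axis=1)
        scale = 1.0 + np.max(np.abs(new_beta), axis=1)
        beta[active] = new_beta
        eta[active] = np.clip(new_beta @ X.T, -30.0 - offset.max(), 30.0 - offset.min())
        done = delta < tol * scale
        converged[active[done]] = True
        active = active[~done]

    mu = np.exp(np.clip(eta + offset, -30.0, 30.0))
    ll = np.empty(g)
    pois = phi == 0
    if pois.any():
        m = mu[pois]
        ll[pois] = np.sum(xlogy(Y[pois], m) - m - gammaln(Y[pois] + 1.0), axis=1)
    if (~pois).any():
        r = 1.0 / phi[~pois][:, None]
        m = mu[~pois]
        y = Y[~pois]
        ll[~pois] = np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(r / (r + m)) + xlogy(y, m / (r + m)),
            axis=1,
        )
    return beta, mu, ll, converged


def _pearson_phi(Y: np.ndarray, mu: np.ndarray, df: float) -> np.ndarray:
    """Solve sum_s (y-mu)^2/(mu+phi*mu^2) = df for phi per row (floored at 0)."""
    resid2 = (Y - mu) ** 2
    def stat(phi):
        return np.sum(resid2 / (mu + phi[:, None] * mu**2), axis=1)

    g = Y.shape[0]
    lo = np.zeros(g)
    hi = np.full(g, 100.0)
    at_zero = stat(lo) <= df
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_big = stat(mid) > df
        lo = np.where(too_big, mid, lo)
        hi = np.where(too_big, hi, mid)
    phi = 0.5 * (lo + hi)
    phi[at_zero] = 0.0
    return phi


def estimate_dispersion(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    norm: NormFactors,
    prior_df: float = 10.0,
) -> DispersionEstimates:
    """Common and shrunk gene-wise NB dispersions.

    Gene-wise estimates solve the Pearson chi-square moment equation
    under fitted patient+status Poisson means; the common value solves
    the pooled equation. Shrinkage weight on the common value is
    prior_df / (prior_df + residual_df). All-zero genes are dropped
    (logged) to mirror a post-QC expressed-gene universe.
    """
    expressed = counts.sum(axis=1) > 0
    n_dropped = int((~expressed).sum())
    if n_dropped:
        logger.info("dispersion estimation: %d all-zero genes dropped", n_dropped)
    Y = counts.loc[expressed].to_numpy(dtype=float)
    X1, _ = _design(sheet, counts.columns)
    offset = np.log(norm.effective_lib_sizes.loc[counts.columns].to_numpy())
    df = Y.shape[1] - X1.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom for dispersion estimation")

    _, mu, _, _ = _irls_nb(Y, X1, offset, np.zeros(Y.shape[0]))
    resid2 = (Y - mu) ** 2

    def pooled(phi: float) -> float:
        return float(np.sum(resid2 / (mu + phi * mu**2)))

    target = Y.shape[0] * df
    if pooled(0.0) <= target:
        common = 0.0
    else:
        lo, hi = 0.0, 100.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if pooled(mid) > target:
                lo = mid
            else:
                hi = mid
        common = 0.5 * (lo + hi)

    genewise = _pearson_phi(Y, mu, float(df))
    w = prior_df / (prior_df + df)
    shrunk = w * common + (1.0 - w) * genewise
    idx = counts.index[expressed]
    logger.info("dispersion: common %.4f over %d genes (residual df %d)",
                common, len(idx), df)
    return DispersionEstimates(
        common=float(common),
        genewise=pd.Series(genewise, index=idx, name="dispersion"),
        shrunk=pd.Series(shrunk, index=idx, name="dispersion"),
        prior_df=prior_df,
    )


def test_de(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    norm: NormFactors | None = None,
    disp: DispersionEstimates | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired NB differential expression (degraded vs intact).

    Fits the full (patient + status) and null (patient only) NB GLMs per
    gene and tests the status coefficient with a likelihood-ratio
    chi-square test on 1 df. Returns a differential table indexed by
    gene with ``effect`` = log2 fold-change, ``p``, BH ``q``,
    ``direction`` and ``significant`` columns; genes whose fits did not
    converge carry missing p and are excluded from BH (logged), as are
    all-zero genes.
    """
    if norm is None:
        norm = tmm_factors(counts)
    if disp is None:
        disp = estimate_dispersion(counts, sheet, norm)
    expressed = counts.sum(axis=1) > 0
    n_dropped = int((~expressed).sum())
    if n_dropped:
        logger.info("DE test: %d all-zero genes dropped", n_dropped)
    kept = counts.loc[expressed]
    Y = kept.to_numpy(dtype=float)
    X1, X0 = _design(sheet, counts.columns)
    offset = np.log(norm.effective_lib_sizes.loc[counts.columns].to_numpy())
    phi = disp.shrunk.reindex(kept.index).fillna(disp.common).to_numpy()

    beta1, _, ll1, conv1 = _irls_nb(Y, X1, offset, phi)
    _, _, ll0, conv0 = _irls_nb(Y, X0, offset, phi)
    dev = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = sps.chi2.sf(dev, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    ok = conv1 & conv0
    n_flagged = int((~ok).sum())
    if n_flagged:
        logger.info("DE test: %d genes flagged non-converged (p set missing)", n_flagged)
    p[~ok] = np.nan
    effect = beta1[:, -1] / LN2
    table = make_diff_table(
        kept.index, effect, p, extra={"converged": ok, "dispersion": phi}, alpha=alpha
    )
    logger.info("DE test: %d genes tested, %d significant at q <= %g",
                int(ok.sum()), int(table["significant"].sum()), alpha)
    return table


def compute_fpkm(counts: pd.DataFrame, gene_models: pd.DataFrame) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments."""
    lengths = gene_models.set_index("gene_id")["length"].reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][0]
        raise ValueError(f"gene {missing!r} absent from gene models")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = counts.columns[(totals == 0)][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
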