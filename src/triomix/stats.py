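"""Shared statistical plumbing: FDR control and exact overlap tests.

These primitives are used by every analysis layer. The multiple-testing
correction is the Benjamini-Hochberg step-up procedure, applied at a 5%
false-discovery rate throughout the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "benjamini_hochberg",
    "hypergeometric_upper",
    "binomial_two_sided",
    "make_diff_table",
]


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Parameters
    ----------
    p : array-like of float
        Raw p-values, each in (0, 1]. NaN entries are allowed: they are
        excluded from the number of tests ``m`` and propagate as NaN.

    Returns
    -------
    numpy.ndarray
        q-values in the input order, ``q_i = min_{j >= rank(i)} p_(j) * m / j``
        capped at 1.

    Raises
    ------
    ValueError
        If any non-missing p-value lies outside (0, 1].
    """
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    vals = flat[mask]
    if vals.size and (np.any(vals <= 0) or np.any(vals > 1)):
        bad = vals[(vals <= 0) | (vals > 1)][0]
        raise ValueError(f"p-values must lie in (0, 1]; got {bad!r}")
    q = np.full(flat.shape, np.nan)
    m = vals.size
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        # step-up: running minimum from the largest p downwards
        qsorted = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(qsorted, 1.0)
        q[mask] = out
    return q.reshape(p.shape)


def hypergeometric_upper(k: int, n_universe: int, n_setA: int, n_setB: int) -> float:
    """One-sided upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when ``n_setB`` items are drawn without replacement
    from a universe of ``n_universe`` items of which ``n_setA`` are marked.
    """
    if not (0 <= n_setA <= n_universe and 0 <= n_setB <= n_universe):
        raise ValueError("set sizes must lie within the universe")
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, n_universe, n_setA, n_setB))


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value as twice the smaller tail, capped at 1.

    This doubled-tail convention (rather than the minimum-likelihood sum)
    is the one used for direction-concordance tests in this pipeline.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    lower = sps.binom.cdf(k, n, p0)
    upper = sps.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def make_diff_table(
    feature_ids,
    effect,
    p,
    extra: dict | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assemble a per-feature differential table with BH q-values.

    Columns: ``effect`` (log2 fold-change or delta-beta), ``p``, ``q``,
    ``direction`` (up/down/zero by the sign of the effect) and
    ``significant`` (q <= alpha). Rows with missing p carry missing q and
    are never significant.
    """
    effect = np.asarray(effect, dtype=float)
    p = np.asarray(p, dtype=float)
    q = benjamini_hochberg(p)
    direction = np.where(effect > 0, "up", np.where(effect < 0, "down", "zero"))
    table = pd.DataFrame(
        {
            "effect": effect,
            "p": p,
            "q": q,
            "direction": direction,
            "significant": (q <= alpha) & ~np.isnan(q),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    if extra:
        for name, col in extra.items():
            table[name] = col
    return table
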