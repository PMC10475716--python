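"""Exact contingency-table tests.

2x2 tables go through scipy. The 2xk Freeman–Halton extension of Fisher's
exact test is implemented here by full enumeration of the margin-fixed
table space in log space, with a seeded Monte Carlo fallback above a
configurable size bound (scipy has no r x c exact test).
"""
from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = ["fisher_exact_2x2", "odds_ratio_estimates", "freeman_halton"]

#: Relative tolerance used when comparing a table's probability against the
#: observed one (standard guard against floating-point ties).
_REL_EPS = 1e-7


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(sample_odds_ratio, p_value)``. The sample OR is ad/bc
    (``inf`` on a zero denominator with non-zero numerator, ``nan`` on
    0/0).
    """
    res = sps.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def odds_ratio_estimates(table) -> dict[str, float]:
    """Odds-ratio estimates for a 2x2 table under both conventions.

    ``cmle`` is the conditional maximum-likelihood estimate (scipy's
    noncentral-hypergeometric fit, the convention that stays finite only
    for interior tables); ``haldane`` adds 0.5 to every cell before the
    cross ratio, which is always finite. The p-value of the exact test
    never uses a continuity correction.
    """
    t = np.asarray(table, dtype=int)
    cmle = float(sps.contingency.odds_ratio(t, kind="conditional").statistic)
    a, b = t[0]
    c, d = t[1]
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return {"cmle": cmle, "haldane": float(haldane)}


def _table_space_size(col_sums: np.ndarray, r1: int) -> float:
    return float(np.prod([min(int(c), r1) + 1 for c in col_sums]))


def freeman_halton(
    table,
    max_tables: float = 2e7,
    n_monte_carlo: int = 200_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-sided exact p-value for a 2xk contingency table.

    Enumerates every table with the observed margins, summing the
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one. Above ``max_tables`` candidate tables, falls
    back to seeded Monte Carlo sampling of the null (pass ``rng``; a
    default-seeded generator is used otherwise so the result stays
    deterministic).

    A table with a zero margin carries probability 1 (the table space is a
    single point): p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError(f"expected a 2xk table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    col_sums = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    if n == 0 or r1 == 0 or r1 == n or (col_sums == 0).all():
        return 1.0
    # Drop empty columns: they do not affect the distribution.
    keep = col_sums > 0
    t = t[:, keep]
    col_sums = col_sums[keep]
    k = t.shape[1]
    if k < 2:
        return 1.0

    lg_cols = [np.array([_log_choose(int(c), a) for a in range(int(c) + 1)])
               for c in col_sums]
    log_denom = _log_choose(n, r1)
    log_p_obs = sum(lg_cols[j][t[0, j]] for j in range(k)) - log_denom
    cutoff = log_p_obs + math.log1p(_REL_EPS)

    if _table_space_size(col_sums, r1) > max_tables:
        return _freeman_halton_mc(col_sums, r1, cutoff, log_denom, lg_cols,
                                  n_monte_carlo, rng)

    # DFS over the k free cells of row 1 with remaining-sum pruning.
    suffix_cap = np.cumsum([int(c) for c in col_sums][::-1])[::-1]
    total = 0.0

    def recurse(j: int, remaining: int, log_num: float) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col_sums[j]:
                lp = log_num + lg_cols[j][remaining] - log_denom
                if lp <= cutoff:
                    total += math.exp(lp)
            return
        cap_rest = suffix_cap[j + 1]
        lo = max(0, remaining - int(cap_rest))
        hi = min(int(col_sums[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, log_num + lg_cols[j][a])

    recurse(0, r1, 0.0)
    return min(total, 1.0)


def _log_choose(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _freeman_halton_mc(col_sums, r1, cutoff, log_denom, lg_cols,
                       n_draws: int, rng: Optional[np.random.Generator]) -> float:
    if rng is None:
        rng = np.random.default_rng(0)
    draws = rng.multivariate_hypergeometric(
        [int(c) for c in col_sums], r1, size=n_draws
    )
    log_p = np.zeros(n_draws)
    for j in range(draws.shape[1]):
        log_p += lg_cols[j][draws[:, j]]
    log_p -= log_denom
    return float(np.mean(log_p <= cutoff))
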