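"""Category statistics for PRF discovery results.

Observed chimeric-peptide counts per category (PRF value, RNA type,
genomic location, type/subtype, sample, ...) are compared against expected
counts derived proportionally from the non-redundant chimeric-model
distribution.  Chi-square tests are used whenever every expected cell is at
least five; otherwise the appropriate exact test is chosen by table shape:
Fisher's exact test for r x c tables, the exact multinomial test for 1 x k,
and the exact binomial test for 1 x 2.  Large exact tests fall back to a
seeded Monte-Carlo (simulated) p-value.  All p-values are two-sided; the
conventional alpha is 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
_REL_TOL = 1 + 1e-9     # pmf comparison tolerance, as in R's exact tests


@dataclass(frozen=True)
class TestResult:
    statistic: Optional[float]
    pvalue: float
    method: str
    df: Optional[int] = None


def expected_from_models(model_counts: Mapping[str, float],
                         total_observed: float,
                         exclude: Sequence[str] = ("other",)) -> dict[str, float]:
    """Expected category counts proportional to the chimeric-model counts.

    Categories named in ``exclude`` (by default the "other" group of models
    from non-overlapping ORFs, which never received peptide support) are
    dropped before normalisation.  The result sums exactly to
    ``total_observed``.
    """
    kept = {k: float(v) for k, v in model_counts.items() if k not in exclude}
    if any(v < 0 for v in kept.values()):
        raise ValueError("negative model counts")
    total = sum(kept.values())
    if total <= 0:
        raise ValueError("all model counts are zero")
    return {k: total_observed * v / total for k, v in kept.items()}


def _exact_multinomial(observed: np.ndarray, probs: np.ndarray,
                       seed: Optional[int], n_mc: int,
                       enumerate_limit: int = 200_000) -> float:
    """Two-sided exact multinomial p: total probability of outcomes no more
    likely than the observed one.  Enumerates when feasible, otherwise uses
    a seeded Monte-Carlo estimate."""
    n = int(observed.sum())
    k = len(observed)
    p_obs = sps.multinomial.pmf(observed, n, probs)
    n_outcomes = math.comb(n + k - 1, k - 1)
    if n_outcomes <= enumerate_limit:
        total = 0.0
        for cuts in itertools.combinations(range(n + k - 1), k - 1):
            counts, prev = [], -1
            for c in cuts:
                counts.append(c - prev - 1)
                prev = c
            counts.append(n + k - 2 - prev)
            p = sps.multinomial.pmf(counts, n, probs)
            if p <= p_obs * _REL_TOL:
                total += p
        return min(1.0, total)
    if seed is None:
        raise ValueError("Monte-Carlo exact multinomial test requires a seed")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=n_mc)
    p_sim = sps.multinomial.pmf(draws, n, probs)
    return (1 + int((p_sim <= p_obs * _REL_TOL).sum())) / (n_mc + 1)


def gof_test(observed: Sequence[float], expected: Sequence[float],
             seed: Optional[int] = None, n_mc: int = 100_000) -> TestResult:
    """Goodness-of-fit of observed counts against expected counts.

    Chi-square when every expected count is >= 5; otherwise the exact
    binomial test for two categories or the exact multinomial test for more
    (Monte-Carlo with ``seed`` when enumeration is infeasible).  Expected
    counts are rescaled to the observed total, which defines the null
    proportions.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be 1-D and equal length")
    if (obs < 0).any() or (exp <= 0).any():
        raise ValueError("counts must be non-negative and expected positive")
    n = obs.sum()
    probs = exp / exp.sum()
    exp_scaled = probs * n

    if (exp_scaled >= 5).all():
        stat = float(((obs - exp_scaled) ** 2 / exp_scaled).sum())
        df = len(obs) - 1
        return TestResult(stat, float(sps.chi2.sf(stat, df)), "chi-square gof", df)
    if len(obs) == 2:
        res = sps.binomtest(int(round(obs[0])), int(round(n)), probs[0])
        return TestResult(None, float(res.pvalue), "exact binomial")
    p = _exact_multinomial(np.round(obs).astype(int), probs, seed, n_mc)
    return TestResult(None, p, "exact multinomial")


def _log_table_prob(table: np.ndarray) -> float:
    """log probability of an r x c table under fixed margins (Fisher null)."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    lg = math.lgamma
    return (sum(lg(x + 1) for x in r) + sum(lg(x + 1) for x in c)
            - lg(n + 1) - sum(lg(x + 1) for x in table.ravel()))


def _enumerate_margin_tables(row_sums, col_sums):
    """Yield every non-negative integer table with the given margins."""
    rows = list(row_sums)
    cols = np.asarray(col_sums, dtype=int)

    def rec(i, remaining):
        if i == len(rows) - 1:
            if (remaining >= 0).all():
                yield [list(remaining)]
            return
        total = rows[i]
        ranges = [range(min(total, remaining[j]) + 1) for j in range(len(cols))]
        for combo in itertools.product(*ranges[:-1]):
            last = total - sum(combo)
            if 0 <= last <= remaining[-1]:
                row = list(combo) + [last]
                for rest in rec(i + 1, remaining - np.asarray(row)):
                    yield [row] + rest

    yield from rec(0, cols.copy())


def _fisher_rxc(table: np.ndarray, seed: Optional[int], n_mc: int,
                enumerate_limit: int = 500_000) -> tuple[float, str]:
    """Two-sided Fisher exact p for an r x c table: total null probability of
    tables (with the observed margins) no more likely than the observed."""
    lp_obs = _log_table_prob(table)
    row_sums = table.sum(axis=1).astype(int)
    col_sums = table.sum(axis=0).astype(int)
    bound = 1
    for rs in row_sums[:-1]:
        for cs in col_sums:
            bound *= min(rs, cs) + 1
        if bound > enumerate_limit:
            break
    if bound <= enumerate_limit:
        total = 0.0
        for t in _enumerate_margin_tables(row_sums, col_sums):
            lp = _log_table_prob(np.asarray(t))
            if lp <= lp_obs + 1e-9:
                total += math.exp(lp)
        return min(1.0, total), "fisher exact (enumerated)"
    if seed is None:
        raise ValueError("Monte-Carlo Fisher test requires a seed")
    rng = np.random.default_rng(seed)
    dist = sps.random_table(row_sums, col_sums)
    sims = dist.rvs(n_mc, random_state=rng)
    lps = np.array([_log_table_prob(t) for t in sims])
    p = (1 + int((lps <= lp_obs + 1e-9).sum())) / (n_mc + 1)
    return p, "fisher exact (simulated p-value)"


def association_test(table: Sequence[Sequence[float]],
                     seed: Optional[int] = None,
                     n_mc: int = 100_000) -> TestResult:
    """Association between the row and column factors of a contingency table.

    Chi-square (without continuity correction, so the statistic matches the
    closed form) when all expected cells are >= 5; otherwise Fisher's exact
    test -- scipy's for 2 x 2, enumeration or a seeded Monte-Carlo simulated
    p-value for larger tables.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (t < 0).any():
        raise ValueError("negative counts")
    chi2, p, df, expected = sps.chi2_contingency(t, correction=False)
    if (expected >= 5).all():
        return TestResult(float(chi2), float(p), "chi-square association", int(df))
    if t.shape == (2, 2):
        res = sps.fisher_exact(np.round(t).astype(int))
        return TestResult(None, float(res.pvalue), "fisher exact")
    pv, method = _fisher_rxc(np.round(t).astype(int), seed, n_mc)
    return TestResult(None, pv, method)
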