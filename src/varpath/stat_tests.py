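"""Goodness-of-fit and homogeneity tests on per-level pathway counts.

The centerpiece is the exact multinomial test: a pathway's level counts
(O_1, ..., O_m) are modeled as Multi(n, p) with p taken from the reference
distribution, and the p-value sums the probabilities of every outcome
vector no more probable than the observed one. The enumeration walks all
C(n+m-1, m-1) compositions of n into m parts — e.g. 496 outcomes for a
30-gene pathway with three levels, 5,151 for 100 genes — so a cap guards
against runaway cost, with the chi-squared test or a Monte-Carlo version
as fallbacks.

All probability work is done in log space; an outcome ties with the
observed one when its log-probability is within 1e-9 (relative), and ties
are counted, so the observed outcome always contributes and p > 0.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom, chi2
from statsmodels.stats.multitest import multipletests

from .errors import EnumerationCapError, ValidationError

__all__ = [
    "DEFAULT_CAP",
    "n_compositions",
    "enumerate_compositions",
    "multinomial_logpmf",
    "ExactMultinomialNull",
    "exact_multinomial_test",
    "monte_carlo_multinomial_test",
    "chisq_test",
    "two_group_test",
    "binomial_level_test",
    "bh_adjust",
    "merge_zero_levels",
]

DEFAULT_CAP = 2_000_000
_LOG_TIE_TOL = 1e-9  # log-space slack ~ relative (1 + 1e-9) on probabilities


def _check_probs(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValidationError("need a probability vector of length >= 2")
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValidationError("probabilities must be finite and >= 0")
    s = p.sum()
    if abs(s - 1.0) > 1e-8:
        raise ValidationError(f"probabilities sum to {s!r}, not 1")
    return p / s


def _check_counts(counts, m: int | None = None) -> np.ndarray:
    o = np.asarray(counts)
    if o.ndim != 1:
        raise ValidationError("counts must be a 1-D vector")
    if np.any(o < 0) or np.any(o != np.floor(o)):
        raise ValidationError("counts must be non-negative integers")
    if m is not None and o.size != m:
        raise ValidationError(f"counts have length {o.size}, expected {m}")
    return o.astype(np.int64)


def n_compositions(n: int, m: int) -> int:
    """Number of ways to write n as an ordered sum of m non-negative
    integers: C(n+m-1, m-1). This is the exact test's enumeration size."""
    return comb(n + m - 1, m - 1)


def enumerate_compositions(n: int, m: int) -> np.ndarray:
    """All compositions of n into m parts, shape (C(n+m-1, m-1), m).

    Deterministic lexicographic order (first coordinate slowest).
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m == 1:
        return np.array([[n]], dtype=np.int64)
    out = np.empty((n_compositions(n, m), m), dtype=np.int64)
    pos = 0
    for first in range(n + 1):
        sub = enumerate_compositions(n - first, m - 1)
        out[pos : pos + len(sub), 0] = first
        out[pos : pos + len(sub), 1:] = sub
        pos += len(sub)
    return out


def multinomial_logpmf(counts: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Log-pmf of Multi(n, probs) at one or many count vectors.

    ``counts`` may be (m,) or (k, m); zero-probability levels contribute 0
    when their count is 0 and -inf otherwise.
    """
    o = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    p = np.asarray(probs, dtype=float)
    n = o.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
        terms = np.where(o > 0, o * logp, 0.0)
    out = gammaln(n + 1) - gammaln(o + 1).sum(axis=1) + terms.sum(axis=1)
    return out if np.asarray(counts).ndim == 2 else out[0]


class ExactMultinomialNull:
    """Pre-enumerated exact multinomial null for repeated testing.

    Builds the full outcome table for Multi(n, probs) once; each p-value
    is then a log-pmf evaluation plus a binary search over the sorted
    outcome probabilities. Useful when many pathways (or simulation
    replicates) share the same n and reference probabilities.
    """

    def __init__(self, n: int, probs, cap: int = DEFAULT_CAP):
        if n < 1:
            raise ValidationError("n must be >= 1")
        self.probs = _check_probs(probs)
        self.n = int(n)
        m = self.probs.size
        total = n_compositions(self.n, m)
        if total > cap:
            raise EnumerationCapError(
                f"exact enumeration needs {total:,} outcome vectors "
                f"(cap {cap:,}); use the chi-squared test or the "
                "Monte-Carlo multinomial test instead"
            )
        self.outcomes = enumerate_compositions(self.n, m)
        lp = multinomial_logpmf(self.outcomes, self.probs)
        order = np.argsort(lp, kind="stable")
        self._sorted_logpmf = lp[order]
        self._cum_prob = np.cumsum(np.exp(self._sorted_logpmf))

    @property
    def n_outcomes(self) -> int:
        """Number of outcome vectors the enumeration visited."""
        return len(self.outcomes)

    def pvalue(self, counts) -> float | np.ndarray:
        """Exact p-value(s); ``counts`` may be (m,) or (k, m)."""
        o = _check_counts_2d(counts, self.probs.size)
        if np.any(o.sum(axis=1) != self.n):
            raise ValidationError(f"counts must sum to n = {self.n}")
        lp = multinomial_logpmf(o, self.probs)
        lp = np.atleast_1d(lp)
        idx = np.searchsorted(self._sorted_logpmf, lp + _LOG_TIE_TOL, side="right")
        pv = np.minimum(self._cum_prob[np.maximum(idx, 1) - 1], 1.0)
        return pv if np.asarray(counts).ndim == 2 else float(pv[0])


def _check_counts_2d(counts, m: int) -> np.ndarray:
    o = np.asarray(counts)
    if o.ndim == 1:
        o = o[None, :]
    if o.ndim != 2 or o.shape[1] != m:
        raise ValidationError(f"counts must have {m} levels")
    if np.any(o < 0) or np.any(o != np.floor(o)):
        raise ValidationError("counts must be non-negative integers")
    return o.astype(np.int64)


def exact_multinomial_test(counts, null_probs, cap: int = DEFAULT_CAP) -> float:
    """Exact multinomial goodness-of-fit p-value by full enumeration.

    P-value = sum of Multi(n, p) probabilities of all outcome vectors whose
    probability is <= that of the observed vector (relative tie tolerance
    1e-9). Raises :class:`EnumerationCapError` when C(n+m-1, m-1) > cap.
    """
    o = _check_counts(counts)
    null = ExactMultinomialNull(int(o.sum()), null_probs, cap=cap)
    return float(null.pvalue(o))


def monte_carlo_multinomial_test(
    counts, null_probs, reps: int = 10_000, seed: int | None = None
) -> float:
    """Monte-Carlo version of the exact test for post-cap pathway sizes.

    p = (1 + #{simulated outcomes no more probable than observed}) / (reps + 1),
    the add-one estimator that keeps the test valid.
    """
    if reps < 1000:
        raise ValidationError("reps must be >= 1000")
    o = _check_counts(counts)
    p = _check_probs(null_probs)
    if np.any((p == 0) & (o > 0)):
        raise ValidationError("observed count in a zero-probability level")
    n = int(o.sum())
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, p, size=reps)
    lp_obs = multinomial_logpmf(o, p)
    lp_sim = multinomial_logpmf(sims, p)
    hits = int(np.count_nonzero(lp_sim <= lp_obs + _LOG_TIE_TOL))
    return (1 + hits) / (reps + 1)


def chisq_test(counts, null_probs) -> tuple[float, float]:
    """Chi-squared goodness-of-fit: X^2 = sum (O_i - E_i)^2 / E_i with
    E_i = n * p_i, compared to chi-squared with m-1 degrees of freedom.

    Returns ``(X2, p_value)``. Levels with p_i = 0 are not allowed here;
    merge them first (see :func:`merge_zero_levels`).
    """
    o = _check_counts(counts)
    p = _check_probs(null_probs)
    if o.size != p.size:
        raise ValidationError("counts and null_probs differ in length")
    n = int(o.sum())
    if n < 1:
        raise ValidationError("counts sum to 0")
    if np.any(p == 0):
        raise ValidationError(
            "null probability 0 in some level; merge zero levels before testing"
        )
    e = n * p
    x2 = float(((o - e) ** 2 / e).sum())
    return x2, float(chi2.sf(x2, df=o.size - 1))


def two_group_test(
    counts_g1,
    counts_g2,
    method: str = "chisq",
    cap: int = DEFAULT_CAP,
) -> float:
    """Test H0: both groups' level counts share one underlying distribution.

    ``chisq`` runs the homogeneity chi-squared on the 2 x m table with
    expected counts from the pooled proportions and m-1 degrees of freedom
    (levels empty in BOTH groups are dropped, reducing the df). ``exact``
    tests group 1's counts against group 2's proportions with the exact
    multinomial test; a 0.5 pseudocount is added to every group-2 level
    when any of them is zero, to avoid an impossible null.
    """
    o1 = _check_counts(counts_g1)
    o2 = _check_counts(counts_g2, m=o1.size)
    keep = (o1 + o2) > 0
    o1, o2 = o1[keep], o2[keep]
    if o1.size < 2:
        raise ValidationError("fewer than 2 non-empty levels; nothing to compare")
    if o1.sum() == 0 or o2.sum() == 0:
        raise ValidationError("all levels empty in one group")

    if method == "chisq":
        table = np.vstack([o1, o2]).astype(float)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        x2 = float(((table - expected) ** 2 / expected).sum())
        return float(chi2.sf(x2, df=o1.size - 1))
    if method == "exact":
        g2 = o2.astype(float)
        if np.any(g2 == 0):
            g2 = g2 + 0.5
        return exact_multinomial_test(o1, g2 / g2.sum(), cap=cap)
    raise ValidationError(f"unknown two-group method {method!r}")


def binomial_level_test(o_i: int, n: int, p_i: float) -> tuple[float, str]:
    """Two-sided exact binomial test for one variability level.

    The two-sided p-value doubles the smaller tail (capped at 1);
    direction is "up" when O_i >= n * p_i, "down" otherwise.
    """
    if not 0 <= o_i <= n:
        raise ValidationError(f"need 0 <= O_i <= n, got O_i={o_i}, n={n}")
    if not 0 < p_i < 1:
        raise ValidationError(f"level probability must be in (0, 1), got {p_i}")
    lower = float(binom.cdf(o_i, n, p_i))
    upper = float(binom.sf(o_i - 1, n, p_i))
    p = min(1.0, 2.0 * min(lower, upper))
    direction = "up" if o_i >= n * p_i else "down"
    return p, direction


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def merge_zero_levels(
    probs, *count_vectors
) -> tuple[np.ndarray, tuple[np.ndarray, ...], list[int]]:
    """Merge levels whose null probability is 0 into the nearest neighbor.

    Returns the reduced probability vector, the reduced count vectors
    (counts from a dropped level are added to its absorbing neighbor —
    the lower one when it exists), and the 1-based indices of merged
    levels. Identity when no probability is zero.
    """
    p = np.asarray(probs, dtype=float)
    counts = [np.asarray(c, dtype=np.int64).copy() for c in count_vectors]
    merged: list[int] = []
    i = 0
    while p.size > 1 and i < p.size:
        if p[i] == 0:
            j = i - 1 if i > 0 else i + 1
            p_new = p.copy()
            p_new[j] += p_new[i]
            p = np.delete(p_new, i)
            for k, c in enumerate(counts):
                c_new = c.copy()
                c_new[j] += c_new[i]
                counts[k] = np.delete(c_new, i)
            merged.append(i + 1)
        else:
            i += 1
    return p, tuple(counts), merged
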