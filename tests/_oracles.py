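"""Independent brute-force oracles, deliberately naive.

These re-derive expected values by direct enumeration in linear
probability space with exact combinatorics, sharing no code with the
package's log-space implementation.
"""

from itertools import product
from math import comb, prod

TIE_REL_TOL = 1e-9


def naive_multinomial_pmf(counts, probs) -> float:
    n = sum(counts)
    coef = 1
    rem = n
    for c in counts:
        coef *= comb(rem, c)
        rem -= c
    return coef * prod(p**c for p, c in zip(probs, counts))


def all_outcomes(n, m):
    """Every vector of m non-negative integers summing to n."""
    for head in product(range(n + 1), repeat=m - 1):
        if sum(head) <= n:
            yield (*head, n - sum(head))


def naive_exact_pvalue(counts, probs) -> float:
    """Sum of probabilities of outcomes no more probable than observed
    (same relative tie tolerance as the implementation under test)."""
    p_obs = naive_multinomial_pmf(counts, probs)
    total = 0.0
    for out in all_outcomes(sum(counts), len(counts)):
        p = naive_multinomial_pmf(out, probs)
        if p <= p_obs * (1 + TIE_REL_TOL):
            total += p
    return min(total, 1.0)


def naive_binomial_twosided(k, n, p) -> float:
    """Two-sided binomial by summing outcomes no more probable than k —
    the m=2 specialization the exact multinomial test must reduce to."""
    return naive_exact_pvalue((k, n - k), (p, 1 - p))
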