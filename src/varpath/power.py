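"""Monte-Carlo power and type-I-error analysis for the pathway tests.

A scenario is a reference probability vector p over the m variability
levels, a perturbed pathway vector q, and a pathway size n_genes; the
effect size is Cohen's w = sqrt(sum (q_i - p_i)^2 / p_i), the standard
chi-squared goodness-of-fit effect size, which makes the noncentral
chi-squared power approximation (noncentrality n_genes * w^2, df m-1)
available as an analytic check.

Simulated power draws pathway count vectors from Multi(n_genes, q) and
records the fraction rejected against p at level alpha; the reported
standard error is the binomial SE of that fraction. Everything is driven
by numpy Generators seeded from one top-level seed: scenario replicate k
uses ``default_rng([seed, k])`` so each point of a grid is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2, ncx2
from sklearn.metrics import adjusted_rand_score

from .errors import ValidationError
from .stat_tests import (
    DEFAULT_CAP,
    ExactMultinomialNull,
    _check_probs,
)

__all__ = [
    "PowerScenario",
    "cohens_w",
    "analytic_chisq_power",
    "simulate_power",
    "simulate_shape_contrast",
    "simulate_estimator_comparison",
]


def cohens_w(p, q) -> float:
    """Chi-squared effect size w = sqrt(sum (q_i - p_i)^2 / p_i)."""
    p = _check_probs(p)
    q = _check_probs(q)
    if p.size != q.size:
        raise ValidationError("p and q differ in length")
    if np.any(p == 0):
        raise ValidationError("reference probabilities must be > 0 for w")
    return float(np.sqrt(((q - p) ** 2 / p).sum()))


@dataclass(frozen=True)
class PowerScenario:
    """One power-simulation condition.

    reference_probs : null level probabilities p (length m)
    pathway_probs   : generating level probabilities q (length m)
    pathway_size    : number of genes n in the simulated pathway
    alpha           : nominal test level
    reps            : Monte-Carlo replicates
    seed            : top-level seed
    test            : "chisq" or "exact"
    """

    reference_probs: tuple[float, ...]
    pathway_probs: tuple[float, ...]
    pathway_size: int
    alpha: float = 0.05
    reps: int = 2000
    seed: int = 0
    test: str = "chisq"

    @property
    def effect_size(self) -> float:
        return cohens_w(self.reference_probs, self.pathway_probs)


def analytic_chisq_power(
    w: float, n_genes: int, m: int, alpha: float = 0.05
) -> float:
    """Noncentral chi-squared approximation to the chi-squared test's power
    at effect size w: noncentrality lambda = n_genes * w^2, df = m - 1."""
    df = m - 1
    crit = chi2.ppf(1 - alpha, df)
    return float(ncx2.sf(crit, df, n_genes * w * w))


def simulate_power(scenario: PowerScenario) -> tuple[float, float]:
    """Estimate rejection probability and its Monte-Carlo standard error.

    Draws ``reps`` multinomial count vectors of size ``pathway_size`` from
    the pathway probabilities and tests each against the reference
    probabilities at level alpha. With q = p this estimates the type-I
    error of the test.
    """
    if scenario.reps < 100:
        raise ValidationError("reps must be >= 100")
    p = _check_probs(scenario.reference_probs)
    q = _check_probs(scenario.pathway_probs)
    if p.size != q.size:
        raise ValidationError("p and q differ in length")
    n, m = scenario.pathway_size, p.size
    rng = np.random.default_rng([scenario.seed, 0])
    counts = rng.multinomial(n, q, size=scenario.reps)

    if scenario.test == "chisq":
        e = n * p
        if np.any(e == 0):
            raise ValidationError("reference probabilities must be > 0")
        x2 = ((counts - e) ** 2 / e).sum(axis=1)
        pvals = chi2.sf(x2, df=m - 1)
    elif scenario.test == "exact":
        null = ExactMultinomialNull(n, p, cap=DEFAULT_CAP)
        pvals = null.pvalue(counts)
    else:
        raise ValidationError(f"unknown test {scenario.test!r}")

    power = float(np.mean(pvals < scenario.alpha))
    se = float(np.sqrt(power * (1 - power) / scenario.reps))
    return power, se


def simulate_shape_contrast(
    skewed_q,
    symmetric_q,
    p,
    n_genes_grid,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
    test: str = "chisq",
) -> pd.DataFrame:
    """Paired power curves for a skewed vs. a symmetric perturbation.

    Both perturbations must carry the same Cohen's w relative to p
    (tolerance 1e-6), so any power difference is attributable to the
    shape of the deviation alone. Returns one row per (shape, n_genes)
    with power and SE.
    """
    w_s = cohens_w(p, skewed_q)
    w_y = cohens_w(p, symmetric_q)
    if abs(w_s - w_y) > 1e-6:
        raise ValidationError(
            f"effect sizes differ: skewed w={w_s:.6f}, symmetric w={w_y:.6f}"
        )
    rows = []
    for shape_idx, (shape, q) in enumerate(
        (("skewed", skewed_q), ("symmetric", symmetric_q))
    ):
        for k, n in enumerate(n_genes_grid):
            sc = PowerScenario(
                reference_probs=tuple(p),
                pathway_probs=tuple(q),
                pathway_size=int(n),
                alpha=alpha,
                reps=reps,
                seed=int(
                    np.random.default_rng([seed, shape_idx, k]).integers(2**31)
                ),
                test=test,
            )
            power, se = simulate_power(sc)
            rows.append(
                {
                    "shape": shape,
                    "n_genes": int(n),
                    "effect_size": w_s,
                    "power": power,
                    "se": se,
                }
            )
    return pd.DataFrame(rows)


def simulate_estimator_comparison(
    config,
    estimators=("sd", "cv", "mad"),
    reps: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare dispersion estimators end-to-end on synthetic matrices.

    For each replicate a full expression matrix with known per-gene
    variability classes is generated, then for each estimator the whole
    pipeline runs (statistic -> mixture levels -> pathway tests). Reported
    per estimator: mean adjusted Rand index between inferred and planted
    level labels, and the fraction of planted pathways detected at
    BH-adjusted alpha.

    ``config`` is a :class:`varpath.synth.GeneratorConfig`; its seed is
    replaced per replicate.
    """
    from .synth import generate  # local import: synth imports estimators
    from .workflow import analyze_one_group

    rows = []
    for r in range(reps):
        rep_seed = int(np.random.default_rng([seed, r]).integers(2**31))
        data = generate(replace(config, seed=rep_seed))
        truth_levels = data.truth.set_index("gene_id")["level"]
        planted = set(data.planted_names)
        for est in estimators:
            res = analyze_one_group(
                data.matrix,
                data.genesets,
                statistic=est,
                seed=rep_seed,
            )
            assign = res.scheme.assignments["all"]
            genes = [g for g in truth_levels.index if g in assign]
            ari = adjusted_rand_score(
                [int(truth_levels[g]) for g in genes],
                [assign[g] for g in genes],
            )
            tab = res.results
            hit = tab[tab["set_name"].isin(planted)]["adj_p_value"] < alpha
            rows.append(
                {
                    "rep": r,
                    "estimator": est,
                    "level_ari": float(ari),
                    "planted_detected": float(hit.mean()) if len(hit) else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby("estimator", sort=False)
        .agg(
            level_ari=("level_ari", "mean"),
            planted_detected=("planted_detected", "mean"),
            reps=("rep", "count"),
        )
        .reset_index()
    )
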