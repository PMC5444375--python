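"""Per-gene variability (and mean) statistics.

Three dispersion estimators are supported, each computed row-wise across the
samples of one group (or all samples):

* ``sd``  — sample standard deviation with the n-1 denominator,
* ``cv``  — coefficient of variation, SD divided by the row mean,
* ``mad`` — median absolute deviation from the median (unscaled),

plus ``mean``, the arithmetic row mean, which substitutes average expression
for variability so that the same pathway machinery doubles as a conventional
mean-based enrichment analysis.

CV is undefined when a gene's mean is not strictly positive (zero or
negative averages produce CV values that say nothing about dispersion);
such genes are flagged as NaN, counted, and excluded from discretization —
never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .errors import ValidationError
from .matrix import ExpressionMatrix

__all__ = [
    "STATISTICS",
    "VariabilityProfile",
    "compute_statistic",
    "mean_variability_correlation",
]

STATISTICS = ("sd", "cv", "mad", "mean")


@dataclass
class VariabilityProfile:
    """Per-gene values of one statistic for one group.

    ``values`` is aligned to ``gene_ids``; undefined entries (e.g. CV with
    non-positive mean) are NaN and listed in ``undefined_gene_ids``.
    """

    gene_ids: list[str]
    statistic: str
    values: np.ndarray
    group: str = "all"
    undefined_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids),):
            raise ValidationError("profile values must align with gene_ids")
        if self.statistic not in STATISTICS:
            raise ValidationError(f"unknown statistic {self.statistic!r}")

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def defined(self) -> tuple[list[str], np.ndarray]:
        """Gene ids and values restricted to genes with a defined statistic."""
        mask = self.defined_mask
        genes = [g for g, m in zip(self.gene_ids, mask) if m]
        return genes, self.values[mask]


def _group_values(matrix: ExpressionMatrix, group: str | None) -> np.ndarray:
    if group is None or group == "all":
        return matrix.values
    cols = matrix.group_columns(group)
    return matrix.values[:, cols]


def compute_statistic(
    matrix: ExpressionMatrix,
    statistic: str,
    group: str | None = None,
) -> VariabilityProfile:
    """Compute one per-gene statistic over the samples of ``group``.

    Parameters
    ----------
    matrix
        Expression matrix (values used as provided; no transformation).
    statistic
        One of ``sd``, ``cv``, ``mad``, ``mean``.
    group
        Group name to restrict to, or None/"all" for every sample.

    Returns
    -------
    VariabilityProfile
        With NaN (and ``undefined_gene_ids``) marking genes whose CV is
        undefined because the row mean is <= 0.
    """
    statistic = statistic.lower()
    if statistic not in STATISTICS:
        raise ValidationError(
            f"statistic must be one of {STATISTICS}, got {statistic!r}"
        )
    vals = _group_values(matrix, group)
    if vals.shape[1] < 2:
        raise ValidationError(
            f"group {group!r} has {vals.shape[1]} sample(s); need >= 2"
        )

    means = vals.mean(axis=1)
    if statistic == "mean":
        out = means
    elif statistic == "sd":
        out = vals.std(axis=1, ddof=1)
    elif statistic == "cv":
        sd = vals.std(axis=1, ddof=1)
        out = np.where(means > 0, sd / np.where(means > 0, means, 1.0), np.nan)
    else:  # mad
        med = np.median(vals, axis=1, keepdims=True)
        out = np.median(np.abs(vals - med), axis=1)

    undef = [g for g, v in zip(matrix.gene_ids, out) if not np.isfinite(v)]
    return VariabilityProfile(
        gene_ids=list(matrix.gene_ids),
        statistic=statistic,
        values=out,
        group=group if group not in (None, "all") else "all",
        undefined_gene_ids=undef,
    )


def mean_variability_correlation(
    matrix: ExpressionMatrix,
    statistic: str,
    group: str | None = None,
) -> float:
    """Pearson correlation between per-gene mean and the chosen statistic.

    A diagnostic for estimator choice: a dispersion estimator strongly
    correlated with average expression mostly recapitulates a mean-based
    analysis. Computed over genes with a defined statistic; returns NaN
    when either vector is constant (degenerate, reported as undefined
    rather than zero).
    """
    prof = compute_statistic(matrix, statistic, group=group)
    means = _group_values(matrix, group).mean(axis=1)
    mask = prof.defined_mask
    if int(mask.sum()) < 3:
        raise ValidationError(
            f"need >= 3 genes with a defined {statistic} value, "
            f"have {int(mask.sum())}"
        )
    x, y = means[mask], prof.values[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(scipy.stats.pearsonr(x, y).statistic)
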