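"""Discretization of per-gene statistics into ordered variability levels.

One-group design: a 1-D Gaussian mixture is fitted to the statistic values
for G = 1..max_levels components, under both an equal-variance and an
unequal-variance model, and the Bayesian Information Criterion picks the
winning (G, model) pair. Components are ordered by mean, genes take their
maximum-posterior component, and fixed numeric boundaries are derived as
midpoints between adjacent assigned clusters so that the scheme can be
re-applied to new values.

Two-group design: the number of levels is fixed at three and the boundaries
are the 33rd and 66th percentiles of the pooled statistic values from both
groups, so the two groups are compared on one common scale. Low variability
is everything up to the 33rd percentile, medium up to the 66th, high above.

Boundary convention throughout: closed below / open above — a value equal
to a boundary belongs to the lower level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .errors import FitError, ValidationError
from .estimators import VariabilityProfile

__all__ = [
    "CategoryScheme",
    "fit_mixture_levels",
    "percentile_levels",
    "assign_levels",
    "write_scheme",
    "read_scheme",
]

_LEVEL_NAMES = ["low", "medium", "high", "very_high"]

ONE_GROUP_MIXTURE = "ONE_GROUP_MIXTURE"
TWO_GROUP_PERCENTILE = "TWO_GROUP_PERCENTILE"


def level_names(m: int) -> list[str]:
    if m <= len(_LEVEL_NAMES):
        if m == 1:
            return ["all"]
        if m == 2:
            return ["low", "high"]
        return _LEVEL_NAMES[:m]
    return [f"level_{i + 1}" for i in range(m)]


@dataclass
class CategoryScheme:
    """Ordered variability levels defined by fixed numeric boundaries.

    ``boundaries`` has length m-1 and is strictly increasing; a value v is
    assigned level i (1-based) when boundaries[i-2] < v <= boundaries[i-1].
    ``assignments`` maps group name -> {gene_id: level index in 1..m}.
    """

    mode: str
    m: int
    boundaries: np.ndarray
    level_names: list[str]
    statistic: str
    assignments: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.shape != (self.m - 1,):
            raise ValidationError("boundaries must have length m-1")
        # ties allowed (degenerate percentile schemes); order must hold
        if self.m > 1 and np.any(np.diff(self.boundaries) < 0):
            raise ValidationError("boundaries must be non-decreasing")
        if len(self.level_names) != self.m:
            raise ValidationError("need one name per level")

    def assign_value(self, v: float) -> int:
        """Level (1-based) of a single value under the <=-lower convention."""
        return int(np.searchsorted(self.boundaries, v, side="left")) + 1


def _assign(values: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    return np.searchsorted(boundaries, values, side="left") + 1


def fit_mixture_levels(
    profile: VariabilityProfile,
    max_levels: int = 4,
    seed: int | None = 0,
) -> CategoryScheme:
    """Infer variability levels with a BIC-selected 1-D Gaussian mixture.

    Both equal-variance ("tied") and per-component-variance ("full")
    models are fitted for each candidate number of components; EM uses
    k-means++ initialization with 3 restarts, tolerance 1e-5, at most 300
    iterations and a 1e-8 variance floor, all seeded. Degenerate input
    (every value identical) short-circuits to a single level.
    """
    if max_levels < 1:
        raise ValidationError("max_levels must be >= 1")
    genes, vals = profile.defined()
    if len(vals) < 10:
        raise ValidationError(
            f"need >= 10 genes with defined {profile.statistic}, have {len(vals)}"
        )
    x = vals.reshape(-1, 1)

    if np.ptp(vals) == 0:
        scheme = CategoryScheme(
            mode=ONE_GROUP_MIXTURE,
            m=1,
            boundaries=np.empty(0),
            level_names=level_names(1),
            statistic=profile.statistic,
        )
        scheme.assignments[profile.group] = {g: 1 for g in genes}
        return scheme

    best = None
    best_bic = np.inf
    n_fail = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for n_comp in range(1, max_levels + 1):
            for cov in ("tied", "full"):
                try:
                    gm = GaussianMixture(
                        n_components=n_comp,
                        covariance_type=cov,
                        n_init=3,
                        init_params="k-means++",
                        tol=1e-5,
                        max_iter=300,
                        reg_covar=1e-8,
                        random_state=seed,
                    ).fit(x)
                    bic = gm.bic(x)
                except (ValueError, np.linalg.LinAlgError):
                    n_fail += 1
                    continue
                if bic < best_bic:
                    best, best_bic = gm, bic
    if best is None:
        raise FitError(
            f"EM failed for all {n_fail} candidate mixture models"
        )

    # order components by ascending mean, keep only non-empty ones
    order = np.argsort(best.means_.ravel())
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    raw = rank[best.predict(x)]  # 0-based, mean-ordered
    present = np.unique(raw)
    remap = {old: new for new, old in enumerate(present)}
    labels = np.array([remap[r] for r in raw])
    m = len(present)

    # boundary between adjacent levels: midpoint of the gap between the
    # largest value assigned below and the smallest assigned above
    boundaries = np.array(
        [
            0.5 * (vals[labels == i].max() + vals[labels == i + 1].min())
            for i in range(m - 1)
        ]
    )
    if m > 1 and np.any(np.diff(boundaries) <= 0):  # overlapping clusters
        raise FitError("mixture produced non-separable (interleaved) clusters")

    scheme = CategoryScheme(
        mode=ONE_GROUP_MIXTURE,
        m=m,
        boundaries=boundaries,
        level_names=level_names(m),
        statistic=profile.statistic,
    )
    # assign via the frozen boundaries, not raw posteriors: guarantees
    # monotonicity in the statistic and idempotence of re-assignment
    lv = _assign(vals, boundaries)
    scheme.assignments[profile.group] = dict(zip(genes, (int(v) for v in lv)))
    return scheme


def percentile_levels(
    profile_g1: VariabilityProfile,
    profile_g2: VariabilityProfile,
) -> CategoryScheme:
    """Three fixed levels from the pooled 33rd/66th percentiles.

    The two per-group profiles must cover the same gene universe with the
    same statistic. Percentiles are computed by linear interpolation over
    the pooled (2 values per gene) distribution; each group's genes are
    then assigned on that common scale.
    """
    if profile_g1.statistic != profile_g2.statistic:
        raise ValidationError("profiles use different statistics")
    if profile_g1.gene_ids != profile_g2.gene_ids:
        if set(profile_g1.gene_ids) != set(profile_g2.gene_ids):
            raise ValidationError("profiles cover different gene universes")
        raise ValidationError("profiles list genes in different orders")
    g1, v1 = profile_g1.defined()
    g2, v2 = profile_g2.defined()
    pooled = np.concatenate([v1, v2])
    if pooled.size == 0:
        raise ValidationError("no defined statistic values to pool")
    q33, q66 = np.percentile(pooled, [33.0, 66.0])
    # m is fixed at 3 by design; tied percentiles (heavy ties in the pooled
    # values) simply leave the middle or upper level empty, and empty levels
    # are merged downstream before testing
    scheme = CategoryScheme(
        mode=TWO_GROUP_PERCENTILE,
        m=3,
        boundaries=np.array([q33, q66]),
        level_names=level_names(3),
        statistic=profile_g1.statistic,
    )
    for genes, vals, grp in ((g1, v1, profile_g1.group), (g2, v2, profile_g2.group)):
        lv = _assign(vals, scheme.boundaries)
        scheme.assignments[grp] = dict(zip(genes, (int(v) for v in lv)))
    return scheme


def assign_levels(
    scheme: CategoryScheme,
    profile: VariabilityProfile,
) -> dict[str, int]:
    """Apply a scheme's frozen boundaries to a (possibly new) profile.

    Genes with an undefined statistic are omitted with a warning.
    Idempotent: re-assigning the profile a scheme was built from
    reproduces the stored assignments.
    """
    if profile.statistic != scheme.statistic:
        raise ValidationError(
            f"profile statistic {profile.statistic!r} does not match "
            f"scheme statistic {scheme.statistic!r}"
        )
    genes, vals = profile.defined()
    n_undef = len(profile.gene_ids) - len(genes)
    if n_undef:
        warnings.warn(
            f"{n_undef} gene(s) with undefined {profile.statistic} omitted "
            "from level assignment",
            stacklevel=2,
        )
    lv = _assign(vals, scheme.boundaries)
    return dict(zip(genes, (int(v) for v in lv)))


def write_scheme(scheme: CategoryScheme, path: str) -> None:
    """Serialize mode, m, boundaries and level names as a small TSV."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"mode\t{scheme.mode}\n")
        fh.write(f"statistic\t{scheme.statistic}\n")
        fh.write(f"m\t{scheme.m}\n")
        fh.write(f"boundaries\t{','.join(repr(float(b)) for b in scheme.boundaries)}\n")
        fh.write(f"level_names\t{','.join(scheme.level_names)}\n")


def read_scheme(path: str) -> CategoryScheme:
    kv: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("key"):
            raise ValidationError(f"{path}: not a scheme file")
        for line in fh:
            if line.strip():
                k, _, v = line.rstrip("\n").partition("\t")
                kv[k] = v
    try:
        bounds = (
            np.array([float(b) for b in kv["boundaries"].split(",")])
            if kv["boundaries"]
            else np.empty(0)
        )
        return CategoryScheme(
            mode=kv["mode"],
            m=int(kv["m"]),
            boundaries=bounds,
            level_names=kv["level_names"].split(","),
            statistic=kv["statistic"],
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing scheme field {exc}")
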