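"""Synthetic expression matrices with planted variability structure.

The generator emulates the data layout the pathway tests assume: each
gene occupies one of a small number of latent variability levels; its
per-sample values are then drawn from a Normal whose standard deviation
is sampled from that level's dispersion range. Planted pathways draw
their members' levels from a perturbed probability vector q while
background genes follow the level fractions p, and decoy gene sets are
sampled from the background so that empirical FDR is measurable against
the recorded truth tables.

The Gaussian family matches the Normal-mixture discretization assumption;
a log-normal option (``noise="lognormal"``) produces skewed values with
mean-coupled dispersion for CV stress-testing. Platform-specific
artifacts (dropout, saturation) are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genesets import GeneSetCollection
from .matrix import ExpressionMatrix

__all__ = [
    "LevelSpec",
    "PlantedPathway",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate",
    "write_dataset",
]


@dataclass(frozen=True)
class LevelSpec:
    """One latent variability level.

    fraction   : share of background genes in this level (fractions sum to 1);
                 doubles as the level's reference probability
    mean_range : per-gene means drawn Uniform(low, high)
    sd_range   : per-gene sampling SDs drawn Uniform(low, high); keep the
                 ranges of adjacent levels separated for recoverable levels
    """

    fraction: float
    mean_range: tuple[float, float]
    sd_range: tuple[float, float]


@dataclass(frozen=True)
class PlantedPathway:
    """A gene set whose members' level probabilities deviate from background.

    level_probs_g2 (two-group designs only) lets the perturbation differ
    between groups; when None, group 2 reuses level_probs.
    """

    name: str
    size: int
    level_probs: tuple[float, ...]
    level_probs_g2: tuple[float, ...] | None = None


# default study conditions: three well-separated dispersion levels in equal
# proportion, 20 samples, and a transcriptome-scale gene universe so that a
# planted pathway of ~100 genes remains a small fraction of the reference
_DEFAULT_LEVELS = (
    LevelSpec(1 / 3, (5.0, 15.0), (0.25, 0.35)),
    LevelSpec(1 / 3, (5.0, 15.0), (0.9, 1.1)),
    LevelSpec(1 / 3, (5.0, 15.0), (2.8, 3.2)),
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 5000
    n_samples: int = 20  # per group
    n_groups: int = 1
    level_specs: tuple[LevelSpec, ...] = _DEFAULT_LEVELS
    planted_pathways: tuple[PlantedPathway, ...] = ()
    decoys_per_planted: int = 5
    noise: str = "normal"  # or "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.array([ls.fraction for ls in self.level_specs])
        if abs(fr.sum() - 1.0) > 1e-8 or np.any(fr < 0):
            raise ValidationError("level fractions must be >= 0 and sum to 1")
        if self.n_groups not in (1, 2):
            raise ValidationError("n_groups must be 1 or 2")
        if self.noise not in ("normal", "lognormal"):
            raise ValidationError(f"unknown noise family {self.noise!r}")
        m = len(self.level_specs)
        total_planted = sum(pw.size for pw in self.planted_pathways)
        if total_planted > self.n_genes:
            raise ValidationError(
                f"planted pathways need {total_planted} genes, "
                f"only {self.n_genes} available"
            )
        for pw in self.planted_pathways:
            for q in (pw.level_probs, pw.level_probs_g2):
                if q is None:
                    continue
                qa = np.asarray(q, dtype=float)
                if qa.size != m or np.any(qa < 0) or abs(qa.sum() - 1) > 1e-8:
                    raise ValidationError(
                        f"pathway {pw.name!r}: level probabilities must be a "
                        f"length-{m} probability vector"
                    )

    @property
    def background_probs(self) -> np.ndarray:
        """Reference probability vector implied by the level fractions."""
        return np.array([ls.fraction for ls in self.level_specs])


@dataclass
class SyntheticDataset:
    """Generated matrix plus ground truth for every latent draw."""

    matrix: ExpressionMatrix
    truth: pd.DataFrame  # gene_id, level (per group), mean, sd, membership
    genesets: GeneSetCollection
    planted_names: list[str] = field(default_factory=list)
    decoy_names: list[str] = field(default_factory=list)
    config: GeneratorConfig | None = None


def _draw_values(
    rng: np.random.Generator,
    means: np.ndarray,
    sds: np.ndarray,
    n_samples: int,
    noise: str,
) -> np.ndarray:
    if noise == "normal":
        return rng.normal(means[:, None], sds[:, None], size=(means.size, n_samples))
    # log-normal parameterized to hit the requested mean and SD on the
    # natural scale: skewed, with dispersion coupled to the mean
    cv2 = (sds / means) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(means) - sigma2 / 2
    return rng.lognormal(
        mu[:, None], np.sqrt(sigma2)[:, None], size=(means.size, n_samples)
    )


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate an expression matrix, truth tables and a gene-set collection.

    Gene layout: planted-pathway members first (levels drawn from each
    pathway's q), then background genes (levels drawn from the level
    fractions). In two-group designs a gene keeps one latent level across
    groups unless its pathway specifies ``level_probs_g2``, in which case
    the group-2 level is redrawn independently.
    """
    rng = np.random.default_rng(config.seed)
    m = len(config.level_specs)
    n_genes = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    levels_g1 = np.empty(n_genes, dtype=int)  # 1-based latent levels
    levels_g2 = np.empty(n_genes, dtype=int)
    membership = np.array(["background"] * n_genes, dtype=object)

    pos = 0
    planted_sets: dict[str, tuple[str, list[str]]] = {}
    for pw in config.planted_pathways:
        sl = slice(pos, pos + pw.size)
        levels_g1[sl] = rng.choice(m, size=pw.size, p=pw.level_probs) + 1
        if pw.level_probs_g2 is not None and config.n_groups == 2:
            levels_g2[sl] = rng.choice(m, size=pw.size, p=pw.level_probs_g2) + 1
        else:
            levels_g2[sl] = levels_g1[sl]
        membership[sl] = pw.name
        planted_sets[pw.name] = ("planted", gene_ids[sl])
        pos += pw.size

    n_bg = n_genes - pos
    bg_levels = rng.choice(m, size=n_bg, p=config.background_probs) + 1
    levels_g1[pos:] = bg_levels
    levels_g2[pos:] = bg_levels
    background_ids = gene_ids[pos:]

    # per-gene means are shared across groups; dispersion follows the level
    means = np.empty(n_genes)
    sds_g1 = np.empty(n_genes)
    sds_g2 = np.empty(n_genes)
    for lv, spec in enumerate(config.level_specs, start=1):
        for levels, sds in ((levels_g1, sds_g1), (levels_g2, sds_g2)):
            idx = levels == lv
            sds[idx] = rng.uniform(*spec.sd_range, size=int(idx.sum()))
        idx = levels_g1 == lv
        means[idx] = rng.uniform(*spec.mean_range, size=int(idx.sum()))

    if config.n_groups == 1:
        values = _draw_values(rng, means, sds_g1, config.n_samples, config.noise)
        sample_ids = [f"S{j + 1:03d}" for j in range(config.n_samples)]
        group_labels = None
    else:
        v1 = _draw_values(rng, means, sds_g1, config.n_samples, config.noise)
        v2 = _draw_values(rng, means, sds_g2, config.n_samples, config.noise)
        values = np.hstack([v1, v2])
        sample_ids = [f"A{j + 1:03d}" for j in range(config.n_samples)] + [
            f"B{j + 1:03d}" for j in range(config.n_samples)
        ]
        group_labels = {s: ("groupA" if s.startswith("A") else "groupB") for s in sample_ids}

    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        group_labels=group_labels,
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "level": levels_g1,
            "level_g2": levels_g2,
            "mean": means,
            "sd": sds_g1,
            "sd_g2": sds_g2,
            "membership": membership,
        }
    )

    # decoy sets: background-only draws, sizes cycled from the planted sizes
    sets = dict(planted_sets)
    decoy_names: list[str] = []
    if config.planted_pathways:
        sizes = [pw.size for pw in config.planted_pathways]
        n_decoys = config.decoys_per_planted * len(config.planted_pathways)
        for d in range(n_decoys):
            size = min(sizes[d % len(sizes)], len(background_ids))
            picked = rng.choice(len(background_ids), size=size, replace=False)
            name = f"DECOY_{d + 1:03d}"
            sets[name] = ("decoy", [background_ids[i] for i in sorted(picked)])
            decoy_names.append(name)

    return SyntheticDataset(
        matrix=matrix,
        truth=truth,
        genesets=GeneSetCollection(sets=sets, source="synthetic"),
        planted_names=list(planted_sets),
        decoy_names=decoy_names,
        config=config,
    )


def write_dataset(data: SyntheticDataset, out_dir: str, sep: str = "\t") -> dict[str, str]:
    """Write expression TSV, group labels, GMT and truth table; returns paths.

    Files round-trip through :func:`varpath.matrix.read_expression`,
    :func:`varpath.matrix.read_group_labels` and
    :func:`varpath.genesets.read_gmt`.
    """
    import os

    from .genesets import write_gmt

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "genesets": os.path.join(out_dir, "genesets.gmt"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    data.matrix.to_frame().to_csv(paths["expression"], sep=sep)
    write_gmt(data.genesets, paths["genesets"])
    data.truth.to_csv(paths["truth"], sep=sep, index=False)
    if data.matrix.group_labels is not None:
        paths["groups"] = os.path.join(out_dir, "groups.tsv")
        with open(paths["groups"], "w") as fh:
            for s in data.matrix.sample_ids:
                fh.write(f"{s}\t{data.matrix.group_labels[s]}\n")
    return paths
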