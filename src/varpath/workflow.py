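"""End-to-end one-group and two-group analyses.

One-group: statistic -> mixture-model levels -> pathway decomposition ->
goodness-of-fit test against the whole-transcriptome reference -> BH ->
per-level binomial localization.

Two-group: per-group statistic -> pooled-percentile levels -> per-group
decomposition -> homogeneity test between the groups -> BH -> per-level
binomial contrast of group 1 against group 2's proportions.

Both paths return an :class:`AnalysisResult` holding the results table,
the frozen category scheme and a machine-readable run log (all effective
parameters, the seed, and everything dropped along the way).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .discretize import (
    CategoryScheme,
    fit_mixture_levels,
    percentile_levels,
    write_scheme,
)
from .errors import EnumerationCapError, ValidationError
from .estimators import compute_statistic
from .genesets import GeneSetCollection, decompose
from .matrix import ExpressionMatrix, read_expression, read_group_labels
from .stat_tests import (
    DEFAULT_CAP,
    bh_adjust,
    binomial_level_test,
    chisq_test,
    exact_multinomial_test,
    merge_zero_levels,
    monte_carlo_multinomial_test,
    two_group_test,
)

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "analyze_one_group",
    "analyze_two_group",
    "run",
]


@dataclass(frozen=True)
class RunConfig:
    """File-level configuration for a CLI run."""

    expr_path: str
    gmt_path: str
    out_dir: str
    groups_path: str | None = None
    statistic: str = "sd"
    design: str = "one"  # "one" | "two"
    test: str = "chisq"  # "chisq" | "exact"
    max_levels: int = 4
    min_size: int = 10
    alpha: float = 0.05
    enumeration_cap: int = DEFAULT_CAP
    mc_fallback: bool = False
    mc_reps: int = 10_000
    seed: int = 0
    sep: str = "\t"

    def __post_init__(self) -> None:
        if self.design not in ("one", "two"):
            raise ValidationError(f"design must be 'one' or 'two', got {self.design!r}")
        if self.test not in ("chisq", "exact"):
            raise ValidationError(f"test must be 'chisq' or 'exact', got {self.test!r}")
        if self.design == "two" and not self.groups_path:
            raise ValidationError("two-group design requires a group-label file")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class AnalysisResult:
    results: pd.DataFrame
    scheme: CategoryScheme
    log: dict[str, Any] = field(default_factory=dict)

    def write(self, out_dir: str) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "results": os.path.join(out_dir, "results.tsv"),
            "scheme": os.path.join(out_dir, "scheme.tsv"),
            "log": os.path.join(out_dir, "run.log"),
        }
        self.results.to_csv(paths["results"], sep="\t", index=False)
        write_scheme(self.scheme, paths["scheme"])
        with open(paths["log"], "w") as fh:
            json.dump(self.log, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return paths


def _single_test(counts, probs, test, cap, mc_fallback, mc_reps, seed, log):
    """Run one pathway's goodness-of-fit test with cap-triggered fallback."""
    if test == "exact":
        try:
            return "exact", exact_multinomial_test(counts, probs, cap=cap)
        except EnumerationCapError:
            if mc_fallback:
                log.setdefault("cap_fallbacks", []).append("monte-carlo")
                return "monte-carlo", monte_carlo_multinomial_test(
                    counts, probs, reps=mc_reps, seed=seed
                )
            log.setdefault("cap_fallbacks", []).append("chisq")
    _, p = chisq_test(counts, probs)
    return "chisq", p


def _level_columns(scheme: CategoryScheme) -> list[str]:
    return scheme.level_names


def analyze_one_group(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    statistic: str = "sd",
    test: str = "chisq",
    max_levels: int = 4,
    min_size: int = 10,
    alpha: float = 0.05,
    enumeration_cap: int = DEFAULT_CAP,
    mc_fallback: bool = False,
    mc_reps: int = 10_000,
    seed: int = 0,
) -> AnalysisResult:
    """Test each pathway's variability-level composition against the
    reference distribution over all measured genes (null H0: the pathway's
    counts were generated from the reference level probabilities)."""
    log: dict[str, Any] = {
        "design": "one-group",
        "statistic": statistic,
        "test": test,
        "max_levels": max_levels,
        "min_size": min_size,
        "alpha": alpha,
        "enumeration_cap": enumeration_cap,
        "seed": seed,
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
    }
    profile = compute_statistic(matrix, statistic)
    log["undefined_statistic_genes"] = len(profile.undefined_gene_ids)
    scheme = fit_mixture_levels(profile, max_levels=max_levels, seed=seed)
    log["n_levels"] = scheme.m
    log["boundaries"] = [float(b) for b in scheme.boundaries]

    pathways, reference, dropped = decompose(
        collection, scheme, group="all", min_size=min_size
    )
    log["dropped_small_sets"] = dropped
    ref_probs_full = reference.probabilities

    rows = []
    for pw in pathways:
        probs, (counts, _), merged = merge_zero_levels(
            ref_probs_full, pw.counts, reference.counts
        )
        if probs.size < 2:
            # everything in one level: no composition to test
            test_used, p_val = "none", float("nan")
        else:
            test_used, p_val = _single_test(
                counts, probs, test, enumeration_cap, mc_fallback, mc_reps, seed, log
            )
        row: dict[str, Any] = {
            "set_name": pw.set_name,
            "n": pw.n,
            "test_used": test_used,
            "p_value": p_val,
        }
        for i, name in enumerate(_level_columns(scheme)):
            row[f"count_{name}"] = int(pw.counts[i])
            row[f"ref_count_{name}"] = int(reference.counts[i])
            p_i = ref_probs_full[i]
            if 0 < p_i < 1:
                bp, direction = binomial_level_test(int(pw.counts[i]), pw.n, p_i)
            else:
                bp, direction = float("nan"), ""
            row[f"binom_p_{name}"] = bp
            row[f"direction_{name}"] = direction
            sig = bp < alpha if np.isfinite(bp) else False
            row[f"sig_genes_{name}"] = (
                ";".join(pw.genes_per_level.get(i + 1, [])) if sig else ""
            )
        if merged:
            row["note"] = f"empty reference level(s) merged: {merged}"
        rows.append(row)

    results = pd.DataFrame(rows)
    if len(results):
        testable = results["p_value"].notna()
        adj = np.full(len(results), np.nan)
        if testable.any():
            adj[testable.to_numpy()] = bh_adjust(results.loc[testable, "p_value"])
        results.insert(
            results.columns.get_loc("p_value") + 1, "adj_p_value", adj
        )
        results.insert(
            results.columns.get_loc("adj_p_value") + 1,
            "significant",
            results["adj_p_value"] < alpha,
        )
    log["n_tested"] = int(len(results))
    return AnalysisResult(results=results, scheme=scheme, log=log)


def analyze_two_group(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    statistic: str = "sd",
    test: str = "chisq",
    min_size: int = 10,
    alpha: float = 0.05,
    enumeration_cap: int = DEFAULT_CAP,
    seed: int = 0,
) -> AnalysisResult:
    """Test, per pathway, whether the two groups' variability-level counts
    were drawn from one underlying distribution (null H0 of homogeneity).

    Levels come from the pooled 33rd/66th percentiles so both groups share
    one scale; per-level binomial contrasts compare group 1's count at a
    level against group 2's proportion there.
    """
    groups = matrix.groups
    if len(groups) != 2:
        raise ValidationError(f"two-group design needs 2 groups, found {groups}")
    g1, g2 = groups
    log: dict[str, Any] = {
        "design": "two-group",
        "groups": groups,
        "statistic": statistic,
        "test": test,
        "min_size": min_size,
        "alpha": alpha,
        "seed": seed,
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
    }
    prof1 = compute_statistic(matrix, statistic, group=g1)
    prof2 = compute_statistic(matrix, statistic, group=g2)
    log["undefined_statistic_genes"] = {
        g1: len(prof1.undefined_gene_ids),
        g2: len(prof2.undefined_gene_ids),
    }
    scheme = percentile_levels(prof1, prof2)
    log["n_levels"] = scheme.m
    log["boundaries"] = [float(b) for b in scheme.boundaries]

    paths1, _, dropped1 = decompose(collection, scheme, group=g1, min_size=min_size)
    paths2, _, dropped2 = decompose(collection, scheme, group=g2, min_size=min_size)
    log["dropped_small_sets"] = sorted(set(dropped1) | set(dropped2))
    by_name2 = {p.set_name: p for p in paths2}

    rows = []
    for pw1 in paths1:
        pw2 = by_name2.get(pw1.set_name)
        if pw2 is None:
            continue
        keep = (pw1.counts + pw2.counts) > 0
        if keep.sum() < 2:
            test_used, p_val = "none", float("nan")
        else:
            test_used = test
            p_val = two_group_test(
                pw1.counts, pw2.counts, method=test, cap=enumeration_cap
            )
        row: dict[str, Any] = {
            "set_name": pw1.set_name,
            "n_" + g1: pw1.n,
            "n_" + g2: pw2.n,
            "test_used": test_used,
            "p_value": p_val,
        }
        # per-level contrast: group-1 count vs group-2 proportion, with the
        # same 0.5 pseudocount guard the exact two-group variant uses
        g2_counts = pw2.counts.astype(float)
        if np.any(g2_counts == 0):
            g2_counts = g2_counts + 0.5
        q2 = g2_counts / g2_counts.sum()
        for i, name in enumerate(_level_columns(scheme)):
            row[f"count_{g1}_{name}"] = int(pw1.counts[i])
            row[f"count_{g2}_{name}"] = int(pw2.counts[i])
            if 0 < q2[i] < 1:
                bp, direction = binomial_level_test(int(pw1.counts[i]), pw1.n, q2[i])
            else:
                bp, direction = float("nan"), ""
            row[f"binom_p_{name}"] = bp
            row[f"direction_{name}"] = direction
            sig = bp < alpha if np.isfinite(bp) else False
            row[f"sig_genes_{name}"] = (
                ";".join(
                    sorted(
                        set(pw1.genes_per_level.get(i + 1, []))
                        | set(pw2.genes_per_level.get(i + 1, []))
                    )
                )
                if sig
                else ""
            )
        rows.append(row)

    results = pd.DataFrame(rows)
    if len(results):
        testable = results["p_value"].notna()
        adj = np.full(len(results), np.nan)
        if testable.any():
            adj[testable.to_numpy()] = bh_adjust(results.loc[testable, "p_value"])
        results.insert(results.columns.get_loc("p_value") + 1, "adj_p_value", adj)
        results.insert(
            results.columns.get_loc("adj_p_value") + 1,
            "significant",
            results["adj_p_value"] < alpha,
        )
    log["n_tested"] = int(len(results))
    return AnalysisResult(results=results, scheme=scheme, log=log)


def run(config: RunConfig) -> AnalysisResult:
    """File-in, file-out driver used by the CLI.

    Reads the expression matrix, gene sets and (two-group) labels, runs
    the configured design, and writes results.tsv, scheme.tsv and run.log
    into the output directory.
    """
    from .genesets import read_gmt

    labels = (
        read_group_labels(config.groups_path, sep=config.sep)
        if config.groups_path
        else None
    )
    matrix = read_expression(config.expr_path, sep=config.sep, group_labels=labels)
    collection = read_gmt(config.gmt_path)
    if config.design == "one":
        res = analyze_one_group(
            matrix,
            collection,
            statistic=config.statistic,
            test=config.test,
            max_levels=config.max_levels,
            min_size=config.min_size,
            alpha=config.alpha,
            enumeration_cap=config.enumeration_cap,
            mc_fallback=config.mc_fallback,
            mc_reps=config.mc_reps,
            seed=config.seed,
        )
    else:
        res = analyze_two_group(
            matrix,
            collection,
            statistic=config.statistic,
            test=config.test,
            min_size=config.min_size,
            alpha=config.alpha,
            enumeration_cap=config.enumeration_cap,
            seed=config.seed,
        )
    res.log["inputs"] = {
        "expression": config.expr_path,
        "gene_sets": config.gmt_path,
        "groups": config.groups_path,
    }
    res.write(config.out_dir)
    return res
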