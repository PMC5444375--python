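import numpy as np
import pytest

from varpath.discretize import (
    assign_levels,
    fit_mixture_levels,
    percentile_levels,
    read_scheme,
    write_scheme,
)
from varpath.errors import ValidationError
from varpath.estimators import VariabilityProfile


def profile(values, statistic="sd", group="all"):
    genes = [f"G{i}" for i in range(len(values))]
    return VariabilityProfile(genes, statistic, np.asarray(values, float), group)


class TestMixtureLevels:
    def test_two_well_separated_components_recovered(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(10, 0.1, 100)])
        scheme = fit_mixture_levels(profile(vals), seed=0)
        assert scheme.m == 2
        assign = scheme.assignments["all"]
        for g, v in zip(scheme.assignments["all"], vals):
            assert assign[g] == (1 if v < 5 else 2)

    def test_all_identical_values_single_level(self):
        scheme = fit_mixture_levels(profile([3.7] * 20), seed=0)
        assert scheme.m == 1
        assert scheme.boundaries.size == 0
        assert set(scheme.assignments["all"].values()) == {1}

    def test_levels_monotone_in_statistic(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate(
            [rng.normal(1, 0.2, 80), rng.normal(5, 0.3, 80), rng.normal(12, 0.5, 80)]
        )
        scheme = fit_mixture_levels(profile(vals), seed=3)
        assign = scheme.assignments["all"]
        order = np.argsort(vals)
        genes = list(assign)
        levels_sorted = [assign[genes[i]] for i in order]
        assert all(a <= b for a, b in zip(levels_sorted, levels_sorted[1:]))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError, match=">= 10"):
            fit_mixture_levels(profile([1.0, 2.0, 3.0]), seed=0)

    def test_max_levels_respected(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(c, 0.1, 60) for c in (0, 4, 8, 12)])
        scheme = fit_mixture_levels(profile(vals), max_levels=2, seed=5)
        assert scheme.m <= 2


class TestPercentileLevels:
    def test_pooled_quantiles_linear_interpolation(self):
        v = np.arange(1.0, 101.0)
        p1, p2 = profile(v[:50], group="A"), profile(v[50:], group="B")
        # pool must cover the same gene universe: use 50 genes, one value each
        p2 = VariabilityProfile(p1.gene_ids, "sd", v[50:], "B")
        scheme = percentile_levels(p1, p2)
        assert scheme.boundaries[0] == pytest.approx(33.67)
        assert scheme.boundaries[1] == pytest.approx(66.34)
        assert scheme.assign_value(33.0) == 1
        assert scheme.assign_value(67.0) == 3

    def test_identical_groups_get_identical_assignments(self):
        rng = np.random.default_rng(1)
        v = rng.gamma(2, 1, 60)
        p1 = profile(v, group="A")
        p2 = VariabilityProfile(p1.gene_ids, "sd", v.copy(), "B")
        scheme = percentile_levels(p1, p2)
        assert scheme.assignments["A"] == scheme.assignments["B"]

    def test_all_equal_pooled_values_collapse_to_lowest_level(self):
        v = np.full(30, 2.5)
        p1 = profile(v, group="A")
        p2 = VariabilityProfile(p1.gene_ids, "sd", v.copy(), "B")
        scheme = percentile_levels(p1, p2)
        assert scheme.m == 3
        assert scheme.boundaries[0] == scheme.boundaries[1]
        assert set(scheme.assignments["A"].values()) == {1}
        assert set(scheme.assignments["B"].values()) == {1}

    def test_tie_free_data_gives_balanced_thirds(self):
        rng = np.random.default_rng(9)
        v1, v2 = rng.normal(size=150), rng.normal(size=150)
        p1 = profile(v1, group="A")
        p2 = VariabilityProfile(p1.gene_ids, "sd", v2, "B")
        scheme = percentile_levels(p1, p2)
        pooled = np.concatenate([v1, v2])
        counts = np.bincount(
            np.searchsorted(scheme.boundaries, pooled, side="left"), minlength=3
        )
        assert all(0.33 * 300 - 1 <= c <= 0.34 * 300 + 1 for c in counts)

    def test_mismatched_gene_universes_rejected(self):
        p1 = profile(np.arange(12.0), group="A")
        p2 = profile(np.arange(10.0), group="B")
        with pytest.raises(ValidationError, match="universe"):
            percentile_levels(p1, p2)

    def test_mismatched_statistics_rejected(self):
        p1 = profile(np.arange(12.0), statistic="sd", group="A")
        p2 = VariabilityProfile(p1.gene_ids, "cv", np.arange(12.0), "B")
        with pytest.raises(ValidationError, match="statistic"):
            percentile_levels(p1, p2)


class TestAssignLevels:
    def test_boundary_convention_closed_below(self):
        scheme = fit_mixture_levels(
            profile(np.concatenate([np.full(10, 1.0), np.full(10, 8.0)])), seed=0
        )
        scheme.boundaries = np.array([2.0, 5.0])
        scheme.m = 3
        scheme.level_names = ["low", "medium", "high"]
        assert scheme.assign_value(2.0) == 1
        assert scheme.assign_value(5.0001) == 3

    def test_reassignment_is_idempotent(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(1, 0.2, 50), rng.normal(9, 0.4, 50)])
        prof = profile(vals)
        scheme = fit_mixture_levels(prof, seed=2)
        assert assign_levels(scheme, prof) == scheme.assignments["all"]

    def test_undefined_values_omitted_with_warning(self):
        vals = np.concatenate([np.full(10, 1.0), np.full(10, 8.0)])
        prof = profile(vals)
        scheme = fit_mixture_levels(prof, seed=0)
        with_nan = VariabilityProfile(
            prof.gene_ids, "sd", np.where(np.arange(20) == 0, np.nan, vals)
        )
        with pytest.warns(UserWarning, match="omitted"):
            out = assign_levels(scheme, with_nan)
        assert "G0" not in out and len(out) == 19


def test_scheme_round_trips_through_file(tmp_path):
    rng = np.random.default_rng(4)
    vals = np.concatenate([rng.normal(1, 0.2, 50), rng.normal(9, 0.4, 50)])
    scheme = fit_mixture_levels(profile(vals), seed=4)
    path = tmp_path / "scheme.tsv"
    write_scheme(scheme, str(path))
    back = read_scheme(str(path))
    assert back.m == scheme.m
    assert back.mode == scheme.mode and back.statistic == scheme.statistic
    np.testing.assert_array_equal(back.boundaries, scheme.boundaries)
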