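import numpy as np
import pandas as pd
import pytest

from strandbias.grouping_analysis import (
    GroupSummary,
    group_correlation,
    group_equal_count,
    group_equal_interval,
    summarize_groups,
)
from strandbias.io_tables import StrandClassTable


def fitness_series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i:03d}" for i in range(len(values))])


def strand_table(classes, prefix="g"):
    return StrandClassTable(
        pd.Series(classes, index=[f"{prefix}{i:03d}" for i in range(len(classes))])
    )


class TestEqualCount:
    def test_even_split(self):
        fitness = fitness_series(np.linspace(0, 1, 100))
        groups = group_equal_count(fitness, k=10)
        assert list(groups.value_counts().sort_index()) == [10] * 10

    def test_remainder_goes_to_first_groups(self):
        fitness = fitness_series(np.linspace(0, 1, 103))
        sizes = list(group_equal_count(fitness, k=10).value_counts().sort_index())
        assert sizes == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]

    def test_group_one_holds_lowest_fitness(self):
        fitness = fitness_series(np.linspace(1, 0, 50))  # descending input
        groups = group_equal_count(fitness, k=5)
        in_group1 = fitness[groups[groups == 1].index]
        assert in_group1.max() <= fitness[groups[groups == 5].index].min()

    def test_all_ties_grouped_deterministically_by_gene_id(self):
        fitness = fitness_series(np.ones(40))
        groups = group_equal_count(fitness, k=4)
        # permuting the input leaves the composition unchanged
        shuffled = fitness.sample(frac=1.0, random_state=1)
        regrouped = group_equal_count(shuffled, k=4)
        pd.testing.assert_series_equal(groups.sort_index(), regrouped.sort_index())
        assert list(groups.value_counts().sort_index()) == [10] * 4

    def test_too_few_genes_is_an_error(self):
        with pytest.raises(ValueError):
            group_equal_count(fitness_series([0.1, 0.2]), k=10)


class TestEqualInterval:
    @pytest.mark.parametrize("value, expected", [
        (0.05, 1),   # [0, 0.1)
        (0.1, 2),    # left-closed boundaries
        (0.95, 10),
        (1.0, 10),   # top interval is closed
        (0.0, 1),
    ])
    def test_boundary_rules(self, value, expected):
        groups = group_equal_interval(pd.Series({"a": value, "b": 0.5}), k=10)
        assert groups["a"] == expected

    def test_sparse_interior_groups_are_allowed(self):
        # interior groups holding 1, 2, 4 and 3 genes summarize without error
        values = ([0.21] * 1 + [0.31, 0.32] + [0.41, 0.42, 0.43, 0.44]
                  + [0.51, 0.52, 0.53] + [1.0] * 10)
        fitness = fitness_series(values)
        classes = (["lagging"] + ["leading"] * 2 + ["leading"] * 3 + ["lagging"]
                   + ["leading"] + ["lagging"] * 2 + ["lagging"] * 10)
        summaries = summarize_groups(
            group_equal_interval(fitness, k=10), fitness, strand_table(classes)
        )
        by_index = {s.group_index: s for s in summaries}
        assert by_index[3].n_genes == 1 and by_index[3].leading_fraction == 0
        assert by_index[4].n_genes == 2 and by_index[4].leading_fraction == 1
        assert by_index[5].n_genes == 4
        assert by_index[5].leading_fraction == pytest.approx(0.75)
        assert by_index[6].n_genes == 3
        assert by_index[6].leading_fraction == pytest.approx(1 / 3)

    def test_empty_groups_are_omitted(self):
        fitness = fitness_series([0.05, 0.06, 0.95, 1.0])
        summaries = summarize_groups(
            group_equal_interval(fitness, k=10), fitness,
            strand_table(["leading"] * 4),
        )
        assert [s.group_index for s in summaries] == [1, 10]


class TestSummaries:
    def test_counts_and_mean(self):
        fitness = fitness_series([0.2, 0.4, 0.6, 0.8])
        assignment = pd.Series(1, index=fitness.index)
        (summary,) = summarize_groups(
            assignment, fitness,
            strand_table(["leading", "leading", "lagging", "lagging"]),
        )
        assert summary.n_genes == 4
        assert summary.leading_fraction == 0.5
        assert summary.mean_fitness == pytest.approx(0.5)

    def test_conservation_over_groups(self):
        rng = np.random.default_rng(5)
        fitness = fitness_series(rng.random(97))
        classes = strand_table(
            np.where(rng.random(97) < 0.6, "leading", "lagging")
        )
        summaries = summarize_groups(
            group_equal_count(fitness, k=10), fitness, classes
        )
        assert sum(s.n_genes for s in summaries) == 97

    def test_missing_strand_class_names_the_gene(self):
        fitness = fitness_series([0.2, 0.4])
        assignment = pd.Series(1, index=fitness.index)
        classes = StrandClassTable(pd.Series({"g000": "leading"}))
        with pytest.raises(ValueError, match="g001"):
            summarize_groups(assignment, fitness, classes)


class TestGroupCorrelation:
    @staticmethod
    def summaries_from(mean_fitness, leading_fraction, n=100):
        return [
            GroupSummary(i + 1, n, int(round(frac * n)), fit)
            for i, (fit, frac) in enumerate(zip(mean_fitness, leading_fraction))
        ]

    def test_perfect_negative_linearity(self):
        summaries = self.summaries_from(
            [0.1, 0.3, 0.5, 0.7, 0.9], [0.9, 0.7, 0.5, 0.3, 0.1], n=10
        )
        corr = group_correlation(summaries)
        assert corr.r == pytest.approx(-1.0)
        assert corr.r_squared == pytest.approx(1.0)
        assert corr.k_used == 5

    def test_constant_leading_fraction_is_an_error(self):
        summaries = self.summaries_from([0.1, 0.5, 0.9], [0.5, 0.5, 0.5], n=10)
        with pytest.raises(ValueError, match="constant"):
            group_correlation(summaries)

    def test_fewer_than_three_groups_is_an_error(self):
        with pytest.raises(ValueError):
            group_correlation(self.summaries_from([0.1, 0.9], [0.8, 0.2]))


def test_grouping_amplifies_a_monotone_link():
    """With a monotone fitness->leading link, the grouped correlation
    magnitude exceeds the ungrouped (binary-outcome) one."""
    from strandbias import SyntheticGenomeSpec, classify_genome, simulate_genome
    from strandbias.correlation_stats import pearson_with_p

    spec = SyntheticGenomeSpec(n_genes=3000, chromosome_length=3_600_000,
                               ter_position=1_800_000, beta=4.0, seed=11)
    genes, annotations, geometry, _ = simulate_genome(spec)
    strand, _ = classify_genome(genes, geometry)
    fitness = annotations.column("fitness")
    ungrouped = pearson_with_p(
        fitness.to_numpy(), strand.binary.reindex(fitness.index).to_numpy()
    )
    grouped = group_correlation(
        summarize_groups(group_equal_count(fitness), fitness, strand)
    )
    assert ungrouped.r < 0
    assert grouped.r < 0
    assert abs(grouped.r) > abs(ungrouped.r)
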