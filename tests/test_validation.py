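"""Expression subsetting, hierarchical clustering, clinical summaries,
cluster-attribute association."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from censignet.validation import (
    ExpressionDataset,
    cluster_association,
    cluster_clinical_summary,
    cluster_samples,
    dichotomize,
    subset_expression,
    zscore_genes,
)


def dataset(matrix, genes, samples, clinical=None):
    return ExpressionDataset(
        expression=pd.DataFrame(matrix, index=genes, columns=samples),
        clinical=clinical if clinical is not None else pd.DataFrame(),
    )


def two_group_dataset(seed=0, n_per_group=20, n_genes=10, shift=8.0):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(2 * n_per_group)]
    x = rng.normal(0.0, 1.0, size=(n_genes, 2 * n_per_group))
    x[:, n_per_group:] += shift
    return dataset(x, [f"G{i}" for i in range(n_genes)], samples)


def fisher_oracle(table):
    """Two-sided Fisher exact by enumerating all tables with fixed margins;
    the p-value sums the probabilities of tables no more probable than the
    observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


class TestSubset:
    data = dataset(np.arange(15.0).reshape(5, 3),
                   [f"G{i}" for i in range(5)], ["A", "B", "C"])

    def test_all_present(self):
        sub = subset_expression(self.data, ["G0", "G2", "G4"])
        assert sub.genes == ["G0", "G2", "G4"]

    def test_missing_gene_dropped(self):
        sub = subset_expression(self.data, ["G0", "G1", "NOPE"])
        assert sub.genes == ["G0", "G1"]

    def test_too_few_matches_rejected(self):
        with pytest.raises(ValueError, match="1 signature gene"):
            subset_expression(self.data, ["G0", "X", "Y"])


class TestClusterSamples:
    def test_separated_groups_partition_by_group(self):
        data = two_group_dataset()
        assign = cluster_samples(data, k=2)
        labels = [assign.assignment[s] for s in data.samples]
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_six_sample_miniature_matches_exhaustive_partition(self):
        """The 2-cut equals the bipartition minimizing within-group spread."""
        data = two_group_dataset(seed=3, n_per_group=3, n_genes=4, shift=6.0)
        assign = cluster_samples(data, k=2)
        x = data.expression.to_numpy().T
        best, best_cost = None, np.inf
        samples = data.samples
        for size in (1, 2, 3):
            for grp in itertools.combinations(range(6), size):
                in_g = set(grp)
                cost = sum(
                    np.linalg.norm(x[i] - x[j])
                    for i, j in itertools.combinations(range(6), 2)
                    if (i in in_g) == (j in in_g)
                )
                if cost < best_cost:
                    best_cost, best = cost, in_g
        ours = {i for i, s in enumerate(samples)
                if assign.assignment[s] == assign.assignment[samples[0]]}
        assert ours == best or ours == set(range(6)) - best

    def test_k_equals_n(self):
        data = two_group_dataset(n_per_group=3, n_genes=4)
        assign = cluster_samples(data, k=6)
        assert sorted(assign.assignment.values()) == [1, 2, 3, 4, 5, 6]

    def test_duplicate_columns_cluster_together(self):
        x = np.array([[0.0, 0.0, 10.0], [1.0, 1.0, 5.0]])
        data = dataset(x, ["G0", "G1"], ["A", "A2", "FAR"])
        assign = cluster_samples(data, k=2)
        assert assign.assignment["A"] == assign.assignment["A2"]
        assert assign.assignment["FAR"] != assign.assignment["A"]

    def test_k_out_of_range_rejected(self):
        data = two_group_dataset(n_per_group=2, n_genes=3)
        with pytest.raises(ValueError):
            cluster_samples(data, k=5)

    def test_pairwise_distances_match_double_loop(self):
        """scipy's condensed pdist equals the naive definition."""
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 10))
        d = squareform(pdist(x, metric="euclidean"))
        for i in range(10):
            for j in range(10):
                ref = math.sqrt(((x[i] - x[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(ref, abs=1e-10)


class TestClinicalSummary:
    def make(self):
        data = two_group_dataset(n_per_group=2, n_genes=3)
        clinical = pd.DataFrame(
            {"age": [40.0, 50.0, 60.0, np.nan]},
            index=pd.Index(data.samples, name="sample"),
        )
        return ExpressionDataset(expression=data.expression, clinical=clinical)

    def test_per_cluster_mean(self):
        data = self.make()
        assign = cluster_samples(data, k=2)
        tab = cluster_clinical_summary(assign, data, ["age"])
        first = assign.assignment[data.samples[0]]
        assert tab.loc[first, "age"] == pytest.approx(45.0)
        other = [c for c in (1, 2) if c != first][0]
        assert tab.loc[other, "n_age"] == 1
        assert tab.loc[other, "age"] == pytest.approx(60.0)

    def test_absent_attribute_lists_available(self):
        data = self.make()
        assign = cluster_samples(data, k=2)
        with pytest.raises(KeyError, match="age"):
            cluster_clinical_summary(assign, data, ["weight"])


class TestAssociation:
    def make_assignment(self, counts):
        """Build an assignment + attribute realizing a 2x2 table
        [[pos1, neg1], [pos2, neg2]]."""
        assign_map, attr = {}, {}
        i = 0
        for cluster, (pos, neg) in enumerate(counts, start=1):
            for v, n in ((1, pos), (0, neg)):
                for _ in range(n):
                    s = f"S{i}"
                    assign_map[s] = cluster
                    attr[s] = v
                    i += 1
        from censignet.validation import ClusterAssignment

        return ClusterAssignment(assign_map, k=2, linkage="average"), attr

    def test_receptor_status_split_is_significant(self):
        assign, attr = self.make_assignment([(104, 14), (30, 50)])
        res = cluster_association(assign, attr, method="fisher")
        assert res.table == ((104, 14), (30, 50))
        assert res.p < 1e-10
        assert res.p == pytest.approx(fisher_oracle(res.table), rel=1e-8)

    def test_identical_proportions_give_p_one(self):
        assign, attr = self.make_assignment([(5, 5), (5, 5)])
        assert cluster_association(assign, attr).p == pytest.approx(1.0)

    def test_perfect_separation_attains_margin_minimum(self):
        assign, attr = self.make_assignment([(10, 0), (0, 10)])
        res = cluster_association(assign, attr)
        # minimal attainable two-sided p for margins (10,10)x(10,10)
        assert res.p == pytest.approx(2 / math.comb(20, 10), rel=1e-8)

    @pytest.mark.parametrize("counts", [
        [(8, 3), (2, 7)], [(1, 5), (4, 2)], [(6, 6), (5, 3)], [(9, 1), (3, 12)],
    ])
    def test_fisher_matches_margin_enumeration(self, counts):
        assign, attr = self.make_assignment(counts)
        res = cluster_association(assign, attr)
        assert res.p == pytest.approx(fisher_oracle(res.table), rel=1e-8)

    def test_label_permutation_invariance(self):
        assign, attr = self.make_assignment([(8, 3), (2, 7)])
        from censignet.validation import ClusterAssignment

        swapped = ClusterAssignment(
            {s: 3 - c for s, c in assign.assignment.items()}, k=2, linkage="average"
        )
        for method in ("fisher", "anova"):
            assert cluster_association(assign, attr, method=method).p == pytest.approx(
                cluster_association(swapped, attr, method=method).p
            )

    def test_anova_detects_imbalance(self):
        assign, attr = self.make_assignment([(18, 2), (3, 17)])
        res = cluster_association(assign, attr, method="anova")
        assert res.p < 1e-5 and res.method == "anova"

    def test_missing_attribute_coverage_enforced(self):
        assign, attr = self.make_assignment([(5, 5), (5, 5)])
        sparse = {s: v for s, v in list(attr.items())[:10]}
        with pytest.raises(ValueError, match="coverage"):
            cluster_association(assign, sparse)

    def test_requires_two_clusters(self):
        from censignet.validation import ClusterAssignment

        assign = ClusterAssignment({"S0": 1}, k=1, linkage="average")
        with pytest.raises(ValueError):
            cluster_association(assign, {"S0": 1})


def test_dichotomize_threshold():
    attr = {"A": 2500.0, "B": 1999.0, "C": 2000.0, "D": float("nan")}
    out = dichotomize(attr, threshold=2000.0)
    assert out == {"A": 1, "B": 0, "C": 0}


def test_zscore_rows_have_zero_mean_unit_sd():
    data = two_group_dataset(n_per_group=5, n_genes=4)
    z = zscore_genes(data).expression
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)
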