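import numpy as np
import pytest

from rhizopan import (
    CompartmentLabels,
    ENDOSPHERE,
    PresenceMatrix,
    RHIZOSPHERE,
)
from rhizopan.carbon import (
    classify_group_bias,
    group_count_ranges,
    group_partition,
    strain_substrate_counts,
    top_biased_compounds,
)
from rhizopan.errors import ConsistencyError
from rhizopan.simulate import ClassSpec, SimTruth, generate_utilization, plant_group_partition


class TestStrainCounts:
    def test_zero_and_full_rows(self):
        m = PresenceMatrix.from_arrays(
            ["a", "b"], [f"c{i}" for i in range(190)],
            np.vstack([np.zeros(190), np.ones(190)]),
            kind="utilization",
        )
        counts = strain_substrate_counts(m)
        assert counts["a"] == 0
        assert counts["b"] == 190

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_row_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 2, size=(7, 23))
        m = PresenceMatrix.from_arrays(
            [f"s{i}" for i in range(7)], [f"c{j}" for j in range(23)],
            values, kind="utilization",
        )
        counts = strain_substrate_counts(m)
        for i in range(7):
            assert counts[f"s{i}"] == sum(int(v) for v in values[i])

    def test_group_ranges(self, small_labels):
        values = np.array(
            [[1, 1, 0], [1, 0, 0], [1, 1, 1], [0, 0, 0], [1, 0, 1]]
        )
        m = PresenceMatrix.from_arrays(
            ["r1", "r2", "e1", "e2", "e3"], ["c1", "c2", "c3"], values,
            kind="utilization",
        )
        ranges = group_count_ranges(m, small_labels)
        assert ranges[RHIZOSPHERE] == (1, 2)
        assert ranges[ENDOSPHERE] == (0, 3)


class TestGroupPartition:
    def test_all_ones(self):
        m = PresenceMatrix.from_arrays(
            ["a", "b"], ["c1", "c2", "c3"], np.ones((2, 3)),
            kind="utilization",
        )
        part = group_partition(m, ["a", "b"])
        assert part == (3, 0, 0)

    def test_planted_counts_recovered(self):
        strains = [f"E{i:02d}" for i in range(1, 16)]
        m = plant_group_partition(strains, 51, 71, 68, seed=5)
        part = group_partition(m, strains)
        assert part == (51, 71, 68)
        assert part.total == 190

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_identity(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(1, 8)), int(rng.integers(1, 40))
        m = PresenceMatrix.from_arrays(
            [f"s{i}" for i in range(n)], [f"c{j}" for j in range(k)],
            rng.integers(0, 2, size=(n, k)), kind="utilization",
        )
        part = group_partition(m, m.strains)
        assert part.total == k

    def test_empty_subset_is_error(self):
        m = PresenceMatrix.from_arrays(["a"], ["c"], [[1]], kind="utilization")
        with pytest.raises(ValueError, match="empty"):
            group_partition(m, [])


def _biased_matrix(small_labels, values, compounds, classes):
    m = PresenceMatrix.from_arrays(
        ["r1", "r2", "e1", "e2", "e3"], compounds, np.array(values),
        kind="utilization",
    )
    return m, classes


class TestClassifyGroupBias:
    def test_equal_fractions_no_bias(self, small_labels):
        # every strain uses exactly one of the two compounds
        values = [[1, 0]] * 5
        m, classes = _biased_matrix(
            small_labels, values, ["c1", "c2"], {"c1": "x", "c2": "x"}
        )
        (res,) = classify_group_bias(m, small_labels, classes)
        assert res.bias_call == "none"
        assert res.enrichment.chi2 == pytest.approx(0.0)

    def test_all_positive_class_is_homogeneous(self, small_labels):
        values = [[1, 1]] * 5
        m, classes = _biased_matrix(
            small_labels, values, ["c1", "c2"], {"c1": "x", "c2": "x"}
        )
        (res,) = classify_group_bias(m, small_labels, classes)
        assert res.enrichment.chi2 == 0.0
        assert res.bias_call == "none"

    def test_perfect_separation_called_endosphere(self, small_labels):
        # all E positive, all R negative over 6 compounds; pooled table
        # [[0, 12], [18, 0]] -> chi2 = 30 by hand (margins 12/18, 12/18)
        compounds = [f"c{j}" for j in range(6)]
        values = [[0] * 6, [0] * 6, [1] * 6, [1] * 6, [1] * 6]
        m, classes = _biased_matrix(
            small_labels, values, compounds, {c: "x" for c in compounds}
        )
        (res,) = classify_group_bias(m, small_labels, classes, alpha=0.01)
        assert res.enrichment.chi2 == pytest.approx(30.0)
        assert res.bias_call == ENDOSPHERE
        assert res.frac_rhizosphere == 0.0
        assert res.frac_endosphere == 1.0

    def test_unclassified_compound_is_error(self, small_labels):
        m, _ = _biased_matrix(
            small_labels, [[1, 0]] * 5, ["c1", "c2"], None
        )
        with pytest.raises(ConsistencyError, match="c2"):
            classify_group_bias(m, small_labels, {"c1": "x"})

    def test_class_without_compounds_is_error(self, small_labels):
        m, _ = _biased_matrix(small_labels, [[1]] * 5, ["c1"], None)
        with pytest.raises(ConsistencyError, match="ghost"):
            classify_group_bias(
                m, small_labels, {"c1": "x", "c9": "ghost"}
            )

    def test_invariant_to_compound_and_strain_order(self, study_labels):
        rng = np.random.default_rng(7)
        strains = study_labels.strains
        compounds = [f"c{j}" for j in range(12)]
        classes = {c: ("a" if j < 5 else "b") for j, c in enumerate(compounds)}
        m = PresenceMatrix.from_arrays(
            strains, compounds, rng.integers(0, 2, size=(19, 12)),
            kind="utilization",
        )
        base = classify_group_bias(m, study_labels, classes, n_perm=300,
                                   seed=3)
        perm_c = list(rng.permutation(compounds))
        perm_s = list(rng.permutation(strains))
        shuffled = m.restrict(strains=perm_s, features=perm_c)
        other = classify_group_bias(shuffled, study_labels, classes,
                                    n_perm=300, seed=3)
        for a, b in zip(base, other):
            assert a.class_name == b.class_name
            assert a.frac_rhizosphere == b.frac_rhizosphere
            assert a.enrichment.chi2 == pytest.approx(b.enrichment.chi2)
            assert a.bias_call == b.bias_call

    def test_planted_bias_recovered_with_permutations(self, study_labels):
        # strong planted effect, moderate class size, permutation route
        truth = SimTruth(
            n_rhizosphere=4, n_endosphere=15,
            class_specs=(
                ClassSpec("biased", 20, 0.75, 0.25),
                ClassSpec("flat", 20, 0.5, 0.5),
            ),
            seed=12,
        )
        util, classes, _ = generate_utilization(truth)
        results = classify_group_bias(util, truth.labels(), classes,
                                      alpha=0.01, n_perm=500, seed=0)
        biased = next(r for r in results if r.class_name == "biased")
        assert biased.bias_call == RHIZOSPHERE


class TestTopBiased:
    def test_exclusive_compound_ranks_first(self, small_labels):
        values = [[1, 1], [1, 0], [0, 1], [0, 0], [0, 1]]
        m = PresenceMatrix.from_arrays(
            ["r1", "r2", "e1", "e2", "e3"], ["rOnly", "mixed"],
            np.array(values), kind="utilization",
        )
        df = top_biased_compounds(m, small_labels, 2, RHIZOSPHERE)
        assert df.iloc[0]["compound"] == "rOnly"
        assert df.iloc[0]["bias_score"] == pytest.approx(1.0)

    def test_uniform_compound_scores_zero(self, small_labels):
        m = PresenceMatrix.from_arrays(
            ["r1", "r2", "e1", "e2", "e3"], ["c1"], np.ones((5, 1)),
            kind="utilization",
        )
        df = top_biased_compounds(m, small_labels, 1, ENDOSPHERE)
        assert df.iloc[0]["bias_score"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_ranking(self, seed, study_labels):
        rng = np.random.default_rng(seed)
        strains = study_labels.strains
        compounds = [f"c{j:02d}" for j in range(15)]
        values = rng.integers(0, 2, size=(19, 15))
        m = PresenceMatrix.from_arrays(strains, compounds, values,
                                       kind="utilization")
        df = top_biased_compounds(m, study_labels, 15, ENDOSPHERE)
        # oracle: per-compound fraction difference, python loops
        r = [s for s in strains if study_labels[s] == RHIZOSPHERE]
        e = [s for s in strains if study_labels[s] == ENDOSPHERE]
        scores = {}
        for j, c in enumerate(compounds):
            fr = sum(values[strains.index(s), j] for s in r) / len(r)
            fe = sum(values[strains.index(s), j] for s in e) / len(e)
            scores[c] = fe - fr
        expected = sorted(scores, key=lambda c: (-scores[c], c))
        assert df["compound"].tolist() == expected

    def test_k_too_large_is_error(self, small_labels):
        m = PresenceMatrix.from_arrays(
            ["r1", "r2", "e1", "e2", "e3"], ["c1"], np.ones((5, 1)),
            kind="utilization",
        )
        with pytest.raises(ValueError, match="exceeds"):
            top_biased_compounds(m, small_labels, 2, RHIZOSPHERE)
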