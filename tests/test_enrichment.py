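import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rhizopan import CompartmentLabels, ENDOSPHERE, PresenceMatrix, RHIZOSPHERE
from rhizopan.enrichment import (
    ContingencyTable,
    build_trait_table,
    chi_square,
    enrichment_table,
    multivariate_enrichment,
    permutation_chi_square,
)
from rhizopan.errors import DegenerateTableError


def brute_force_chi2(counts):
    """Independent Pearson chi-square: explicit margin loops."""
    counts = [list(map(float, row)) for row in counts]
    nrows, ncols = len(counts), len(counts[0])
    total = sum(sum(row) for row in counts)
    row_sums = [sum(row) for row in counts]
    col_sums = [sum(counts[i][j] for i in range(nrows)) for j in range(ncols)]
    chi2 = 0.0
    for i in range(nrows):
        for j in range(ncols):
            exp = row_sums[i] * col_sums[j] / total
            chi2 += (counts[i][j] - exp) ** 2 / exp
    return chi2


def exhaustive_permutation_p(pos, n_r):
    """Exact enumeration of every compartment assignment (<=10 strains)."""
    n = len(pos)
    obs_chi2 = _assignment_chi2(pos, set(range(n_r)))
    total = 0
    exceed = 0
    for r_set in itertools.combinations(range(n), n_r):
        total += 1
        if _assignment_chi2(pos, set(r_set)) >= obs_chi2 - 1e-12:
            exceed += 1
    return exceed / total


def _assignment_chi2(pos, r_set):
    n = len(pos)
    pos_r = sum(pos[i] for i in r_set)
    pos_e = sum(pos) - pos_r
    n_r = len(r_set)
    table = [[pos_r, n_r - pos_r], [pos_e, (n - n_r) - pos_e]]
    return brute_force_chi2(table)


def traits_matrix(r_values, e_values, trait="t1"):
    strains = [f"r{i}" for i in range(len(r_values))] + [
        f"e{i}" for i in range(len(e_values))
    ]
    labels = CompartmentLabels(
        {s: (RHIZOSPHERE if s.startswith("r") else ENDOSPHERE)
         for s in strains}
    )
    m = PresenceMatrix.from_arrays(
        strains, [trait], np.array(r_values + e_values).reshape(-1, 1),
        kind="trait",
    )
    return m, labels


class TestBuildTraitTable:
    def test_study_shaped_example(self):
        # 4 R strains, 1 positive; 15 E strains, 8 positive
        m, labels = traits_matrix([1, 0, 0, 0], [1] * 8 + [0] * 7)
        table = build_trait_table(m, labels, "t1")
        assert table.counts.tolist() == [[1, 3], [8, 7]]
        assert table.row_labels == (RHIZOSPHERE, ENDOSPHERE)

    def test_all_positive_gives_zero_negative_column(self):
        m, labels = traits_matrix([1, 1], [1, 1, 1])
        table = build_trait_table(m, labels, "t1")
        assert table.counts[:, 1].tolist() == [0, 0]

    def test_unknown_trait_is_error(self):
        m, labels = traits_matrix([1, 0], [0, 1])
        with pytest.raises(KeyError):
            build_trait_table(m, labels, "nope")


class TestChiSquare:
    def test_perfect_homogeneity(self):
        t = ContingencyTable(
            np.array([[5, 5], [5, 5]]), ("r", "e"), ("positive", "negative")
        )
        res = chi_square(t)
        assert res.chi2 == 0.0
        assert res.p_asymptotic == 1.0
        assert res.direction is None

    def test_perfect_separation_hand_computed(self):
        # expected cells all 5 -> chi2 = 4 * 25/5 = 20
        t = ContingencyTable(
            np.array([[10, 0], [0, 10]]), ("r", "e"), ("positive", "negative")
        )
        res = chi_square(t)
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        counts = rng.integers(1, 30, size=(2, k))
        t = ContingencyTable(
            counts, ("r", "e"), tuple(f"c{j}" for j in range(k))
        )
        res = chi_square(t)
        assert res.chi2 == pytest.approx(brute_force_chi2(counts))
        assert res.df == k - 1
        assert res.p_asymptotic == pytest.approx(
            float(stats.chi2.sf(res.chi2, res.df))
        )

    def test_zero_margin_is_error_naming_column(self):
        t = ContingencyTable(
            np.array([[3, 0], [5, 0]]), ("r", "e"), ("positive", "negative")
        )
        with pytest.raises(DegenerateTableError, match="negative"):
            chi_square(t)

    def test_row_swap_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 20, size=(2, 3))
        labels = ("r", "e")
        cols = ("a", "b", "c")
        res1 = chi_square(ContingencyTable(counts, labels, cols))
        res2 = chi_square(ContingencyTable(counts[::-1], labels[::-1], cols))
        assert res1.chi2 == pytest.approx(res2.chi2)

    def test_direction_points_to_higher_positive_fraction(self):
        t = ContingencyTable(
            np.array([[1, 3], [8, 7]]), (RHIZOSPHERE, ENDOSPHERE),
            ("positive", "negative"),
        )
        assert chi_square(t).direction == ENDOSPHERE


class TestPermutation:
    def test_homogeneous_trait_p_near_one(self):
        m, labels = traits_matrix([1, 0, 1, 0], [1, 0, 1, 0, 1, 0])
        res = permutation_chi_square(m, labels, "t1", n_perm=2000, seed=0)
        assert res.p_permutation > 0.5

    def test_two_plus_two_indicator_matches_enumeration(self):
        # trait == compartment indicator over 2+2 strains: exact p = 2/6
        m, labels = traits_matrix([1, 1], [0, 0])
        exact = exhaustive_permutation_p([1, 1, 0, 0], 2)
        assert exact == pytest.approx(1 / 3)
        res = permutation_chi_square(m, labels, "t1", n_perm=30000, seed=1)
        assert res.p_permutation == pytest.approx(exact, abs=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        n_r = int(rng.integers(2, n - 1))
        pos = rng.integers(0, 2, size=n).tolist()
        if sum(pos) in (0, n):
            pos[0] = 1 - pos[0]
        m, labels = traits_matrix(pos[:n_r], pos[n_r:])
        exact = exhaustive_permutation_p(pos, n_r)
        res = permutation_chi_square(m, labels, "t1", n_perm=8000, seed=seed)
        assert res.p_permutation == pytest.approx(exact, abs=0.03)

    def test_same_seed_same_p(self):
        m, labels = traits_matrix([1, 0, 0, 0], [1] * 8 + [0] * 7)
        p1 = permutation_chi_square(m, labels, "t1", 500, seed=11).p_permutation
        p2 = permutation_chi_square(m, labels, "t1", 500, seed=11).p_permutation
        assert p1 == p2

    def test_nperm_zero_rejected(self):
        m, labels = traits_matrix([1, 0], [0, 1])
        with pytest.raises(ValueError):
            permutation_chi_square(m, labels, "t1", 0, seed=0)


class TestMultivariate:
    def _matrix(self, rows, n_traits):
        strains = [f"s{i}" for i in range(len(rows))]
        labels = CompartmentLabels(
            {s: (RHIZOSPHERE if i < 2 else ENDOSPHERE)
             for i, s in enumerate(strains)}
        )
        m = PresenceMatrix.from_arrays(
            strains, [f"t{j}" for j in range(n_traits)], np.array(rows),
            kind="trait",
        )
        return m, labels

    def test_identical_fractions_gives_zero_chi2(self):
        # each trait positive in exactly half of each compartment
        rows = [[1, 1], [0, 0], [1, 1], [0, 0]]
        m, labels = self._matrix(rows, 2)
        res = multivariate_enrichment(m, labels)
        assert res.overall.chi2 == pytest.approx(0.0)

    def test_aligned_traits_exceed_critical_value(self):
        # every trait positive in all R, absent in all E strains;
        # hand computation on the stacked 2 x 2K table gives chi2 = 5K
        k = 4
        rows = [[1] * k, [1] * k, [0] * k, [0] * k, [0] * k]
        m, labels = self._matrix(rows, k)
        res = multivariate_enrichment(m, labels)
        assert res.overall.chi2 == pytest.approx(5.0 * k)
        assert res.overall.chi2 > stats.chi2.ppf(0.95, df=k - 1)
        assert res.overall.direction == RHIZOSPHERE

    def test_stacked_table_matches_brute_force(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, size=(6, 5))
        rows[0] = 1  # no trait absent everywhere ...
        rows[-1] = 0  # ... and none present everywhere
        m, labels = self._matrix(rows.tolist(), 5)
        res = multivariate_enrichment(m, labels)
        assert res.overall.chi2 == pytest.approx(
            brute_force_chi2(res.table.counts)
        )

    def test_needs_two_traits(self):
        m, labels = self._matrix([[1], [0], [1], [0]], 1)
        with pytest.raises(ValueError, match="two traits"):
            multivariate_enrichment(m, labels)


class TestEnrichmentTable:
    def test_columns_and_constant_trait_handling(self, study_labels):
        rng = np.random.default_rng(0)
        strains = study_labels.strains
        values = rng.integers(0, 2, size=(len(strains), 3))
        values[:, 2] = 1  # constant trait -> NaN statistics, not an abort
        m = PresenceMatrix.from_arrays(
            strains, ["a", "b", "const"], values, kind="trait"
        )
        df = enrichment_table(m, study_labels, n_perm=200, seed=0)
        assert list(df["trait_id"]) == ["a", "b", "const"]
        assert math.isnan(df.loc[2, "chi2"])
        assert not df.loc[2, "significant"]

    def test_bh_correction_monotone(self, study_labels):
        rng = np.random.default_rng(1)
        strains = study_labels.strains
        values = rng.integers(0, 2, size=(len(strains), 6))
        values[0] = 1
        m = PresenceMatrix.from_arrays(
            strains, [f"t{j}" for j in range(6)], values, kind="trait"
        )
        df = enrichment_table(m, study_labels, n_perm=0, bh_correct=True)
        ok = df.dropna(subset=["p_bh"])
        assert (ok["p_bh"] >= ok["p_asymptotic"] - 1e-12).all()
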