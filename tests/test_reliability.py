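"""Coincidence matrix, Krippendorff's alpha, percent agreement, ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nisslcyto.reliability import (
    CoincidenceMatrix,
    EmptyDataError,
    RatingsTable,
    UndefinedAlphaError,
    alpha_from_ratings,
    build_coincidence_matrix,
    disagreement_ranking,
    krippendorff_alpha,
    pairwise_percent_agreement,
)
from nisslcyto.vocab import RATING_LABELS

from ._alpha_oracle import brute_alpha, brute_percent_agreement
from .conftest import random_ratings_table


def table(data, index=None, **kwargs):
    df = pd.DataFrame(data, index=index)
    return RatingsTable(values=df, **kwargs)


class TestCoincidenceMatrix:
    def test_agreeing_pair_adds_two_to_the_diagonal(self, two_rater_agree):
        cm = build_coincidence_matrix(two_rater_agree)
        i = RATING_LABELS.index("neuron")
        assert cm.counts[i, i] == 2
        assert cm.n == 2

    def test_split_pair_adds_one_to_each_symmetric_cell(self, two_rater_split):
        cm = build_coincidence_matrix(two_rater_split)
        i, j = RATING_LABELS.index("neuron"), RATING_LABELS.index("astrocyte")
        assert cm.counts[i, j] == 1
        assert cm.counts[j, i] == 1
        assert cm.n == 2

    def test_full_table_pair_count_is_n_m_m_minus_1(self):
        rng = np.random.default_rng(0)
        N, m = 17, 5
        df = random_full(rng, N, m)
        cm = build_coincidence_matrix(RatingsTable(df))
        assert cm.n == N * m * (m - 1)

    def test_single_rating_units_are_excluded(self):
        t = table(
            {"A": ["neuron", "astrocyte"], "B": ["neuron", None]},
            index=["c1", "c2"],
        )
        cm = build_coincidence_matrix(t)
        assert cm.n == 2  # only c1 contributes
        assert cm.n_excluded_units == 1

    def test_no_pairable_unit_is_an_error(self):
        t = table({"A": ["neuron"], "B": [None]}, index=["c1"])
        with pytest.raises(EmptyDataError):
            build_coincidence_matrix(t)

    def test_symmetry_and_marginal_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            df = random_ratings_table(rng)
            cm = build_coincidence_matrix(RatingsTable(df))
            assert np.array_equal(cm.counts, cm.counts.T)
            m_u = df.notna().sum(axis=1)
            expected_n = int((m_u * (m_u - 1)).where(m_u >= 2, 0).sum())
            assert cm.n == expected_n
            assert np.allclose(cm.marginals, cm.counts.sum(axis=1))
            assert cm.marginals.sum() == cm.n


def random_full(rng, n_units, n_raters):
    cats = np.array(RATING_LABELS, dtype=object)
    return pd.DataFrame(
        cats[rng.integers(0, len(cats), size=(n_units, n_raters))],
        index=[f"u{i}" for i in range(n_units)],
        columns=[f"r{j}" for j in range(n_raters)],
    )


class TestAlpha:
    def test_perfect_agreement_gives_alpha_exactly_one(self):
        t = table(
            {
                "A": ["neuron", "astrocyte", "microglia"],
                "B": ["neuron", "astrocyte", "microglia"],
                "C": ["neuron", "astrocyte", "microglia"],
            },
            index=["c1", "c2", "c3"],
        )
        report = alpha_from_ratings(t)
        assert report.alpha == 1.0
        assert report.D_o == 0.0

    def test_one_dissenting_rater_pulls_alpha_below_one(self):
        t = table(
            {
                "A": ["neuron", "astrocyte"],
                "B": ["neuron", "astrocyte"],
                "C": ["astrocyte", "neuron"],
            },
            index=["c1", "c2"],
        )
        assert alpha_from_ratings(t).alpha < 1.0

    def test_known_2x2_coincidence_matrix(self):
        # Six two-rater units realizing counts [[4, 2], [2, 4]] (n = 12):
        # alpha = 1 - 11 * 4 / (144 - 72) = 7/18.
        t = table(
            {
                "A": ["neuron"] * 2 + ["astrocyte"] * 2 + ["neuron"] * 2,
                "B": ["neuron"] * 2 + ["astrocyte"] * 2 + ["astrocyte"] * 2,
            },
            index=[f"c{i}" for i in range(6)],
        )
        cm = build_coincidence_matrix(t)
        i, j = RATING_LABELS.index("neuron"), RATING_LABELS.index("astrocyte")
        assert cm.counts[i, i] == 4 and cm.counts[j, j] == 4
        assert cm.counts[i, j] == 2 and cm.counts[j, i] == 2
        report = krippendorff_alpha(cm)
        assert report.alpha == pytest.approx(7 / 18, abs=1e-12)
        assert report.alpha == pytest.approx(brute_alpha(t.values), abs=1e-12)
        assert report.alpha == pytest.approx(1 - report.D_o / report.D_e, abs=1e-12)

    def test_single_category_alpha_is_undefined(self):
        t = table({"A": ["neuron"] * 3, "B": ["neuron"] * 3}, index=list("abc"))
        with pytest.raises(UndefinedAlphaError):
            alpha_from_ratings(t)

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            df = random_ratings_table(rng, with_missing=True)
            report = alpha_from_ratings(RatingsTable(df))
            assert report.alpha == pytest.approx(brute_alpha(df), abs=1e-10)

    def test_coincidence_path_equals_direct_path(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            df = random_ratings_table(rng)
            t = RatingsTable(df)
            via_cm = krippendorff_alpha(build_coincidence_matrix(t)).alpha
            direct = alpha_from_ratings(t).alpha
            assert via_cm == direct

    @given(perm=st.permutations(list(RATING_LABELS)))
    @settings(max_examples=30, derandomize=True)
    def test_alpha_invariant_under_category_relabeling(self, perm):
        rng = np.random.default_rng(7)
        df = random_ratings_table(rng)
        mapping = dict(zip(RATING_LABELS, perm))
        relabeled = df.map(lambda v: mapping[v] if isinstance(v, str) else v)
        a0 = alpha_from_ratings(RatingsTable(df)).alpha
        a1 = alpha_from_ratings(RatingsTable(relabeled)).alpha
        assert a1 == pytest.approx(a0, abs=1e-12)

    def test_moving_mass_off_diagonal_decreases_alpha(self):
        # Same marginals, growing off-diagonal mass.
        i, j = 0, 1
        K = len(RATING_LABELS)
        alphas = []
        for off in (0, 2, 4):
            counts = np.zeros((K, K))
            counts[i, i] = 10 - off
            counts[j, j] = 10 - off
            counts[i, j] = counts[j, i] = off
            cm = CoincidenceMatrix(categories=RATING_LABELS, counts=counts)
            alphas.append(krippendorff_alpha(cm).alpha)
        assert alphas[0] == 1.0
        assert alphas[0] > alphas[1] > alphas[2]


class TestPercentAgreement:
    def test_identical_raters_agree_completely(self):
        t = table(
            {"A": ["neuron", "microglia"], "B": ["neuron", "microglia"]},
            index=["c1", "c2"],
        )
        assert pairwise_percent_agreement(t) == (100.0, 0.0)

    def test_three_of_four_units_equal_is_75_percent(self):
        t = table(
            {
                "A": ["neuron", "astrocyte", "microglia", "endothelial"],
                "B": ["neuron", "astrocyte", "microglia", "neuron"],
            },
            index=["c1", "c2", "c3", "c4"],
        )
        mean, sem = pairwise_percent_agreement(t)
        assert mean == 75.0
        assert sem == 0.0

    def test_matches_bruteforce_over_all_pairs(self):
        rng = np.random.default_rng(23)
        df = random_full(rng, 30, 8)
        t = RatingsTable(df)
        mean, sem = pairwise_percent_agreement(t)
        bmean, bsem = brute_percent_agreement(df)
        assert mean == pytest.approx(bmean, abs=1e-10)
        assert sem == pytest.approx(bsem, abs=1e-10)

    def test_no_shared_units_is_an_error(self):
        t = table({"A": ["neuron", None], "B": [None, "neuron"]}, index=["c1", "c2"])
        with pytest.raises(EmptyDataError):
            pairwise_percent_agreement(t)


class TestDisagreementRanking:
    def test_diagonal_only_matrix_ranks_nothing(self):
        counts = np.diag([5.0, 3.0, 2.0, 1.0, 1.0])
        cm = CoincidenceMatrix(categories=RATING_LABELS, counts=counts)
        assert disagreement_ranking(cm) == []

    def test_reported_pair_counts_and_half_count_convention(self):
        K = len(RATING_LABELS)
        counts = np.zeros((K, K))
        a, e = RATING_LABELS.index("astrocyte"), RATING_LABELS.index("endothelial")
        n_, o_ = RATING_LABELS.index("neuron"), RATING_LABELS.index("oligodendrocyte")
        counts[a, e] = counts[e, a] = 341
        counts[n_, a] = counts[a, n_] = 327
        counts[o_, RATING_LABELS.index("microglia")] = 267
        counts[RATING_LABELS.index("microglia"), o_] = 267
        np.fill_diagonal(counts, 100)
        cm = CoincidenceMatrix(categories=RATING_LABELS, counts=counts)
        ranking = disagreement_ranking(cm)
        assert ranking[0] == (("astrocyte", "endothelial"), 682)
        assert ranking[1] == (("neuron", "astrocyte"), 654)
        half = disagreement_ranking(cm, half_counts=True)
        assert half[0] == (("astrocyte", "endothelial"), 341)

    def test_matches_bruteforce_sort_on_random_matrices(self):
        rng = np.random.default_rng(31)
        K = len(RATING_LABELS)
        for _ in range(20):
            sym = rng.integers(0, 50, size=(K, K)).astype(float)
            sym = sym + sym.T
            cm = CoincidenceMatrix(categories=RATING_LABELS, counts=sym)
            ranking = disagreement_ranking(cm)
            brute = sorted(
                (
                    ((RATING_LABELS[i], RATING_LABELS[j]), sym[i, j] + sym[j, i])
                    for i, j in itertools.combinations(range(K), 2)
                    if sym[i, j] + sym[j, i] > 0
                ),
                key=lambda item: (
                    -item[1],
                    RATING_LABELS.index(item[0][0]),
                    RATING_LABELS.index(item[0][1]),
                ),
            )
            assert ranking == brute


class TestRatingsTableValidation:
    def test_unknown_token_rejected_with_location(self):
        with pytest.raises(ValueError, match="glia"):
            table({"A": ["glia"], "B": ["neuron"]}, index=["c1"])

    def test_duplicate_unit_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            table({"A": ["neuron", "neuron"]}, index=["c1", "c1"])

    def test_subset_by_experience_and_test(self):
        t = table(
            {"E1": ["neuron", "astrocyte"], "I1": ["neuron", None]},
            index=["c1", "c2"],
            rater_experience={"E1": "experienced", "I1": "inexperienced"},
            unit_test={"c1": "test1", "c2": "test2"},
        )
        sub = t.select(experience="experienced", test="test2")
        assert sub.raters == ["E1"]
        assert sub.units == ["c2"]
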