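"""PCR result rubric, pooling, matrix summaries, CA, and the exact test."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from epicfinder.pcr import (
    Fragment,
    PcrResultMatrix,
    ca_coordinates,
    classify,
    clade_mean_amplifying,
    degeneracy_contingency_table,
    degeneracy_contingency_test,
    exact_test,
    find_universal_introns,
    pool,
    summarize_by_genus,
)
from epicfinder.synthetic import simulate_pcr_matrix


def _band(size, intensity="strong", constant=False):
    return Fragment(size=size, intensity=intensity, constant=constant)


class TestClassify:
    EXPECTED = 150  # exon-only size; intron-sized means >= 220

    def test_clean_long_product_in_all_individuals_is_promising(self):
        obs = [[_band(self.EXPECTED + 200)] for _ in range(4)]
        assert classify(obs, self.EXPECTED) == "P"

    def test_one_failing_individual_downgrades_to_intron_size(self):
        obs = [[_band(self.EXPECTED + 200)] for _ in range(3)] + [[]]
        assert classify(obs, self.EXPECTED) == "I"

    def test_faint_products_downgrade_to_intron_size(self):
        obs = [[_band(self.EXPECTED + 200, intensity="faint")] for _ in range(4)]
        assert classify(obs, self.EXPECTED) == "I"

    def test_three_bands_admitted_only_with_a_constant_band(self):
        with_const = [
            [_band(self.EXPECTED + 200), _band(300), _band(90, constant=True)]
            for _ in range(2)
        ]
        assert classify(with_const, self.EXPECTED) == "P"
        without = [
            [_band(self.EXPECTED + 200), _band(300), _band(90)] for _ in range(2)
        ]
        assert classify(without, self.EXPECTED) == "I"

    def test_more_than_three_bands_is_intron_size(self):
        obs = [[_band(self.EXPECTED + 200 + k) for k in range(4)] for _ in range(2)]
        assert classify(obs, self.EXPECTED) == "I"

    def test_products_at_exon_only_size_are_amplification(self):
        obs = [[_band(self.EXPECTED)] for _ in range(4)]
        assert classify(obs, self.EXPECTED) == "A"

    def test_just_below_and_at_the_intron_threshold(self):
        at = [[_band(self.EXPECTED + 70)] for _ in range(4)]
        below = [[_band(self.EXPECTED + 69)] for _ in range(4)]
        assert classify(at, self.EXPECTED) == "P"
        assert classify(below, self.EXPECTED) == "A"

    def test_no_products_anywhere_is_null(self):
        assert classify([[], [], []], self.EXPECTED) == "null"

    def test_unknown_expected_size_treats_products_as_intron_sized(self):
        assert classify([[_band(120)]], None) == "P"

    def test_zero_individuals_rejected(self):
        with pytest.raises(ValueError):
            classify([], self.EXPECTED)


class TestPool:
    @pytest.mark.parametrize(
        "cats,expected",
        [(["I", "P", "null"], "P"), (["A"], "A"), (["na", "na"], "na"),
         (["na", "null"], "null"), (["A", "I"], "I")],
    )
    def test_examples(self, cats, expected):
        assert pool(cats) == expected

    def test_join_semilattice_laws(self):
        cats = ["null", "A", "I", "P", "na"]
        for a, b, c in itertools.product(cats, repeat=3):
            assert pool([a, b]) == pool([b, a])
            assert pool([pool([a, b]), c]) == pool([a, pool([b, c])])
            assert pool([a, a]) == a if a != "na" else pool([a, a]) == "na"

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool([])


def _matrix(cells, genera=None, merge=None):
    df = pd.DataFrame(
        cells, index=[str(i + 1) for i in range(len(cells))],
        columns=genera or [f"G{j}" for j in range(len(cells[0]))],
    )
    return PcrResultMatrix(data=df, merge_groups=merge or [])


def test_matrix_tsv_round_trip(tmp_path):
    m = _matrix(
        [["P", "I"], ["null", "na"], ["A", "P"]], merge=[["1", "3"]]
    )
    path = tmp_path / "m.tsv"
    m.to_tsv(path)
    back = PcrResultMatrix.from_tsv(path)
    pd.testing.assert_frame_equal(back.data, m.data)
    assert back.merge_groups == m.merge_groups


def test_summaries_match_simulator_truth_and_count_conservation():
    m, truth = simulate_pcr_matrix(40, ["Ga", "Gb", "Gc"], seed=9)
    s = summarize_by_genus(m)
    for g in m.genera:
        for c in ("P", "I", "A", "null"):
            assert s.loc[g, c] == truth[g][c]
        assert (
            s.loc[g, "P"] + s.loc[g, "I"] + s.loc[g, "A"]
            + s.loc[g, "null"] + s.loc[g, "na"] == 40
        )


def test_empty_matrix_summary_is_all_zero():
    m = _matrix([["na", "na"]])
    s = summarize_by_genus(m)
    assert (s[["P", "I", "A", "null", "total"]].values == 0).all()


def test_summary_invariant_to_presentation_order():
    m, _ = simulate_pcr_matrix(25, ["Ga", "Gb"], seed=4)
    shuffled = PcrResultMatrix(data=m.data.sample(frac=1, random_state=0))
    pd.testing.assert_frame_equal(summarize_by_genus(m), summarize_by_genus(shuffled))


def test_clade_mean_single_genus_is_its_own_count():
    m, truth = simulate_pcr_matrix(30, ["Solo"], seed=2)
    means = clade_mean_amplifying(m, {"Solo": "cladeX"})
    assert means["cladeX"] == truth["Solo"]["P"] + truth["Solo"]["I"]


def test_universal_requires_amplification_wherever_tested():
    m = _matrix(
        [
            ["P", "P", "P"],
            ["P", "P", "null"],
            ["I", "na", "P"],
            ["A", "P", "P"],
        ]
    )
    assert find_universal_introns(m) == ["1", "3"]


def test_merge_groups_pool_before_universality():
    m = _matrix(
        [["P", "null"], ["null", "P"]], merge=[["1", "2"]]
    )
    assert find_universal_introns(m) == ["1+2"]


def test_downgrading_a_cell_never_adds_universal_introns():
    rnd = random.Random(13)
    m, _ = simulate_pcr_matrix(15, ["Ga", "Gb", "Gc"], seed=5)
    base = set(find_universal_introns(m))
    order = {"P": "I", "I": "A", "A": "null", "null": "null", "na": "na"}
    for _ in range(20):
        df = m.data.copy()
        i = rnd.choice(df.index)
        g = rnd.choice(df.columns)
        df.loc[i, g] = order[df.loc[i, g]]
        assert set(find_universal_introns(PcrResultMatrix(data=df))) <= base


# --- correspondence analysis ------------------------------------------------


def test_identical_genus_profiles_get_identical_coordinates():
    m = _matrix([["P", "P", "A"], ["I", "I", "P"], ["null", "null", "I"]])
    coords = ca_coordinates(m, dims=2)
    assert np.allclose(coords.loc["G0"], coords.loc["G1"])
    assert not np.allclose(coords.loc["G0"], coords.loc["G2"])


def test_genus_permutation_permutes_coordinates():
    m, _ = simulate_pcr_matrix(20, ["Ga", "Gb", "Gc", "Gd"], seed=21)
    c1 = ca_coordinates(m, dims=2)
    c2 = ca_coordinates(m, dims=2, genera=["Gc", "Ga", "Gd", "Gb"])
    for g in m.genera:
        assert np.allclose(c1.loc[g].values, c2.loc[g].values)


def test_full_rank_coordinates_reproduce_chi_square_distances():
    m, _ = simulate_pcr_matrix(30, ["Ga", "Gb", "Gc", "Gd"], seed=8)
    scored = m.data.map(lambda c: {"null": 0, "A": 1, "I": 2, "P": 3}.get(c, 0))
    scored = scored.loc[scored.sum(axis=1) > 0]
    N = scored.values.astype(float)
    P = N / N.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    coords = ca_coordinates(m, dims=len(m.genera)).values
    for j, k in itertools.combinations(range(len(m.genera)), 2):
        chi2 = np.sum((P[:, j] / c[j] - P[:, k] / c[k]) ** 2 / r)
        d2 = np.sum((coords[j] - coords[k]) ** 2)
        assert d2 == pytest.approx(chi2, rel=1e-8)


def test_zero_sum_rows_dropped_with_warning():
    m = _matrix([["P", "I"], ["null", "null"], ["I", "P"]])
    with pytest.warns(UserWarning, match="zero-sum"):
        coords = ca_coordinates(m)
    assert len(coords) == 2


# --- exact test -------------------------------------------------------------


def _log_prob(tbl):
    tbl = np.asarray(tbl)
    return (
        sum(math.lgamma(v + 1) for v in tbl.sum(axis=1))
        + sum(math.lgamma(v + 1) for v in tbl.sum(axis=0))
        - math.lgamma(tbl.sum() + 1)
        - sum(math.lgamma(v + 1) for v in tbl.ravel())
    )


def _brute_force_p(tbl):
    """Independent enumeration: nested loops over all margin-fixed tables."""
    tbl = np.asarray(tbl)
    rows, cols = tbl.sum(axis=1), tbl.sum(axis=0)
    obs_lp = _log_prob(tbl)
    r, c = tbl.shape
    total = 0.0
    # enumerate the first r-1 rows cell by cell
    ranges = []

    def rec(cells, row, col, row_left, cols_left):
        nonlocal total
        if row == r - 1:
            last = cols_left
            if all(v >= 0 for v in last):
                cand = np.array(cells + list(last)).reshape(r, c)
                lp = _log_prob(cand)
                if lp <= obs_lp + 1e-9:
                    total += math.exp(lp)
            return
        if col == c - 1:
            v = row_left
            if 0 <= v <= cols_left[col]:
                nxt = list(cols_left)
                nxt[col] -= v
                rec(cells + [v], row + 1, 0, rows[row + 1], nxt)
            return
        for v in range(min(row_left, cols_left[col]) + 1):
            nxt = list(cols_left)
            nxt[col] -= v
            rec(cells + [v], row, col + 1, row_left - v, nxt)

    rec([], 0, 0, rows[0], list(cols))
    return min(total, 1.0)


def test_two_by_two_matches_scipy_closed_form():
    rnd = random.Random(17)
    for _ in range(20):
        tbl = [[rnd.randint(0, 8), rnd.randint(0, 8)],
               [rnd.randint(0, 8), rnd.randint(0, 8)]]
        if sum(map(sum, tbl)) == 0 or min(map(sum, tbl)) == 0:
            continue
        t = pd.DataFrame(tbl)
        if (t.sum(axis=0) == 0).any():
            continue
        res = exact_test(t)
        expected = scipy.stats.fisher_exact(tbl)[1]
        assert res["p"] == pytest.approx(expected, abs=1e-10)


def test_identical_column_distributions_give_p_one():
    t = pd.DataFrame([[4, 4, 4], [2, 2, 2], [1, 1, 1], [3, 3, 3]])
    assert exact_test(t)["p"] == pytest.approx(1.0)


def test_enumeration_matches_independent_brute_force_on_random_tables():
    rnd = random.Random(23)
    done = 0
    while done < 12:
        r, c = rnd.choice([(2, 3), (3, 3), (4, 3), (2, 2)])
        tbl = np.array([[rnd.randint(0, 4) for _ in range(c)] for _ in range(r)])
        if tbl.sum() == 0 or tbl.sum() > 40:
            continue
        tbl = tbl[tbl.sum(axis=1) > 0][:, tbl.sum(axis=0) > 0]
        if tbl.shape[0] < 2 or tbl.shape[1] < 2:
            continue
        res = exact_test(pd.DataFrame(tbl))
        assert res["method"] == "enumeration"
        assert res["p"] == pytest.approx(_brute_force_p(tbl), abs=1e-9)
        done += 1


def test_monte_carlo_converges_to_enumeration_within_three_se():
    t = pd.DataFrame([[6, 1, 2], [1, 5, 1], [2, 2, 6]])
    exact = exact_test(t)["p"]
    mc = exact_test(t, max_tables=10, n_monte_carlo=20000, seed=42)
    assert mc["method"] == "monte_carlo"
    assert abs(mc["p"] - exact) <= 3 * mc["se"]


def test_contingency_table_classes_count_primers_over_sixfold():
    cases = [
        ("P", 2, 4),   # class 0
        ("I", 8, 4),   # class 1
        ("null", 8, 16),  # class 2
        ("A", 6, 6),   # boundary: "more than 6-fold" is strict
    ]
    tbl = degeneracy_contingency_table(cases, threshold=6)
    assert tbl.loc["P", 0] == 1
    assert tbl.loc["I", 1] == 1
    assert tbl.loc["null", 2] == 1
    assert tbl.loc["A", 0] == 1
    assert tbl.values.sum() == 4


def test_contingency_test_rejects_nonpositive_degeneracy():
    with pytest.raises(ValueError):
        degeneracy_contingency_test([("P", 0, 4)])
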