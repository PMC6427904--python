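import math

import numpy as np
import pytest
from scipy.stats import norm

from tumorvox.mrmr_selection import (
    discretize,
    dimension_sweep,
    mrmr_rank,
    mutual_information,
    rank_sum_select,
    sweep_f_values,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_mi_bits(x, y):
    """Plug-in MI by explicit dictionary counting."""
    n = len(x)
    joint, px, py = {}, {}, {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
        px[a] = px.get(a, 0) + 1
        py[b] = py.get(b, 0) + 1
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / n
        mi += p * math.log2(p / ((px[a] / n) * (py[b] / n)))
    return mi


def oracle_greedy_mrmr(columns, labels):
    """Exhaustive per-step argmax of relevance - mean-redundancy.

    Recomputes every MI from scratch each step; ties broken by input order.
    """
    names = list(columns)
    disc = {n: discretize(columns[n]) for n in names}
    selected = []
    while len(selected) < len(names):
        best, best_score = None, -np.inf
        for n in names:
            if n in selected:
                continue
            rel = oracle_mi_bits(disc[n], labels)
            red = (
                sum(oracle_mi_bits(disc[n], disc[s]) for s in selected) / len(selected)
                if selected
                else 0.0
            )
            if rel - red > best_score:
                best, best_score = n, rel - red
        selected.append(best)
    return selected


class TestDiscretize:
    def test_standard_normal_proportions(self, rng):
        x = rng.standard_normal(200_000)
        codes = discretize(x)
        frac = np.bincount(codes, minlength=3) / x.size
        tail = 1 - norm.cdf(1.0)  # ~0.1587
        assert frac[0] == pytest.approx(tail, abs=0.01)
        assert frac[1] == pytest.approx(1 - 2 * tail, abs=0.01)
        assert frac[2] == pytest.approx(tail, abs=0.01)

    def test_constant_column_single_level(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            codes = discretize(np.full(10, 3.0))
        assert set(codes) == {0}

    def test_three_point_column_spans_levels(self):
        # mu = 0, population sigma = sqrt(200/3) ~ 8.165: thresholds +-8.165
        codes = discretize(np.array([-10.0, 0.0, 10.0]))
        np.testing.assert_array_equal(codes, [0, 1, 2])


class TestMutualInformation:
    def test_independent_product_counts(self):
        x = np.repeat([0, 0, 1, 1], 5)
        y = np.tile([0, 1], 10)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_identity_balanced_binary_one_bit(self):
        x = np.array([0, 1] * 50)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_matches_summation_oracle_on_small_joint(self):
        # joint counts [[2, 1], [1, 2]]
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        assert mutual_information(x, y) == pytest.approx(oracle_mi_bits(x, y), abs=1e-12)

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(20):
            x = rng.integers(0, 3, size=200)
            y = rng.integers(0, 4, size=200)
            assert mutual_information(x, y) == pytest.approx(
                oracle_mi_bits(x, y), abs=1e-10
            )

    def test_symmetry(self, rng):
        x = rng.integers(0, 3, size=500)
        y = rng.integers(0, 3, size=500)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x), abs=1e-12
        )

    def test_bounded_by_min_entropy(self, rng):
        def entropy(z):
            p = np.bincount(z) / len(z)
            p = p[p > 0]
            return float(-(p * np.log2(p)).sum())

        for _ in range(10):
            x = rng.integers(0, 3, size=300)
            y = rng.integers(0, 5, size=300)
            assert mutual_information(x, y) <= min(entropy(x), entropy(y)) + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3), np.zeros(4))


def _toy_table(rng, n=300):
    """Informative feature, its exact duplicate, and two noise columns."""
    labels = rng.integers(0, 2, size=n)
    informative = labels * 2.0 + rng.normal(0, 0.1, n)
    return {
        "informative": informative,
        "duplicate": informative.copy(),
        "noise_a": rng.normal(0, 1, n),
        "noise_b": rng.normal(0, 1, n),
    }, labels


class TestMRMRRank:
    def test_single_feature(self, rng):
        labels = rng.integers(0, 2, size=100)
        x = labels + rng.normal(0, 0.1, 100)
        result = mrmr_rank({"only": x}, labels)
        assert result.order == ["only"]
        assert result.steps[0].score == pytest.approx(result.steps[0].relevance)
        assert result.steps[0].redundancy == 0.0

    def test_full_order_matches_exhaustive_oracle(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            columns, labels = _toy_table(r)
            result = mrmr_rank(columns, labels)
            assert result.order == oracle_greedy_mrmr(columns, labels), f"seed {seed}"

    def test_six_feature_tables_match_oracle(self):
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            labels = r.integers(0, 3, size=150)
            columns = {}
            for i in range(6):
                signal = labels if i % 2 == 0 else r.integers(0, 3, size=150)
                columns[f"f{i}"] = signal + r.normal(0, 0.5 + i * 0.2, 150)
            assert mrmr_rank(columns, labels).order == oracle_greedy_mrmr(columns, labels)

    def test_label_determining_feature_first(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            labels = r.integers(0, 3, size=200)
            columns = {
                "noise_1": r.normal(0, 1, 200),
                "determines": labels * 3.0,
                "noise_2": r.normal(0, 1, 200),
            }
            assert mrmr_rank(columns, labels).order[0] == "determines"

    def test_step_one_is_max_relevance(self, rng):
        columns, labels = _toy_table(rng)
        result = mrmr_rank(columns, labels)
        rels = {n: mutual_information(discretize(c), labels) for n, c in columns.items()}
        assert result.order[0] == max(columns, key=lambda n: rels[n])

    def test_duplicate_penalized_by_self_relevance(self, rng):
        columns, labels = _toy_table(rng)
        result = mrmr_rank(columns, labels, k=4)
        assert result.order[0] == "informative"
        # Once "informative" is selected, the duplicate's pairwise MI with it
        # equals its discretized self-entropy, which bounds its relevance from
        # above -- so its score goes non-positive and noise enters before it.
        d_inf = discretize(columns["informative"])
        d_dup = discretize(columns["duplicate"])
        rel_dup = mutual_information(d_dup, labels)
        assert mutual_information(d_dup, d_inf) >= rel_dup - 1e-12
        assert result.order[-1] == "duplicate"

    def test_duplicate_never_precedes_equal_independent_feature(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            labels = r.integers(0, 2, size=400)
            first = labels * 2.0 + r.normal(0, 0.5, 400)
            # equally relevant signal with noise independent of "first"
            other = labels * 2.0 + r.normal(0, 0.5, 400)
            columns = {
                "first": first,
                "dup_of_first": first.copy(),
                "other": other,
            }
            order = mrmr_rank(columns, labels).order
            assert order.index("other") < order.index("dup_of_first")

    def test_empty_and_bad_k(self, rng):
        with pytest.raises(ValueError):
            mrmr_rank({}, np.array([]))
        columns, labels = _toy_table(rng)
        with pytest.raises(ValueError):
            mrmr_rank(columns, labels, k=0)
        with pytest.raises(ValueError):
            mrmr_rank(columns, labels, k=99)


class TestDimensionSweep:
    def test_f_value_list(self):
        assert sweep_f_values() == [62, 57, 52, 47, 42, 37, 32, 27, 22, 17, 12, 7, 2]

    def test_identical_metrics_select_smaller_f(self):
        tables = {10: {"a": 0.5, "b": 0.7}, 5: {"a": 0.5, "b": 0.7}}
        result = rank_sum_select(tables)
        assert result.selected_dimension == 5
        assert result.rank_sums[10] == result.rank_sums[5]

    def test_toy_rank_sums_match_hand_computation(self):
        # 3 dimensions x 2 metrics; higher is better.
        # m1: f=15 -> 0.9 (rank 1), f=10 -> 0.8 (rank 2), f=5 -> 0.7 (rank 3)
        # m2: f=15 -> 0.5 (rank 2.5, tied), f=10 -> 0.5 (rank 2.5), f=5 -> 0.6 (rank 1)
        tables = {
            15: {"m1": 0.9, "m2": 0.5},
            10: {"m1": 0.8, "m2": 0.5},
            5: {"m1": 0.7, "m2": 0.6},
        }
        result = rank_sum_select(tables)
        assert result.rank_sums == {15: 3.5, 10: 4.5, 5: 4.0}
        assert result.selected_dimension == 15

    def test_sweep_uses_ranking_prefixes(self):
        ranking = [f"f{i}" for i in range(6)]
        seen = []

        def evaluate(features):
            seen.append(tuple(features))
            return {"metric": len(features) * 0.1}  # bigger sets score higher

        result = dimension_sweep(ranking, [6, 4, 2], evaluate)
        assert seen == [tuple(ranking[:6]), tuple(ranking[:4]), tuple(ranking[:2])]
        assert result.selected_dimension == 6
        assert result.ranking == ranking

    def test_f_exceeding_feature_count_rejected(self):
        with pytest.raises(ValueError):
            dimension_sweep(["a", "b"], [3], lambda fs: {"m": 1.0})

    def test_undefined_cells_excluded(self):
        tables = {
            4: {"a": 0.5, "b": float("nan")},
            2: {"a": 0.6, "b": 0.1},
        }
        result = rank_sum_select(tables)
        assert result.rank_sums == {4: 2.0, 2: 1.0}
        assert result.selected_dimension == 2
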