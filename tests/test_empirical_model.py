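import math

import numpy as np
import pytest

from helpers import (
    naive_conditional_entropy,
    naive_gap,
    naive_structured_ll,
    naive_tally,
    random_discrete_dataset,
)
from mcec import (
    DiscreteTimeSeriesDataset,
    SyntheticSpec,
    conditional_entropy,
    count_configurations,
    entropy,
    entropy_gap,
    generate,
    maxent_structure_check,
    structured_log_likelihood,
    total_correlation,
)


class TestCountConfigurations:
    def test_single_instance(self):
        data = DiscreteTimeSeriesDataset(np.array([[[0], [1], [0]]]), [2], ["a"])
        counts = count_configurations(data, 2)
        assert counts.joint == {((0, 1), (0,), "a"): 1}
        assert counts.support_a == 1 and counts.n_classes == 1

    def test_matches_naive_tally_on_toy(self, toy_dataset):
        for n in (1, 2, 3):
            counts = count_configurations(toy_dataset, n)
            assert counts.joint == dict(naive_tally(toy_dataset, n))

    def test_matches_naive_tally_random(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            data = random_discrete_dataset(rng)
            n = int(rng.integers(1, data.length + 1))
            counts = count_configurations(data, n)
            assert counts.joint == dict(naive_tally(data, n))

    def test_conservation(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            data = random_discrete_dataset(rng)
            for n in range(1, data.length + 1):
                counts = count_configurations(data, n)
                N = data.n_instances
                assert sum(counts.joint.values()) == N
                assert sum(counts.count_a.values()) == N
                assert sum(counts.count_ab.values()) == N
                assert sum(counts.count_ac.values()) == N
                assert sum(counts.count_c.values()) == N

    def test_support_nondecreasing_in_n(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            data = random_discrete_dataset(rng)
            supports = [
                count_configurations(data, n).support_a
                for n in range(1, data.length + 1)
            ]
            assert supports == sorted(supports)
            assert supports[-1] <= data.n_instances

    def test_empty_suffix_at_full_length(self, toy_dataset):
        counts = count_configurations(toy_dataset, 3)
        assert all(b == () for (_, b, _) in counts.joint)

    def test_split_out_of_range(self, toy_dataset):
        for bad in (0, 4):
            with pytest.raises(ValueError):
                count_configurations(toy_dataset, bad)


class TestEntropy:
    @pytest.mark.parametrize(
        "dist, expected",
        [([0.5, 0.5], 1.0), ([1.0], 0.0), ([0.25] * 4, 2.0)],
    )
    def test_known_values(self, dist, expected):
        assert entropy(dist) == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_distributions(self):
        with pytest.raises(ValueError):
            entropy([0.7, 0.7])
        with pytest.raises(ValueError):
            entropy([-0.1, 1.1])


class TestConditionalEntropy:
    def test_functional_dependence_gives_zero(self):
        # class is exactly the first symbol
        rng = np.random.default_rng(13)
        symbols = rng.integers(0, 2, size=(40, 3, 1))
        labels = [str(int(s)) for s in symbols[:, 0, 0]]
        data = DiscreteTimeSeriesDataset(symbols, [2], labels)
        counts = count_configurations(data, 2)
        assert conditional_entropy(counts, "C", "A") == pytest.approx(0.0, abs=1e-12)

    def test_balanced_independence_gives_one_bit(self, balanced_dataset):
        counts = count_configurations(balanced_dataset, 1)
        assert conditional_entropy(counts, "C", "A") == pytest.approx(1.0, abs=1e-12)

    def test_toy_matches_hand_summation(self, toy_dataset):
        for n in (1, 2, 3):
            counts = count_configurations(toy_dataset, n)
            prefixes = [
                tuple(int(v) for v in toy_dataset.symbols[j, :n, 0])
                for j in range(6)
            ]
            labels = toy_dataset.labels
            assert conditional_entropy(counts, "C", "A") == pytest.approx(
                naive_conditional_entropy(list(zip(prefixes, labels))), abs=1e-12
            )

    def test_unsupported_pair_rejected(self, toy_dataset):
        counts = count_configurations(toy_dataset, 1)
        with pytest.raises(ValueError):
            conditional_entropy(counts, "A", "C")


class TestEntropyGap:
    def test_zero_at_full_length(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            data = random_discrete_dataset(rng)
            assert entropy_gap(data, data.length) == 0.0

    def test_nonnegative_and_matches_naive(self):
        rng = np.random.default_rng(15)
        for _ in range(15):
            data = random_discrete_dataset(rng)
            for n in range(1, data.length + 1):
                gap = entropy_gap(data, n)
                assert gap >= -1e-9
                assert gap == pytest.approx(naive_gap(data, n), abs=1e-9)

    def test_nonincreasing_in_n(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            data = random_discrete_dataset(rng)
            gaps = [entropy_gap(data, n) for n in range(1, data.length + 1)]
            for g1, g2 in zip(gaps, gaps[1:]):
                assert g2 <= g1 + 1e-9

    def test_planted_conditional_independence(self):
        """With the class depending only on the prefix, the gap at the
        planted split is within sampling error of zero."""
        data = generate(SyntheticSpec(N=2000, L=6, n_star=2, alphabet_size=2, seed=17))
        assert entropy_gap(data, 2) < 0.05
        assert entropy_gap(data, 1) > 0.3


class TestTotalCorrelation:
    def test_independent_fair_bits(self):
        # population table of two independent fair coins
        cols = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert total_correlation(cols) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_copy_is_one_bit(self):
        cols = np.array([[0, 0], [1, 1], [0, 0], [1, 1]])
        assert total_correlation(cols) == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        cols = np.array([[0, 1, 1], [0, 0, 1], [1, 1, 0], [0, 1, 1]])
        # direct evaluation: sum of marginal entropies minus joint entropy
        from collections import Counter

        from helpers import naive_entropy

        expected = sum(
            naive_entropy(Counter(cols[:, v]).values()) for v in range(3)
        ) - naive_entropy(Counter(map(tuple, cols.tolist())).values())
        assert total_correlation(cols) == pytest.approx(expected, abs=1e-12)
        assert total_correlation(cols) >= 0


class TestStructuredLogLikelihood:
    def test_identical_instances_have_zero_ll(self, identical_dataset):
        for n in range(1, 5):
            counts = count_configurations(identical_dataset, n)
            assert structured_log_likelihood(counts) == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_instance_sum(self, toy_dataset):
        for n in (1, 2, 3):
            counts = count_configurations(toy_dataset, n)
            assert structured_log_likelihood(counts) == pytest.approx(
                naive_structured_ll(toy_dataset, n), abs=1e-9
            )

    def test_entropy_duality_random(self):
        rng = np.random.default_rng(18)
        for _ in range(15):
            data = random_discrete_dataset(rng)
            for n in range(1, data.length + 1):
                counts = count_configurations(data, n)
                ll = structured_log_likelihood(counts)
                h = (
                    conditional_entropy(counts, "B", "A")
                    + conditional_entropy(counts, "C", "A")
                )
                # add H(A) via the duality with the naive per-instance sum
                assert ll == pytest.approx(
                    naive_structured_ll(data, n), abs=1e-9
                )
                assert ll <= 1e-12
                assert h >= -1e-12

    def test_full_length_convention(self, toy_dataset):
        """At n = L the empty suffix contributes nothing: LL reduces to
        -N [H(A) + H(C|A)]."""
        counts = count_configurations(toy_dataset, 3)
        assert conditional_entropy(counts, "B", "A") == pytest.approx(0.0, abs=1e-12)
        ll = structured_log_likelihood(counts)
        assert ll == pytest.approx(naive_structured_ll(toy_dataset, 3), abs=1e-9)


class TestMaxEntCheck:
    def test_random_tiny_systems(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            data = random_discrete_dataset(rng, max_n=20, max_l=3, max_a=2, max_m=1)
            n = int(rng.integers(1, data.length + 1))
            report = maxent_structure_check(count_configurations(data, n))
            assert report.distance <= 1e-6
            assert report.entropy_maxent >= report.entropy_empirical - 1e-9

    def test_product_form_is_fixed_point(self, balanced_dataset):
        """A dataset whose joint already factors as P(a)P(b|a)P(c|a) is left
        untouched: distance is numerically zero."""
        report = maxent_structure_check(count_configurations(balanced_dataset, 1))
        assert report.distance <= 1e-12
        assert report.entropy_maxent == pytest.approx(
            report.entropy_empirical, abs=1e-9
        )

    def test_refuses_large_state_space(self):
        data = generate(SyntheticSpec(N=400, L=12, seed=20))
        with pytest.raises(ValueError, match="guard"):
            maxent_structure_check(count_configurations(data, 6))
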