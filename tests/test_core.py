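"""Unit tests for the encoding/interference/retrieval primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmrecall import ModelParams
from fmrecall.core import (
    SerialPositionCurve,
    Trace,
    compute_distance,
    end_of_list_interference,
    generate_item_trace,
    luce_probabilities,
    luce_sample,
    overwrite_adjacent,
    perturbation_step_matrix,
    positional_uncertainty,
    recovery_probability,
    sample_output_order,
    similarity,
    simulate_curve,
    simulate_trial,
    simulate_trials,
)
from fmrecall.designs import ConditionSpec


def _trace(md, mi):
    return Trace(md=np.asarray(md, dtype=np.int8), mi=np.asarray(mi, dtype=np.int8))


class TestTraceGeneration:
    def test_values_and_segment_sizes(self, rng):
        tr = generate_item_trace(0, 20, rng)
        assert tr.md.size == 0 and tr.mi.size == 20
        assert set(np.unique(tr.mi)) <= {-1, 1}
        tr = generate_item_trace(2, 20, rng)
        assert tr.n_features == 22

    def test_same_seed_same_trace(self):
        a = generate_item_trace(5, 5, np.random.default_rng(7))
        b = generate_item_trace(5, 5, np.random.default_rng(7))
        assert np.array_equal(a.values, b.values)

    def test_feature_mean_is_centred(self, rng):
        draws = np.array(
            [generate_item_trace(0, 4, rng).values for _ in range(10_000)]
        )
        assert np.abs(draws.mean(axis=0)).max() < 0.03

    @pytest.mark.parametrize("n_md,n_mi", [(-1, 5), (5, -1), (0, 0)])
    def test_invalid_counts_rejected(self, rng, n_md, n_mi):
        with pytest.raises(ValueError):
            generate_item_trace(n_md, n_mi, rng)


class TestOverwriting:
    def test_total_match_zeroes_everything(self):
        tr = _trace([1, -1], [1, 1, -1])
        out = overwrite_adjacent(tr, tr)
        assert np.array_equal(out.values, np.zeros(5))

    def test_no_match_leaves_unchanged(self):
        tr = _trace([1, -1], [1, 1, -1])
        flipped = _trace(-tr.md, -tr.mi)
        out = overwrite_adjacent(tr, flipped)
        assert np.array_equal(out.values, tr.values)

    def test_zeroed_count_follows_binomial_oracle(self, rng):
        # matches between independent +-1 pairs are Bernoulli(1/2) per feature
        n, reps = 20, 4000
        zeroed = np.empty(reps)
        for i in range(reps):
            a = generate_item_trace(0, n, rng)
            b = generate_item_trace(0, n, rng)
            zeroed[i] = (overwrite_adjacent(a, b).values == 0).sum()
        se = np.sqrt(n * 0.25 / reps)
        assert abs(zeroed.mean() - n / 2) < 4 * se

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overwrite_adjacent(_trace([1], [1, 1]), _trace([1, 1], [1]))

    def test_degradation_is_one_way(self, rng):
        # zeros can only accumulate through successive overwriting passes
        tr = generate_item_trace(4, 16, rng)
        zeros = 0
        for _ in range(5):
            tr = overwrite_adjacent(tr, generate_item_trace(4, 16, rng))
            now = int((tr.values == 0).sum())
            assert now >= zeros
            zeros = now


class TestEndOfListInterference:
    def test_md_segment_untouched(self, rng):
        tr = generate_item_trace(20, 20, rng)
        out = end_of_list_interference(tr, rng)
        assert np.array_equal(out.md, tr.md)

    def test_mi_zeroing_matches_binomial_oracle(self, rng):
        reps, n_mi = 4000, 20
        zeroed = np.empty(reps)
        for i in range(reps):
            tr = generate_item_trace(2, n_mi, rng)
            zeroed[i] = (end_of_list_interference(tr, rng).mi == 0).sum()
        se = np.sqrt(n_mi * 0.25 / reps)
        assert abs(zeroed.mean() - n_mi / 2) < 4 * se

    def test_no_mi_features_is_identity(self, rng):
        tr = generate_item_trace(10, 0, rng)
        assert np.array_equal(end_of_list_interference(tr, rng).values, tr.values)


class TestDistanceAndSimilarity:
    def test_identical_traces_have_zero_distance(self, rng):
        tr = generate_item_trace(3, 7, rng)
        assert compute_distance(tr, tr, a=17.0) == 0.0

    def test_full_mismatch_gives_a(self):
        pm = _trace([], [1] * 20)
        sm = _trace([], [-1] * 20)
        assert compute_distance(pm, sm, a=20.0) == pytest.approx(20.0)

    def test_printed_formula(self):
        # 5 mismatches out of N=20 at a=20 -> d = 5
        pm = _trace([], [-1] * 5 + [1] * 15)
        sm = _trace([], [1] * 20)
        assert compute_distance(pm, sm, a=20.0) == pytest.approx(5.0)

    def test_overwritten_zero_counts_as_mismatch(self):
        pm = _trace([], [0, 1])
        sm = _trace([], [1, 1])
        assert compute_distance(pm, sm, a=2.0) == pytest.approx(1.0)

    def test_similarity_values_and_monotonicity(self):
        assert similarity(0.0) == 1.0
        assert similarity(5.0) == pytest.approx(np.exp(-5))
        with pytest.raises(ValueError):
            similarity(-0.1)

    @given(st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_similarity_orders_by_distance(self, d1, d2):
        # non-increasing everywhere; strictly decreasing once the distances
        # differ beyond float resolution of the exponential
        if d1 < d2:
            assert similarity(d1) >= similarity(d2)
            if d2 - d1 > 1e-9:
                assert similarity(d1) > similarity(d2)


class TestLuceRule:
    def test_single_candidate(self, rng):
        pm = generate_item_trace(0, 10, rng)
        assert luce_probabilities(pm, [generate_item_trace(0, 10, rng)], 20.0) == (
            pytest.approx([1.0])
        )

    def test_symmetric_candidates_split_evenly(self):
        pm = _trace([], [1] * 4)
        sm = _trace([], [-1, 1, 1, 1])  # each candidate 1 mismatch
        probs = luce_probabilities(pm, [sm, sm, sm], 8.0)
        assert probs == pytest.approx([1 / 3] * 3)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ratio_rule(self):
        # candidates at 0, 1, 2 mismatches of 4 features, a=4 -> s = e^0, e^-1, e^-2
        pm = _trace([], [1, 1, 1, 1])
        sms = [
            _trace([], [1, 1, 1, 1]),
            _trace([], [-1, 1, 1, 1]),
            _trace([], [-1, -1, 1, 1]),
        ]
        probs = luce_probabilities(pm, sms, a=4.0)
        s = np.exp([-0.0, -1.0, -2.0])
        assert probs == pytest.approx(s / s.sum())

    def test_empty_search_set_rejected(self, rng):
        with pytest.raises(ValueError):
            luce_probabilities(generate_item_trace(0, 4, rng), [], 4.0)


class TestRecoveryProbability:
    @pytest.mark.parametrize(
        "r,c,expected",
        [(0, 3.0, 1.0), (5, 0.0, 1.0), (1, 2.0, np.exp(-2.0))],
    )
    def test_values(self, r, c, expected):
        assert recovery_probability(r, c) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            recovery_probability(-1, 1.0)


class TestPositionalUncertainty:
    def test_no_perturbation_is_identity(self):
        assert np.array_equal(positional_uncertainty(5, 0.0, 10), np.eye(5))
        assert np.array_equal(positional_uncertainty(5, 0.05, 0), np.eye(5))

    def test_boundary_equation_one_step(self):
        u = positional_uncertainty(2, 0.05, 1)
        assert u[0, 0] == pytest.approx(1 - 0.05 / 2)
        assert u[0, 1] == pytest.approx(0.05 / 2)

    def test_rows_stay_stochastic_and_nonnegative(self):
        u = positional_uncertainty(7, 0.3, 25)
        assert np.all(u >= 0)
        assert u.sum(axis=1) == pytest.approx(np.ones(7), abs=1e-12)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            positional_uncertainty(5, 1.5, 3)
        with pytest.raises(ValueError):
            perturbation_step_matrix(0, 0.05)


class TestOutputOrder:
    def test_identity_without_drift(self, rng):
        u = np.eye(6)
        for _ in range(20):
            assert np.array_equal(sample_output_order(u, rng), np.arange(6))

    def test_marginal_order_matches_enumeration_oracle(self):
        # Brute force: enumerate all joint sampled-position combinations for
        # n=3 and, within each, average the item->output-position assignment
        # over uniform tie-breaking.
        import itertools

        u = positional_uncertainty(3, 0.3, 4)
        expected = np.zeros((3, 3))
        for combo in itertools.product(range(3), repeat=3):
            prob = np.prod([u[i, combo[i]] for i in range(3)])
            orders = []
            for perm in itertools.permutations(range(3)):
                # a tie-break permutation is consistent iff it sorts combo
                if all(
                    combo[perm[k]] <= combo[perm[k + 1]] for k in range(2)
                ):
                    orders.append(perm)
            for order in orders:
                for out_pos, item in enumerate(order):
                    expected[item, out_pos] += prob / len(orders)

        rng = np.random.default_rng(99)
        counts = np.zeros((3, 3))
        reps = 60_000
        for _ in range(reps):
            order = sample_output_order(u, rng)
            for out_pos, item in enumerate(order):
                counts[item, out_pos] += 1
        freqs = counts / reps
        se = np.sqrt(expected * (1 - expected) / reps)
        assert np.all(np.abs(freqs - expected) < 5 * np.maximum(se, 1e-4))


class TestTrialSimulation:
    def test_fixed_seed_is_bit_identical(self, cond7, paper_params):
        a = simulate_trial(cond7, paper_params, np.random.default_rng(3))
        b = simulate_trial(cond7, paper_params, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_perfect_recall_limit(self, cond7):
        # no output interference, no drift, no adoption, no overwriting and a
        # steep similarity gradient: the matching target dominates every cue
        params = ModelParams(a_verbal=200.0, a_spatial=200.0, c=0.0, theta=0.0)
        trials = simulate_trials(
            cond7, params, 2000, np.random.default_rng(11), disable_overwriting=True
        )
        assert trials.mean() > 0.999

    def test_flat_similarity_recall_is_at_chance(self):
        # a ~ 0 makes all similarities equal; with c=0 recall reduces to a
        # uniform draw without replacement, so each position is correct 1/n
        cond = ConditionSpec(
            id="c3", task_domain="verbal", dual_task="none",
            list_length=3, n_md=0, n_mi=20,
        )
        params = ModelParams(a_verbal=1e-9, c=0.0, theta=0.0)
        acc = simulate_trials(cond, params, 60_000, np.random.default_rng(2)).mean(0)
        se = np.sqrt((1 / 3) * (2 / 3) / 60_000)
        assert np.all(np.abs(acc - 1 / 3) < 4 * se)

    def test_curve_aggregation(self, cond7, paper_params):
        one = simulate_curve(cond7, paper_params, 1, np.random.default_rng(0))
        assert set(np.unique(one.proportions)) <= {0.0, 1.0}
        with pytest.raises(ValueError):
            simulate_curve(cond7, paper_params, 0, np.random.default_rng(0))

    def test_two_seeds_agree_within_sampling_error(self, cond7, paper_params):
        n = 5000
        a = simulate_curve(cond7, paper_params, n, np.random.default_rng(1))
        b = simulate_curve(cond7, paper_params, n, np.random.default_rng(2))
        se = np.sqrt(a.proportions * (1 - a.proportions) / n)
        assert np.all(np.abs(a.proportions - b.proportions) < 3 * np.sqrt(2) * se)

    def test_curve_type_validates_range(self):
        with pytest.raises(ValueError):
            SerialPositionCurve(condition="x", n_items=2, proportions=[0.5, 1.2])


class TestLuceSampling:
    def test_frequencies_match_probabilities(self):
        pm = _trace([], [1, 1, 1, 1, 0, 0, -1, -1])
        sms = [
            _trace([], [1, 1, 1, 1, 1, 1, -1, -1]),
            _trace([], [-1, 1, 1, 1, 1, -1, 1, -1]),
            _trace([], [-1, -1, -1, 1, 1, 1, 1, 1]),
        ]
        probs = luce_probabilities(pm, sms, a=8.0)
        draws = luce_sample(pm, sms, 8.0, 1.0, np.random.default_rng(4), 50_000)
        freqs = np.bincount(draws, minlength=3) / draws.size
        se = np.sqrt(probs * (1 - probs) / draws.size)
        assert np.all(np.abs(freqs - probs) < 4 * se)
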