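import itertools
import math

import numpy as np
import pytest
from scipy import stats

from fluorosim import (
    ErrorParams,
    Peptide,
    apply_dye_failure,
    apply_edman_dilation,
    apply_photobleaching,
    dilation_pmf,
    encode_ideal,
    halflife_to_decay_constant,
    label_positions,
    minutes_to_cycles,
    simulate_batch,
    simulate_observed_fluorosequence,
)


def brute_force_dilation_pmf(d, e, p):
    """Independent oracle: enumerate all Bernoulli trial strings of length d+e
    that end in a success and contain exactly d successes."""
    total = 0.0
    for trials in itertools.product([0, 1], repeat=d + e):
        if trials[-1] == 1 and sum(trials) == d:
            total += p ** d * (1 - p) ** e
    return total


class TestDilationPmf:
    def test_perfect_chemistry(self):
        assert dilation_pmf(3, 0, 1.0) == 1.0
        assert dilation_pmf(3, 2, 1.0) == 0.0

    def test_geometric_wait_for_unit_interval(self):
        for e in range(5):
            assert dilation_pmf(1, e, 0.5) == pytest.approx(0.5 ** (1 + e))

    def test_worked_value(self):
        # C(2,1) * 0.9^2 * 0.1 = 0.162
        assert dilation_pmf(2, 1, 0.9) == pytest.approx(0.162)

    @pytest.mark.parametrize("p", [0.5, 0.9, 0.95])
    def test_matches_brute_force_enumeration(self, p):
        for d in range(1, 4):
            for e in range(7):
                assert dilation_pmf(d, e, p) == pytest.approx(
                    brute_force_dilation_pmf(d, e, p), abs=1e-12
                )

    @pytest.mark.parametrize("d,p", [(1, 0.5), (3, 0.9), (5, 0.95)])
    def test_normalization(self, d, p):
        total = sum(dilation_pmf(d, e, p) for e in range(2000))
        assert abs(total - 1.0) < 1e-9

    def test_sampled_mean_matches_negative_binomial(self, rng):
        """Mean extra cycles for an interval d is d*q/p."""
        d, p = 4, 0.9
        draws = rng.negative_binomial(d, p, size=100_000)
        expected = d * (1 - p) / p
        assert np.mean(draws) == pytest.approx(expected, abs=4 * np.std(draws) / math.sqrt(draws.size))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            dilation_pmf(0, 0, 0.9)
        with pytest.raises(ValueError):
            dilation_pmf(1, -1, 0.9)


class TestDyeFailure:
    def test_u_zero_is_identity(self, rng):
        labels = [(2, "K"), (5, "K")]
        assert apply_dye_failure(labels, 0.0, rng) == labels

    def test_u_one_deletes_all(self, rng):
        assert apply_dye_failure([(2, "K"), (5, "K")], 1.0, rng) == []

    def test_out_of_range(self, rng):
        with pytest.raises(ValueError):
            apply_dye_failure([], 1.5, rng)

    def test_order_preserved(self, rng):
        labels = [(i, "K") for i in range(1, 40)]
        survivors = apply_dye_failure(labels, 0.5, rng)
        assert survivors == sorted(survivors)


class TestEdmanDilation:
    def test_perfect_chemistry_removal_at_position(self, rng):
        out = apply_edman_dilation([(2, "K"), (5, "K")], 1.0, None, rng)
        assert out == [(2, "K", 2.0), (5, "K", 5.0)]

    def test_labels_at_or_past_anchor_never_removed(self, rng):
        out = apply_edman_dilation([(1, "K"), (4, "K")], 1.0, 3, rng)
        assert out[0][2] == 1.0
        assert math.isinf(out[1][2])

    def test_removal_cycles_strictly_increasing(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            out = apply_edman_dilation(
                [(1, "K"), (3, "K"), (4, "Y"), (9, "K")], 0.7, None, rng
            )
            cycles = [c for _, _, c in out]
            assert all(a < b for a, b in zip(cycles, cycles[1:]))
            # a removal can never precede the label's position
            assert all(c >= pos for pos, _, c in out)


class TestPhotobleaching:
    def test_b_zero_drops_at_removal_cycles(self, rng):
        read = apply_photobleaching([(2, "K", 2.0), (5, "K", 5.0)], 0.0, 30, rng)
        assert read.to_string() == "(K,2),(K,5)"

    def test_budget_truncation(self, rng):
        read = apply_photobleaching([(2, "K", 2.0), (5, "K", 5.0)], 0.0, 2, rng)
        assert read.to_string() == "(K,2)"

    def test_negative_decay_constant(self, rng):
        with pytest.raises(ValueError):
            apply_photobleaching([], -0.1, 30, rng)

    def test_observed_cycle_never_exceeds_removal_cycle(self):
        rng = np.random.default_rng(0)
        b = halflife_to_decay_constant(5)
        for _ in range(200):
            read = apply_photobleaching([(4, "K", 4.0)], b, 30, rng)
            assert all(cycle <= 4 for _, cycle in read)

    def test_anchored_label_can_bleach_into_a_drop(self):
        # removal is infinite (label sits past the anchor) but a bleach within
        # the budget still registers as a luminosity drop
        rng = np.random.default_rng(1)
        b = halflife_to_decay_constant(2)
        reads = [apply_photobleaching([(5, "K", math.inf)], b, 30, rng) for _ in range(50)]
        assert any(read for read in reads)


class TestHalflifeConversion:
    def test_infinite_half_life_means_no_bleaching(self):
        assert halflife_to_decay_constant(math.inf) == 0.0

    def test_survival_at_half_life_is_half(self):
        for h in [1, 20, 1800]:
            b = halflife_to_decay_constant(h)
            assert math.exp(-b * h) == pytest.approx(0.5)

    def test_minutes_to_cycles_at_one_second_exposure(self):
        assert minutes_to_cycles(30.0, 1.0) == pytest.approx(1800.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            halflife_to_decay_constant(0)
        with pytest.raises(ValueError):
            minutes_to_cycles(1.0, 0.0)


class TestComposedSimulation:
    def test_zero_error_equals_ideal(self, toy_peptides, rng):
        params = ErrorParams()  # u=0, p=1, b=0
        for pep in toy_peptides.values():
            for scheme in ["K", "K+Y+W"]:
                assert simulate_observed_fluorosequence(
                    pep, scheme, params, 30, rng
                ) == encode_ideal(pep, scheme, 30)

    def test_seed_determinism(self, toy_peptides):
        pep = toy_peptides["swap_demo"]
        params = ErrorParams(0.2, 0.9, halflife_to_decay_constant(20))
        reads_a = [
            simulate_observed_fluorosequence(pep, "K", params, 6, np.random.default_rng(s))
            for s in range(20)
        ]
        reads_b = [
            simulate_observed_fluorosequence(pep, "K", params, 6, np.random.default_rng(s))
            for s in range(20)
        ]
        assert reads_a == reads_b

    def test_batch_zero_error_equals_ideal(self, toy_peptides, rng):
        pep = toy_peptides["Y"]
        counts = simulate_batch(pep, "K", ErrorParams(), 30, 100, rng)
        assert counts == {encode_ideal(pep, "K", 30): 100}

    def test_batch_counts_sum_to_depth(self, toy_peptides, rng):
        params = ErrorParams(0.3, 0.85, halflife_to_decay_constant(10))
        counts = simulate_batch(toy_peptides["Y"], "K", params, 30, 5000, rng)
        assert sum(counts.values()) == 5000

    def test_unlabeled_peptide_yields_empty_reads(self, rng):
        counts = simulate_batch(Peptide("GGGG", "P", 4), "K", ErrorParams(), 30, 50, rng)
        (read, count), = counts.items()
        assert not read and count == 50

    def test_batch_distribution_matches_per_copy_path(self, toy_peptides):
        """The vectorized batch simulator and the literal per-copy composition
        draw from the same read distribution (two-sample chi-square)."""
        pep = toy_peptides["swap_demo"]
        params = ErrorParams(0.2, 0.9, halflife_to_decay_constant(20))
        n = 20_000
        batch = simulate_batch(pep, "K", params, 6, n, np.random.default_rng(111))
        rng = np.random.default_rng(222)
        scalar = {}
        for _ in range(n):
            read = simulate_observed_fluorosequence(pep, "K", params, 6, rng)
            scalar[read] = scalar.get(read, 0) + 1
        support = sorted(set(batch) | set(scalar), key=lambda fs: fs.drops)
        table = np.array(
            [[batch.get(fs, 0) for fs in support], [scalar.get(fs, 0) for fs in support]]
        )
        # pool rare outcomes to keep expected cell counts reasonable
        keep = table.sum(axis=0) >= 10
        pooled = np.c_[table[:, keep], table[:, ~keep].sum(axis=1)]
        result = stats.chi2_contingency(pooled)
        assert result.pvalue > 1e-3
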