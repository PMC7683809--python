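"""Hierarchical bootstrap, joint-probability comparison, functional and
within-subject omnibus tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetalink.stats import (
    GroupedValues,
    alpha_policy,
    circuit_comparison,
    compare_grouped,
    functional_anova,
    functional_two_sample_F,
    hierarchical_bootstrap,
    joint_prob_pboot,
    two_tailed,
)


class TestHierarchicalBootstrap:
    def test_constant_values_give_constant_replicates(self):
        g = GroupedValues("x", {"a": [3.0, 3.0, 3.0], "b": [3.0, 3.0]})
        reps = hierarchical_bootstrap(g, 500, seed=1)
        assert np.all(reps == 3.0)

    def test_single_subject_matches_exact_enumeration(self):
        """One subject with trials {0, 1}: resampled means take values
        {0, 1/2, 1} with probabilities {1/4, 1/2, 1/4}."""
        g = GroupedValues("y", {"a": [0.0, 1.0]})
        with pytest.warns(UserWarning, match="degenerate"):
            reps = hierarchical_bootstrap(g, 40_000, seed=2)
        vals, counts = np.unique(reps, return_counts=True)
        np.testing.assert_array_equal(vals, [0.0, 0.5, 1.0])
        freqs = counts / len(reps)
        # 4 MC sigma bands around the enumerated probabilities
        for freq, p in zip(freqs, (0.25, 0.5, 0.25)):
            se = np.sqrt(p * (1 - p) / len(reps))
            assert abs(freq - p) < 4 * se

    def test_replicate_mean_targets_balanced_population_mean(self):
        """E[replicate] is the equal-subject-weight mean, not the pooled
        trial mean, even with unbalanced trial counts."""
        g = GroupedValues("z", {"a": [0.0] * 30, "b": [6.0, 6.0]})
        reps = hierarchical_bootstrap(g, 20_000, seed=3)
        balanced = 3.0  # (0 + 6) / 2
        se = reps.std(ddof=1) / np.sqrt(len(reps))
        assert abs(reps.mean() - balanced) < 2 * se + 0.05

    def test_seeded_determinism(self):
        g = GroupedValues("w", {"a": [1.0, 2.0, 5.0], "b": [0.0, 4.0]})
        r1 = hierarchical_bootstrap(g, 1000, seed=7)
        r2 = hierarchical_bootstrap(g, 1000, seed=7)
        np.testing.assert_array_equal(r1, r2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GroupedValues("e", {})


class TestJointProbability:
    def test_full_separation(self):
        assert joint_prob_pboot([1.0, 2.0], [3.0, 4.0]) == 1.0

    def test_enumerated_four_pairs(self):
        """{0,1} vs {0,1}: pairs with b >= a are (0,0),(0,1),(1,1) -> 3/4."""
        assert joint_prob_pboot([0.0, 1.0], [0.0, 1.0]) == 0.75

    def test_positive_translation_gives_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        assert joint_prob_pboot(a, a + 10.0) == 1.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(40), rng.standard_normal(50)
        brute = np.mean([bj >= ai for ai in a for bj in b])
        assert joint_prob_pboot(a, b) == pytest.approx(brute, abs=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=20),
           st.lists(st.floats(-100, 100), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_with_tie_mass(self, a, b):
        """Pr(B >= A) + Pr(A >= B) = 1 + Pr(A = B)."""
        a, b = np.asarray(a), np.asarray(b)
        ties = np.mean([bj == ai for ai in a for bj in b])
        total = joint_prob_pboot(a, b) + joint_prob_pboot(b, a)
        assert total == pytest.approx(1.0 + ties, abs=1e-12)


class TestTwoTailed:
    @pytest.mark.parametrize("p_boot, expected", [
        (0.001097, 0.002194),
        (0.32920, 0.65840),
        (0.12820, 0.25640),
        (0.86316, 0.27368),
        (2.9935e-4, 5.987e-4),
        (0.0053185, 0.010637),
        (0.5, 1.0),
    ])
    def test_conversion_values(self, p_boot, expected):
        assert two_tailed(p_boot) == pytest.approx(expected, rel=1e-9)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, p):
        assert two_tailed(p) == pytest.approx(two_tailed(1.0 - p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            two_tailed(1.5)


class TestCompareGrouped:
    def test_seeded_determinism_to_last_digit(self):
        rng = np.random.default_rng(4)
        ga = GroupedValues("A", {f"s{i}": rng.random(10) for i in range(4)})
        gb = GroupedValues("B", {f"t{i}": rng.random(10) for i in range(4)})
        c1 = compare_grouped(ga, gb, n_boot=500, seed=11)
        c2 = compare_grouped(ga, gb, n_boot=500, seed=11)
        assert c1.p_boot == c2.p_boot and c1.p_two == c2.p_two

    def test_obvious_separation_detected(self):
        rng = np.random.default_rng(5)
        ga = GroupedValues("A", {f"s{i}": rng.normal(0, 0.1, 20) for i in range(5)})
        gb = GroupedValues("B", {f"t{i}": rng.normal(5, 0.1, 20) for i in range(4)})
        c = compare_grouped(ga, gb, n_boot=1000, seed=12)
        assert c.p_boot == 1.0 and c.p_two == 0.0


class TestFunctionalTests:
    def test_copied_groups_not_significant(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((4, 60))
        r = functional_two_sample_F(base, base.copy(), n_perm=200, seed=1)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p > 0.5

    def test_offset_groups_hit_permutation_floor_exhaustive_oracle(self):
        """10 dB offset, negligible noise, n=4+5: the observed statistic is
        the maximum over all C(9,4)=126 distinct relabelings, so p reaches
        the sampled-permutation floor."""
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 0.01, (4, 60))
        b = rng.normal(10.0, 0.01, (5, 60))
        r = functional_two_sample_F(a, b, n_perm=500, seed=2)
        # exhaustive oracle over distinct relabelings
        from thetalink.stats import _pointwise_F
        curves = np.vstack([a, b])
        stats_all = []
        for idx in itertools.combinations(range(9), 4):
            labels = np.array(["b"] * 9)
            labels[list(idx)] = "a"
            stats_all.append(_pointwise_F(curves, labels))
        assert r.statistic == pytest.approx(max(stats_all), rel=1e-12)
        assert r.p <= 10.0 / 501.0  # near the add-one floor

    def test_statistic_invariant_to_within_group_order(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((4, 30))
        b = rng.standard_normal((5, 30))
        r1 = functional_two_sample_F(a, b, n_perm=10, seed=3)
        r2 = functional_two_sample_F(a[::-1], b[[2, 0, 1, 4, 3]], n_perm=10, seed=3)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_anova_identical_groups_not_significant(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((3, 40))
        r = functional_anova({"d": base, "p": base.copy(), "e": base.copy()},
                             n_perm=200, seed=4)
        assert r.p > 0.5

    def test_anova_one_offset_group_at_floor(self):
        rng = np.random.default_rng(10)
        groups = {"d": rng.normal(0, 0.01, (3, 40)),
                  "p": rng.normal(0, 0.01, (3, 40)),
                  "e": rng.normal(8, 0.01, (3, 40))}
        r = functional_anova(groups, n_perm=500, seed=5)
        assert r.p <= 10.0 / 501.0

    def test_two_group_anova_equals_two_sample(self):
        rng = np.random.default_rng(11)
        a, b = rng.standard_normal((4, 25)), rng.standard_normal((3, 25))
        r1 = functional_two_sample_F(a, b, n_perm=10, seed=6)
        r2 = functional_anova({"a": a, "b": b}, n_perm=10, seed=6)
        assert abs(r1.statistic - r2.statistic) < 1e-9

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            functional_two_sample_F(np.zeros((1, 10)), np.zeros((3, 10)))


class TestCircuitComparison:
    CIRCUITS = ["vHPC-PrL", "dHPC-PrL", "vHPC-IL", "dHPC-IL"]

    def test_identical_columns_trivially_non_significant(self):
        df = pd.DataFrame(np.tile([[1.0, 1.0, 1.0, 1.0]], (5, 1)),
                          columns=self.CIRCUITS)
        cc = circuit_comparison(df)
        assert cc.p > 0.99

    def test_two_tier_structure_detected_with_correct_posthoc_pattern(self):
        """Columns (0,0,10,10) + tiny noise, 9 subjects: omnibus p < 1e-4 and
        exactly the four cross-tier pairs significant."""
        rng = np.random.default_rng(1)
        data = np.tile([0.0, 0.0, 10.0, 10.0], (9, 1)) + rng.normal(0, 0.05, (9, 4))
        cc = circuit_comparison(pd.DataFrame(data, columns=self.CIRCUITS))
        assert cc.p < 1e-4
        ph = cc.posthoc.set_index(["pair_a", "pair_b"])["p"]
        cross = [("vHPC-PrL", "vHPC-IL"), ("vHPC-PrL", "dHPC-IL"),
                 ("dHPC-PrL", "vHPC-IL"), ("dHPC-PrL", "dHPC-IL")]
        within = [("vHPC-PrL", "dHPC-PrL"), ("vHPC-IL", "dHPC-IL")]
        assert all(ph[c] < 1e-4 for c in cross)
        assert all(ph[w] > 0.05 for w in within)

    def test_friedman_branch_matches_manual_rank_oracle(self):
        """Heavy-tailed data routes to Friedman+Dunn; mean ranks equal a
        manual within-subject ranking."""
        rng = np.random.default_rng(2)
        data = rng.standard_cauchy((12, 4))
        data[:, 3] += 50.0  # one clearly larger circuit
        df = pd.DataFrame(data, columns=self.CIRCUITS)
        cc = circuit_comparison(df)
        assert cc.method == "friedman_dunn"
        from scipy.stats import rankdata
        manual = rankdata(data, axis=1).mean(axis=0)
        assert manual[3] == max(manual)
        dunn = cc.posthoc.set_index(["pair_a", "pair_b"])
        # the dominant circuit differs from the smallest-rank circuit
        small = self.CIRCUITS[int(np.argmin(manual))]
        key = (small, "dHPC-IL") if (small, "dHPC-IL") in dunn.index \
            else ("dHPC-IL", small)
        assert dunn.loc[key, "p"] < 0.05

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame(np.zeros((2, 4)), columns=self.CIRCUITS)
        with pytest.raises(ValueError, match="subjects"):
            circuit_comparison(df)


class TestAlphaPolicy:
    def test_families(self):
        assert alpha_policy("two-group") == 0.05
        assert alpha_policy("estrous-pairwise") == 0.0167

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            alpha_policy("posthoc")
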