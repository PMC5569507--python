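import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from srnakit.preprocess import ReadSet
from srnakit.stats import (
    build_family_matrix,
    chi2_composition_test,
    classify_conservation,
    consensus_and_variation,
    five_prime_composition,
    ratio_24_21,
    size_distribution,
    wilcoxon_rank_sum,
)


class TestSizeDistribution:
    def test_single_length(self):
        rs = ReadSet(counts={"A" * 21: 10, "C" * 21: 5}, library_id="x")
        dist = size_distribution(rs)
        assert dist.proportions[21] == 1.0

    def test_two_lengths_arithmetic(self):
        rs = ReadSet(counts={"A" * 21: 100, "G" * 24: 300})
        dist = size_distribution(rs)
        assert dist.proportions[21] == pytest.approx(0.25)
        assert dist.proportions[24] == pytest.approx(0.75)

    def test_proportions_sum_to_one(self, rng):
        counts = {}
        for _ in range(50):
            length = int(rng.integers(16, 27))
            counts["".join(rng.choice(list("ACGU"), length))] = \
                int(rng.integers(1, 500))
        dist = size_distribution(ReadSet(counts=counts))
        assert sum(dist.proportions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            size_distribution(ReadSet(counts={}))


class TestRatio2421:
    def test_basic(self):
        rs = ReadSet(counts={"A" * 24: 200, "C" * 21: 100})
        assert ratio_24_21(rs) == pytest.approx(2.0)

    def test_zero_24(self):
        rs = ReadSet(counts={"C" * 21: 100})
        assert ratio_24_21(rs) == 0.0

    def test_missing_21_is_none(self):
        rs = ReadSet(counts={"A" * 24: 100})
        assert ratio_24_21(rs) is None

    def test_matches_bruteforce_count(self, rng):
        counts = {"".join(rng.choice(list("ACGU"), int(rng.integers(16, 27)))):
                  int(rng.integers(1, 50)) for _ in range(100)}
        rs = ReadSet(counts=counts)
        c21 = sum(v for k, v in counts.items() if len(k) == 21)
        c24 = sum(v for k, v in counts.items() if len(k) == 24)
        got = ratio_24_21(rs)
        if c21 == 0:
            assert got is None
        else:
            assert got == pytest.approx(c24 / c21)


class TestWilcoxon:
    def test_enumerated_example(self):
        # all C(6,3)=20 splits; only the two extreme splits are as far
        # from the mean rank sum -> p = 2/20
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert wilcoxon_rank_sum([2, 2, 2], [2, 2, 2]) == 1.0

    def test_matches_enumeration_for_small_groups(self, rng):
        for _ in range(30):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = list(rng.normal(size=n))
            b = list(rng.normal(size=m))
            p = wilcoxon_rank_sum(a, b)
            # full enumeration oracle on raw values
            pooled = a + b
            ranks = sps.rankdata(pooled)
            mu = n * (n + m + 1) / 2
            obs = abs(ranks[:n].sum() - mu)
            hits = sum(
                1 for idx in itertools.combinations(range(n + m), n)
                if abs(sum(ranks[i] for i in idx) - mu) >= obs - 1e-12)
            total = sum(1 for _ in itertools.combinations(range(n + m), n))
            assert p == pytest.approx(hits / total)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(100):
            n, m = int(rng.integers(3, 9)), int(rng.integers(3, 9))
            a = list(rng.normal(size=n))
            b = list(rng.normal(size=m))
            ours = wilcoxon_rank_sum(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_large_groups_normal_approximation(self, rng):
        a = list(rng.normal(size=30))
        b = list(rng.normal(loc=0.5, size=30))
        ours = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestFivePrimeComposition:
    def test_all_u(self):
        comp = five_prime_composition(["UAAA", "UCCC", "UGGG"])
        assert comp["U"] == 1.0

    def test_three_one_split(self):
        comp = five_prime_composition(["UAAA", "UCCC", "UGGG", "CAAA"])
        assert comp["U"] == pytest.approx(0.75)
        assert comp["C"] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), 21)) for _ in range(40)]
        comp = five_prime_composition(seqs)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)


class TestChi2:
    def test_identical_composition(self):
        chi2, p = chi2_composition_test((50, 50), (50, 50))
        assert chi2 == 0.0 and p == 1.0

    def test_closed_form_hand_computation(self):
        table = np.array([[90, 10], [50, 50]], dtype=float)
        row, col = table.sum(1), table.sum(0)
        expected = np.outer(row, col) / table.sum()
        hand = float(((table - expected) ** 2 / expected).sum())
        chi2, p = chi2_composition_test((90, 10), (50, 50))
        assert chi2 == pytest.approx(hand)
        assert p == pytest.approx(float(sps.chi2.sf(hand, 1)))

    def test_agrees_with_scipy_contingency(self):
        ref_chi2, ref_p, _, _ = sps.chi2_contingency(
            [[80, 20], [55, 45]], correction=False)
        chi2, p = chi2_composition_test((80, 20), (55, 45))
        assert chi2 == pytest.approx(ref_chi2)
        assert p == pytest.approx(ref_p)

    def test_monotone_in_composition_gap(self):
        pvals = []
        for k in range(0, 40, 5):
            _, p = chi2_composition_test((60 + k, 40 - k), (60 - k, 40 + k))
            pvals.append(p)
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_composition_test((0, 0), (5, 5))


class TestConsensusAndVariation:
    def test_identical_members(self):
        fv = consensus_and_variation(["ACGUACGU"] * 3)
        assert fv.consensus == "ACGUACGU"
        assert fv.variations == [0, 0, 0]
        assert fv.mean == 0.0

    def test_single_substitution_member(self):
        s = "ACGUACGUACGUACGUACGUA"
        s2 = s[:5] + "A" + s[6:]
        assert s2 != s
        fv = consensus_and_variation([s, s, s2])
        assert fv.consensus == s
        assert fv.variations == [0, 0, 1]
        assert fv.mean == pytest.approx(1 / 3)

    def test_length_difference_counts(self):
        s = "ACGUACGUACGUACGUACGUA"
        fv = consensus_and_variation([s, s, s[:-2]])
        assert fv.consensus == s
        assert fv.variations == [0, 0, 2]

    def test_low_variation_family_classifies_below_one(self, rng):
        base = "".join(rng.choice(list("ACGU"), 21))
        members = [base] * 5
        one_off = base[:7] + ("A" if base[7] != "A" else "C") + base[8:]
        members.append(one_off)
        fv = consensus_and_variation(members)
        assert fv.mean < 1.0

    def test_mean_zero_iff_identical(self, rng):
        base = "".join(rng.choice(list("ACGU"), 21))
        assert consensus_and_variation([base, base]).mean == 0.0
        other = base[:3] + ("G" if base[3] != "G" else "U") + base[4:]
        assert consensus_and_variation([base, other]).mean > 0.0


class TestClassifyConservation:
    def _matrix(self, n_species=20):
        # exact expression blocks: constant rows row-scale to identical
        # vectors, so each block is a zero-diameter cluster
        species = [f"sp{i:02d}" for i in range(n_species)]
        data = {}
        for s_i, sp in enumerate(species):
            col = {}
            for f in range(10):  # class-I block: high everywhere
                col[f"famA{f:02d}"] = 500.0
            for f in range(10):  # fern-only block (species 8+)
                col[f"famB{f:02d}"] = 200.0 if s_i >= 8 else 0.0
            for f in range(10):  # lycophyte-only block (species 0-7)
                col[f"famC{f:02d}"] = 50.0 if s_i < 8 else 0.0
            data[sp] = col
        return build_family_matrix(data)

    def test_high_everywhere_block_is_class_one(self):
        labels = classify_conservation(self._matrix(), top=30, k=3)
        a_classes = set(labels.loc[[f"famA{f:02d}" for f in range(10)],
                                   "conservation_class"])
        assert a_classes == {"I"}

    def test_subset_block_not_class_one(self):
        labels = classify_conservation(self._matrix(), top=30, k=3)
        b_classes = set(labels.loc[[f"famB{f:02d}" for f in range(10)],
                                   "conservation_class"])
        assert "I" not in b_classes

    def test_column_permutation_invariance(self, rng):
        m = self._matrix()
        labels = classify_conservation(m, top=30, k=3)
        perm = list(rng.permutation(m.rpm.columns))
        m2 = build_family_matrix({sp: m.rpm[sp].to_dict() for sp in perm})
        labels2 = classify_conservation(m2, top=30, k=3)
        pd.testing.assert_series_equal(labels["conservation_class"],
                                       labels2["conservation_class"])

    def test_uniform_rescaling_invariance(self):
        m = self._matrix()
        labels = classify_conservation(m, top=30, k=3)
        m2 = build_family_matrix(
            {sp: (m.rpm[sp] * 3.0).to_dict() for sp in m.rpm.columns})
        labels2 = classify_conservation(m2, top=30, k=3)
        assert (labels["conservation_class"]
                == labels2["conservation_class"]).all()

    def test_detection_flag(self):
        m = self._matrix()
        labels = classify_conservation(m, top=30, k=3)
        assert labels.loc["famA00", "conserved"]
        assert bool(labels.loc["famA00", "n_species_detected"] == 20)

    def test_too_few_families_rejected(self):
        m = build_family_matrix({"sp1": {"f1": 5.0, "f2": 1.0}})
        with pytest.raises(ValueError):
            classify_conservation(m, top=50, k=5)
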