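"""TPM normalization, rank-sum tests vs exact enumeration, diversity."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phageminer.community import (
    category_abundance,
    compare_diversity,
    compare_groups,
    diversity,
    rank_sum_test,
    tpm,
    tpm_table,
)


class TestTpm:
    def test_hand_example(self):
        """Lengths 2000/1000 bp with counts 100/50 give equal rates, so each
        feature gets half the 1e6 budget."""
        out = tpm([100, 50], [2000, 1000])
        assert out == pytest.approx([5e5, 5e5])

    def test_single_feature_gets_everything(self):
        assert tpm([7], [500]) == pytest.approx([1e6])

    def test_scale_invariance(self):
        a = tpm([100, 50, 10], [2000, 1000, 700])
        b = tpm([200, 100, 20], [2000, 1000, 700])
        assert a == pytest.approx(b)

    def test_all_zero_counts_stay_zero(self):
        assert tpm([0, 0], [100, 100]) == pytest.approx([0, 0])

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(20, 5)),
            index=[f"f{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(5)],
        )
        lengths = {f"f{i}": int(rng.integers(500, 5000)) for i in range(20)}
        table = tpm_table(counts, lengths)
        for col in table.columns:
            assert table[col].sum() == pytest.approx(1e6, rel=1e-6)


def exact_enumeration_p(a, b):
    """Two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1.0
    n = len(a)
    observed = ranks[:n].sum()
    total = math.comb(len(pooled), n)
    center = n * (len(pooled) + 1) / 2
    count = sum(
        1
        for combo in itertools.combinations(range(len(pooled)), n)
        if abs(ranks[list(combo)].sum() - center) >= abs(observed - center) - 1e-12
    )
    return count / total


class TestRankSum:
    def test_identical_constant_groups_give_one(self):
        assert rank_sum_test([3, 3, 3], [3, 3, 3]) == 1.0

    def test_fully_separated_n3(self):
        """A={1,2,3} vs B={10,11,12}: the most extreme of C(6,3)=20
        arrangements on both sides, p = 2/20."""
        assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_fully_separated_n4(self):
        assert rank_sum_test([1, 2, 3, 4], [10, 11, 12, 13]) == pytest.approx(2 / 70)

    def test_symmetry_under_group_swap(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=6)
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_test(b, a))

    def test_matches_exact_enumeration_small_groups(self, rng):
        """Agreement with brute-force enumeration for all n+m <= 10."""
        for n, m in [(2, 2), (2, 3), (3, 3), (2, 5), (4, 4), (3, 6), (5, 5), (4, 6)]:
            for _ in range(5):
                a = rng.normal(size=n)
                b = rng.normal(size=m)
                assert rank_sum_test(a, b) == pytest.approx(
                    exact_enumeration_p(a, b), abs=1e-10
                )

    def test_null_type_i_error_rate(self):
        """1000 null features: the fraction with p < 0.05 stays near 5%."""
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(1000):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            rejections += rank_sum_test(a, b) < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07


class TestCompareGroups:
    def _table(self, rng, n_features=30, shift_first=5):
        cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        data = rng.normal(size=(n_features, 8))
        data[:shift_first, 4:] += 5  # first features truly different
        return pd.DataFrame(data, index=[f"f{i}" for i in range(n_features)], columns=cols)

    def test_detects_shifted_features_and_orders_fdr(self, rng):
        table = self._table(rng)
        results = compare_groups(table, [f"a{i}" for i in range(4)],
                                 [f"b{i}" for i in range(4)])
        shifted = [r for r in results if int(r.feature_id[1:]) < 5]
        assert all(r.significant_raw for r in shifted)
        assert all(r.bh_fdr >= r.p_value for r in results)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_groups(self._table(rng), ["a0"], ["b0", "b1"])

    def test_unknown_sample_rejected(self, rng):
        with pytest.raises(KeyError):
            compare_groups(self._table(rng), ["a0", "zz"], ["b0", "b1"])


class TestDiversity:
    def test_uniform_four_taxa(self):
        rep = diversity([1.0, 1.0, 1.0, 1.0])
        assert rep.shannon == pytest.approx(math.log(4), abs=1e-9)
        assert rep.pielou == pytest.approx(1.0, abs=1e-9)
        assert rep.simpson == pytest.approx(0.75, abs=1e-9)

    def test_single_taxon(self):
        rep = diversity([5.0])
        assert rep.shannon == 0.0
        assert rep.simpson == 0.0
        assert not rep.pielou_defined and math.isnan(rep.pielou)

    def test_zero_taxa_excluded_from_richness(self):
        rep = diversity([0.5, 0.5, 0.0, 0.0])
        assert rep.richness == 2
        assert rep.shannon == pytest.approx(math.log(2), abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            diversity([0.0, 0.0])

    def test_matches_closed_forms_on_random_compositions(self, rng):
        """H, D, J recomputed with independent formulas to 1e-9."""
        for _ in range(100):
            p = rng.dirichlet(np.ones(int(rng.integers(2, 12))))
            rep = diversity(p)
            h = -sum(pi * math.log(pi) for pi in p if pi > 0)
            d = 1 - sum(pi**2 for pi in p)
            assert rep.shannon == pytest.approx(h, abs=1e-9)
            assert rep.simpson == pytest.approx(d, abs=1e-9)
            assert rep.pielou == pytest.approx(h / math.log(len(p)), abs=1e-9)

    def test_inverse_simpson_flag(self):
        rep = diversity([1, 1, 1, 1], inverse_simpson=True)
        assert rep.simpson == pytest.approx(4.0)


class TestCompareDiversity:
    def _reports(self, values):
        return [diversity([v, 1.0]) for v in values]

    def test_identical_groups_p_one(self):
        a = self._reports([1, 1, 1])
        assert compare_diversity(a, a)["shannon"] == 1.0

    def test_separated_shannon_values(self):
        # near-even compositions (H close to ln 2) vs highly uneven ones
        a = self._reports([1.0, 0.95, 0.9, 0.85])
        b = self._reports([0.05, 0.04, 0.03, 0.02])
        assert compare_diversity(a, b)["shannon"] == pytest.approx(2 / 70)

    def test_label_swap_invariance(self):
        a = self._reports([0.5, 1.5, 2.0])
        b = self._reports([3.0, 4.0, 5.0])
        assert compare_diversity(a, b)["shannon"] == pytest.approx(
            compare_diversity(b, a)["shannon"]
        )


class TestCategoryAbundance:
    def test_sums_gene_tpm_per_category(self):
        gene_tpm = pd.DataFrame(
            [[100.0, 200.0], [50.0, 25.0], [10.0, 1.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
        cats = {"g1": ["K1"], "g2": ["K1", "K2"], "g3": ["K2"]}
        out = category_abundance(gene_tpm, cats)
        assert out.loc["K1", "s1"] == pytest.approx(150.0)
        assert out.loc["K2", "s2"] == pytest.approx(26.0)
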