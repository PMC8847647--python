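import math
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidtraffic import (
    GeneratorConfig,
    bonferroni_threshold,
    compare_groups,
    enfc,
    fa_ratio,
    generate_study,
    relative_abundance,
)
from conftest import make_dataset


def ranksum_pvalue_oracle(g1, g2):
    """Two-sided exact Mann-Whitney p by full enumeration of group labellings."""
    pooled = sorted(g1) + sorted(g2)
    n1 = len(g1)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}

    def u_stat(idx):
        r1 = sum(ranks[pooled[i]] for i in idx)
        return r1 - n1 * (n1 + 1) / 2

    obs = u_stat(range(n1))
    mean_u = n1 * (len(pooled) - n1) / 2
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        hits += abs(u_stat(idx) - mean_u) >= abs(obs - mean_u) - 1e-12
    assert total == comb(len(pooled), n1)
    return hits / total


class TestRelativeAbundance:
    def test_example(self):
        assert relative_abundance([2, 2, 4]).tolist() == [0.25, 0.25, 0.5]

    def test_single_nonzero(self):
        assert relative_abundance([0, 3.2, 0]).tolist() == [0, 1.0, 0]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance([0, 0])

    @given(
        profile=st.lists(st.floats(0.01, 1e6), min_size=1, max_size=20),
        k=st.floats(0.001, 1e3),
    )
    def test_sums_to_one_and_scale_invariant(self, profile, k):
        out = relative_abundance(profile)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        scaled = relative_abundance(np.asarray(profile) * k)
        assert np.allclose(out, scaled, rtol=1e-9)


class TestCompareGroups:
    def test_separated_triples_hit_exact_floor(self):
        r = compare_groups([1, 2, 3], [10, 11, 12])
        assert r.method == "exact"
        assert r.p_raw == pytest.approx(0.1)  # 2/20, smallest attainable
        assert r.statistic == 0.0

    def test_identical_groups(self):
        r = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p_raw == pytest.approx(1.0)

    def test_symmetric_under_swap(self):
        a, b = [1.0, 5.0, 2.0, 9.0], [4.0, 3.0, 8.0, 7.0]
        assert compare_groups(a, b).p_raw == compare_groups(b, a).p_raw

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_mode_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        g1 = rng.permutation(np.arange(100, dtype=float))[:4]
        g2 = rng.permutation(np.arange(100, 200, dtype=float))[:4]
        r = compare_groups(g1, g2)
        assert r.method == "exact"
        assert r.p_raw == pytest.approx(ranksum_pvalue_oracle(list(g1), list(g2)))

    def test_large_or_tied_samples_use_asymptotic(self):
        rng = np.random.default_rng(0)
        r = compare_groups(rng.normal(size=20), rng.normal(size=20))
        assert r.method == "asymptotic"
        r = compare_groups([1, 1, 2], [2, 3, 4])  # tie across groups
        assert r.method == "asymptotic"

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [3, 4, 5])

    def test_bonferroni_flag(self):
        r = compare_groups([1, 2, 3], [10, 11, 12]).with_bonferroni(0.05, 33)
        assert r.significant is False  # 0.1 > 0.00152


class TestBonferroni:
    def test_33_variables_at_005(self):
        thr = bonferroni_threshold(0.05, 33)
        assert float(f"{thr:.3g}") == 0.00152

    @pytest.mark.parametrize(
        "alpha, m, expected", [(0.05, 1, 0.05), (0.01, 10, 0.001)]
    )
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


def ratio_dataset(num_lean, num_obese, den_lean, den_obese):
    rows = []
    for g, nums, dens in (("lean", num_lean, den_lean), ("obese", num_obese, den_obese)):
        for i, (nu, de) in enumerate(zip(nums, dens)):
            rows.append((f"{g}_heart_{i}", "heart", g, [nu, de]))
            rows.append((f"{g}_serum_{i}", "serum", g, [nu, de]))
    return make_dataset(rows, ["FA(15:0)", "FA(17:0)"])


class TestFaRatio:
    def test_constant_ratio(self):
        ds = ratio_dataset([3, 3], [3, 3], [1, 1], [1, 1])
        assert fa_ratio(ds, "FA(15:0)", "FA(17:0)", "lean", "heart").mean == 3.0

    def test_identical_num_and_den(self):
        ds = ratio_dataset([2, 5], [2, 5], [2, 5], [2, 5])
        r = fa_ratio(ds, "FA(15:0)", "FA(15:0)", "lean", "heart")
        assert r.mean == 1.0

    def test_zero_denominator_excluded_with_warning(self):
        ds = ratio_dataset([3, 4], [3, 3], [1, 0], [1, 1])
        with pytest.warns(UserWarning, match="zero denominator"):
            r = fa_ratio(ds, "FA(15:0)", "FA(17:0)", "lean", "heart")
        assert r.n_excluded == 1 and r.mean == 3.0

    def test_all_zero_denominators_rejected(self):
        ds = ratio_dataset([3, 4], [3, 3], [0, 0], [1, 1])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="undefined"):
                fa_ratio(ds, "FA(15:0)", "FA(17:0)", "lean", "heart")

    def test_planted_group_ratios_recovered(self):
        """Two groups with true per-sample ratios 2.4 (lean) and 3.7 (obese)
        at 10% CV, n = 8: group means recovered within 15%."""
        rng = np.random.default_rng(42)
        n = 8
        den_lean = rng.lognormal(0, 0.1, n)
        den_obese = rng.lognormal(0, 0.1, n)
        num_lean = 2.4 * den_lean * rng.normal(1, 0.1, n)
        num_obese = 3.7 * den_obese * rng.normal(1, 0.1, n)
        ds = ratio_dataset(num_lean, num_obese, den_lean, den_obese)
        lean = fa_ratio(ds, "FA(15:0)", "FA(17:0)", "lean", "heart")
        obese = fa_ratio(ds, "FA(15:0)", "FA(17:0)", "obese", "heart")
        assert lean.mean == pytest.approx(2.4, rel=0.15)
        assert obese.mean == pytest.approx(3.7, rel=0.15)

    def test_ratio_of_means_option(self):
        ds = ratio_dataset([2, 4], [3, 3], [1, 3], [1, 1])
        r = fa_ratio(ds, "FA(15:0)", "FA(17:0)", "lean", "heart", per_sample=False)
        assert r.ratios.tolist() == [6 / 4]


class TestEnfc:
    def test_equal_groups_give_zero(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        r = enfc(vals, vals)
        assert r.fold_change == 1.0 and r.enfc == 0.0

    def test_doubling_case_increases_magnitude(self):
        control = [1.0, 1.2, 0.9, 1.1]
        case = [1.5, 1.8, 1.4, 1.6]
        r1 = enfc(case, control)
        r2 = enfc([2 * v for v in case], control)
        assert r2.fold_change == pytest.approx(2 * r1.fold_change)
        assert abs(r2.enfc) > abs(r1.enfc) and r2.enfc > 0

    @settings(deadline=None)
    @given(
        case=st.lists(st.floats(0.01, 1e4), min_size=3, max_size=12),
        control=st.lists(st.floats(0.01, 1e4), min_size=3, max_size=12),
    )
    def test_exact_antisymmetry(self, case, control):
        assert enfc(case, control).enfc == -enfc(control, case).enfc

    def test_twofold_lognormal_effect_recovered(self):
        rng = np.random.default_rng(99)
        control = rng.lognormal(mean=1.0, sigma=0.25, size=10)
        case = rng.lognormal(mean=1.0 + math.log(2), sigma=0.25, size=10)
        r = enfc(case, control)
        assert r.enfc > 0
        assert r.fold_change == pytest.approx(2.0, rel=0.2)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            enfc([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])

    def test_degenerate_zero_variance(self):
        r = enfc([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert math.isinf(r.enfc) and r.enfc > 0


def test_planted_fold_changes_flow_through_enfc():
    """Variables generated with a 2-fold planted effect yield positive ENFC
    and roughly the planted fold change in the generated study."""
    config = GeneratorConfig(n_samples=10, n_regulated=10)
    dataset, truth = generate_study(config, seed=8)
    control, case = config.groups
    regulated = [v for v, fc in truth.planted_fold_changes.items() if fc != 1.0]
    assert len(regulated) == 10
    fcs = []
    for var in regulated:
        if truth.planted_presence[(case, var)] != frozenset(config.network.compartments):
            continue
        r = enfc(
            dataset.values(case, "liver", var),
            dataset.values(control, "liver", var),
        )
        fcs.append(r.fold_change)
    assert np.median(fcs) == pytest.approx(2.0, rel=0.25)
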