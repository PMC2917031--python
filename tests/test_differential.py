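import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methsubtypes.differential import (
    PermutationAnova,
    SamTwoClass,
    frequency_by_group,
    permutation_anova,
    sam_two_class,
)
from methsubtypes.preprocess import centre, stratify
from methsubtypes.simulate import SimulationConfig, null_config, simulate

from conftest import make_relative


def anova_setup(n_cpgs=12, n=8, seed=0):
    rng = np.random.default_rng(seed)
    rel = make_relative(rng.normal(size=(n_cpgs, n)))
    groups = {f"s{j}": ("a" if j < n // 2 else "b") for j in range(n)}
    return rel, groups


class TestPermutationAnovaOracle:
    def test_null_matches_exhaustive_enumeration(self):
        """With all 4! label permutations supplied, the permutation null
        equals the enumeration computed independently with scipy's F."""
        rel, groups = anova_setup(n_cpgs=6, n=4, seed=1)
        perms = np.array(list(itertools.permutations(range(4))))
        res = PermutationAnova(rel, groups).fit(permutations=perms)
        labels = np.array([groups[s] for s in rel.sample_ids])
        x = rel.values.to_numpy()
        for i, cpg in enumerate(rel.values.index):
            f_obs = stats.f_oneway(x[i, labels == "a"],
                                   x[i, labels == "b"]).statistic
            f_null = np.array([stats.f_oneway(x[i, p[:2]],
                                              x[i, p[2:]]).statistic
                               for p in perms])
            np.testing.assert_allclose(np.sort(res.null_F[:, i]),
                                       np.sort(f_null), atol=1e-10)
            assert res.table["F"].iloc[i] == pytest.approx(f_obs, abs=1e-10)
            p_expected = (1 + np.sum(f_null >= f_obs - 1e-9)) \
                / (len(perms) + 1)
            # tie counting may differ by float rounding on equal partitions
            assert abs(res.table["p_value"].iloc[i] - p_expected) \
                <= 4 / (len(perms) + 1) + 1e-12

    def test_f_invariant_under_row_shift(self):
        rel, groups = anova_setup(seed=2)
        shifted = make_relative(rel.values.to_numpy() + 0.0)
        shifted.values.iloc[0] += 5.0
        a = permutation_anova(rel, groups, n_perm=50, seed=1)
        b = permutation_anova(shifted, groups, n_perm=50, seed=1)
        assert a.table["F"].iloc[0] == pytest.approx(
            b.table["F"].iloc[0], rel=1e-12)

    def test_same_seed_bit_reproducible(self):
        rel, groups = anova_setup(n_cpgs=30, n=12, seed=3)
        a = permutation_anova(rel, groups, n_perm=200, seed=9)
        b = permutation_anova(rel, groups, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.p_cutoff == b.p_cutoff

    def test_group_with_one_member_rejected(self):
        rel = make_relative(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            PermutationAnova(rel, {"s0": "a", "s1": "a", "s2": "b"})


class TestPermutationAnovaRecovery:
    def test_planted_cpgs_recovered_with_low_fdr(self):
        """500 CpGs at the study's subtype sizes: >=90% of the 50 planted
        differential CpGs selected, implied FDR <= 1%."""
        cohort = simulate(SimulationConfig(seed=1))
        truth = cohort.truth.sample_subtype
        tumours = truth[truth != "normal-tissue"]
        rel = centre(stratify(cohort.beta), tumours.index)
        res = permutation_anova(rel.subset_samples(tumours.index), tumours,
                                n_perm=1000, fsn_max=10, seed=5)
        planted = set(cohort.truth.differential_ids)
        recovered = len(set(res.selected) & planted)
        assert recovered >= 0.9 * len(planted)
        assert res.fsn <= 10
        assert res.implied_fdr <= 0.01

    def test_pure_noise_selects_nearly_nothing(self):
        cohort = simulate(null_config(n_cpgs=500, seed=3))
        truth = cohort.truth.sample_subtype
        tumours = truth[truth != "normal-tissue"]
        rel = centre(stratify(cohort.beta), tumours.index)
        res = permutation_anova(rel.subset_samples(tumours.index), tumours,
                                n_perm=500, seed=5)
        assert len(res.selected) <= 5
        if res.selected:
            assert res.implied_fdr <= 0.01

    def test_different_seeds_agree_on_strong_effects(self):
        cohort = simulate(SimulationConfig(n_cpgs=200, n_genes=100,
                                           diff_effect=0.6, seed=8))
        truth = cohort.truth.sample_subtype
        tumours = truth[truth != "normal-tissue"]
        rel = centre(stratify(cohort.beta),
                     tumours.index).subset_samples(tumours.index)
        sel = []
        for seed in (1, 2):
            res = permutation_anova(rel, tumours, n_perm=500, seed=seed)
            sel.append(set(res.selected))
        jaccard = len(sel[0] & sel[1]) / len(sel[0] | sel[1])
        assert jaccard >= 0.9


def sam_d_oracle(x, in_mask, s0):
    """Tusher d computed independently, plain numpy."""
    a, b = x[:, in_mask], x[:, ~in_mask]
    n1, n2 = a.shape[1], b.shape[1]
    ss = ((a - a.mean(1, keepdims=True)) ** 2).sum(1) \
        + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
    s = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
    return (a.mean(1) - b.mean(1)) / (s + s0)


class TestSamOracle:
    def test_expected_order_statistics_match_enumeration(self):
        """3 vs 3 samples: with all 20 class assignments supplied as
        permutations, the expected order statistics equal the independent
        enumeration average."""
        rng = np.random.default_rng(4)
        rel = make_relative(rng.normal(size=(10, 6)))
        in_group = ["s0", "s1", "s2"]
        assignments = list(itertools.combinations(range(6), 3))
        perms = []
        for combo in assignments:
            rest = [j for j in range(6) if j not in combo]
            perms.append(list(combo) + rest)
        perms = np.array(perms)
        res = SamTwoClass(rel, in_group).fit(permutations=perms)
        x = rel.values.to_numpy()
        d_sorted_all = []
        for combo in assignments:
            mask = np.zeros(6, bool)
            mask[list(combo)] = True
            d_sorted_all.append(np.sort(sam_d_oracle(x, mask, res.s0)))
        expected = np.mean(d_sorted_all, axis=0)
        ours = np.sort(res.table["d_expected"].to_numpy())
        np.testing.assert_allclose(ours, expected, atol=1e-10)

    def test_d_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        rel = make_relative(rng.normal(size=(15, 10)))
        in_group = [f"s{j}" for j in range(4)]
        res = sam_two_class(rel, in_group, n_perm=20, seed=1)
        mask = np.array([s in set(in_group) for s in rel.sample_ids])
        oracle = sam_d_oracle(rel.values.to_numpy(), mask, res.s0)
        np.testing.assert_allclose(res.table["d"], oracle, atol=1e-10)

    def test_d_invariant_under_row_shift(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 10))
        rel_a = make_relative(x)
        x2 = x.copy(); x2[0] += 3.0
        rel_b = make_relative(x2)
        in_group = [f"s{j}" for j in range(5)]
        d_a = sam_two_class(rel_a, in_group, n_perm=10, seed=0).table["d"]
        d_b = sam_two_class(rel_b, in_group, n_perm=10, seed=0).table["d"]
        assert d_a.iloc[0] == pytest.approx(d_b.iloc[0], rel=1e-9)

    def test_both_classes_need_two_samples(self):
        rel = make_relative(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            SamTwoClass(rel, ["s0"])


class TestSamCalls:
    def test_null_contract_no_calls_at_fdr_zero(self):
        """Identical per-CpG distributions in both classes: nothing called."""
        rng = np.random.default_rng(0)
        u = rng.uniform(size=(150, 40))
        tern = np.where(u < 0.3, 1.0, np.where(u < 0.5, 0.5, 0.0))
        rel = make_relative(tern - tern.mean(axis=1, keepdims=True))
        res = sam_two_class(rel, [f"s{j}" for j in range(12)],
                            n_perm=300, target_fdr=0.0, seed=2)
        assert res.n_called == 0
        assert res.median_false_calls == 0.0

    def test_planted_hypermethylation_recovered(self):
        """30 planted CpGs (effect 0.5) at 20 vs 40 samples: >=27 called,
        the hyper ones in the positive tail."""
        cfg = SimulationConfig(
            n_cpgs=300, n_genes=150, n_samples={"lumB": 20, "lumA": 40},
            baseline_meth_prob={"lumB": 0.3, "lumA": 0.3},
            n_normal_tissue=0, n_differential_cpgs=30, diff_effect=0.5,
            diff_target_subtypes=("lumB",), seed=2)
        cohort = simulate(cfg)
        truth = cohort.truth.sample_subtype
        rel = centre(stratify(cohort.beta), truth.index)
        res = sam_two_class(rel, truth[truth == "lumB"].index,
                            n_perm=1000, target_fdr=0.0, seed=7)
        planted = set(cohort.truth.differential_ids)
        assert len(set(res.called) & planted) >= 27
        hyper_planted = set(cohort.truth.differential_cpgs.query(
            "direction == 'hyper'")["cpg_id"])
        assert len(set(res.hypermethylated) & hyper_planted) >= \
            0.9 * len(hyper_planted)

    def test_selection_respects_fdr_zero_bookkeeping(self):
        cfg = SimulationConfig(
            n_cpgs=200, n_genes=100, n_samples={"lumB": 15, "lumA": 30},
            baseline_meth_prob={"lumB": 0.3, "lumA": 0.3},
            n_normal_tissue=0, n_differential_cpgs=20, diff_effect=0.6,
            diff_target_subtypes=("lumB",), seed=5)
        cohort = simulate(cfg)
        truth = cohort.truth.sample_subtype
        rel = centre(stratify(cohort.beta), truth.index)
        res = sam_two_class(rel, truth[truth == "lumB"].index,
                            n_perm=500, target_fdr=0.0, seed=3)
        assert res.median_false_calls == 0.0
        assert res.fdr == 0.0


class TestFrequencyByGroup:
    def test_toy_hand_computed_means(self, fixture_bundle):
        tern = stratify(fixture_bundle.beta)
        table, stat, p = frequency_by_group(
            tern, None, fixture_bundle.annotations, "subtype")
        # lumA samples s1/s2: frequencies 2/8 and 3/8
        assert table.loc["lumA", "mean_frequency"] == pytest.approx(
            (2 / 8 + 3 / 8) / 2)
        assert table.loc["lumA", "n"] == 2

    def test_identical_samples_give_zero_sd_and_f(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(size=100)
        tern_col = np.where(u < 0.3, 1.0, 0.0)
        tern = np.tile(tern_col[:, None], (1, 12))
        from methsubtypes.containers import TernaryMatrix
        idx = [f"c{i}" for i in range(100)]
        mat = TernaryMatrix(
            pd.DataFrame(tern, index=idx,
                         columns=[f"s{j}" for j in range(12)]),
            pd.Series(idx, index=idx))
        from methsubtypes.containers import SampleAnnotation
        annotations = [SampleAnnotation(f"s{j}",
                                        subtype="lumA" if j < 6 else "lumB")
                       for j in range(12)]
        table, stat, p = frequency_by_group(mat, None, annotations, "subtype")
        assert table["sd_frequency"].fillna(0).eq(0).all()
        assert stat == pytest.approx(0.0, abs=1e-12) or np.isnan(stat)

    def test_planted_group_frequencies_recovered(self):
        cfg = SimulationConfig(
            n_cpgs=196, n_genes=98, n_samples={"lumA": 40, "lumB": 40},
            baseline_meth_prob={"lumA": 0.28, "lumB": 0.35},
            n_normal_tissue=0, n_differential_cpgs=0, seed=11)
        cohort = simulate(cfg)
        tern = stratify(cohort.beta)
        table, stat, p = frequency_by_group(
            tern, None, cohort.annotations, "subtype")
        truth = cohort.truth.states
        for subtype in ("lumA", "lumB"):
            expected = (truth[subtype] == "methylated").mean()
            assert table.loc[subtype, "mean_frequency"] == pytest.approx(
                expected, abs=0.01)
        assert p < 0.05  # 0.28 vs 0.35 separates at n = 40 + 40
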