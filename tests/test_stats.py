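import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from coloc3d import (GeneList, RegulonSet, batch_test, bonferroni,
                     empirical_pvalue, ks_two_sample, pairwise_distances,
                     permutation_null, plant_colocalized_module,
                     sample_random_module)
from coloc3d.stats import test_module as module_test
from coloc3d.errors import ParameterError


def brute_force_ks(sample, reference):
    """Exhaustive sup over the pooled evaluation points of the two ECDFs."""
    sample = np.sort(sample)
    reference = np.sort(reference)
    pooled = np.concatenate([sample, reference])
    best = 0.0
    for x in pooled:
        f1 = np.sum(sample <= x) / len(sample)
        f2 = np.sum(reference <= x) / len(reference)
        best = max(best, abs(f1 - f2))
    return best


class TestKsTwoSample:
    def test_identical_multisets_give_zero(self):
        a = np.array([1.0, 2.0, 2.0, 5.0])
        D, p = ks_two_sample(a, a.copy())
        assert D == 0.0
        assert p == 1.0

    def test_disjoint_supports_give_one(self):
        D, _ = ks_two_sample(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        assert D == 1.0

    def test_matches_exhaustive_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n1 = int(rng.integers(1, 40))
            n2 = int(rng.integers(1, 40))
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            if trial % 2:  # force heavy ties half the time
                a = np.round(a, 1)
                b = np.round(b, 1)
            D, _ = ks_two_sample(a, b)
            assert D == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_statistic_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(2, 80)))
            b = rng.normal(0.3, 1.0, size=int(rng.integers(2, 80)))
            D, _ = ks_two_sample(a, b)
            assert D == pytest.approx(sps.ks_2samp(a, b).statistic,
                                      abs=1e-12)

    def test_pvalue_is_asymptotic_kolmogorov(self):
        # closed-form check: P = Q_KS(sqrt(n1 n2/(n1+n2)) * D)
        rng = np.random.default_rng(2)
        a = rng.normal(size=50)
        b = rng.normal(1.0, 1.0, size=70)
        D, p = ks_two_sample(a, b)
        en = 50 * 70 / 120
        assert p == pytest.approx(
            float(sps.kstwobign.sf(np.sqrt(en) * D)), rel=1e-9)

    def test_sorted_reference_shortcut_equivalent(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=30)
        b = rng.normal(size=500)
        assert ks_two_sample(a, b) == \
            ks_two_sample(a, np.sort(b), reference_sorted=True)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            ks_two_sample(np.array([]), np.array([1.0]))


class TestBonferroni:
    @pytest.mark.parametrize("pval,m,expected,fmt,printed", [
        (2e-07, 176, 3.52e-05, "{:.0e}", "4e-05"),   # 1 s.f.
        (7e-05, 176, 0.01232, "{:.2g}", "0.012"),    # 2 s.f.
        (2e-06, 176, 3.52e-04, "{:.1g}", "0.0004"),  # 1 s.f.
    ])
    def test_worked_examples_and_printed_forms(self, pval, m, expected, fmt,
                                               printed):
        adj = bonferroni(pval, m)
        assert adj == pytest.approx(expected, rel=1e-12)
        assert fmt.format(adj) == printed

    def test_cap_at_one(self):
        assert bonferroni(0.5, 176) == 1.0

    def test_single_test_is_identity(self):
        assert bonferroni(0.01, 1) == 0.01

    @given(p=st.floats(1e-12, 1.0, exclude_min=False),
           m1=st.integers(1, 1000), m2=st.integers(1, 1000))
    @settings(max_examples=200, deadline=None)
    def test_monotone_never_below_raw_capped(self, p, m1, m2):
        lo, hi = sorted((m1, m2))
        assert bonferroni(p, lo) <= bonferroni(p, hi) <= 1.0
        assert bonferroni(p, lo) >= p

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bonferroni(0.0, 3)
        with pytest.raises(ParameterError):
            bonferroni(0.5, 0)


class TestTestModule:
    def test_self_comparison_is_null(self, small_genome):
        dset = small_genome["dset"]
        res = module_test(dset, GeneList(ids=dset.ids, label="all"))
        assert res.ks == 0.0
        assert res.direction == 0.0
        assert res.n_pairs == len(dset)

    def test_planted_module_detected(self, small_genome):
        coords, dset = small_genome["coords"], small_genome["dset"]
        genes = plant_colocalized_module(coords, k=25, radius=0.2, seed=5)
        res = module_test(dset, genes, m=20)
        assert res.direction < 0
        assert res.pval_adjusted < 0.05
        assert 0 < res.ks <= 1

    def test_module_too_small_flagged_untested(self, small_genome):
        dset = small_genome["dset"]
        res = module_test(dset, GeneList(ids=[dset.ids[0], "GHOST"]))
        assert not res.tested
        assert np.isnan(res.ks)
        assert res.n_targets_matched == 1
        assert res.unmatched == ["GHOST"]

    def test_adjustment_uses_m(self, small_genome):
        dset = small_genome["dset"]
        genes = GeneList(ids=dset.ids[:10])
        r1 = module_test(dset, genes, m=1)
        r5 = module_test(dset, genes, m=5)
        assert r5.pval_adjusted == pytest.approx(min(1.0, 5 * r1.pval))


def regulons_from_modules(modules: dict[str, list[str]]) -> RegulonSet:
    rows = [(tf, g, "binding") for tf, targets in modules.items()
            for g in targets]
    return RegulonSet(records=pd.DataFrame(rows,
                                           columns=["tf", "target", "evidence"]))


class TestBatchTest:
    @pytest.fixture()
    def mixed_modules(self, small_genome):
        coords = small_genome["coords"]
        features = small_genome["features"]
        modules = {}
        for i in range(5):
            modules[f"PLANTED{i}"] = list(
                plant_colocalized_module(coords, k=20, radius=0.15,
                                         seed=100 + i).ids)
        for i in range(20):
            modules[f"RANDOM{i}"] = list(
                sample_random_module(features, k=20, seed=200 + i).ids)
        return modules

    def test_planted_modules_occupy_top_ranks(self, small_genome, mixed_modules):
        table, report = batch_test(small_genome["dset"],
                                   regulons_from_modules(mixed_modules))
        assert report["m"] == 25
        assert all(tf.startswith("PLANTED") for tf in table["tf"].head(5))
        assert np.all(np.diff(table["ks"].to_numpy()) <= 0)

    def test_output_invariant_to_input_order(self, small_genome, mixed_modules):
        regs = regulons_from_modules(mixed_modules)
        shuffled = RegulonSet(records=regs.records.sample(
            frac=1.0, random_state=3).reset_index(drop=True))
        t1, _ = batch_test(small_genome["dset"], regs)
        t2, _ = batch_test(small_genome["dset"], shuffled)
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_module_adjustment_is_identity(self, small_genome):
        dset = small_genome["dset"]
        regs = regulons_from_modules({"ONLY": dset.ids[:15]})
        table, report = batch_test(dset, regs)
        assert report["m"] == 1
        assert table["pval_adjusted"].iloc[0] == table["pval"].iloc[0]

    def test_min_targets_controls_m(self, small_genome):
        dset = small_genome["dset"]
        regs = regulons_from_modules({"BIG": dset.ids[:30],
                                      "SMALL": dset.ids[:3]})
        table, report = batch_test(dset, regs, min_targets=10)
        assert report["m"] == 1
        assert report["untested"] == ["SMALL"]
        assert list(table["tf"]) == ["BIG"]

    def test_zero_testable_modules_is_hard_error(self, small_genome):
        regs = regulons_from_modules({"GHOSTS": ["NOPE1", "NOPE2", "NOPE3"]})
        with pytest.raises(ParameterError):
            batch_test(small_genome["dset"], regs)


class TestPermutationNull:
    def test_reproducible_under_seed(self, small_genome):
        dset = small_genome["dset"]
        a = permutation_null(dset, k=10, n_perm=25, seed=4)
        b = permutation_null(dset, k=10, n_perm=25, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_single_permutation_pvalues(self, small_genome):
        dset = small_genome["dset"]
        null = permutation_null(dset, k=5, n_perm=1, seed=1)
        assert empirical_pvalue(0.0, null) == 1.0           # D_obs below null
        assert empirical_pvalue(null[0] + 1.0, null) == 0.5  # D_obs above

    def test_extreme_observation_floor(self):
        null = np.linspace(0.0, 0.5, 999)
        assert empirical_pvalue(0.9, null) == pytest.approx(1 / 1000)

    def test_k_exceeding_feature_count_rejected(self, small_genome):
        dset = small_genome["dset"]
        with pytest.raises(ParameterError):
            permutation_null(dset, k=dset.n + 1, n_perm=2, seed=0)
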