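import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedagg.fa_tests import (
    TestConfig as TestConfig_,  # alias keeps pytest from collecting the dataclass
    bh_adjust,
    empirical_p,
    family_min_p,
    gc_statistic,
    gr_statistic,
    if_statistic,
    ks_statistic,
    pb_test,
    rank_units,
    resample_null,
    run_test,
    run_tests,
    trait_prevalence,
)
from pedagg.kinship import kinship_matrix
from pedagg.pedigree import Phenotype
from pedagg.simulate import generate_controls
from pedagg.synthetic import PedigreeSpec, generate_pedigree
from pedagg.pedigree import split_families


class TestStatistics:
    def test_if_two_affected_sibs(self, three_gen):
        K = kinship_matrix(three_gen)
        assert if_statistic({"c1", "c2"}, K) == 0.25

    def test_if_parent_and_two_children(self, three_gen):
        K = kinship_matrix(three_gen)
        # a with children c1, c2: all three pairs at phi 0.25
        assert if_statistic({"a", "c1", "c2"}, K) == pytest.approx(0.25)

    def test_if_mixed_branches_pair_enumeration(self, three_gen):
        K = kinship_matrix(three_gen)
        aff = ["c1", "c2", "d"]
        pairs = list(itertools.combinations(aff, 2))
        expected = np.mean([K.phi(x, y) for x, y in pairs])
        assert if_statistic(aff, K) == pytest.approx(expected)
        assert if_statistic(aff, K) == pytest.approx((0.25 + 0.0625 + 0.0625) / 3)

    def test_if_requires_two_affected(self, three_gen):
        with pytest.raises(ValueError):
            if_statistic({"c1"}, kinship_matrix(three_gen))

    def test_ks_examples(self, three_gen):
        K = kinship_matrix(three_gen)
        assert ks_statistic("c1", {"c1", "c2", "gp1"}, K) == pytest.approx(0.375)
        # affected parent and affected cousin
        assert ks_statistic("c1", {"c1", "a", "d"}, K) == pytest.approx(0.3125)
        with pytest.raises(ValueError):
            ks_statistic("c1", {"c1"}, K)

    def test_ks_matches_brute_force_sum(self, three_gen):
        K = kinship_matrix(three_gen)
        aff = {"c1", "c2", "d", "gp2"}
        expected = sum(K.phi("c1", j) for j in aff - {"c1"})
        assert ks_statistic("c1", aff, K) == pytest.approx(expected)

    def test_gr_counts_affected_in_group(self, nuclear):
        K = kinship_matrix(nuclear)
        phen = set(nuclear.phenotyped_ids())
        # group {i, s1, s2, p2}; affected = {i, s1}
        assert gr_statistic("i", {"i", "s1"}, K, phen) == 2

    def test_gr_all_group_affected(self, nuclear):
        K = kinship_matrix(nuclear)
        phen = set(nuclear.phenotyped_ids())
        assert gr_statistic("i", {"i", "s1", "s2", "p2"}, K, phen) == 4

    def test_gc_closest_affected(self, three_gen):
        K = kinship_matrix(three_gen)
        assert gc_statistic("c1", {"c1", "c2", "d"}, K) == 0.25  # sib beats cousin
        assert gc_statistic("c1", {"c1", "d"}, K) == 0.0625
        with pytest.raises(ValueError):
            gc_statistic("c1", {"c1"}, K)


class TestBinomial:
    def test_whole_sample_space(self):
        assert pb_test(20, 0, 0.1) == 1.0

    def test_validates_inputs(self):
        with pytest.raises(ValueError):
            pb_test(10, 2, 1.5)
        with pytest.raises(ValueError):
            pb_test(10, 11, 0.1)

    def test_equals_exhaustive_pmf_sum(self):
        from scipy.stats import binom

        n, r = 30, 0.07
        pmf = binom.pmf(np.arange(n + 1), n, r)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        for k in (0, 1, 5, 30):
            assert pb_test(n, k, r) == pytest.approx(pmf[k:].sum(), rel=1e-12)

    def test_prevalence_helper(self):
        assert trait_prevalence(1, 4) == 0.25
        with pytest.raises(ValueError):
            trait_prevalence(5, 4)


class TestEmpiricalP:
    def test_add_one_bounds(self):
        assert empirical_p(10.0, [0.0] * 999) == pytest.approx(1 / 1000)
        assert empirical_p(-1.0, [0.0] * 999) == 1.0

    def test_rejects_empty_null(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, [])

    def test_exhaustive_enumeration_gives_exact_permutation_p(self, three_gen):
        """Feeding all label assignments but one observed copy reproduces the
        exact permutation P value #[stat >= observed] / #assignments."""
        K = kinship_matrix(three_gen)
        ids = three_gen.ids
        k = 3
        observed = ("c1", "c2", "d")
        obs_stat = if_statistic(observed, K)
        all_stats = [
            if_statistic(combo, K) for combo in itertools.combinations(ids, k)
        ]
        null = list(all_stats)
        null.remove(obs_stat)  # drop one copy of the observed assignment
        exact = np.mean([s >= obs_stat - 1e-12 for s in all_stats])
        assert empirical_p(obs_stat, null) == pytest.approx(exact)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        null = rng.normal(size=50)
        p = empirical_p(float(rng.normal()), null)
        assert 0 < p <= 1


class TestResampling:
    def test_full_pool_sample(self):
        reps = list(resample_null(["a", "b", "c"], 3, 5, seed=1))
        assert all(r == {"a", "b", "c"} for r in reps)

    def test_same_seed_same_stream(self):
        pool = [f"i{k}" for k in range(30)]
        r1 = list(resample_null(pool, 7, 20, seed=9))
        r2 = list(resample_null(pool, 7, 20, seed=9))
        assert r1 == r2

    def test_marginal_inclusion_frequency(self):
        pool = [f"i{k}" for k in range(40)]
        n, B = 10, 10_000
        counts = {i: 0 for i in pool}
        for rep in resample_null(pool, n, B, seed=4):
            for i in rep:
                counts[i] += 1
        expect = n / len(pool)
        se = np.sqrt(expect * (1 - expect) / B)
        for i in pool:
            assert abs(counts[i] / B - expect) < 4 * se

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            list(resample_null(["a"], 2, 1, seed=0))


class TestAdjustAndRank:
    def test_bh_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_bh_closed_form_pair(self):
        assert bh_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bh_monotone_and_permutation_invariant(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert bh_adjust(list(np.asarray(p)[perm])) == pytest.approx(adj[perm])

    def test_rank_tie_averaging(self):
        assert rank_units([0.001, 0.002, 0.002]).tolist() == [1.0, 2.5, 2.5]

    def test_rank_distinct_is_permutation(self):
        p = [0.5, 0.1, 0.9, 0.3]
        assert rank_units(p).tolist() == [3.0, 1.0, 4.0, 2.0]

    def test_rank_skips_nan(self):
        ranks = rank_units([0.5, np.nan, 0.1])
        assert np.isnan(ranks[1]) and ranks.tolist()[::2] == [2.0, 1.0]


@pytest.fixture(scope="module")
def small_run():
    ped = generate_pedigree(PedigreeSpec(n_families=6, seed=21))
    rng = np.random.default_rng(8)
    pheno = {}
    for fam in split_families(ped):
        pheno.update(generate_controls(fam, 0.25, rng).status)
    cfg = TestConfig_(B=300, seed=13)
    return ped, pheno, cfg, run_tests(ped, pheno, cfg)


class TestRunEngine:

    def test_engine_matches_naive_recomputation(self, small_run):
        from helpers import naive_mc_pvalues

        ped, pheno, cfg, results = small_run
        full_pheno = {i.id: pheno.get(i.id, i.phenotype) for i in ped}
        naive = naive_mc_pvalues(ped, full_pheno, B=cfg.B, seed=cfg.seed)
        for t in ("IF", "KS", "GR", "GC"):
            df = results[t]
            ok = df[df.status == "ok"]
            assert set(ok.unit_id) == set(naive[t])
            for row in ok.itertuples():
                p_ref, beff_ref = naive[t][row.unit_id]
                assert row.P_raw == pytest.approx(p_ref), (t, row.unit_id)
                assert row.effective_B == beff_ref

    def test_all_p_values_in_unit_interval(self, small_run):
        _, _, _, results = small_run
        for t, df in results.items():
            ok = df[df.status == "ok"]
            assert len(ok) > 0
            assert ((ok.P_raw > 0) & (ok.P_raw <= 1)).all()
            assert (ok.P_adj >= ok.P_raw - 1e-15).all()

    def test_na_units_excluded_from_ranking(self, small_run):
        _, _, _, results = small_run
        for df in results.values():
            na = df[df.status == "na"]
            assert na["rank"].isna().all() and na["P_raw"].isna().all()

    def test_deterministic_rerun(self, small_run):
        ped, pheno, cfg, results = small_run
        again = run_tests(ped, pheno, cfg)
        for t in results:
            assert results[t].equals(again[t])

    def test_single_test_run_consistent_with_joint(self, small_run):
        ped, pheno, cfg, results = small_run
        alone = run_test("KS", ped, pheno, cfg)
        assert alone.equals(results["KS"])

    def test_pb_single_family_closed_form(self, trio):
        df = run_test("PB", trio, config=TestConfig_(tests=("PB",), seed=0))
        # 2 affected of 3 phenotyped, R = 2/3
        assert df.P_raw[0] == pytest.approx(pb_test(3, 2, 2 / 3))

    def test_prevalence_override(self, trio):
        cfg = TestConfig_(tests=("PB",), seed=0, prevalence_override=0.1)
        df = run_test("PB", trio, config=cfg)
        assert df.P_raw[0] == pytest.approx(pb_test(3, 2, 0.1))

    def test_family_min_p(self, small_run):
        _, _, _, results = small_run
        df = results["KS"]
        mins = family_min_p(df)
        ok = df[df.status == "ok"]
        for fam, expected in ok.groupby("family_id")["P_raw"].min().items():
            assert mins[fam] == expected
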