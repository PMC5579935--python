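import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import exact_pairing_p, rank_pearson, van_elteren_exact

from mirstrat import association_stats as ast
from mirstrat.association_stats import (
    DiseaseCatalog,
    TargetTable,
    disease_age_enrichment,
    disease_count_vs_age,
    expression_breadth,
    jaccard,
    mann_whitney,
    mesh_collapse,
    mwu_z,
    pairwise_profile_similarity,
    permutation_target_test,
    spearman_corr,
    stratified_mwu,
    target_age_fraction,
    tf_target_fraction,
)
from mirstrat.ortho_grouping import family_table_from_mapping


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_corr([1, 2, 3], [2, 4, 6]).statistic == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3], [6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_constant_vector_flagged_not_nan_silent(self):
        res = spearman_corr([1, 1, 1], [1, 2, 3])
        assert not res.defined
        assert "constant" in res.note

    def test_equals_pearson_on_midranks_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = x * 0.5 + rng.integers(0, 4, size=n)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            res = spearman_corr(x, y)
            assert res.statistic == pytest.approx(rank_pearson(x, y), abs=1e-12)


class TestMannWhitney:
    def test_normal_branch_matches_scipy_asymptotic(self, rng):
        for _ in range(50):
            x = rng.integers(0, 10, size=20).astype(float)
            y = rng.integers(0, 10, size=25).astype(float)
            res = mann_whitney(x, y)
            ref = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            assert res.pvalue == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_all_tied_gives_p_one(self):
        res = mann_whitney([5.0] * 10, [5.0] * 12)
        assert res.pvalue == pytest.approx(1.0)


class TestStratifiedMwu:
    def test_single_stratum_reduces_to_plain_z(self, rng):
        for _ in range(50):
            n1, n2 = int(rng.integers(3, 15)), int(rng.integers(3, 15))
            x = rng.integers(0, 8, size=n1).astype(float)
            y = rng.integers(0, 8, size=n2).astype(float)
            vals = np.concatenate([x, y])
            grp = np.array([True] * n1 + [False] * n2)
            res = stratified_mwu(vals, grp, np.zeros(n1 + n2))
            assert res.statistic == pytest.approx(mwu_z(x, y), abs=1e-10)

    def test_identical_groups_within_strata(self):
        vals = [1, 2, 3, 1, 2, 3, 7, 8, 7, 8]
        grp = [True, True, True, False, False, False, True, True, False, False]
        strat = ["a"] * 6 + ["b"] * 4
        res = stratified_mwu(vals, grp, strat)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_uninformative_strata_dropped(self):
        vals = [1.0, 2.0, 3.0, 4.0, 9.0, 10.0]
        grp = [True, False, True, False, True, True]
        strat = ["a", "a", "a", "a", "b", "b"]  # b has no control
        res = stratified_mwu(vals, grp, strat)
        assert res.effect["n_strata"] == 1

    def test_no_informative_stratum_errors(self):
        with pytest.raises(ValueError):
            stratified_mwu([1.0, 2.0], [True, True], ["a", "a"])

    def test_normal_p_within_exact_permutation_neighborhood(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 7))
            m = int(rng.integers(4, 7))
            vals = np.concatenate([rng.normal(size=n), rng.normal(1.0, 1.0, size=m)])
            grp = np.concatenate(
                [rng.random(n) < 0.5, rng.random(m) < 0.5]
            )
            strat = np.array(["a"] * n + ["b"] * m)
            if any(
                grp[strat == s].all() or not grp[strat == s].any() for s in ("a", "b")
            ):
                continue
            res = stratified_mwu(vals, grp, strat)
            z_obs, p_lo, p_hi = van_elteren_exact(vals, grp, strat)
            assert res.statistic == pytest.approx(z_obs, abs=1e-10)
            assert p_lo - 0.05 <= res.pvalue <= p_hi + 0.05


class TestMeshCollapse:
    def _catalog(self):
        return DiseaseCatalog(
            associations={
                "hepatocellular carcinoma": {"m1", "m2"},
                "lung carcinoma": {"m2", "m3"},
                "epilepsy": {"m4"},
            },
            mesh={
                "hepatocellular carcinoma": ("C04.557.470",),
                "lung carcinoma": ("C04.557.337",),
                "epilepsy": ("C10.228",),
            },
        )

    def test_level_one_merges_shared_prefix(self):
        out = mesh_collapse(self._catalog(), 1)
        assert out.associations["C04"] == {"m1", "m2", "m3"}
        assert out.associations["C10"] == {"m4"}

    def test_level_beyond_depth_is_identity_on_labels(self):
        cat = self._catalog()
        out = mesh_collapse(cat, 10)
        # deep truncation keeps each full path as its own label
        assert len(out.associations) == len(cat.associations)

    def test_multi_path_disease_contributes_to_each_label(self):
        cat = DiseaseCatalog(
            associations={"d": {"m1"}},
            mesh={"d": ("C04.1", "C10.2")},
        )
        out = mesh_collapse(cat, 1)
        assert out.associations["C04"] == {"m1"}
        assert out.associations["C10"] == {"m1"}

    def test_merged_sets_equal_brute_force_union(self):
        cat = self._catalog()
        out = mesh_collapse(cat, 1)
        expected = set()
        for term, paths in cat.mesh.items():
            if any(p.startswith("C04") for p in paths):
                expected |= cat.associations[term]
        assert out.associations["C04"] == expected

    def test_missing_path_kept_uncollapsed(self):
        cat = DiseaseCatalog(associations={"orphan": {"m1"}}, mesh={})
        out = mesh_collapse(cat, 1)
        assert out.associations["orphan"] == {"m1"}


class TestDiseaseCountVsAge:
    def test_counts_include_zero_association_mirnas(self):
        ages = pd.DataFrame({"accession": ["a", "b"], "age_my": [10.0, 500.0]})
        cat = DiseaseCatalog(associations={"d1": {"b"}})
        res, counts = disease_count_vs_age(ages, cat)
        assert counts["a"] == 0 and counts["b"] == 1
        assert not res.defined  # n=2 < 3

    def test_cancer_merge_reduces_catalog(self):
        cat = DiseaseCatalog(
            associations={"lung cancer": {"a"}, "leukemia": {"b"}, "epilepsy": {"c"}}
        )
        reduced = cat.collapse_cancer()
        assert set(reduced.associations) == {"cancer_merged", "epilepsy"}
        assert reduced.associations["cancer_merged"] == {"a", "b"}

    def test_planted_age_effect_recovered(self, rng):
        n = 300
        ages = rng.uniform(0, 800, size=n)
        terms = [f"d{i}" for i in range(40)]
        assoc = {t: set() for t in terms}
        for i, a in enumerate(ages):
            k = rng.poisson(0.5 + 0.02 * a)
            for t in rng.choice(terms, size=min(k, len(terms)), replace=False):
                assoc[t].add(f"m{i}")
        frame = pd.DataFrame({"accession": [f"m{i}" for i in range(n)], "age_my": ages})
        res, _ = disease_count_vs_age(frame, DiseaseCatalog(associations=assoc))
        assert res.statistic > 0
        assert res.pvalue < 0.01


class TestDiseaseAgeEnrichment:
    def test_oldest_members_give_minimal_p_among_subsets(self):
        import itertools

        ages = pd.DataFrame(
            {"accession": [f"m{i}" for i in range(8)], "age_my": [10, 20, 30, 40, 50, 60, 70, 80]}
        )
        oldest = {"m5", "m6", "m7"}
        cat = DiseaseCatalog(associations={"d": oldest})
        p_obs = disease_age_enrichment(ages, cat)["p_raw"].iloc[0]
        ps = []
        for subset in itertools.combinations(ages["accession"], 3):
            c = DiseaseCatalog(associations={"d": set(subset)})
            ps.append(disease_age_enrichment(ages, c)["p_raw"].iloc[0])
        assert p_obs == pytest.approx(min(ps))

    def test_constant_ages_give_p_one(self):
        ages = pd.DataFrame({"accession": [f"m{i}" for i in range(10)], "age_my": [50.0] * 10})
        cat = DiseaseCatalog(associations={"d1": {"m0", "m1"}, "d2": {"m2", "m3", "m4"}})
        table = disease_age_enrichment(ages, cat)
        assert np.allclose(table["p_raw"], 1.0)

    def test_small_diseases_skipped(self):
        ages = pd.DataFrame({"accession": ["a", "b", "c"], "age_my": [1.0, 2.0, 3.0]})
        cat = DiseaseCatalog(associations={"tiny": {"a"}})
        assert len(disease_age_enrichment(ages, cat)) == 0

    def test_null_type_one_error_calibrated(self, rng):
        """Raw p<0.05 rate under random membership stays near nominal."""
        n, k, reps = 40, 8, 1000
        hits = 0
        for _ in range(reps):
            ages = pd.DataFrame(
                {"accession": [f"m{i}" for i in range(n)], "age_my": rng.uniform(0, 800, n)}
            )
            members = set(rng.choice(ages["accession"], size=k, replace=False))
            table = disease_age_enrichment(ages, DiseaseCatalog(associations={"d": members}))
            hits += int(table["p_raw"].iloc[0] < 0.05)
        lo, hi = sps.binom.interval(0.999, reps, 0.05)
        assert lo <= hits <= hi


class TestTargetAgeFraction:
    def test_hand_examples(self):
        assert target_age_fraction(50, [100, 200, 10]) == pytest.approx(2 / 3)
        assert target_age_fraction(500, [100, 200, 10]) == 0.0

    def test_tie_counts_as_not_older(self):
        assert target_age_fraction(100, [100, 200]) == pytest.approx(0.5)

    def test_empty_targets_undefined(self):
        with pytest.raises(ValueError):
            target_age_fraction(10, [])

    def test_matches_counting_oracle(self, rng):
        for _ in range(50):
            age = float(rng.uniform(0, 500))
            targets = rng.uniform(0, 1000, size=int(rng.integers(1, 30)))
            expected = sum(1 for t in targets if t > age) / targets.size
            assert target_age_fraction(age, targets) == pytest.approx(expected)


def _target_table(mapping):
    t = TargetTable()
    for m, ages in mapping.items():
        genes = {f"{m}:g{i}": a for i, a in enumerate(ages)}
        t.targets[m] = set(genes)
        t.gene_ages.update(genes)
    return t


class TestPermutationTargetTest:
    def test_identical_ages_give_p_one(self):
        t = _target_table({"a": [10, 20], "b": [5, 30], "c": [40]})
        ages = {"a": 15.0, "b": 15.0, "c": 15.0}
        res = permutation_target_test(ages, t, n_perm=200, seed=0)
        assert res.pvalue == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        t = _target_table({"a": [10, 200], "b": [5, 300], "c": [40, 45, 700]})
        ages = {"a": 1.0, "b": 150.0, "c": 50.0}
        r1 = permutation_target_test(ages, t, n_perm=500, seed=7)
        r2 = permutation_target_test(ages, t, n_perm=500, seed=7)
        assert r1.pvalue == r2.pvalue and r1.statistic == r2.statistic

    def test_three_mirna_p_close_to_exact_enumeration(self):
        sets = {"a": [100.0, 300.0], "b": [10.0, 20.0, 500.0], "c": [250.0]}
        ages = {"a": 5.0, "b": 240.0, "c": 90.0}
        t = _target_table(sets)
        n_perm = 10_000
        res = permutation_target_test(ages, t, n_perm=n_perm, seed=3)
        _, p_exact = exact_pairing_p(
            [ages[m] for m in sorted(sets)], [sets[m] for m in sorted(sets)]
        )
        mc_se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.pvalue - p_exact) <= 3 * mc_se + 2 / n_perm

    def test_nperm_validation(self):
        t = _target_table({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            permutation_target_test({"a": 1.0, "b": 2.0}, t, n_perm=0)


class TestTfTargetFraction:
    def test_hand_example(self):
        t = _target_table({"a": [1, 2, 3, 4]})
        genes = sorted(t.targets["a"])
        t.tf_flags = {g: (i == 0) for i, g in enumerate(genes)}
        assert tf_target_fraction(t, {"a"}) == pytest.approx(0.25)

    def test_no_flags_gives_zero(self):
        t = _target_table({"a": [1, 2], "b": [3]})
        assert tf_target_fraction(t, {"a", "b"}) == 0.0

    def test_empty_after_exclusions_errors(self):
        t = _target_table({"a": [1.0]})
        with pytest.raises(ValueError):
            tf_target_fraction(t, {"zzz"})

    def test_matches_counting_oracle(self, rng):
        t = _target_table({f"m{i}": rng.uniform(0, 100, size=rng.integers(1, 10)) for i in range(10)})
        for g in t.gene_ages:
            t.tf_flags[g] = bool(rng.random() < 0.3)
        expected = np.mean(
            [
                np.mean([t.tf_flags[g] for g in sorted(t.targets[m])])
                for m in sorted(t.targets)
            ]
        )
        assert tf_target_fraction(t, set(t.targets)) == pytest.approx(float(expected))


class TestExpressionBreadth:
    def _matrix(self, data, samples):
        return pd.DataFrame(data, index=[f"m{i}" for i in range(len(data))], columns=samples)

    def test_all_zero_row_breadth_zero(self):
        mat = self._matrix([[0, 0, 0, 0]], ["t1_r1", "t1_r2", "t2_r1", "t2_r2"])
        smap = {"t1_r1": "t1", "t1_r2": "t1", "t2_r1": "t2", "t2_r2": "t2"}
        summary = expression_breadth(mat, smap)
        assert summary.breadth["m0"] == 0

    def test_single_replicate_presence(self):
        mat = self._matrix([[0, 3.0, 0, 0]], ["t1_r1", "t1_r2", "t2_r1", "t2_r2"])
        smap = {"t1_r1": "t1", "t1_r2": "t1", "t2_r1": "t2", "t2_r2": "t2"}
        summary = expression_breadth(mat, smap)
        assert summary.tissues["m0"] == {"t1"}

    def test_unmapped_sample_errors_naming_it(self):
        mat = self._matrix([[1.0]], ["mystery"])
        with pytest.raises(ValueError, match="mystery"):
            expression_breadth(mat, {})

    def test_random_matrix_matches_brute_force(self, rng):
        samples = [f"t{t}_r{r}" for t in range(4) for r in range(3)]
        smap = {s: s.split("_")[0] for s in samples}
        data = rng.random((10, 12)) * (rng.random((10, 12)) < 0.4)
        mat = self._matrix(data, samples)
        summary = expression_breadth(mat, smap)
        for i, m in enumerate(mat.index):
            expected = {
                f"t{t}" for t in range(4) if (data[i, t * 3:(t + 1) * 3] > 0).any()
            }
            assert summary.tissues[m] == expected

    def test_mean_above_rule(self):
        mat = self._matrix([[1.0, 0.0]], ["t1_r1", "t1_r2"])
        smap = {"t1_r1": "t1", "t1_r2": "t1"}
        lo = expression_breadth(mat, smap, presence_rule="mean_above", threshold=0.4)
        hi = expression_breadth(mat, smap, presence_rule="mean_above", threshold=0.6)
        assert lo.breadth["m0"] == 1 and hi.breadth["m0"] == 0


class TestJaccard:
    def test_basic_values(self):
        assert jaccard([1, 1, 0], [1, 1, 0]) == 1.0
        assert jaccard([1, 0, 0], [0, 0, 1]) == 0.0
        assert jaccard([1, 1, 0], [0, 1, 1]) == pytest.approx(1 / 3)

    def test_both_empty_is_nan(self):
        assert np.isnan(jaccard([0, 0], [0, 0]))

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError):
            jaccard([1, 0], [1, 0, 1])

    @given(
        st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()), min_size=1, max_size=24)
    )
    def test_symmetry_and_triangle_distance(self, rows):
        a = np.array([r[0] for r in rows])
        b = np.array([r[1] for r in rows])
        c = np.array([r[2] for r in rows])
        pairs = [(a, b), (b, c), (a, c)]
        if any(np.logical_or(u, v).sum() == 0 for u, v in pairs):
            return
        dab = 1 - jaccard(a, b)
        dbc = 1 - jaccard(b, c)
        dac = 1 - jaccard(a, c)
        assert jaccard(a, b) == pytest.approx(jaccard(b, a))
        assert dac <= dab + dbc + 1e-12


class TestPairwiseProfileSimilarity:
    def test_pair_counts_follow_combinatorics(self, rng):
        labels = [f"L{i}" for i in range(12)]
        accs = [f"m{i}" for i in range(12)]
        profiles = pd.DataFrame(
            rng.integers(0, 2, size=(12, len(labels))), index=accs, columns=labels
        )
        profiles.iloc[:, 0] = 1  # no empty profiles
        fams = family_table_from_mapping(
            {"f1": accs[:3], "f2": accs[3:6]}, accs
        )
        sim = pairwise_profile_similarity(profiles, fams, min_family_size=3)
        assert sim.within_family.size == 3 + 3  # C(3,2) per family
        assert sim.between_family.size == 9  # 3 x 3 cross-family
        assert sim.singleton.size == 15  # C(6,2)

    def test_shared_family_profiles_scored_higher(self, rng):
        labels = [f"L{i}" for i in range(40)]
        rows = {}
        fam_map = {}
        base = rng.integers(0, 2, size=40)
        fam_map["f1"] = [f"fm{i}" for i in range(6)]
        for m in fam_map["f1"]:
            keep = rng.random(40) < 0.9
            rows[m] = base * keep
        singles = [f"s{i}" for i in range(10)]
        for m in singles:
            rows[m] = rng.integers(0, 2, size=40)
        profiles = pd.DataFrame.from_dict(rows, orient="index")
        profiles.columns = labels
        fams = family_table_from_mapping(fam_map, list(rows))
        sim = pairwise_profile_similarity(profiles, fams, min_family_size=5)
        assert sim.within_family.mean() > sim.singleton.mean()
        assert sim.tests["within_vs_singleton"].pvalue < 0.05

    def test_family_size_filter_applied(self):
        accs = [f"m{i}" for i in range(6)]
        profiles = pd.DataFrame(np.eye(6, dtype=int), index=accs)
        fams = family_table_from_mapping({"small": accs[:2]}, accs)
        sim = pairwise_profile_similarity(profiles, fams, min_family_size=5)
        # the undersized family is ignored; its members are not singletons
        assert sim.within_family.size == 0
        assert sim.singleton.size == 6  # C(4,2)
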