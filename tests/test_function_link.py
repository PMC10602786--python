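"""Taxon-function association, rank tests, diversity and core-taxon logic."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from consortium_net import (
    AbundanceTable,
    DegradationRecord,
    community_metrics,
    core_and_unique,
    group_compare,
    taxon_function_scores,
    top_tables,
)
from consortium_net.synthetic import SyntheticSpec, simulate_study, study_spec


def _records_from_efficiencies(table, fraction, eff):
    return [
        DegradationRecord(g, r, fraction, 10.0, 10.0 * (1 - e))
        for g, r, e in zip(table.generations, table.replicates, eff)
    ]


@pytest.fixture(scope="module")
def planted_run():
    spec = study_spec(seed=100)
    table, records, truth = simulate_study(spec)
    return table, records, truth


class TestTaxonFunctionScores:
    def test_perfect_dependence_gives_positive_combined(self, small_table):
        eff = small_table.values[:, 2].copy()  # efficiency == taxon t2 abundance
        records = _records_from_efficiencies(small_table, "TPH", eff)
        assocs = taxon_function_scores(small_table, records, "TPH",
                                       permutations=200, seed=1)
        best = {a.taxon: a for a in assocs}["t2"]
        assert best.combined > 0
        assert all(z > 0 for z in best.measure_z.values())
        assert best.combined == max(a.combined for a in assocs)

    def test_planted_keystone_attains_top_coefficient(self, planted_run):
        table, records, _ = planted_run
        assocs = taxon_function_scores(table, records, "TPH", permutations=300, seed=2)
        best = max(assocs, key=lambda a: a.combined)
        assert best.taxon == "taxon_00"
        assert best.direction == "+"

    def test_antisymmetric_under_response_negation(self, small_table):
        r = np.random.default_rng(3)
        eff = r.normal(0.3, 0.1, small_table.n_samples)
        pos = taxon_function_scores(
            small_table, _records_from_efficiencies(small_table, "TPH", eff),
            "TPH", permutations=200, seed=4)
        neg = taxon_function_scores(
            small_table, _records_from_efficiencies(small_table, "TPH", -eff),
            "TPH", permutations=200, seed=4)
        for a, b in zip(pos, neg):
            assert a.taxon == b.taxon
            for m in a.measure_z:
                assert np.sign(a.measure_z[m]) == -np.sign(b.measure_z[m]) or (
                    a.measure_z[m] == b.measure_z[m] == 0
                )
            assert np.sign(a.combined) == -np.sign(b.combined)

    def test_null_combined_bounded_by_dependence_ceiling(self):
        # five z's on the same samples are strongly dependent; the combined
        # null spread stays below the perfect-dependence ceiling of 5 z-units
        pool = []
        for seed in range(20):
            spec = SyntheticSpec(n_taxa=15, seed=4000 + seed, noise_sd=0.05)
            table, records, _ = simulate_study(spec)
            assocs = taxon_function_scores(table, records, "TPH",
                                           permutations=200, seed=seed)
            pool.extend(abs(a.combined) for a in assocs)
        assert np.percentile(pool, 95) < 10.0  # 1.96 * 5 ~ perfect dependence

    def test_permutation_p_uniform_under_null(self):
        pvals = []
        for seed in range(30):
            spec = SyntheticSpec(n_taxa=10, seed=5000 + seed, noise_sd=0.05)
            table, records, _ = simulate_study(spec)
            assocs = taxon_function_scores(table, records, "TPH",
                                           permutations=200, seed=seed)
            pvals.extend(a.pvalue for a in assocs[:2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_samples_rejected(self, small_table):
        sub_vals = small_table.values[:4]
        t = AbundanceTable(
            sample_ids=small_table.sample_ids[:4],
            taxon_ids=small_table.taxon_ids,
            values=sub_vals / sub_vals.sum(axis=1, keepdims=True),
            generations=small_table.generations[:4],
            replicates=small_table.replicates[:4],
            mode="relative",
        )
        records = _records_from_efficiencies(t, "TPH", np.full(4, 0.3))
        with pytest.raises(ValueError):
            taxon_function_scores(t, records, "TPH")


class TestTopTables:
    def test_planted_keystone_leads_positive_table(self, planted_run):
        table, records, _ = planted_run
        assocs = taxon_function_scores(table, records, "TPH", permutations=300, seed=5)
        pos, neg = top_tables(assocs, k=1)
        assert pos.loc[0, "taxon"] == "taxon_00"

    def test_empty_input_gives_empty_report(self):
        pos, neg = top_tables([], k=5)
        assert pos.empty and neg.empty

    def test_truncation_when_k_exceeds_taxa(self, planted_run):
        table, records, _ = planted_run
        assocs = taxon_function_scores(table, records, "TPH", permutations=200, seed=6)
        pos, neg = top_tables(assocs, k=10_000)
        assert len(pos) == len(assocs)


class TestGroupCompare:
    def test_exact_wilcoxon_fully_separated(self):
        stat, p = group_compare([np.array([1, 2, 3.0]), np.array([4, 5, 6.0])],
                                test="wilcoxon-mann-whitney")
        assert p == pytest.approx(0.1)  # 2/C(6,3) = 2/20

    def test_exact_wilcoxon_enumeration_oracle(self):
        x, y = np.array([1.0, 2.5, 7.0]), np.array([3.0, 4.5, 6.0])
        _, p = group_compare([x, y], test="wilcoxon-mann-whitney")
        pooled = np.concatenate([x, y])
        u_obs = sum((xi > yj) for xi in x for yj in y)
        count = 0
        for combo in itertools.combinations(range(6), 3):
            xs = pooled[list(combo)]
            ys = pooled[[i for i in range(6) if i not in combo]]
            u = sum((xi > yj) for xi in xs for yj in ys)
            if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
                count += 1
        assert p == pytest.approx(count / 20)

    def test_identical_groups_not_significant(self):
        _, p = group_compare([np.array([1, 2, 3.0]), np.array([1, 2, 3.0])])
        assert p > 0.5

    def test_kruskal_label_permutation_invariance(self, rng):
        groups = [rng.random(3), rng.random(3), rng.random(3)]
        h1, p1 = group_compare(groups, test="kruskal-wallis")
        h2, p2 = group_compare(groups[::-1], test="kruskal-wallis")
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)

    def test_kruskal_exact_matches_enumeration_scale(self):
        # tiny groups use full enumeration; p must lie on the 1/1680 grid
        groups = [np.array([1, 2.0]), np.array([3, 4.0]), np.array([5, 6.0])]
        _, p = group_compare(groups, test="kruskal-wallis")
        total = math.factorial(6) // (2 * 2 * 2)
        assert (p * total) == pytest.approx(round(p * total), abs=1e-9)
        assert p < 0.2


class TestCommunityMetrics:
    def test_uniform_four_taxa(self):
        vals = np.full((2, 4), 0.25)
        t = AbundanceTable(["a", "b"], list("wxyz"), vals, ["G1", "G1"], [1, 2], "relative")
        alpha, beta = community_metrics(t)
        assert alpha["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert alpha["evenness"].iloc[0] == pytest.approx(1.0)
        assert beta.iloc[0, 1] == pytest.approx(0.0)

    def test_single_taxon_sample(self):
        vals = np.array([[1.0, 0, 0], [0.2, 0.3, 0.5]])
        t = AbundanceTable(["a", "b"], list("xyz"), vals, ["G1", "G1"], [1, 2], "relative")
        alpha, _ = community_metrics(t)
        assert alpha["shannon"].iloc[0] == 0.0
        assert alpha["evenness"].iloc[0] == 0.0

    def test_direct_summation_oracle(self, rng):
        vals = rng.gamma(2, 1, (4, 5))
        vals /= vals.sum(axis=1, keepdims=True)
        t = AbundanceTable(["a", "b", "c", "d"], list("vwxyz"), vals,
                           ["G1"] * 4, [1, 2, 3, 4], "relative")
        alpha, beta = community_metrics(t)
        for i in range(4):
            h = -sum(p * np.log(p) for p in vals[i] if p > 0)
            assert alpha["shannon"].iloc[i] == pytest.approx(h, abs=1e-12)
        np.testing.assert_allclose(beta.values, beta.values.T, atol=1e-12)
        assert np.allclose(np.diag(beta.values), 0.0)


class TestCoreAndUnique:
    def _gen_tables(self, membership):
        """membership: dict taxon -> dict generation -> abundance (0 = absent)."""
        taxa = sorted(membership)
        tables = []
        for g in ("G1", "G2", "G3", "G4"):
            rows = []
            for rep in range(3):
                row = np.array([membership[t].get(g, 0.0) for t in taxa])
                filler = max(0.0, 1.0 - row.sum())
                rows.append(np.append(row, filler))
            vals = np.array(rows)
            tables.append(AbundanceTable(
                [f"{g}r{r}" for r in range(3)], taxa + ["filler"], vals,
                [g] * 3, [1, 2, 3], "relative",
            ))
        return tables

    def test_ubiquitous_abundant_taxon_is_core(self):
        tables = self._gen_tables({"core1": {g: 0.01 for g in ("G1", "G2", "G3", "G4")}})
        out = core_and_unique(tables)
        assert "core1" in out["core"]
        assert "core1" in out["shared"]

    def test_low_abundance_fails_core(self):
        tables = self._gen_tables({"rare": {g: 0.0005 for g in ("G1", "G2", "G3", "G4")}})
        out = core_and_unique(tables)
        assert "rare" not in out["core"]
        assert "rare" in out["shared"]  # present everywhere, just rare

    def test_venn_counts_match_hand_enumeration(self):
        membership = {
            "everywhere": {g: 0.05 for g in ("G1", "G2", "G3", "G4")},
            "only_g1": {"G1": 0.02},
            "only_g4": {"G4": 0.02},
            "g1_and_g2": {"G1": 0.02, "G2": 0.02},
        }
        out = core_and_unique(self._gen_tables(membership))
        assert out["counts"]["unique"] == {"G1": 1, "G2": 0, "G3": 0, "G4": 1}
        assert out["shared"] >= {"everywhere", "filler"}
        assert "g1_and_g2" not in out["shared"]

    def test_core_set_shrinks_as_thresholds_rise(self):
        tables = [t.to_relative() for t, *_ in [simulate_study(study_spec(seed=8))]]
        gens = tables[0].generation_labels()
        per_gen = [tables[0].select_generation(g) for g in gens]
        loose = core_and_unique(per_gen, prevalence_min=0.5, abundance_min=0.001)
        tight = core_and_unique(per_gen, prevalence_min=0.9, abundance_min=0.01)
        assert tight["core"] <= loose["core"]
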