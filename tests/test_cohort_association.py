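import numpy as np
import pandas as pd
import pytest

from ithkit.cohort_association import (
    MutationMatrix,
    build_mutation_matrix,
    collapse_to_categories,
    default_category_map,
    evaluate_model,
    fit_category_model,
    fit_lasso_drivers,
    _penalty_grid,
    predict_ith,
)
from ithkit.synthetic_data import CohortSpec, simulate_cohort
from ithkit.variant_io import SampleVariantSet


def _variant_sets(make_variant, assignments):
    """assignments: {sample_id: [(gene, n_variants), ...]}"""
    sets = []
    pos = 1
    for sid, genes in assignments.items():
        vs = []
        for gene, n in genes:
            for _ in range(n):
                vs.append(make_variant(pos=pos, sample_id=sid, gene=gene))
                pos += 1
        sets.append(SampleVariantSet(sid, "SYN", vs))
    return sets


class TestMutationMatrix:
    def test_multiplicity_collapsed_to_one(self, make_variant):
        sets = _variant_sets(make_variant, {"S1": [("A", 10)]})
        m = build_mutation_matrix(sets)
        assert m.data.loc["S1", "A"] == 1

    def test_matches_brute_force_recount(self, random_variant_set):
        for seed in range(10):
            sets = [random_variant_set(seed * 3 + i, n=30, sample_id=f"S{i}")
                    for i in range(3)]
            m = build_mutation_matrix(sets)
            for s in sets:
                genes_present = {v.gene for v in s if v.gene}
                for g in m.gene_ids:
                    assert m.data.loc[s.sample_id, g] == int(g in genes_present)

    def test_gene_universe_restricts_columns(self, make_variant):
        sets = _variant_sets(make_variant, {"S1": [("A", 1), ("B", 1)]})
        m = build_mutation_matrix(sets, gene_universe=["A"])
        assert m.gene_ids == ["A"]

    def test_empty_universe_is_fatal(self, make_variant):
        sets = _variant_sets(make_variant, {"S1": [("", 0)]})
        with pytest.raises(ValueError):
            build_mutation_matrix(sets)

    def test_entries_must_be_binary(self):
        df = pd.DataFrame([[2]], index=["S1"], columns=["A"])
        with pytest.raises(ValueError):
            MutationMatrix(df, pd.Series({"S1": "X"}))


class TestCategoryCollapse:
    def test_or_over_member_genes(self, make_variant):
        sets = _variant_sets(make_variant,
                             {"S1": [("A", 1)], "S2": [("B", 1)],
                              "S3": [("C", 1)]})
        m = build_mutation_matrix(sets)
        cm = collapse_to_categories(m, {"A": "cat1", "B": "cat1", "C": "cat2"})
        assert list(cm.data["cat1"]) == [1, 1, 0]
        assert list(cm.data["cat2"]) == [0, 0, 1]

    def test_matches_brute_force_or(self, random_variant_set):
        cmap = {f"G{i:02d}": f"cat{i % 3}" for i in range(6)}  # G06,G07 unmapped
        for seed in range(10):
            sets = [random_variant_set(100 + seed * 4 + i, n=30,
                                       sample_id=f"S{i}") for i in range(4)]
            m = build_mutation_matrix(sets)
            cm = collapse_to_categories(m, cmap)
            for sid in m.sample_ids:
                for cat in cm.gene_ids:
                    member = [g for g in m.gene_ids
                              if cmap.get(g) == cat]
                    expected = int(any(m.data.loc[sid, g] for g in member))
                    assert cm.data.loc[sid, cat] == expected

    def test_bundled_category_table_loads(self):
        cmap = default_category_map()
        assert cmap["SETD2"] == "epigenetic modifiers"
        assert cmap["DNMT1"] == "epigenetic modifiers"
        assert len(set(cmap.values())) == 17


class TestCategoryModel:
    @staticmethod
    def _simulated(seed, effect=3.0, n=200, noise=0.1):
        rng = np.random.default_rng(seed)
        cats = ["epigenetic", "cellcycle", "mapk"]
        data = pd.DataFrame(
            rng.binomial(1, 0.3, size=(n, 3)),
            index=[f"S{i}" for i in range(n)], columns=cats, dtype=np.int8)
        ith = 2 + effect * data["epigenetic"] + rng.normal(0, noise, n)
        m = MutationMatrix(data, pd.Series("KIRC", index=data.index))
        return m, pd.Series(ith, index=data.index)

    def test_recovers_injected_coefficient(self):
        m, ith = self._simulated(0)
        res = fit_category_model(m, ith, "KIRC")
        assert 2.8 <= res.coefficients["epigenetic"] <= 3.2
        assert res.adjusted_p["epigenetic"] < 0.05

    def test_null_model_false_positive_rate(self):
        false_pos = 0
        for seed in range(100):
            m, _ = self._simulated(seed)
            rng = np.random.default_rng(10_000 + seed)
            ith = pd.Series(rng.normal(2, 1, len(m.data)), index=m.data.index)
            res = fit_category_model(m, ith, "KIRC")
            if any(p is not None and p < 0.05 for p in res.adjusted_p.values()):
                false_pos += 1
        assert false_pos <= 10

    def test_unmutated_category_dropped_with_undefined_coefficient(self):
        m, ith = self._simulated(1)
        data = m.data.copy()
        data["silent"] = 0
        m2 = MutationMatrix(data, m.cancer_types)
        with pytest.warns(UserWarning, match="constant"):
            res = fit_category_model(m2, ith, "KIRC")
        assert res.coefficients["silent"] is None
        assert "silent" in res.dropped

    def test_bh_adjustment_is_monotone_and_never_smaller(self):
        m, ith = self._simulated(2)
        res = fit_category_model(m, ith, "KIRC")
        raw = [res.p_values[c] for c in m.data.columns]
        adj = [res.adjusted_p[c] for c in m.data.columns]
        for r, a in zip(raw, adj):
            assert a >= r - 1e-12
        order_raw = np.argsort(raw)
        assert all(np.diff(np.array(adj)[order_raw]) >= -1e-12)


def _driver_cohort(seed, n=300, n_genes=50, effect=10.0, noise=5.0):
    genes = [f"G{i:04d}" for i in range(n_genes)]
    spec = CohortSpec(
        n_samples=n, genes=genes,
        prevalence={g: 0.2 for g in genes},
        effects={genes[0]: effect}, baseline_sd=noise, seed=seed)
    matrix, ith, _ = simulate_cohort(spec)
    return matrix, ith


class TestLassoDrivers:
    def test_injected_driver_enters_first(self):
        matrix, ith = _driver_cohort(7)
        res = fit_lasso_drivers(matrix, ith, seed=7)
        assert res.entry_ranks["G0000"] == 1
        assert res.coefficients["G0000"] > 0

    def test_entry_ranks_are_a_permutation(self):
        matrix, ith = _driver_cohort(3)
        res = fit_lasso_drivers(matrix, ith, seed=3)
        assert sorted(res.entry_ranks.values()) == \
            list(range(1, len(res.genes) + 1))

    def test_all_coefficients_zero_at_largest_penalty(self):
        matrix, ith = _driver_cohort(5)
        df = matrix.data
        X = (df - df.mean()) / df.std()
        grid = _penalty_grid(X.to_numpy(), ith.to_numpy())
        from sklearn.linear_model import lasso_path
        _, coefs, _ = lasso_path(X.to_numpy(), ith.to_numpy(), alphas=grid)
        assert np.allclose(coefs[:, 0], 0.0)
        assert np.any(coefs[:, -1] != 0.0)

    def test_null_ith_rarely_significant(self):
        n_sig = 0
        for seed in range(50):
            matrix, _ = _driver_cohort(seed, effect=0.0)
            rng = np.random.default_rng(20_000 + seed)
            ith = pd.Series(rng.normal(30, 5, len(matrix.data)),
                            index=matrix.data.index)
            res = fit_lasso_drivers(matrix, ith, seed=seed)
            if res.significant:
                n_sig += 1
        assert n_sig <= 5

    def test_unmutated_genes_give_empty_model(self):
        data = pd.DataFrame(0, index=[f"S{i}" for i in range(40)],
                            columns=["A", "B"], dtype=np.int8)
        m = MutationMatrix(data, pd.Series("X", index=data.index))
        ith = pd.Series(np.arange(40.0), index=data.index)
        res = fit_lasso_drivers(m, ith)
        assert res.genes == [] and res.r_squared == 0.0
        assert not res.significant


class TestEvaluateModel:
    def test_noiseless_generative_ith_gives_r_one(self):
        matrix, ith = _driver_cohort(11)
        res = fit_lasso_drivers(matrix, ith, seed=11)
        synthetic_ith = predict_ith(res, matrix)
        _, r, p = evaluate_model(res, matrix, synthetic_ith)
        assert r == pytest.approx(1.0)

    def test_driver_scenario_gives_strong_correlation(self):
        matrix, ith = _driver_cohort(7)
        res = fit_lasso_drivers(matrix, ith, seed=7)
        _, r, _ = evaluate_model(res, matrix, ith)
        assert r > 0.5

    def test_shuffled_ith_gives_weak_correlation(self):
        matrix, ith = _driver_cohort(13)
        res = fit_lasso_drivers(matrix, ith, seed=13)
        hits = 0
        rng = np.random.default_rng(13)
        for _ in range(100):
            shuffled = pd.Series(rng.permutation(ith.to_numpy()),
                                 index=ith.index)
            _, r, _ = evaluate_model(res, matrix, shuffled)
            if abs(r) < 0.15:
                hits += 1
        assert hits >= 95

    def test_empty_model_has_undefined_r(self):
        data = pd.DataFrame(0, index=[f"S{i}" for i in range(40)],
                            columns=["A"], dtype=np.int8)
        m = MutationMatrix(data, pd.Series("X", index=data.index))
        ith = pd.Series(np.arange(40.0), index=data.index)
        res = fit_lasso_drivers(m, ith)
        _, r, p = evaluate_model(res, m, ith)
        assert r is None and p is None
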