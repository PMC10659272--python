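"""Normalization, differential expression, gene programs, and aging statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainaging.errors import DataError
from brainaging.transcriptome_aging import (
    classify_gene_programs,
    compare_correlations,
    composition_trend,
    count_shared,
    de_frame,
    differential_expression,
    gene_set_enrichment,
    length_decile_foldchange,
    log_normalize,
    shared_down_permutation,
)


class TestLogNormalize:
    def test_zero_counts_stay_zero(self):
        X = np.array([[0, 4], [5, 0]])
        N = log_normalize(X)
        assert N[0, 0] == 0.0 and N[1, 1] == 0.0

    def test_single_gene_cell_closed_form(self):
        X = np.array([[7], [0]])
        N = log_normalize(X)
        assert N[0, 0] == pytest.approx(np.log1p(10_000))

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(3.0, (50, 4)) + 1
        np.testing.assert_allclose(log_normalize(X), log_normalize(2 * X))

    def test_all_zero_cell_named(self):
        X = np.zeros((5, 3))
        X[:, 0] = 1
        with pytest.raises(DataError, match=r"\[1, 2\]|column"):
            log_normalize(X)


class TestDifferentialExpression:
    def _null_matrix(self, n_genes=60, n_cells=40, seed=0):
        rng = np.random.default_rng(seed)
        return rng.poisson(5.0, (n_genes, n_cells)) + 1

    def test_identical_groups_yield_nothing(self):
        X = log_normalize(self._null_matrix())
        idx = np.arange(20)
        res = differential_expression(X, [f"g{i}" for i in range(60)], idx, idx)
        assert all(not r.significant for r in res)
        assert all(r.log2_fc == 0 for r in res)

    def test_swap_antisymmetry(self):
        X = log_normalize(self._null_matrix(seed=3))
        genes = [f"g{i}" for i in range(60)]
        e, a = np.arange(20), np.arange(20, 40)
        fwd = differential_expression(X, genes, e, a)
        rev = differential_expression(X, genes, a, e)
        for r_f, r_r in zip(fwd, rev):
            assert r_f.log2_fc == pytest.approx(-r_r.log2_fc)
            assert r_f.p_value == pytest.approx(r_r.p_value, rel=1e-9)

    def test_small_group_rejected(self):
        X = log_normalize(self._null_matrix())
        with pytest.raises(DataError):
            differential_expression(X, [f"g{i}" for i in range(60)], [0, 1], np.arange(10, 30))

    def test_planted_twofold_down_recovered(self, expression, de_results, toy_genome):
        """Well-expressed genes planted at ~2-fold down are called at >= 90%."""
        _, truth = expression
        _, genes, _ = toy_genome
        lam = {g.gene_id: np.expm1(g.mean_expression["ExN"]) for g in genes}
        res = {r.gene_id: r for r in de_results["ExN"]}
        planted = truth.planted_lfc["ExN"]
        targets = [
            g for g in planted[planted <= -0.9].index if lam[g] >= 0.5 and g in res
        ]
        assert len(targets) >= 20
        hits = [g for g in targets if res[g].significant and res[g].direction == "down"]
        assert len(hits) / len(targets) >= 0.9

    def test_null_type_one_error_calibrated(self, toy_genome):
        from brainaging.synthetic_data import GeneratorConfig, simulate_expression
        from brainaging.transcriptome_aging import de_by_cell_type

        _, genes, _ = toy_genome
        cfg = GeneratorConfig(seed=7, hk_decline_max=0.0, shared_down_genes=0)
        cm, truth = simulate_expression(cfg, genes)
        assert (truth.planted_lfc.to_numpy() == 0).all()
        de = de_by_cell_type(cm)
        ps = np.array([r.p_value for rs in de.values() for r in rs])
        frac = (ps < 0.05).mean()
        assert abs(frac - 0.05) < 0.02
        assert sum(r.significant for rs in de.values() for r in rs) == 0

    def test_frame_carries_optional_fdr(self, de_results):
        df = de_frame(de_results)
        assert {"gene_id", "cell_type", "log2_fc", "p_value", "fdr_bh"} <= set(df.columns)
        assert (df["fdr_bh"] >= df["p_value"] - 1e-12).all()


class TestClassifyGenePrograms:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["excitatory", "inhibitory", "microglia", "endothelia"]
        )

    def test_rule_application(self):
        m = self._frame([[0.50, 0.52, 0.48, 0.49], [0.30, 0.30, 0.05, 0.05]])
        out = classify_gene_programs(m)
        assert list(out["gene_class"]) == ["housekeeping", "neuron_specific"]

    def test_boundary_difference_exactly_point_one_is_other(self):
        m = self._frame([[0.50, 0.50, 0.50, 0.60]])
        assert classify_gene_programs(m)["gene_class"].iloc[0] == "other"

    def test_shift_invariance_of_difference_criterion(self):
        base = self._frame([[0.50, 0.52, 0.48, 0.49]])
        shifted = base + 0.7
        assert classify_gene_programs(shifted)["gene_class"].iloc[0] == "housekeeping"

    def test_floor_can_flip_the_call(self):
        low = self._frame([[0.08, 0.09, 0.07, 0.06]])  # spread < 0.1 but under floor
        assert classify_gene_programs(low)["gene_class"].iloc[0] == "other"

    def test_missing_cell_type_rejected(self):
        with pytest.raises(DataError, match="endothelia"):
            classify_gene_programs(
                pd.DataFrame({"excitatory": [1.0], "inhibitory": [1.0], "microglia": [1.0]})
            )


CATS4 = {"ex": "excitatory", "in": "inhibitory", "gl1": "glial", "gl2": "glial"}


class TestSharedDownPermutation:
    def test_empty_down_sets_give_p_one(self):
        genes = {f"g{i}" for i in range(10)}
        down = {ct: set() for ct in CATS4}
        expressed = {ct: genes for ct in CATS4}
        obs, _, p = shared_down_permutation(down, expressed, CATS4, n_perm=99, seed=0)
        assert obs == 0 and p == 1.0

    def test_p_bounded_below_by_permutation_resolution(self):
        genes = [f"g{i}" for i in range(12)]
        down = {ct: {"g0", "g1"} for ct in CATS4}
        expressed = {ct: set(genes) for ct in CATS4}
        obs, _, p = shared_down_permutation(down, expressed, CATS4, n_perm=200, seed=1)
        assert obs == 2
        assert 1 / 201 <= p <= 1.0

    def test_null_mean_matches_analytic_expectation(self):
        # 4 cell types, 10 genes, 2 down each: P(shared) = (2/10)^4 per gene
        genes = [f"g{i}" for i in range(10)]
        down = {ct: {"g0", "g1"} for ct in CATS4}
        expressed = {ct: set(genes) for ct in CATS4}
        _, perm, _ = shared_down_permutation(down, expressed, CATS4, n_perm=20_000, seed=3)
        expected = 10 * (2 / 10) ** 4
        se = perm.std() / np.sqrt(len(perm))
        assert abs(perm.mean() - expected) < max(4 * se, 0.005)

    def test_down_not_subset_rejected(self):
        down = {ct: {"zz"} for ct in CATS4}
        expressed = {ct: {"g0"} for ct in CATS4}
        with pytest.raises(DataError):
            shared_down_permutation(down, expressed, CATS4, n_perm=10, seed=0)

    def test_missing_category_rejected(self):
        cats = {"gl1": "glial", "gl2": "glial"}
        down = {ct: set() for ct in cats}
        expressed = {ct: {"g0"} for ct in cats}
        with pytest.raises(DataError, match="excitatory"):
            shared_down_permutation(down, expressed, cats, n_perm=10, seed=0)

    def test_criterion_counts_cross_category_genes_only(self):
        down = {
            "ex": {"g0", "g1"},
            "in": {"g0"},
            "gl1": {"g0", "g2"},
            "gl2": {"g0", "g2"},
        }
        assert count_shared(down, CATS4) == 1  # only g0 spans ex + in + 2 glial


class TestGeneSetEnrichment:
    def _de(self, down_genes, background):
        from brainaging.transcriptome_aging import DEResult

        return [
            DEResult(
                gene_id=g, cell_type="x", log2_fc=-1.0 if g in down_genes else 0.0,
                p_value=0.001 if g in down_genes else 0.9,
                pct_adult=1.0, pct_elderly=1.0,
                significant=g in down_genes,
                direction="down" if g in down_genes else "none",
            )
            for g in background
        ]

    def test_background_rate_set_gives_null(self):
        background = {f"g{i:03d}" for i in range(100)}
        down = {f"g{i:03d}" for i in range(0, 100, 5)}  # 20% down overall
        gene_set = {f"g{i:03d}" for i in range(10)}  # contains g000, g005: same 20% rate
        res = gene_set_enrichment(self._de(down, sorted(background)), gene_set, background)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle_on_small_tables(self):
        # exhaustive check over a grid of 2x2 tables with total <= 60
        for a, b, c, d in [(8, 2, 10, 40), (1, 9, 9, 41), (5, 5, 5, 45), (0, 10, 20, 30)]:
            n_set, n_down = a + b, a + c
            total = a + b + c + d
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            # oracle: sum hypergeometric probabilities <= that of the observed table
            rv = stats.hypergeom(total, n_set, n_down)
            support = np.arange(max(0, n_set + n_down - total), min(n_set, n_down) + 1)
            pmf = rv.pmf(support)
            oracle = pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum()
            assert p_scipy == pytest.approx(oracle, rel=1e-7)
            background = {f"g{i}" for i in range(total)}
            ordered = sorted(background)
            gene_set = set(ordered[:n_set])
            down = set(ordered[:a]) | set(ordered[n_set : n_set + c])
            res = gene_set_enrichment(self._de(down, ordered), gene_set, background)
            assert res["p_value"] == pytest.approx(oracle, rel=1e-7)

    def test_fully_down_set_is_extreme(self):
        background = {f"g{i}" for i in range(500)}
        gene_set = {f"g{i}" for i in range(50)}
        down = gene_set | {"g100", "g101"}
        res = gene_set_enrichment(self._de(down, sorted(background)), gene_set, background)
        assert res["p_value"] < 1e-6

    def test_empty_background_rejected(self):
        with pytest.raises(DataError):
            gene_set_enrichment([], set(), set())


class TestCompositionTrend:
    def test_identical_fractions_give_p_one(self):
        assert composition_trend([0.1, 0.1, 0.1], [0.1, 0.1]) == pytest.approx(1.0)

    def test_extreme_two_vs_eleven_split(self):
        """The printed OPC decline p-value arises from this exact configuration."""
        infants = [0.9, 0.8]
        older = [0.5 - 0.01 * i for i in range(11)]
        p = composition_trend(infants, older)
        assert p == pytest.approx(2 / 78, rel=1e-9)  # 2/C(13,2) = 0.0256

    def test_label_swap_symmetry(self):
        a = [0.3, 0.6, 0.2]
        b = [0.5, 0.1, 0.4, 0.25]
        assert composition_trend(a, b) == pytest.approx(composition_trend(b, a))

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            composition_trend([], [0.1])


class TestLengthDecileFoldChange:
    def test_length_independent_fold_changes_flat(self):
        rng = np.random.default_rng(0)
        idx = [f"g{i:03d}" for i in range(200)]
        lfc = pd.Series(rng.normal(0, 0.2, 200), index=idx)
        lengths = pd.Series(rng.integers(200, 20_000, 200), index=idx)
        _, fit = length_decile_foldchange(lfc, lengths)
        assert fit.p_value > 0.01 or abs(fit.slope) < 0.02

    def test_planted_gradient_recovered(self, de_results, expression, toy_genome):
        _, truth = expression
        _, genes, _ = toy_genome
        hk = [g.gene_id for g in genes if g.gene_class == "housekeeping"]
        lengths = pd.Series({g.gene_id: g.length for g in genes})
        lfc = pd.Series({r.gene_id: r.log2_fc for r in de_results["ExN"]})
        common = [g for g in hk if g in lfc.index]
        summary, fit = length_decile_foldchange(lfc[common], lengths[common])
        planted_slope = -truth.planted_lfc["ExN"].min() / 9  # hk_decline_max over 9 steps
        assert fit.slope > 0
        assert abs(fit.slope - planted_slope) <= 0.15 * planted_slope

    def test_identical_fits_compare_to_null(self):
        z, p = compare_correlations(0.6, 100, 0.6, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_fewer_genes_than_deciles_rejected(self):
        lfc = pd.Series([0.1] * 5, index=list("abcde"))
        lengths = pd.Series([100] * 5, index=list("abcde"))
        with pytest.raises(DataError):
            length_decile_foldchange(lfc, lengths)
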