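import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.spatial.distance import jensenshannon

from otokit.matrix import ValidationError
from otokit.diffexpr import (
    bh_adjust,
    build_de_table,
    filter_testable_genes,
    js_divergence,
    lrt_group_test,
    organ_exclusive_genes,
    refine_marker_list,
    specificity_scores,
    split_by_marker_expression,
)
from otokit.preprocess import apply_lod_log2
from otokit.simulate import simulate_cell_types, CellTypeSpec
from otokit.matrix import ExpressionMatrix
from conftest import make_matrix


def two_group_series(n_a, n_b, prefix="c"):
    cells = [f"{prefix}{i}" for i in range(n_a + n_b)]
    return pd.Series(["A"] * n_a + ["B"] * n_b, index=cells)


class TestFilterTestableGenes:
    def test_rules_and_boundary(self):
        values = np.array([
            [0.0] * 6,                          # silent -> removed
            [9, 9, 9, 0, 0, 0],                 # 3 cells in A, 0 in B -> kept
            [9, 9, 0, 9, 9, 0],                 # exactly 2 per group -> removed
        ], dtype=float)
        m = make_matrix(values, units="nTPM")
        groups = two_group_series(3, 3)
        assert filter_testable_genes(m, groups) == ["g1"]
        assert filter_testable_genes(m, groups, require_all_groups=True) == []


class TestLrtGroupTest:
    def test_strong_effect_is_overwhelmingly_significant(self, rng):
        a = np.abs(rng.normal(10, 1, size=(5, 20)))
        b = np.abs(rng.normal(5, 1, size=(5, 20)))
        m = make_matrix(np.hstack([a, b]), units="log2nTPM")
        table = lrt_group_test(m, two_group_series(20, 20), noise_sd=0.01, seed=0)
        assert (table["q_value"] < 1e-6).all()

    def test_single_group_rejected(self, random_log2):
        groups = pd.Series("A", index=random_log2.cell_ids)
        with pytest.raises(ValidationError):
            lrt_group_test(random_log2, groups)

    def test_ordering_matches_anova_oracle(self, rng):
        values = np.abs(rng.normal(5, 1, size=(500, 40)))
        m = make_matrix(values, units="log2nTPM")
        table = lrt_group_test(m, two_group_series(20, 20), noise_sd=0.0, seed=0)
        anova = np.array([
            stats.f_oneway(values[i, :20], values[i, 20:]).pvalue for i in range(500)
        ])
        rho = stats.spearmanr(table["p_value"], anova).statistic
        assert rho >= 0.999

    def test_zero_variance_gene_guarded(self):
        values = np.vstack([np.ones(8) * 4.0, np.r_[np.zeros(4), np.ones(4) * 9]])
        m = make_matrix(values, units="log2nTPM")
        table = lrt_group_test(m, two_group_series(4, 4), noise_sd=0.0, seed=0)
        assert np.isfinite(table["p_value"]).all()


class TestBhAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.005, 0.04], [0.01, 0.04]),
    ])
    def test_hand_cases(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    @staticmethod
    def brute_force_bh(p):
        """Literal step-up definition: q_i = min over j with p_j >= p_i of
        min(1, m * p_j / rank_j)."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        raw = [min(1.0, p[order[j]] * m / (j + 1)) for j in range(m)]
        for j in range(m):
            q[order[j]] = min(raw[j:])
        return q

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_adjust(p), self.brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=1000)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSpecificity:
    def test_perfect_marker_scores_one(self):
        values = np.array([[8.0, 8.0, 0, 0, 0, 0]])
        m = make_matrix(values, units="nTPM")
        groups = pd.Series(["A", "A", "B", "B", "C", "C"],
                           index=m.cell_ids)
        scores = specificity_scores(m, groups)
        assert scores.loc["g0", "A"] == pytest.approx(1.0)
        assert scores.loc["g0", "B"] == pytest.approx(scores.loc["g0", "C"])

    def test_uniform_two_group_closed_form(self):
        values = np.array([[4.0, 4.0, 4.0, 4.0]])
        m = make_matrix(values, units="nTPM")
        scores = specificity_scores(m, two_group_series(2, 2))
        assert scores.loc["g0", "A"] == pytest.approx(0.442076, abs=1e-6)

    def test_disjoint_support_scores_zero(self):
        values = np.array([[0.0, 0.0, 8.0, 8.0]])
        m = make_matrix(values, units="nTPM")
        scores = specificity_scores(m, two_group_series(2, 2))
        assert scores.loc["g0", "A"] == pytest.approx(0.0)
        assert scores.loc["g0", "B"] == pytest.approx(1.0)

    def test_divergence_matches_scipy(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            assert np.sqrt(js_divergence(p, q)) == pytest.approx(
                jensenshannon(p, q, base=2), abs=1e-12
            )

    def test_permutation_equivariance_and_bounds(self, rng):
        values = np.abs(rng.lognormal(2, 1, size=(50, 9)))
        m = make_matrix(values, units="nTPM")
        groups = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=m.cell_ids)
        scores = specificity_scores(m, groups)
        assert ((scores >= 0) & (scores <= 1)).all().all()
        # relabel groups: scores follow the labels
        swapped = groups.map({"A": "B", "B": "A", "C": "C"})
        scores2 = specificity_scores(m, swapped)
        assert np.allclose(scores["A"], scores2["B"])
        assert np.allclose(scores["C"], scores2["C"])


class TestMarkerRefinement:
    def test_empty_table_gives_empty_lists(self):
        de = pd.DataFrame(columns=["q_value", "spec_A", "spec_B", "detfrac_A", "detfrac_B"])
        assert refine_marker_list(de) == {"A": [], "B": []}

    def test_threshold_boundary_excludes(self):
        de = pd.DataFrame({
            "q_value": [0.04], "spec_A": [0.45], "spec_B": [0.1],
            "detfrac_A": [1.0], "detfrac_B": [0.0],
        }, index=["g0"])
        assert refine_marker_list(de, specificity_threshold=0.5) == {"A": [], "B": []}

    def test_planted_markers_recovered_exactly(self):
        specs = [CellTypeSpec(n, n_cells=20, n_marker_genes=5, log2_sd=0.0,
                              baseline_log2_mean=0.0, marker_log2_mean=8.0,
                              dropout_midpoint=-100.0)
                 for n in ("A", "B", "C")]
        matrix, ann = simulate_cell_types(specs, n_background_genes=50, seed=0)
        ntpm = ExpressionMatrix(matrix.values, "nTPM")  # noiseless; already comparable
        log2 = apply_lod_log2(ntpm)
        de = build_de_table(ntpm, log2, ann["truth_label"], noise_sd=0.01, seed=1)
        markers = refine_marker_list(de, specificity_threshold=0.5)
        for name in ("A", "B", "C"):
            assert sorted(markers[name]) == sorted(
                g for g in matrix.gene_ids if g.startswith(f"marker_{name}_")
            )


class TestMarkerSplit:
    def test_split_assignments(self):
        values = np.array([[12.0, 5.0, 0.0, 11.0]])
        m = make_matrix(values, units="log2nTPM")
        labels = split_by_marker_expression(m, "g0")
        assert labels.to_dict() == {"c0": "positive", "c3": "positive", "c2": "negative"}
        assert "c1" not in labels.index  # intermediate cells excluded

    def test_empty_group_rejected(self):
        m = make_matrix(np.array([[5.0, 5.0]]), units="log2nTPM")
        with pytest.raises(ValidationError):
            split_by_marker_expression(m, "g0")


class TestOrganExclusive:
    def test_six_gene_fixture_partitions_exactly(self):
        n_a, n_b = 12, 12
        rows = {
            "a_specific": np.r_[np.full(11, 6.0), 0.0, np.zeros(n_b)],
            "a_boundary": np.r_[np.full(10, 6.0), [0.0, 0.0], np.zeros(n_b)],
            "b_specific": np.r_[np.zeros(n_a), np.full(11, 6.0), 0.0],
            "shared": np.r_[np.full(n_a, 6.0), np.full(n_b, 6.2)],
            "leaky": np.r_[np.full(11, 6.0), 0.0, np.r_[2.0, np.zeros(n_b - 1)]],
            "nonsig": np.r_[np.full(n_a, 6.0), np.full(n_b - 1, 6.0), 0.0],
        }
        values = np.vstack(list(rows.values()))
        genes = list(rows)
        cells = [f"c{i}" for i in range(n_a + n_b)]
        df = pd.DataFrame(values, index=genes, columns=cells)
        mat_a = ExpressionMatrix(df.iloc[:, :n_a], "log2nTPM")
        mat_b = ExpressionMatrix(df.iloc[:, n_a:], "log2nTPM")
        de = pd.DataFrame({
            "q_value": [1e-6, 1e-6, 1e-6, 0.5, 1e-6, 0.5],
            "spec_A": [1.0, 1.0, 0.0, 0.45, 0.8, 0.5],
            "spec_B": [0.0, 0.0, 1.0, 0.55, 0.2, 0.5],
        }, index=genes)
        a_spec, b_spec, shared = organ_exclusive_genes(
            mat_a, mat_b, de, min_cells=10, organ_a="A", organ_b="B"
        )
        assert a_spec == ["a_specific"]      # strict >10 excludes the boundary gene
        assert b_spec == ["b_specific"]
        assert shared == ["shared"]

    def test_gene_universe_mismatch_rejected(self):
        mat_a = make_matrix(np.ones((2, 3)), units="log2nTPM")
        mat_b = ExpressionMatrix(
            pd.DataFrame(np.ones((2, 3)), index=["g0", "gX"],
                         columns=["d0", "d1", "d2"]), "log2nTPM")
        with pytest.raises(ValidationError, match="differ"):
            organ_exclusive_genes(mat_a, mat_b, pd.DataFrame())
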