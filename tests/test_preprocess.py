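import numpy as np
import pandas as pd
import pytest

from otokit.matrix import ExpressionMatrix, UnitsError, ValidationError
from otokit.preprocess import (
    UNDETERMINABLE,
    NoReferenceGenesError,
    apply_lod_log2,
    correct_batch_effects,
    estimate_lod_from_spikeins,
    expected_unique_genes,
    identify_outlier_cells,
    median_ratio_normalize,
    saturation_read_cutoff,
)
from otokit.simulate import SpikeInSeries, simulate_spikeins
from conftest import make_matrix


class TestMedianRatioNormalize:
    def test_hand_oracle(self, small_tpm):
        """Geometric means 4 and 8 (third gene excluded); factors 0.5, 2."""
        result = median_ratio_normalize(small_tpm)
        assert np.allclose(result.size_factor.to_numpy(), [0.5, 2.0])
        assert result.n_genes_used == 2
        expected = np.array([[4.0, 4.0], [8.0, 8.0], [0.0, 0.5]])
        assert np.allclose(result.matrix.to_numpy(), expected)
        assert result.matrix.units == "nTPM"

    def test_identical_cells_unchanged(self, rng):
        col = rng.lognormal(2, 1, size=50)
        m = make_matrix(np.column_stack([col, col]), units="TPM")
        result = median_ratio_normalize(m)
        assert np.allclose(result.size_factor.to_numpy(), 1.0)
        assert np.allclose(result.matrix.to_numpy(), m.to_numpy())

    def test_single_cell_gets_factor_one(self, rng):
        m = make_matrix(rng.lognormal(2, 1, size=(30, 1)), units="TPM")
        assert median_ratio_normalize(m).size_factor.iloc[0] == pytest.approx(1.0)

    def test_no_reference_genes_error(self):
        m = make_matrix([[0.0, 1.0], [1.0, 0.0]], units="TPM")
        with pytest.raises(NoReferenceGenesError):
            median_ratio_normalize(m)

    def test_idempotent_on_normalized_output(self, rng):
        m = make_matrix(rng.lognormal(2, 1, size=(300, 25)), units="TPM")
        once = median_ratio_normalize(m)
        twice = median_ratio_normalize(ExpressionMatrix(once.matrix.values, "TPM"))
        assert np.abs(twice.size_factor.to_numpy() - 1.0).max() < 1e-9


class TestApplyLodLog2:
    @pytest.mark.parametrize("value,expected", [(0.9, 0.0), (1.0, 0.0), (8.0, 3.0)])
    def test_mapping(self, value, expected):
        m = make_matrix([[value]], units="nTPM")
        assert apply_lod_log2(m).to_numpy()[0, 0] == pytest.approx(expected)

    def test_monotone_and_maps_sub_lod_to_zero(self, rng):
        values = rng.lognormal(0, 2, size=(100, 5))
        m = make_matrix(values, units="nTPM")
        out = apply_lod_log2(m).to_numpy()
        assert (out[values < 1.0] == 0).all()
        order = np.argsort(values.ravel())
        assert (np.diff(out.ravel()[order]) >= 0).all()

    def test_requires_ntpm_units(self):
        with pytest.raises(UnitsError):
            apply_lod_log2(make_matrix([[1.0]], units="TPM"))


class TestSpikeinLod:
    def test_all_detected_returns_smallest_mean(self):
        measured = pd.DataFrame(np.arange(1, 93, dtype=float)[:, None] * [1.0, 1.0])
        series = SpikeInSeries([f"s{i}" for i in range(92)],
                               np.geomspace(1, 1e6, 92), measured)
        assert estimate_lod_from_spikeins(series) == pytest.approx(1.0)

    def test_none_detected_is_undeterminable(self):
        series = SpikeInSeries([f"s{i}" for i in range(92)],
                               np.geomspace(1, 1e6, 92),
                               pd.DataFrame(np.zeros((92, 3))))
        assert estimate_lod_from_spikeins(series) == UNDETERMINABLE

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_planted_threshold_within_factor_two(self, seed):
        series = simulate_spikeins(30, 0.1, seed=seed)
        lod = estimate_lod_from_spikeins(series)
        assert 0.5 <= lod <= 2.0


class TestSaturation:
    def test_single_gene_cutoff_is_one_read(self):
        assert saturation_read_cutoff([100], fraction=0.9).cutoff_depth == 1

    def test_full_depth_detects_everything(self):
        curve = saturation_read_cutoff([1, 1, 1, 1], fraction=0.9,
                                       depth_grid=range(1, 5))
        assert curve.expected_unique_genes[-1] == pytest.approx(4.0)
        assert curve.cutoff_depth <= 4

    def test_curve_is_non_decreasing(self, rng):
        counts = rng.poisson(2, 200)
        curve = saturation_read_cutoff(counts)
        assert (np.diff(curve.expected_unique_genes) >= -1e-9).all()

    def test_analytic_expectation_matches_monte_carlo(self, rng):
        counts = rng.poisson(3, 1000)
        depth = int(counts.sum() * 0.3)
        mc = np.mean([
            (rng.multivariate_hypergeometric(counts, depth) > 0).sum()
            for _ in range(1000)
        ])
        analytic = expected_unique_genes(counts, depth)
        assert abs(analytic - mc) / mc < 0.01

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            saturation_read_cutoff([0, 0, 0])


class TestOutlierCells:
    def test_identical_cells_no_outliers(self, rng):
        col = rng.lognormal(2, 1, size=200)
        m = make_matrix(np.tile(col[:, None], (1, 20)), units="nTPM")
        assert identify_outlier_cells(m).outlier_cell_ids == []

    def test_flags_exactly_the_scaled_cell(self, rng):
        values = rng.lognormal(2, 1, size=(500, 51))
        values[:, 50] *= 0.01
        m = make_matrix(values, units="nTPM")
        assert identify_outlier_cells(m).outlier_cell_ids == ["c50"]

    def test_no_trimming_when_criterion_already_met(self, rng):
        values = np.maximum(rng.lognormal(3, 0.5, size=(100, 10)), 2.0)  # all detected
        m = make_matrix(values, units="nTPM")
        report = identify_outlier_cells(m)
        assert len(report.retained_gene_ids) == 100

    def test_invariant_to_cell_and_gene_order(self, rng):
        values = rng.lognormal(2, 1, size=(120, 30))
        values[:, 7] *= 0.01
        m = make_matrix(values, units="nTPM")
        flagged = set(identify_outlier_cells(m).outlier_cell_ids)

        gene_perm = rng.permutation(120)
        cell_perm = rng.permutation(30)
        shuffled = ExpressionMatrix(
            m.values.iloc[gene_perm, cell_perm], "nTPM"
        )
        assert set(identify_outlier_cells(shuffled).outlier_cell_ids) == flagged

    def test_exhausted_trimming_raises(self):
        m = make_matrix(np.full((5, 4), 0.5), units="nTPM")  # nothing detectable
        with pytest.raises(ValidationError, match="detection criterion"):
            identify_outlier_cells(m)


class TestBatchCorrection:
    def test_single_batch_identity(self, random_log2):
        batches = pd.Series("b1", index=random_log2.cell_ids)
        out = correct_batch_effects(random_log2, batches)
        assert np.allclose(out.to_numpy(), random_log2.to_numpy())

    def test_removes_planted_shift_and_preserves_grand_mean(self, rng):
        base = np.abs(rng.normal(8, 1, size=(100, 40)))
        shifted = base.copy()
        shifted[:, 20:] += 2.0
        m = make_matrix(shifted, units="log2nTPM")
        batches = pd.Series(["b1"] * 20 + ["b2"] * 20, index=m.cell_ids)
        out = correct_batch_effects(m, batches).to_numpy()
        gap = out[:, 20:].mean(axis=1) - out[:, :20].mean(axis=1)
        assert np.abs(gap).max() < 1e-9
        assert np.abs(out.mean(axis=1) - shifted.mean(axis=1)).max() < 1e-9

    def test_batch_free_data_nearly_unchanged(self, rng):
        base = np.abs(rng.normal(8, 1, size=(60, 30)))
        m = make_matrix(base, units="log2nTPM")
        batches = pd.Series(["b1"] * 15 + ["b2"] * 15, index=m.cell_ids)
        out = correct_batch_effects(m, batches).to_numpy()
        # adjustment bounded by the per-gene sampling noise of batch means/sds
        assert np.abs(out - base).max() < 2.0
        assert np.corrcoef(out.ravel(), base.ravel())[0, 1] > 0.95

    def test_singleton_batch_warns_and_adjusts_location_only(self, rng):
        base = np.abs(rng.normal(8, 1, size=(50, 5)))
        m = make_matrix(base, units="log2nTPM")
        batches = pd.Series(["b1"] * 4 + ["solo"], index=m.cell_ids)
        with pytest.warns(UserWarning, match="single cell"):
            out = correct_batch_effects(m, batches)
        means = out.to_numpy().mean(axis=1)
        assert np.abs(means - base.mean(axis=1)).max() < 1e-9
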