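"""Pre-processing operators: truncation, baselines, normalisation, pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plasmavib as pv
from plasmavib.preprocess import (
    PreprocessParams,
    band_integral,
    preprocess_modality,
    truncate_grid,
)
from plasmavib.spectral_io import IntegrityError

from _oracles import asls_dense, rubberband_brute


def _spec(grid, y, modality="ATR-FTIR", hydration="wet"):
    return pv.Spectrum(grid, y, modality, hydration, "P1")


class TestTruncate:
    def test_bio_fingerprint_window_point_count(self):
        grid = np.arange(800.0, 2001.0, 2.0)
        s = truncate_grid(grid, 900.0, 1800.0)
        assert s.sum() == 451
        assert grid[s][0] == 900.0 and grid[s][-1] == 1800.0

    def test_identity_when_already_inside(self):
        grid = np.arange(1000.0, 1501.0, 2.0)
        s = _spec(grid, np.ones_like(grid))
        out = pv.truncate(s, (900.0, 1800.0))
        assert np.array_equal(out.grid, grid)
        assert np.array_equal(out.intensities, s.intensities)

    def test_disjoint_range_rejected(self):
        grid = np.arange(800.0, 2001.0, 2.0)
        with pytest.raises(ValueError):
            truncate_grid(grid, 100.0, 200.0)


class TestAtmosphericCorrection:
    grid = np.arange(900.0, 1801.0, 2.0)

    def _refs(self):
        vapor = np.sin(self.grid / 7.0) ** 2
        co2 = np.exp(-0.5 * ((self.grid - 1550) / 15) ** 2)
        return (
            _spec(self.grid, vapor),
            _spec(self.grid, co2),
        )

    def test_known_mixture_recovered(self):
        vapor, co2 = self._refs()
        clean = np.exp(-0.5 * ((self.grid - 1650) / 40) ** 2)
        contaminated = clean + 0.3 * vapor.intensities
        out = pv.atmospheric_correction(_spec(self.grid, contaminated), vapor, co2)
        rms = np.sqrt(np.mean((out.intensities - clean) ** 2))
        assert rms < 1e-6

    def test_zero_contamination_is_identity(self):
        # a spectrum whose first differences are orthogonal to both
        # references has truly-zero optimal coefficients
        vapor, co2 = self._refs()
        clean = np.exp(-0.5 * ((self.grid - 1650) / 40) ** 2)
        A = np.column_stack([np.diff(vapor.intensities), np.diff(co2.intensities)])
        d = np.diff(clean)
        d -= A @ np.linalg.lstsq(A, d, rcond=None)[0]
        clean = np.concatenate([[clean[0]], clean[0] + np.cumsum(d)])
        out = pv.atmospheric_correction(_spec(self.grid, clean), vapor, co2)
        assert np.allclose(out.intensities, clean, atol=1e-9)

    def test_anticorrelated_coefficient_clipped_to_zero(self):
        vapor, co2 = self._refs()
        # artefact anti-correlated with the references: coefficients clip to 0
        y = 1.0 - 0.3 * vapor.intensities
        out = pv.atmospheric_correction(_spec(self.grid, y), vapor, co2)
        assert np.allclose(out.intensities, y, atol=1e-12)

    def test_all_zero_reference_rejected(self):
        vapor, _ = self._refs()
        zero = _spec(self.grid, np.zeros_like(self.grid) )
        with pytest.raises(ValueError, match="zero"):
            pv.atmospheric_correction(vapor, zero, vapor)


class TestAslsBaseline:
    def test_constant_input_returns_itself(self):
        y = np.full(100, 3.7)
        z, corrected = pv.asls_baseline(y)
        assert np.allclose(z, 3.7, atol=1e-8)
        assert np.allclose(corrected, 0.0, atol=1e-8)

    def test_straight_line_fully_removed(self):
        y = np.linspace(0.0, 5.0, 150)
        _, corrected = pv.asls_baseline(y)
        assert np.max(np.abs(corrected)) < 1e-6

    def test_gaussian_peak_matches_dense_oracle(self):
        x = np.arange(200.0)
        y = 1.0 + np.exp(-0.5 * ((x - 100) / 3.0) ** 2)
        z, _ = pv.asls_baseline(y, 1000.0, 0.05, 10)
        assert np.max(np.abs(z - asls_dense(y))) <= 1e-8

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.integers(50, 500))
    def test_banded_solver_equals_dense_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 1, n)
        y = (
            rng.normal(0, 0.05, n)
            + rng.uniform(0.5, 2) * np.exp(-0.5 * ((x - rng.uniform(0, 1)) / 0.05) ** 2)
            + rng.uniform(-1, 1) * x
            + rng.uniform(0, 1)
        )
        z, _ = pv.asls_baseline(y)
        assert np.max(np.abs(z - asls_dense(y))) <= 1e-8

    def test_peak_shape_preserved(self):
        # narrow planted Gaussian on a linear baseline: apex survives AsLS
        x = np.arange(900.0, 1801.0, 2.0)
        peak = np.exp(-0.5 * ((x - 1450) / 4.0) ** 2)
        y = 0.5 + 0.0005 * (x - 900) + peak
        _, corrected = pv.asls_baseline(y, 1000.0, 0.05, 10)
        apex = x[np.argmax(corrected)]
        assert abs(apex - 1450.0) <= 2.0
        assert abs(corrected.max() - 1.0) <= 0.05

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pv.asls_baseline(np.array([1.0, np.nan, 2.0]))


class TestRubberband:
    def test_convex_curve_is_its_own_hull(self):
        grid = np.linspace(1000, 1800, 120)
        y = (grid - grid.mean()) ** 2
        _, corrected = pv.rubberband_baseline(y, grid)
        assert np.allclose(corrected, 0.0, atol=1e-9)

    def test_linear_input_removed(self):
        grid = np.linspace(1000, 1800, 120)
        y = 0.01 * grid + 3
        _, corrected = pv.rubberband_baseline(y, grid)
        assert np.allclose(corrected, 0.0, atol=1e-9)

    def test_single_peak_baseline_is_endpoint_segment(self):
        grid = np.linspace(0.0, 100.0, 101)
        y = np.exp(-0.5 * ((grid - 50) / 5.0) ** 2)
        baseline, corrected = pv.rubberband_baseline(y, grid)
        seg = np.interp(grid, [grid[0], grid[-1]], [y[0], y[-1]])
        assert np.allclose(baseline, seg, atol=1e-12)
        assert corrected[0] == 0.0 and corrected[-1] == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(10, 200))
    def test_matches_brute_force_hull_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        grid = np.sort(rng.uniform(0, 100, n))
        grid += np.arange(n) * 1e-9  # enforce strict ascent
        y = rng.normal(0, 1, n) + 0.1 * grid
        baseline, corrected = pv.rubberband_baseline(y, grid)
        assert np.array_equal(baseline, rubberband_brute(y, grid))
        assert corrected.min() >= -1e-12


class TestNormalisation:
    def test_vector_normalize_three_four_five(self):
        assert np.allclose(pv.vector_normalize(np.array([3.0, 4.0])), [0.6, 0.8])

    def test_vector_normalize_idempotent_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0.1, 2.0, 64)
        once = pv.vector_normalize(y)
        assert np.allclose(pv.vector_normalize(once), once, atol=1e-12)
        assert np.allclose(pv.vector_normalize(7 * y), once, atol=1e-12)
        assert abs(np.linalg.norm(once) - 1.0) < 1e-12

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            pv.vector_normalize(np.zeros(5))

    def test_band_area_normalize_halves_double_integral(self):
        grid = np.arange(1300.0, 1551.0, 2.0)
        y = np.full_like(grid, 2.0 / (1490.1 - 1378.1))  # band integral 2.0
        s = _spec(grid, y, modality="Raman")
        out = pv.band_area_normalize(s, (1378.1, 1490.1), target=1.0)
        assert np.allclose(out.intensities, y / 2.0)

    def test_band_area_normalize_scale_invariant_and_exact(self):
        rng = np.random.default_rng(1)
        grid = np.arange(1300.0, 1551.0, 2.0)
        y = rng.uniform(0.5, 1.5, grid.size)
        s1 = pv.band_area_normalize(_spec(grid, y, modality="Raman"), (1378.1, 1490.1))
        s2 = pv.band_area_normalize(_spec(grid, 2 * y, modality="Raman"), (1378.1, 1490.1))
        assert np.allclose(s1.intensities, s2.intensities, atol=1e-12)
        integral = band_integral(grid, s1.intensities, 1378.1, 1490.1)
        assert abs(integral - 1.0) <= 1e-10

    def test_non_positive_band_integral_rejected(self):
        grid = np.arange(1300.0, 1551.0, 2.0)
        with pytest.raises(ValueError, match="integral"):
            pv.band_area_normalize(
                _spec(grid, np.full_like(grid, -1.0), modality="Raman"),
                (1378.1, 1490.1),
            )


class TestResample:
    def test_identity_on_same_grid(self):
        grid = np.linspace(0, 10, 50)
        s = _spec(grid, np.sin(grid))
        out = pv.resample_to_grid(s, grid)
        assert np.array_equal(out.intensities, s.intensities)

    def test_linear_function_exact_on_denser_grid(self):
        grid = np.linspace(0, 10, 11)
        s = _spec(grid, 2 * grid + 1)
        dense = np.linspace(0, 10, 101)
        out = pv.resample_to_grid(s, dense)
        assert np.allclose(out.intensities, 2 * dense + 1, atol=1e-12)

    def test_gaussian_interp_error_bound(self):
        # |interp error| <= (h^2 / 8) * max|f''| for linear interpolation
        grid = np.arange(-10.0, 10.1, 0.5)
        sd = 2.0
        s = _spec(grid, np.exp(-0.5 * (grid / sd) ** 2))
        half = np.arange(-10.0, 10.01, 0.25)
        out = pv.resample_to_grid(s, half)
        err = np.max(np.abs(out.intensities - np.exp(-0.5 * (half / sd) ** 2)))
        assert err < 0.5**2 / 8 * (1 / sd**2)

    def test_extrapolation_rejected(self):
        grid = np.linspace(0, 10, 11)
        s = _spec(grid, grid)
        with pytest.raises(ValueError, match="extrapolation"):
            pv.resample_to_grid(s, np.linspace(-1, 5, 10))


class TestAverageReplicates:
    def test_mean_and_permutation_invariance(self, toy_dataset):
        ds = pv.SpectralDataset(
            grid=toy_dataset.grid,
            matrix=np.array([[1.0] * 5, [3.0] * 5]),
            samples=[
                pv.SampleRecord("P1", "cancer", "ATR-FTIR", "wet", 1),
                pv.SampleRecord("P1", "cancer", "ATR-FTIR", "wet", 2),
            ],
        )
        out = pv.average_replicates(ds)
        assert out.n_samples == 1
        assert np.allclose(out.matrix[0], 2.0)
        flipped = pv.average_replicates(ds.subset_rows([1, 0]))
        assert np.array_equal(out.matrix, flipped.matrix)

    def test_conflicting_labels_rejected(self, toy_dataset):
        ds = pv.SpectralDataset(
            grid=toy_dataset.grid,
            matrix=np.ones((2, 5)),
            samples=[
                pv.SampleRecord("P1", "cancer", "ATR-FTIR", "wet", 1),
                pv.SampleRecord("P1", "healthy", "ATR-FTIR", "wet", 2),
            ],
        )
        with pytest.raises(IntegrityError, match="conflicting"):
            pv.average_replicates(ds)


class TestPreprocessModality:
    def test_ftir_rows_unit_norm(self, small_config):
        raw = pv.synth_study(small_config)["ftir_wet"]
        out = preprocess_modality(raw, PreprocessParams(), "ATR-FTIR")
        norms = np.linalg.norm(out.matrix, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert out.grid[0] == 900.0 and out.grid[-1] == 1800.0

    def test_raman_rows_unit_band_integral(self, small_config):
        raw = pv.synth_study(small_config)["raman_wet"]
        params = PreprocessParams()
        out = preprocess_modality(raw, params, "Raman", purpose="single")
        for row in out.matrix:
            integral = band_integral(out.grid, row, *params.raman_band)
            assert abs(integral - params.raman_band_target) <= 1e-10

    def test_fused_purpose_gives_unit_norm_raman(self, small_config):
        raw = pv.synth_study(small_config)["raman_wet"]
        out = preprocess_modality(raw, PreprocessParams(), "Raman", purpose="fused")
        assert np.allclose(np.linalg.norm(out.matrix, axis=1), 1.0, atol=1e-9)

    def test_raman_pipeline_exactly_idempotent(self):
        # rubber-band correction leaves a non-negative spectrum whose lower
        # hull is the zero segment, so a second pass is the identity; the
        # band-area scaling is then 1
        cfg = pv.SyntheticConfig(
            n_cancer=2, n_pcos=2, n_healthy=2, seed=4, noise_sd=0.0,
            baseline_amplitude=0.0,
        )
        raw = pv.synth_study(cfg)["raman_wet"]
        once = preprocess_modality(raw, PreprocessParams(), "Raman")
        twice = preprocess_modality(once, PreprocessParams(), "Raman")
        assert np.max(np.abs(twice.matrix - once.matrix)) < 1e-10

    def test_ftir_second_pass_changes_bounded(self):
        # AsLS is not exactly idempotent: re-application erodes a small
        # further share of smooth band mass; bound the effect
        cfg = pv.SyntheticConfig(
            n_cancer=2, n_pcos=2, n_healthy=2, seed=4, noise_sd=0.0,
            baseline_amplitude=0.0, water_jitter_sd=0.0,
            water_band_amplitude=0.0,
        )
        raw = pv.synth_study(cfg)["ftir_wet"]
        once = preprocess_modality(raw, PreprocessParams(), "ATR-FTIR")
        twice = preprocess_modality(once, PreprocessParams(), "ATR-FTIR")
        assert np.max(np.abs(twice.matrix - once.matrix)) < 0.05

    def test_wrong_modality_rejected(self, small_config):
        raw = pv.synth_study(small_config)["raman_wet"]
        with pytest.raises(IntegrityError, match="modality"):
            preprocess_modality(raw, PreprocessParams(), "ATR-FTIR")
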