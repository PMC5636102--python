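"""The pre-treatment chain: domain arithmetic, SG oracle, QC, PCA screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirspec.io import Spectrum, SpectraSet, Stage, ValidationError
from mirspec.preprocess import (
    CoverageError,
    GridError,
    PreprocessConfig,
    analysis_grid,
    extract_analysis_domain,
    pca_outlier_screen,
    preprocess_set,
    preprocess_spectrum,
    quality_test,
    replace_co2_gap,
    restrict_to_work_domain,
    second_derivative,
    vector_normalize,
)
from mirspec.synthetic import CohortConfig, simulate_cohort, simulate_spectrum, work_grid

CFG = PreprocessConfig()


def wide_spectrum(fn, lo=400.0, hi=4000.0):
    grid = np.arange(lo, hi + 1, 2.0)
    return Spectrum("t", grid, fn(grid))


class TestDomainArithmetic:
    def test_restriction_gives_1126_points(self):
        s = restrict_to_work_domain(wide_spectrum(np.sin), CFG)
        assert len(s) == 1126
        assert s.wavenumbers[0] == 950 and s.wavenumbers[-1] == 3200

    def test_restriction_is_identity_on_exact_grid(self):
        s = wide_spectrum(np.cos, 950, 3200)
        r = restrict_to_work_domain(s, CFG)
        assert np.array_equal(r.absorbance, s.absorbance)

    def test_insufficient_coverage_rejected(self):
        with pytest.raises(CoverageError):
            restrict_to_work_domain(wide_spectrum(np.sin, 1000, 3000), CFG)

    def test_extraction_gives_615_variables(self):
        s = wide_spectrum(np.sin, 950, 3200)
        d = second_derivative(replace_co2_gap(s, CFG), CFG)
        assert len(d) == 1114
        assert d.wavenumbers[0] == 962 and d.wavenumbers[-1] == 3188
        a = extract_analysis_domain(d, CFG)
        assert len(a) == 615
        low = a.wavenumbers[a.wavenumbers <= 1800]
        high = a.wavenumbers[a.wavenumbers >= 2800]
        assert len(low) == 420 and len(high) == 195
        assert 1800.0 in a.wavenumbers and 2800.0 in a.wavenumbers

    def test_analysis_grid_helper_matches(self):
        s = wide_spectrum(np.sin, 950, 3200)
        a = extract_analysis_domain(second_derivative(replace_co2_gap(s, CFG), CFG), CFG)
        assert np.array_equal(analysis_grid(CFG), a.wavenumbers)


class TestCo2Gap:
    def test_spike_replaced_by_chord_midpoint(self):
        grid = np.arange(950.0, 3202.0, 2.0)
        y = np.full(grid.size, 0.0)
        y[grid == 1800] = 0.4
        y[grid == 2800] = 0.2
        y[grid == 2300] = 5.0
        s = replace_co2_gap(Spectrum("t", grid, y), CFG)
        assert s.absorbance[s.wavenumbers == 2300][0] == pytest.approx(0.3)
        # endpoints verbatim
        assert s.absorbance[s.wavenumbers == 1800][0] == 0.4
        assert s.absorbance[s.wavenumbers == 2800][0] == 0.2
        assert s.stage is Stage.GAP_REPLACED

    def test_constant_spectrum_unchanged(self):
        s = wide_spectrum(lambda g: np.full(g.size, 0.7), 950, 3200)
        assert np.allclose(replace_co2_gap(s, CFG).absorbance, 0.7)

    def test_idempotent(self):
        s = wide_spectrum(np.sin, 950, 3200)
        once = replace_co2_gap(s, CFG)
        twice = replace_co2_gap(once, CFG)
        assert np.array_equal(once.absorbance, twice.absorbance)

    def test_missing_endpoints_rejected(self):
        s = Spectrum("t", np.arange(951.0, 3203.0, 2.0), np.ones(1126))
        with pytest.raises(GridError):
            replace_co2_gap(s, CFG)


class TestSecondDerivative:
    def test_parabola_oracle(self):
        s = wide_spectrum(lambda g: g**2, 950, 3200)
        d = second_derivative(s, CFG)
        assert np.allclose(d.absorbance, 2.0, atol=1e-8)

    def test_line_maps_to_zero(self):
        d = second_derivative(wide_spectrum(lambda g: 3 * g + 7, 950, 3200), CFG)
        assert np.allclose(d.absorbance, 0.0, atol=1e-9)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValidationError):
            second_derivative(Spectrum("t", np.arange(5.0), np.ones(5)), CFG)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(-5, 5), st.floats(-5, 5))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        grid = np.arange(950.0, 1052.0, 2.0)
        f, g = rng.random(grid.size), rng.random(grid.size)
        df = second_derivative(Spectrum("f", grid, f), CFG).absorbance
        dg = second_derivative(Spectrum("g", grid, g), CFG).absorbance
        dfg = second_derivative(Spectrum("fg", grid, a * f + b * g), CFG).absorbance
        assert np.allclose(dfg, a * df + b * dg, atol=1e-10)


class TestVectorNormalize:
    def test_three_four_five(self):
        v = np.zeros(615)
        v[0], v[1] = 3.0, 4.0
        s = vector_normalize(Spectrum("t", analysis_grid(CFG), v))
        assert s.absorbance[0] == pytest.approx(0.6)
        assert s.absorbance[1] == pytest.approx(0.8)
        assert s.stage is Stage.NORMALIZED

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(0.01, 100.0))
    def test_scale_invariance(self, seed, c):
        v = np.random.default_rng(seed).standard_normal(20) + 0.1
        grid = np.arange(20.0) + 1
        a = vector_normalize(Spectrum("t", grid, v)).absorbance
        b = vector_normalize(Spectrum("t", grid, c * v)).absorbance
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            vector_normalize(Spectrum("t", np.arange(3.0) + 1, np.zeros(3)))


class TestFullChain:
    def test_any_conforming_spectrum_maps_to_unit_615_vector(self):
        cfg = CohortConfig(n=8, seed=3)
        spectra, _, _ = simulate_cohort(cfg)
        for s in spectra.spectra():
            out = preprocess_spectrum(s)
            assert len(out) == 615
            assert np.linalg.norm(out.absorbance) == pytest.approx(1.0)

    def test_set_and_spectrum_paths_agree(self, small_cohort):
        spectra, _, _ = small_cohort
        whole = preprocess_set(spectra)
        single = preprocess_spectrum(next(spectra.spectra()))
        assert np.allclose(whole.matrix[0], single.absorbance, atol=1e-12)


class TestQualityTest:
    def test_clean_synthetic_spectrum_passes(self):
        rng = np.random.default_rng([5, 1, 0])
        s = simulate_spectrum(0, CohortConfig(seed=5), rng)
        qc = quality_test(s, CFG)
        assert qc.passed and qc.reasons == []

    def test_scaled_spectrum_fails_signal_range(self):
        rng = np.random.default_rng([5, 1, 0])
        s = simulate_spectrum(0, CohortConfig(seed=5), rng)
        qc = quality_test(s.with_values(s.wavenumbers, s.absorbance * 100), CFG)
        assert not qc.passed and "signal_high" in qc.reasons

    def test_all_spectra_of_a_default_cohort_pass(self):
        spectra, _, _ = simulate_cohort(CohortConfig(n=116, seed=1))
        results = [quality_test(s, CFG) for s in spectra.spectra()]
        assert all(r.passed for r in results)


class TestPcaOutlierScreen:
    def test_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        n = 400
        ss = SpectraSet([f"s{i}" for i in range(n)], np.arange(60.0) + 1,
                        rng.standard_normal((n, 60)))
        frac = len(pca_outlier_screen(ss, CFG)) / n
        tol = 3 * np.sqrt(CFG.pca_alpha * (1 - CFG.pca_alpha) / n)
        assert frac <= CFG.pca_alpha + tol

    def test_displaced_sample_flagged(self):
        rng = np.random.default_rng(11)
        M = rng.standard_normal((200, 60))
        M[7] += 10 * np.linalg.svd(M, full_matrices=False)[2][0]
        ss = SpectraSet([f"s{i}" for i in range(200)], np.arange(60.0) + 1, M)
        assert "s7" in pca_outlier_screen(ss, CFG)

    def test_too_few_samples_rejected(self):
        ss = SpectraSet([f"s{i}" for i in range(5)], np.arange(20.0) + 1,
                        np.random.default_rng(0).standard_normal((5, 20)))
        with pytest.raises(ValidationError):
            pca_outlier_screen(ss, CFG)
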