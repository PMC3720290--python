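import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midakit import (
    AbundanceMatrix,
    ConditioningError,
    InputError,
    IsotopePair,
    MetaboliteRecord,
    ObservedSpectrum,
    ShapeError,
    build_abundance_matrix,
    clamp_negatives,
    correct_spectrum,
    forward_convolve,
    least_squares_solve,
    natural_abundance_distribution,
)
from .conftest import brute_force_convolve, forward_substitution

NA3 = natural_abundance_distribution(3, IsotopePair.from_heavy(0.0111))


class TestBuildAbundanceMatrix:
    def test_structure_4x2(self):
        a1, a2, a3 = 0.5, 0.3, 0.2
        m = build_abundance_matrix([a1, a2, a3], n_rows=4, n_cols=2)
        np.testing.assert_array_equal(
            m.entries, [[a1, 0], [a2, a1], [a3, a2], [0, a3]]
        )

    def test_unit_generator_gives_identity(self):
        m = build_abundance_matrix([1.0], n_rows=3, n_cols=3)
        np.testing.assert_array_equal(m.entries, np.eye(3))

    def test_natural_abundance_first_column(self):
        m = build_abundance_matrix(NA3.values, n_rows=7, n_cols=4)
        expected = [0.967068262369, 0.032564842893, 0.000365527107, 1.367631e-06,
                    0, 0, 0]
        np.testing.assert_allclose(m.entries[:, 0], expected, rtol=1e-10, atol=0)

    def test_toeplitz_placement_rule(self):
        g = np.array([4.0, 3.0, 2.0])
        m = build_abundance_matrix(g, n_rows=6, n_cols=4)
        for i in range(6):
            for j in range(4):
                expected = g[i - j] if 0 <= i - j < len(g) else 0.0
                assert m.entries[i, j] == expected

    def test_underdetermined_shape_rejected(self):
        with pytest.raises(ShapeError):
            build_abundance_matrix([1.0, 0.5], n_rows=2, n_cols=3)

    def test_empty_generator_rejected(self):
        with pytest.raises(InputError):
            build_abundance_matrix([], n_rows=2, n_cols=2)


class TestLeastSquaresSolve:
    def test_identity_system(self):
        A = build_abundance_matrix([1.0], n_rows=4, n_cols=4)
        fit = least_squares_solve(A, np.array([0.7, 0, 0, 0.3]))
        np.testing.assert_allclose(fit.raw, [0.7, 0, 0, 0.3], atol=1e-14)

    def test_noise_free_round_trip(self):
        truth = np.array([0.5, 0.1, 0.1, 0.3])
        observed = brute_force_convolve(truth, NA3.values)
        A = build_abundance_matrix(NA3.values, n_rows=7, n_cols=4)
        fit = least_squares_solve(A, observed)
        np.testing.assert_allclose(fit.raw, truth, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_forward_substitution(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0.1, 2.0, size=5)
        A = build_abundance_matrix(g, n_rows=5, n_cols=5)
        b = rng.uniform(0.0, 5.0, size=5)
        fit = least_squares_solve(A, b)
        oracle = forward_substitution(A.entries, b)
        np.testing.assert_allclose(fit.raw, oracle, rtol=1e-10)

    def test_rank_deficient_raises_with_condition(self):
        A = AbundanceMatrix(entries=np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]]),
                            generator=np.array([1.0]))
        with pytest.raises(ConditioningError) as excinfo:
            least_squares_solve(A, np.ones(3))
        assert excinfo.value.condition > 1e12

    def test_length_mismatch(self):
        A = build_abundance_matrix([1.0, 0.5], n_rows=4, n_cols=2)
        with pytest.raises(ShapeError):
            least_squares_solve(A, np.ones(3))

    def test_reconstruction_uses_clamped(self):
        A = build_abundance_matrix([1.0], n_rows=2, n_cols=2)
        fit = least_squares_solve(A, np.array([1.0, 0.0]))
        np.testing.assert_allclose(fit.reconstruction, A.entries @ fit.clamped)

    @pytest.mark.parametrize("seed", range(20))
    def test_residual_optimality(self, seed):
        # perturbing any coordinate never shrinks the residual
        rng = np.random.default_rng(100 + seed)
        A = build_abundance_matrix(rng.uniform(0.05, 1.0, size=4), n_rows=7, n_cols=4)
        P = rng.uniform(0.0, 1.0, size=7)
        fit = least_squares_solve(A, P)
        best = np.linalg.norm(A.entries @ fit.raw - P)
        for i in range(4):
            for delta in (1e-3, -1e-3):
                x = fit.raw.copy()
                x[i] += delta
                assert np.linalg.norm(A.entries @ x - P) >= best - 1e-12


class TestClampNegatives:
    def test_mixed_signs(self):
        np.testing.assert_array_equal(
            clamp_negatives(np.array([1.02, -0.003, -0.001, 0.44])),
            [1.02, 0.0, 0.0, 0.44],
        )

    def test_zero_vector(self):
        np.testing.assert_array_equal(clamp_negatives(np.array([0.0, 0.0])), [0.0, 0.0])

    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=20))
    def test_identity_on_non_negatives(self, values):
        vec = np.array(values)
        np.testing.assert_array_equal(clamp_negatives(vec), vec)


def _record_from_truth(truth, p1=0.0111, base_mz=300.0, scale=1.0):
    n = len(truth) - 1
    na = natural_abundance_distribution(n, IsotopePair.from_heavy(p1))
    intensities = scale * brute_force_convolve(truth, na.values)
    mz = tuple(base_mz + k + 0.1 for k in range(len(intensities)))
    return MetaboliteRecord(
        name="truth",
        mz_values=mz,
        intensities=tuple(intensities),
        n_carbons_metabolite=n,
        n_carbons_fragment=n,
    )


class TestCorrectSpectrum:
    def test_round_trip_recovers_distribution(self):
        truth = np.array([0.7000085, 0, 0, 0.2999915])
        fit = correct_spectrum(_record_from_truth(truth))
        np.testing.assert_allclose(fit.raw, truth, atol=1e-9)

    @pytest.mark.parametrize("n", [1, 2, 3, 6, 12])
    def test_round_trip_all_sizes(self, n):
        rng = np.random.default_rng(n)
        truth = rng.dirichlet(np.ones(n + 1))
        fit = correct_spectrum(_record_from_truth(truth))
        np.testing.assert_allclose(fit.raw, truth, atol=1e-9)

    def test_single_peak_no_heavy_isotope(self):
        record = MetaboliteRecord(
            name="pure", mz_values=(100.0,), intensities=(5.5,),
            n_carbons_metabolite=1, n_carbons_fragment=1,
        )
        # one observation vs two groups is underdetermined
        with pytest.raises(ShapeError):
            correct_spectrum(record, IsotopePair.from_heavy(0.0))
        record2 = MetaboliteRecord(
            name="pure", mz_values=(100.0, 101.0), intensities=(5.5, 0.0),
            n_carbons_metabolite=1, n_carbons_fragment=1,
        )
        fit = correct_spectrum(record2, IsotopePair.from_heavy(0.0))
        np.testing.assert_allclose(fit.raw, [5.5, 0.0], atol=1e-12)

    def test_all_zero_intensities_rejected(self):
        record = MetaboliteRecord(
            name="zero", mz_values=(100.0, 101.0), intensities=(0.0, 0.0),
            n_carbons_metabolite=1, n_carbons_fragment=1,
        )
        with pytest.raises(InputError):
            correct_spectrum(record)

    def test_scale_invariance_up_to_factor(self):
        truth = np.array([0.6, 0.1, 0.0, 0.3])
        fit1 = correct_spectrum(_record_from_truth(truth, scale=1.0))
        fit2 = correct_spectrum(_record_from_truth(truth, scale=137.5))
        np.testing.assert_allclose(fit2.raw, 137.5 * fit1.raw, rtol=1e-9, atol=1e-12)

    def test_extra_carbons_change_generator_only(self):
        # generate with 2 derivative carbons folded into the natural abundance
        truth = np.array([0.8, 0.0, 0.2])
        na5 = natural_abundance_distribution(5, IsotopePair.from_heavy(0.0111))
        intensities = brute_force_convolve(truth, na5.values)
        record = MetaboliteRecord(
            name="derivatized",
            mz_values=tuple(150.0 + k + 0.1 for k in range(len(intensities))),
            intensities=tuple(intensities),
            n_carbons_metabolite=2,
            n_carbons_fragment=2,
        )
        fit = correct_spectrum(record, extra_carbons=3)
        assert len(fit.raw) == 3
        np.testing.assert_allclose(fit.raw, truth, atol=1e-9)

    def test_two_stage_mode_runs(self):
        truth = np.array([0.7, 0, 0, 0.3])
        fit = correct_spectrum(_record_from_truth(truth), two_stage=True)
        assert fit.raw.shape == (4,)
        assert np.all(np.isfinite(fit.raw))

    def test_m0_override_shifts_window(self):
        truth = np.array([0.7, 0, 0, 0.3])
        record = _record_from_truth(truth, base_mz=300.0)
        # treating the first peak as M-1 drops it from the fit
        fit = correct_spectrum(record, m0=301)
        assert len(fit.observed) == len(record.intensities) - 1


class TestParameterRecovery:
    def test_mean_absolute_error_under_noise(self):
        from midakit import SyntheticSpec, recovery_experiment

        spec = SyntheticSpec(
            true_fractions=(0.7, 0.0, 0.0, 0.3), n_carbons=3,
            noise_sd=0.01, seed=42,
        )
        summary = recovery_experiment(spec, n_replicates=500)
        assert np.max(np.abs(summary.bias)) < 0.01


class TestObservedSpectrum:
    def test_mismatched_lengths(self):
        with pytest.raises(ShapeError):
            ObservedSpectrum(intensities=np.ones(3), offsets=np.arange(2))

    def test_non_increasing_offsets(self):
        with pytest.raises(InputError):
            ObservedSpectrum(intensities=np.ones(2), offsets=np.array([1, 1]))

    def test_negative_intensity(self):
        with pytest.raises(InputError):
            ObservedSpectrum(intensities=np.array([-1.0]), offsets=np.array([0]))
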