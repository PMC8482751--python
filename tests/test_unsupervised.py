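"""Descriptors, PCA, PAMM-style density clustering, FES, and rate matrices."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fiberex.surrogate import BULK, DEFECT, SurrogateRates, gillespie_stack
from fiberex.unsupervised import (
    DescriptorParams,
    PAMMParams,
    center_descriptors,
    fes_from_populations,
    pamm_cluster,
    pca_reduce,
    rate_matrix,
    stride_corrected_rates,
)


class TestDescriptors:
    def test_dimension_is_324_at_defaults(self):
        rng = np.random.default_rng(0)
        X = center_descriptors(rng.normal(size=(12, 3)) * 2.0)
        assert X.shape == (12, 324)
        assert DescriptorParams().dimension == 324

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(15, 3)) * 2.0
        R = Rotation.random(random_state=2).as_matrix()
        moved = c @ R.T + np.array([3.0, -1.0, 7.0])
        assert np.abs(
            center_descriptors(c) - center_descriptors(moved)
        ).max() < 1e-8

    def test_neighbor_permutation_invariance(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=(15, 3)) * 2.0
        perm = rng.permutation(15)
        a = center_descriptors(c)
        b = center_descriptors(c[perm])
        assert np.abs(a[perm] - b).max() < 1e-8

    def test_empty_environment_zero_vector(self):
        c = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0], [0.0, 100.0, 0.0]])
        X = center_descriptors(c, DescriptorParams(rcut=5.0))
        assert np.all(X == 0.0)
        assert np.array_equal(X[0], X[1])

    def test_minimum_system_size(self):
        with pytest.raises(ValueError):
            center_descriptors(np.zeros((1, 3)))


class TestPCA:
    def test_planar_data_two_components_suffice(self):
        rng = np.random.default_rng(4)
        basis = rng.normal(size=(2, 6))
        X = rng.normal(size=(300, 2)) @ basis
        _, evr, _ = pca_reduce(X, k=2)
        assert evr.sum() == pytest.approx(1.0)

    def test_isotropic_gaussian_flat_spectrum(self):
        rng = np.random.default_rng(5)
        d = 5
        X = rng.normal(size=(20000, d))
        _, evr, _ = pca_reduce(X, k=d)
        assert np.allclose(evr, 1.0 / d, atol=3 * np.sqrt(2.0 / 20000))

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        scores, _, model = pca_reduce(X, k=3)
        back = scores @ model.components_ + model.mean_
        assert np.abs(back - X).max() < 1e-10

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 4))
        s1, _, _ = pca_reduce(X, 2)
        s2, _, _ = pca_reduce(X.copy(), 2)
        assert np.array_equal(s1, s2)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca_reduce(np.ones((10, 4)), k=2)


class TestPAMM:
    def test_two_gaussians_two_macroclusters(self, bundle):
        X, y = bundle["two_gaussians"]
        model = pamm_cluster(X, PAMMParams(grid_size=1000), seed=2)
        assert model.n_macro == 2
        acc = max(
            (model.assignments == y).mean(), (model.assignments == 1 - y).mean()
        )
        assert acc >= 0.99

    def test_single_gaussian_one_macrocluster(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0.0, 0.1, size=(3000, 2))
        model = pamm_cluster(X, PAMMParams(grid_size=800), seed=3)
        assert model.n_macro == 1

    def test_merger_threshold_one_collapses_everything(self, bundle):
        X, _ = bundle["two_gaussians"]
        model = pamm_cluster(
            X[::4], PAMMParams(grid_size=400, merger_threshold=0.999), seed=2
        )
        assert model.n_macro == 1

    def test_populations_sum_to_one_and_assignment_total(self, bundle):
        X, _ = bundle["two_gaussians"]
        model = pamm_cluster(X, PAMMParams(grid_size=500), seed=4)
        assert model.populations.sum() == pytest.approx(1.0)
        assert model.assignments.shape == (X.shape[0],)

    def test_oversized_grid_rejected(self):
        with pytest.raises(ValueError):
            pamm_cluster(np.zeros((10, 2)), PAMMParams(grid_size=100), seed=0)

    def test_predict_matches_training_assignments(self, bundle):
        X, _ = bundle["two_gaussians"]
        model = pamm_cluster(X[::2], PAMMParams(grid_size=500), seed=5)
        assert np.array_equal(model.predict(X[::2]), model.assignments)


class TestFES:
    def test_equal_populations_flat_surface(self):
        f = fes_from_populations(np.array([0.25, 0.25, 0.25, 0.25]))
        assert np.allclose(f, 0.0)

    def test_boltzmann_ratio_one_kT(self):
        f = fes_from_populations(np.array([1.0, np.exp(-1.0)]))
        assert f[0] == 0.0
        assert f[1] == pytest.approx(1.0)

    def test_two_kcal_gap_at_room_temperature(self):
        # k_B T = 0.5962 kcal/mol at 300 K: a 2 kcal/mol defect state has
        # relative population exp(-2/0.5962) ~ 0.0349
        kT = 0.5962
        p = np.array([1.0, 0.0349])
        f = fes_from_populations(p / p.sum(), kT=kT)
        assert f[1] == pytest.approx(2.0, abs=0.01)

    def test_zero_population_excluded_as_inf(self):
        f = fes_from_populations(np.array([0.9, 0.1, 0.0]))
        assert np.isinf(f[2])

    def test_round_trip_through_sampling(self):
        # Boltzmann-sample states from known free energies, re-estimate
        rng = np.random.default_rng(9)
        kT = 1.0
        f_true = np.array([0.0, 1.2, 2.5])
        p = np.exp(-f_true / kT)
        p /= p.sum()
        draws = rng.choice(3, size=200_000, p=p)
        p_hat = np.bincount(draws) / draws.size
        f_hat = fes_from_populations(p_hat, kT=kT)
        se = kT * np.sqrt((1 - p) / (p * draws.size)) * 3
        assert np.all(np.abs(f_hat - f_true) < 3 * np.maximum(se, 0.01))


class TestRateMatrix:
    def test_constant_labels_zero_rates(self):
        lab = np.zeros((50, 4), dtype=int)
        rm = rate_matrix(lab, t_stride=0.1, states=[0, 1])
        assert rm.r_tr.sum() == 0.0

    def test_event_count_arithmetic(self):
        # 30 a->b switches in 10 time units -> 3 per unit time
        lab = np.array(([0] + [0, 1] * 30 + [0] * 39)[:100])
        rm = rate_matrix(lab, t_stride=0.1, states=[0, 1])
        assert rm.t_tot == pytest.approx(10.0)
        assert rm.n_events[0, 1] == 30
        assert rm.r_tr[0, 1] == pytest.approx(3.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rate_matrix(np.zeros((1, 4), dtype=int), t_stride=0.1)

    def test_ctmc_recovery_within_three_se(self):
        k_bd, k_db = 0.3, 14.0
        st = gillespie_stack(
            40, SurrogateRates(k_bulk_def=k_bd, k_def_bulk=k_db),
            t_end=500.0, seed=21, t_stride=0.01,
        )
        rm = rate_matrix(st.states[:, 1:-1], 0.01, states=[BULK, DEFECT])
        kab, se_ab, kba, se_ba = stride_corrected_rates(rm, BULK, DEFECT)
        assert abs(kab - k_bd) < 3 * se_ab
        assert abs(kba - k_db) < 3 * se_ba
        # annihilation/creation ratio of the recovered rates
        assert kba / kab == pytest.approx(k_db / k_bd, rel=0.1)

    def test_stride_coarsening_bias_grows_monotonically(self):
        k_bd, k_db = 1.0, 9.0
        st = gillespie_stack(
            40, SurrogateRates(k_bulk_def=k_bd, k_def_bulk=k_db),
            t_end=400.0, seed=22, t_stride=0.005,
        )
        naive = []
        for sub in (1, 10, 40):
            rm = rate_matrix(
                st.states[::sub, 1:-1], 0.005 * sub, states=[BULK, DEFECT]
            )
            k = rm.per_monomer_rates(corrected=False)
            naive.append(k[1, 0])  # annihilation, the faster (more biased) rate
        assert naive[0] > naive[1] > naive[2]
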