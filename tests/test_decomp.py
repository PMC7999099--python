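import numpy as np
import pytest

from ospca import (
    DataMatrix,
    SampleDesign,
    autoscale,
    autoscale_by_average,
    contribution_ratios,
    fit_ospca,
    fit_ospca_repeated,
    fit_pca,
    fit_smoothed_pca,
    make_averaging_matrix,
    make_difference_matrix,
)

from .conftest import one_group_design, random_autoscaled

SQ2 = np.sqrt(2.0)


def _match_sign(a, b):
    """Align per-column signs of a to b."""
    flips = np.sign(np.sum(a * b, axis=0))
    flips[flips == 0] = 1.0
    return a * flips


@pytest.fixture
def ordered_data(rng):
    """Autoscaled data with a smooth per-group trend plus noise."""
    from ospca import SimulationSpec, simulate_metabolome

    spec = SimulationSpec(
        seed=42, n_groups=3, timepoints=tuple(range(8)), n_metabolites=20,
        n_trend_metabolites=6, n_groupdiff_metabolites=0,
    )
    data, design, _ = simulate_metabolome(spec)
    return autoscale(data), design


class TestPCA:
    def test_rank_one_toy_by_hand(self):
        X = DataMatrix(
            np.array([[1.0, 1.0], [-1.0, -1.0]]), ("s0", "s1"), ("a", "b"), "centered"
        )
        m = fit_pca(X, 1)
        np.testing.assert_allclose(m.eigenvalues, [2.0])
        np.testing.assert_allclose(np.abs(m.weights_x[:, 0]), [1 / SQ2, 1 / SQ2])
        np.testing.assert_allclose(np.abs(m.scores_t[:, 0]), [SQ2, SQ2])
        np.testing.assert_allclose(m.contribution, [1.0])
        assert m.contribution_basis == "variance"

    def test_eigen_residual_and_contribution_sum(self, rng):
        X = random_autoscaled(rng, 12, 7)
        m = fit_pca(X, 7)
        C = X.values.T @ X.values / X.n
        for j in range(m.k):
            np.testing.assert_allclose(
                C @ m.weights_x[:, j], m.eigenvalues[j] * m.weights_x[:, j], atol=1e-10
            )
        assert m.contribution.sum() <= 1.0 + 1e-12
        full_total = np.sum(np.linalg.eigvalsh(C).clip(min=0))
        np.testing.assert_allclose(m.eigenvalues.sum() / full_total, m.contribution.sum())

    def test_k_truncated_to_rank(self, rng):
        # n=4 autoscaled -> rank at most 3
        X = random_autoscaled(rng, 4, 6)
        m = fit_pca(X, 6)
        assert m.k <= 3

    def test_requires_scaled_input(self, rng):
        raw = DataMatrix(rng.normal(size=(5, 3)), tuple("abcde"), ("x", "y", "z"))
        with pytest.raises(ValueError, match="expects data"):
            fit_pca(raw)


class TestSmoothedPCA:
    def test_kappa_zero_matches_pca(self, rng):
        X = random_autoscaled(rng, 10, 6)
        D = make_difference_matrix(one_group_design(10), 1)
        sp = fit_smoothed_pca(X, D, 0.0, 4)
        pc = fit_pca(X, 4)
        np.testing.assert_allclose(sp.eigenvalues, pc.eigenvalues, rtol=1e-10)
        np.testing.assert_allclose(
            _match_sign(sp.scores_t, pc.scores_t), pc.scores_t, atol=1e-8
        )

    def test_generalized_eigen_residual_and_constraint(self, rng):
        X = random_autoscaled(rng, 10, 6)
        D = make_difference_matrix(one_group_design(10), 2)
        m = fit_smoothed_pca(X, D, 0.5, 3)
        C = X.values.T @ X.values / X.n
        P = m.penalty.matrix
        for j in range(m.k):
            w = m.weights_x[:, j]
            np.testing.assert_allclose(
                C @ w, m.eigenvalues[j] * (P @ w), atol=1e-8
            )
            np.testing.assert_allclose(w @ P @ w, 1.0, atol=1e-10)

    def test_smoothing_reduces_score_roughness(self, ordered_data):
        X, design = ordered_data
        D = make_difference_matrix(design, 2)

        def roughness(kappa):
            m = fit_smoothed_pca(X, D, kappa, 1)
            t = m.scores_t[:, 0]
            t = t / np.linalg.norm(t)
            return (D.matrix @ t) @ (D.matrix @ t)

        assert roughness(0.1) <= roughness(0.0) + 1e-9


class TestOSPCA:
    def test_kappa_zero_weights_coincide(self, rng):
        X = random_autoscaled(rng, 9, 5)
        D = make_difference_matrix(one_group_design(9), 1)
        m = fit_ospca(X, D, 0.0, 4)
        pc = fit_pca(X, 4)
        np.testing.assert_allclose(m.weights_y, m.weights_x, atol=1e-9)
        np.testing.assert_allclose(2 * m.lambda_x, pc.eigenvalues, rtol=1e-10)

    @pytest.mark.parametrize("kappa", [0.0, 0.1, 0.999])
    def test_weight_orthonormality(self, rng, kappa):
        X = random_autoscaled(rng, 12, 8)
        D = make_difference_matrix(one_group_design(12), 2)
        m = fit_ospca(X, D, kappa, 5)
        gram = m.weights_x.T @ m.weights_x
        assert np.max(np.abs(gram - np.eye(m.k))) < 1e-10

    def test_auxiliary_constraint_and_positive_covariance(self, rng):
        X = random_autoscaled(rng, 12, 8)
        D = make_difference_matrix(one_group_design(12), 2)
        m = fit_ospca(X, D, 0.9, 4)
        P = m.penalty.matrix
        for j in range(m.k):
            np.testing.assert_allclose(m.weights_y[:, j] @ P @ m.weights_y[:, j], 1.0, atol=1e-10)
            cov = (m.scores_t[:, j] @ m.scores_s[:, j]) / X.n
            assert cov >= -1e-12

    def test_stationarity_relations(self, rng):
        X = random_autoscaled(rng, 10, 6)
        D = make_difference_matrix(one_group_design(10), 2)
        m = fit_ospca(X, D, 0.7, 4)
        G = X.values.T @ X.values
        P = m.penalty.matrix
        for j in range(m.k):
            wx, wy = m.weights_x[:, j], m.weights_y[:, j]
            lx, ly = m.lambda_x[j], m.lambda_y[j]
            np.testing.assert_allclose(G @ wy / X.n, 2 * lx * wx, atol=1e-8)
            np.testing.assert_allclose(G @ wx / X.n, 2 * ly * (P @ wy), atol=1e-8)
            np.testing.assert_allclose(4 * lx * ly, m.eigenvalues[j], rtol=1e-8)

    def test_covariance_contributions_reduce_to_variance_at_kappa_zero(self, rng):
        X = random_autoscaled(rng, 9, 5)
        D = make_difference_matrix(one_group_design(9), 1)
        m = fit_ospca(X, D, 0.0, 3)
        pc = fit_pca(X, 3)
        frac, basis = contribution_ratios(m)
        assert basis == "covariance"
        np.testing.assert_allclose(frac, contribution_ratios(pc)[0], rtol=1e-8)


class TestOSPCARepeated:
    def test_identity_averaging_reduces_to_ospca(self, rng):
        design = one_group_design(8)
        raw = DataMatrix(
            rng.normal(size=(8, 5)), tuple(design.sample_ids), tuple(f"m{j}" for j in range(5))
        )
        M = make_averaging_matrix(design)
        D = make_difference_matrix(design, 2)
        rep = fit_ospca_repeated(autoscale_by_average(raw, M), M, D, 0.5, 3)
        plain = fit_ospca(autoscale(raw), D, 0.5, 3)
        np.testing.assert_allclose(rep.scores_t, plain.scores_t, atol=1e-10)
        np.testing.assert_allclose(rep.scores_avg, plain.scores_s, atol=1e-10)
        np.testing.assert_allclose(rep.eigenvalues, plain.eigenvalues, rtol=1e-10)

    def test_auxiliary_constraint_under_q(self, rng):
        sizes = 3
        n = 6 * sizes
        ids = tuple(f"s{i}" for i in range(n))
        reps = tuple(f"r{i // sizes}" for i in range(n))
        orders = tuple(float(i // sizes) for i in range(n))
        design = SampleDesign(ids, ("G",) * n, orders, reps)
        raw = DataMatrix(rng.normal(size=(n, 7)), ids, tuple(f"m{j}" for j in range(7)))
        M = make_averaging_matrix(design)
        D = make_difference_matrix(design.collapsed(), 2)
        m = fit_ospca_repeated(autoscale_by_average(raw, M), M, D, 0.9, 3)
        for j in range(m.k):
            np.testing.assert_allclose(
                m.weights_y[:, j] @ m.penalty.matrix @ m.weights_y[:, j], 1.0, atol=1e-10
            )

    def test_replicate_duplication_matches_unduplicated_auxiliary_scores(self, rng):
        # duplicating every measurement into two identical replicates must
        # reproduce the unduplicated model's auxiliary scores as set means
        n, p = 9, 6
        base_design = one_group_design(n)
        raw = DataMatrix(rng.normal(size=(n, p)), tuple(base_design.sample_ids), tuple(f"m{j}" for j in range(p)))
        ids, groups, orders, reps = [], [], [], []
        for i in range(n):
            for suffix in ("a", "b"):
                ids.append(f"s{i}{suffix}")
                groups.append("A")
                orders.append(float(i))
                reps.append(f"s{i}")
        dup_design, perm = SampleDesign(tuple(ids), tuple(groups), tuple(orders), tuple(reps)).sorted()
        dup_raw = DataMatrix(
            np.repeat(raw.values, 2, axis=0), tuple(ids), raw.metabolite_names
        ).take_rows(perm)
        M = make_averaging_matrix(dup_design)
        D = make_difference_matrix(dup_design.collapsed(), 2)
        rep = fit_ospca_repeated(autoscale_by_average(dup_raw, M), M, D, 0.9, 3)
        plain = fit_ospca(autoscale(raw), make_difference_matrix(base_design, 2), 0.9, 3)
        aligned = _match_sign(rep.scores_avg, plain.scores_s)
        np.testing.assert_allclose(aligned, plain.scores_s, atol=1e-8)

    def test_requires_collapsed_difference_matrix(self, rng):
        design = SampleDesign(
            ("a", "b", "c", "d"), ("G",) * 4, (0.0, 0.0, 1.0, 1.0), ("r0", "r0", "r1", "r1")
        )
        raw = DataMatrix(rng.normal(size=(4, 3)), tuple(design.sample_ids), ("x", "y", "z"))
        M = make_averaging_matrix(design)
        D_full = make_difference_matrix(design, 1)  # built on measurements, wrong
        with pytest.raises(ValueError, match="collapsed"):
            fit_ospca_repeated(autoscale_by_average(raw, M), M, D_full, 0.5)
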