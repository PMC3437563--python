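"""Classical scaling: distances, eigen-structure, goodness of fit, loadings."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from vetelicit import (
    BeliefVector,
    axis_loadings,
    belief_vectors,
    classical_scale,
    distance_matrix,
    scale_vectors,
)


def make_vectors(X):
    X = np.clip(X, 0.0, 1.0)
    return [BeliefVector(str(i), tuple(row)) for i, row in enumerate(X)]


@pytest.fixture(scope="module")
def random_vectors():
    rng = np.random.default_rng(5)
    return make_vectors(rng.uniform(0.05, 0.95, size=(24, 10)))


class TestDistanceMatrix:
    def test_identical_vectors_zero_distance(self):
        v = BeliefVector("a", (0.5,) * 10)
        D = distance_matrix([v, BeliefVector("b", (0.5,) * 10)])
        assert D[0, 1] == 0.0

    def test_unit_hypercube_corners(self):
        D = distance_matrix(
            [BeliefVector("a", (0.0,) * 10), BeliefVector("b", (1.0,) * 10)]
        )
        assert D[0, 1] == pytest.approx(10.0)

    def test_matches_brute_force_double_loop(self, random_vectors):
        D = distance_matrix(random_vectors)
        X = np.array([v.values for v in random_vectors])
        for i in range(len(X)):
            for j in range(len(X)):
                want = float((X[i] - X[j]) @ (X[i] - X[j]))
                assert D[i, j] == pytest.approx(want, abs=1e-12)

    def test_symmetry_and_zero_diagonal(self, random_vectors):
        D = distance_matrix(random_vectors)
        np.testing.assert_allclose(D, D.T)
        assert np.all(np.diag(D) == 0)


class TestClassicalScale:
    def test_planar_configuration_recovered_exactly(self):
        """Points lying in a 2-D plane embedded in 10-D give gof(2) = 1."""
        rng = np.random.default_rng(0)
        plane = rng.normal(size=(2, 10)) * 0.1
        coords2 = rng.uniform(-1, 1, size=(15, 2))
        X = 0.5 + coords2 @ plane
        res = classical_scale(distance_matrix(make_vectors(X)))
        assert res.gof[1] == pytest.approx(1.0, abs=1e-10)

    def test_distances_reconstructed_for_low_rank(self):
        """Recovered coordinates reproduce the input squared distances when
        the configuration has rank <= 3."""
        rng = np.random.default_rng(1)
        basis, _ = np.linalg.qr(rng.normal(size=(10, 3)))
        X = 0.5 + rng.uniform(-0.5, 0.5, size=(20, 3)) @ basis.T * 0.4
        D = distance_matrix(make_vectors(X))
        res = classical_scale(D)
        C = res.coordinates[:, :3]
        sq = (C * C).sum(axis=1)
        D_hat = sq[:, None] + sq[None, :] - 2 * C @ C.T
        np.testing.assert_allclose(D_hat, D, atol=1e-8)

    def test_agrees_with_pca_oracle_up_to_rotation(self, random_vectors):
        """Squared-Euclidean classical scaling equals PCA scores of the
        centred data matrix up to an orthogonal transform."""
        res = classical_scale(distance_matrix(random_vectors))
        X = np.array([v.values for v in random_vectors])
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        scores = U * s
        r = res.rank
        R, _ = orthogonal_procrustes(res.coordinates, scores[:, :r])
        resid = np.linalg.norm(res.coordinates @ R - scores[:, :r])
        assert resid < 1e-8

    def test_gof_monotone_and_reaches_one(self, random_vectors):
        res = classical_scale(distance_matrix(random_vectors))
        assert np.all(np.diff(res.gof) >= -1e-12)
        assert res.gof[9] == pytest.approx(1.0, abs=1e-10)

    def test_translation_invariance(self, random_vectors):
        X = np.array([v.values for v in random_vectors])
        res1 = classical_scale(distance_matrix(random_vectors))
        res2 = classical_scale(distance_matrix(make_vectors(X * 0.5 + 0.05)))
        # scaling by c scales eigenvalues by c^2; translation does nothing
        np.testing.assert_allclose(res2.eigenvalues, 0.25 * res1.eigenvalues, atol=1e-10)

    def test_trace_identity(self, random_vectors):
        """Positive eigenvalues sum to the total centred variance."""
        res = classical_scale(distance_matrix(random_vectors))
        X = np.array([v.values for v in random_vectors])
        Xc = X - X.mean(axis=0)
        assert res.eigenvalues.sum() == pytest.approx((Xc**2).sum(), rel=1e-10)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            classical_scale(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestAxisLoadings:
    def test_theta3_only_variation_loads_on_theta3(self):
        """A cohort differing only in theta3 judgements puts axis-1 weight
        entirely on the five theta3 positions."""
        rng = np.random.default_rng(2)
        X = np.tile(np.linspace(0.3, 0.7, 10), (12, 1))
        X[:, 5:] += rng.uniform(-0.2, 0.2, size=(12, 5))
        res = scale_vectors(make_vectors(X))
        s = axis_loadings(res, 0)
        theta3_mass = s.filter(like="theta3").abs().sum()
        assert theta3_mass / s.abs().sum() > 0.999

    def test_theta1_only_variation_loads_on_theta1(self):
        rng = np.random.default_rng(3)
        X = np.tile(np.linspace(0.3, 0.7, 10), (12, 1))
        X[:, :5] += rng.uniform(-0.2, 0.2, size=(12, 5))
        res = scale_vectors(make_vectors(X))
        s = axis_loadings(res, 0)
        theta1_mass = s.filter(like="theta1").abs().sum()
        assert theta1_mass / s.abs().sum() > 0.999

    def test_constant_cohort_is_degenerate(self):
        vs = [BeliefVector(str(i), (0.4,) * 10) for i in range(5)]
        with pytest.raises(ValueError, match="degenerate"):
            classical_scale(distance_matrix(vs))

    def test_dimension_out_of_range(self, random_vectors):
        res = scale_vectors(random_vectors)
        with pytest.raises(IndexError):
            axis_loadings(res, res.rank)


class TestCohortScaling:
    def test_cohort_axis_one_tracks_theta3(self, cohort24):
        """On the default cohort the dominant axis separates experts mostly
        by their theta3 beliefs, as archetypes differ mainly there."""
        res = scale_vectors(belief_vectors(cohort24))
        s = axis_loadings(res, 0)
        assert s.filter(like="theta3").abs().sum() > s.filter(like="theta1").abs().sum()

    def test_gof_defined_on_cohort(self, cohort24):
        res = scale_vectors(belief_vectors(cohort24))
        assert 0 < res.gof[2] <= 1 + 1e-12
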