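"""Correlation-matrix PCA, Kaiser retention and varimax rotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import feedscreen as fs
from feedscreen.datasets import load_published_eigenvalues
from feedscreen.errors import DegenerateInputError, FeedscreenError
from feedscreen.pca_varimax import varimax_criterion


def _standardize(X):
    return (X - X.mean(0)) / X.std(0, ddof=1)


class TestAssembleMatrix:
    def test_columns_standardized(self, config, normalizer):
        panel = fs.make_panel([("pliable", 2)], config, seed=0)
        vecs = [normalizer.transform_one(p) for p in panel.profiles]
        Z = fs.assemble_matrix(vecs)
        assert Z.shape == (config.grid_points_total, 2)
        np.testing.assert_allclose(Z.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(0, ddof=1), 1.0, atol=1e-12)

    def test_duplicate_filaments_correlate_perfectly(self, config, normalizer):
        panel = fs.make_panel([("pliable", 1)], config, seed=1)
        v = normalizer.transform_one(panel.profiles[0])
        Z = fs.assemble_matrix([v, v])
        assert np.corrcoef(Z.iloc[:, 0], Z.iloc[:, 1])[0, 1] == pytest.approx(1.0)

    def test_flat_profile_named_in_degenerate_error(self):
        grid = np.arange(4.0)
        good = fs.NormalizedProfileVector("good", grid, np.array([0.1, 0.2, 0.3, 0.4]))
        flat = fs.NormalizedProfileVector("flatliner", grid, np.full(4, 0.25))
        with pytest.raises(DegenerateInputError, match="flatliner"):
            fs.assemble_matrix([good, flat])


class TestPcaEigen:
    @given(st.floats(-0.95, 0.95))
    @settings(max_examples=30, deadline=None)
    def test_two_variable_closed_form(self, r):
        # eigenvalues of a 2x2 correlation matrix [[1,r],[r,1]] are 1±r
        rng = np.random.default_rng(12)
        x = rng.normal(size=500)
        noise = rng.normal(size=500)
        y = r * x + np.sqrt(max(1 - r**2, 1e-12)) * noise
        Z = _standardize(np.column_stack([x, y]))
        r_emp = np.corrcoef(Z.T)[0, 1]
        eigval, loadings = fs.pca_eigen(Z)
        np.testing.assert_allclose(
            np.sort(eigval), np.sort([1 - abs(r_emp), 1 + abs(r_emp)]), atol=1e-9
        )
        # loadings scaled so squared loadings per component sum to eigenvalue
        np.testing.assert_allclose((loadings**2).sum(0), eigval, atol=1e-9)

    def test_uncorrelated_columns_give_unit_eigenvalues(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(4000, 4))
        eigval, _ = fs.pca_eigen(_standardize(Z))
        np.testing.assert_allclose(eigval, 1.0, atol=0.15)

    def test_trace_identity(self, config, normalizer):
        panel = fs.make_panel([("pliable", 3), ("sharp_brittle", 3)], config, seed=5)
        Z = fs.assemble_matrix([normalizer.transform_one(p) for p in panel.profiles])
        eigval, _ = fs.pca_eigen(Z)
        assert eigval.sum() == pytest.approx(6.0, abs=1e-6)
        assert np.all(np.diff(eigval) <= 1e-12)  # descending

    def test_single_observation_is_a_rank_error(self):
        with pytest.raises(FeedscreenError):
            fs.pca_eigen(np.ones((1, 3)))

    def test_sign_convention_dominant_entry_positive(self):
        rng = np.random.default_rng(8)
        Z = _standardize(rng.normal(size=(60, 5)))
        _, loadings = fs.pca_eigen(Z)
        for j in range(loadings.shape[1]):
            col = loadings[:, j]
            assert col[np.argmax(np.abs(col))] >= 0


class TestKaiserSelect:
    def test_published_eigenvalue_list_retains_three(self):
        assert fs.kaiser_select(load_published_eigenvalues()) == 3

    def test_no_component_reaching_one_warns(self):
        with pytest.warns(UserWarning):
            assert fs.kaiser_select(np.array([0.99, 0.5])) == 0

    def test_boundary_eigenvalue_of_exactly_one_is_retained(self):
        assert fs.kaiser_select(np.array([1.0])) == 1


class TestVarimax:
    def test_single_component_returned_unchanged(self):
        L = np.array([[0.9], [0.8], [0.1]])
        rotated, n_iter, converged = fs.varimax(L)
        np.testing.assert_allclose(rotated, L)
        assert converged

    @given(st.integers(0, 2**31 - 1), st.integers(2, 4))
    @settings(max_examples=30, deadline=None)
    def test_communalities_preserved(self, seed, k):
        rng = np.random.default_rng(seed)
        L = rng.uniform(-1, 1, size=(7, k))
        rotated, _, _ = fs.varimax(L)
        np.testing.assert_allclose(
            (rotated**2).sum(1), (L**2).sum(1), atol=1e-8
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_single_angle_oracle_for_k2(self, seed):
        # for two components every orthogonal rotation (up to sign and
        # permutation) is a single angle in [0, pi/2); scan it at 1e-4
        rng = np.random.default_rng(seed)
        L = rng.uniform(-1, 1, size=(6, 2))
        h = np.sqrt((L**2).sum(1))
        A = L / h[:, None]  # Kaiser-normalized rows, same as the implementation
        best = -np.inf
        for theta in np.arange(0, np.pi / 2, 1e-4):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s], [s, c]])
            best = max(best, varimax_criterion(A @ R))
        # run the rotation to tight convergence for the oracle comparison
        rotated, _, _ = fs.varimax(L, max_iterations=200, tolerance=1e-12)
        achieved = varimax_criterion(rotated / h[:, None])
        assert achieved >= varimax_criterion(A) - 1e-12  # never worse than input
        assert achieved == pytest.approx(best, abs=1e-6)

    def test_agrees_with_statsmodels_raw_varimax(self):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        rng = np.random.default_rng(21)
        L = rng.uniform(-1, 1, size=(9, 3))
        ours, _, _ = fs.varimax(L, kaiser_normalize=False, max_iterations=500)
        theirs, _ = rotate_factors(L, "varimax")
        assert varimax_criterion(ours) == pytest.approx(
            varimax_criterion(theirs), rel=1e-6
        )

    def test_empty_rotation_is_a_noop_with_warning(self):
        with pytest.warns(UserWarning):
            rotated, _, _ = fs.varimax(np.empty((4, 0)))
        assert rotated.shape == (4, 0)


@pytest.fixture(scope="module")
def fitted(config, normalizer):
    panel = fs.make_panel(
        [("pliable", 5), ("sharp_brittle", 5), ("strain_bearing_brittle", 5)],
        config,
        seed=42,
    )
    vecs = [normalizer.transform_one(p) for p in panel.profiles]
    return fs.VarimaxPCA().fit(vecs), panel


class TestVarimaxPCAEstimator:
    def test_eigenvalues_sum_to_variable_count(self, fitted):
        model, panel = fitted
        assert model.eigenvalues_.sum() == pytest.approx(len(panel), abs=1e-6)

    def test_kaiser_retention_and_loading_shapes(self, fitted):
        model, panel = fitted
        assert model.n_components_ == np.sum(model.eigenvalues_ >= 1.0)
        assert model.loadings_.shape == (len(panel), model.n_components_)
        assert model.rotated_loadings_.shape == model.loadings_.shape

    def test_rotation_preserves_communalities_and_total_variance(self, fitted):
        model, _ = fitted
        before = (model.loadings_**2).sum(1)
        after = (model.rotated_loadings_**2).sum(1)
        np.testing.assert_allclose(before, after, atol=1e-8)
        assert after.sum() == pytest.approx(before.sum(), abs=1e-8)

    def test_rotation_respects_iteration_cap(self, fitted):
        model, _ = fitted
        assert model.n_iter_ <= model.max_iterations

    def test_deterministic_refit(self, config, normalizer, fitted):
        model, panel = fitted
        vecs = [normalizer.transform_one(p) for p in panel.profiles]
        again = fs.VarimaxPCA().fit(vecs)
        np.testing.assert_array_equal(again.rotated_loadings_, model.rotated_loadings_)

    def test_param_protocol(self):
        model = fs.VarimaxPCA(max_iterations=50)
        assert model.get_params()["max_iterations"] == 50
        model.set_params(tolerance=1e-8)
        assert model.tolerance == 1e-8
        with pytest.raises(ValueError):
            model.set_params(bogus=1)

    def test_phenotype_silhouette_positive_in_rotated_space(self, fitted):
        from sklearn.metrics import silhouette_score

        model, panel = fitted
        labels = [p.metadata["phenotype"] for p in panel.profiles]
        assert silhouette_score(model.rotated_loadings_, labels) > 0


class TestSpacePlotCoordinates:
    def test_coordinates_table_with_group_labels(self, config, normalizer, tmp_path):
        panel = fs.make_panel([("pliable", 5), ("sharp_brittle", 5)], config, seed=9)
        vecs = [normalizer.transform_one(p) for p in panel.profiles]
        model = fs.VarimaxPCA().fit(vecs)
        sol = model.solution_(panel.truth)
        out = tmp_path / "coords.csv"
        coords = fs.space_plot_coordinates(sol, out_csv=out)
        assert len(coords) == 10
        assert coords.shape[1] == min(model.n_components_, 3) + 1  # + group column
        assert out.exists()
        assert set(coords["group"]) == {"feedable", "non-feedable"}

    def test_within_group_closer_than_between_group(self, config, normalizer):
        from scipy.spatial.distance import pdist, squareform

        panel = fs.make_panel([("pliable", 5), ("sharp_brittle", 5)], config, seed=9)
        vecs = [normalizer.transform_one(p) for p in panel.profiles]
        coords = fs.VarimaxPCA().fit_transform(vecs)
        D = squareform(pdist(coords))
        same = np.zeros_like(D, dtype=bool)
        same[:5, :5] = same[5:, 5:] = True
        np.fill_diagonal(same, False)
        off = ~same
        np.fill_diagonal(off, False)
        assert D[same].mean() < D[off].mean()

    def test_fewer_than_two_components_is_a_plot_error(self):
        sol = fs.PcaSolution(
            variable_names=["a", "b"],
            eigenvalues=np.array([1.5, 0.5]),
            n_retained=1,
            loadings_unrotated=np.ones((2, 1)),
            loadings_rotated=np.ones((2, 1)),
            rotation_iterations=0,
            converged=True,
        )
        with pytest.raises(FeedscreenError, match="1-D"):
            fs.space_plot_coordinates(sol)

    def test_rendered_plot_written(self, config, normalizer, tmp_path):
        pytest.importorskip("matplotlib")
        panel = fs.make_panel([("pliable", 3), ("sharp_brittle", 3)], config, seed=2)
        vecs = [normalizer.transform_one(p) for p in panel.profiles]
        model = fs.VarimaxPCA().fit(vecs)
        png = tmp_path / "space.png"
        fs.space_plot_coordinates(model.solution_(), out_plot=png)
        assert png.stat().st_size > 0
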