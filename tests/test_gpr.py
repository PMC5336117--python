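"""Gaussian process regression against dense-matrix and scikit-learn oracles."""

import numpy as np
import pytest

from smithsquat import gpr, synthdata
from smithsquat.gpr import KernelParams, TrainingSet
from smithsquat.model import CaseSpec


def _fixture_set(n=12, dim=3, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, dim))
    y = np.sin(3 * X[:, 0]) + 0.5 * X[:, -1] ** 2 + (
        rng.normal(0, np.sqrt(noise), n) if noise else 0.0)
    params = KernelParams(signal_variance=1.5,
                          length_scales=tuple([0.4] * dim),
                          noise_variance=noise)
    return TrainingSet(X, y, "fixture"), params


def _dense_oracle(train, params, Xstar):
    """Brute-force dense-matrix evaluation of the predictive equations."""
    def k(a, b):
        ls = np.array(params.length_scales)
        d = (a / ls) - (b / ls)
        return params.signal_variance * np.exp(-0.5 * d @ d)

    n, m = train.n, len(Xstar)
    K = np.array([[k(train.X[i], train.X[j]) for j in range(n)]
                  for i in range(n)])
    Ks = np.array([[k(train.X[i], Xstar[j]) for j in range(m)]
                   for i in range(n)])
    Kss = np.array([[k(Xstar[i], Xstar[j]) for j in range(m)]
                    for i in range(m)])
    ybar = train.y.mean()
    inv = np.linalg.inv(K + params.noise_variance * np.eye(n))
    mean = Ks.T @ inv @ (train.y - ybar) + ybar
    cov = Kss - Ks.T @ inv @ Ks
    return mean, cov


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        params = KernelParams(2.5, (0.3, 0.7, 1.0))
        x = np.array([[0.1, 0.2, 0.9]])
        assert gpr.kernel_matrix(params, x, x)[0, 0] == pytest.approx(2.5)

    def test_kernel_decays_to_zero(self):
        params = KernelParams(1.0, (0.1,))
        far = gpr.kernel_matrix(params, [[0.0]], [[50.0]])
        assert far[0, 0] < 1e-300 or far[0, 0] == 0.0

    def test_gram_matches_elementwise_oracle(self):
        train, params = _fixture_set(n=3, dim=2, seed=3)
        K = gpr.kernel_matrix(params, train.X, train.X)
        ls = np.array(params.length_scales)
        for i in range(3):
            for j in range(3):
                d = train.X[i] / ls - train.X[j] / ls
                expected = params.signal_variance * np.exp(-0.5 * d @ d)
                assert K[i, j] == pytest.approx(expected, rel=1e-14)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            KernelParams(1.0, (0.0,))
        with pytest.raises(ValueError):
            KernelParams(-1.0, (0.5,))


class TestFitPredict:
    def test_noiseless_gp_interpolates(self):
        train, _ = _fixture_set(n=10, noise=0.0)
        params = KernelParams(1.5, (0.4, 0.4, 0.4), noise_variance=0.0)
        model = gpr.fit_gpr(train, params)
        mean, cov = gpr.predict(model, train.X, return_cov=True)
        assert np.abs(mean - train.y).max() < 1e-7
        assert np.abs(np.diag(cov)).max() < 1e-6

    def test_alpha_matches_dense_solve(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (3, 1))
        y = rng.normal(0, 1, 3)
        params = KernelParams(1.0, (0.5,), noise_variance=0.1)
        train = TrainingSet(X, y, "tiny")
        model = gpr.fit_gpr(train, params, center=False)
        K = gpr.kernel_matrix(params, X, X) + 0.1 * np.eye(3)
        assert np.allclose(model.alpha, np.linalg.solve(K, y), atol=1e-12)

    @pytest.mark.parametrize("n,noise", [(12, 0.05), (30, 0.0), (50, 0.2)])
    def test_predictions_match_dense_oracle(self, n, noise):
        train, params = _fixture_set(n=n, noise=noise, seed=n)
        model = gpr.fit_gpr(train, params)
        Xstar = np.random.default_rng(99).uniform(0, 1, (7, 3))
        mean, cov = gpr.predict(model, Xstar, return_cov=True)
        mean_o, cov_o = _dense_oracle(train, params, Xstar)
        scale = max(1.0, np.abs(mean_o).max())
        assert np.abs(mean - mean_o).max() / scale < 1e-10
        assert np.abs(cov - cov_o).max() / params.signal_variance < 1e-10

    def test_far_test_point_recovers_prior(self):
        train, _ = _fixture_set(n=8)
        params = KernelParams(2.0, (0.2, 0.2, 0.2), noise_variance=0.01)
        model = gpr.fit_gpr(train, params)
        far = np.array([[50.0, 50.0, 50.0]])
        mean, cov = gpr.predict(model, far, return_cov=True)
        assert mean[0] == pytest.approx(model.y_mean, abs=1e-10)
        assert cov[0, 0] == pytest.approx(params.signal_variance, rel=1e-12)

    def test_duplicate_rows_exercise_jitter_path(self):
        X = np.array([[0.1], [0.1], [0.5]])
        y = np.array([1.0, 1.0, 2.0])
        params = KernelParams(1.0, (0.3,), noise_variance=0.0)
        model = gpr.fit_gpr(TrainingSet(X, y, "dup"), params)
        assert model.jitter > 0.0
        assert np.all(np.isfinite(gpr.predict(model, [[0.3]])))

    def test_dimension_mismatch(self):
        train, params = _fixture_set()
        model = gpr.fit_gpr(train, params)
        with pytest.raises(ValueError):
            gpr.predict(model, [[0.1, 0.2]])

    def test_matches_sklearn(self):
        """Cross-check against an independent GPR implementation."""
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        train, params = _fixture_set(n=25, noise=0.09, seed=7)
        model = gpr.fit_gpr(train, params, center=False)
        sk = sklearn_gp.GaussianProcessRegressor(
            kernel=ConstantKernel(params.signal_variance,
                                  constant_value_bounds="fixed")
            * RBF(params.length_scales, length_scale_bounds="fixed"),
            alpha=params.noise_variance, optimizer=None, normalize_y=False)
        sk.fit(train.X, train.y)
        Xs = np.random.default_rng(1).uniform(0, 1, (9, 3))
        ours = gpr.predict(model, Xs)
        theirs = sk.predict(Xs)
        assert np.abs(ours - theirs).max() < 1e-8


class TestHyperparameters:
    def test_recovers_generative_length_scale(self):
        """Data from a known SE-GP: fitted scale within x/÷2 of truth."""
        rng = np.random.default_rng(42)
        true = KernelParams(1.0, (0.3,), noise_variance=0.01)
        X = rng.uniform(0, 1, (60, 1))
        K = gpr.kernel_matrix(true, X, X) + true.noise_variance * np.eye(60)
        y = rng.multivariate_normal(np.zeros(60), K, method="cholesky")
        train = TrainingSet(X, y, "gen")
        init = KernelParams(1.0, (0.8,), noise_variance=0.05)
        best = gpr.optimize_hyperparameters(train, init, n_restarts=3, seed=0)
        assert 0.15 <= best.length_scales[0] <= 0.6

    def test_white_noise_never_worse_than_init(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (40, 1))
        y = rng.normal(0, 1, 40)
        train = TrainingSet(X, y, "noise")
        init = KernelParams(1.0, (0.3,), noise_variance=0.1)
        best = gpr.optimize_hyperparameters(train, init, seed=1)
        assert gpr.log_marginal_likelihood(train, best) >= \
            gpr.log_marginal_likelihood(train, init) - 1e-9

    def test_deterministic_given_seed(self):
        train, params = _fixture_set(n=20, noise=0.05)
        a = gpr.optimize_hyperparameters(train, params, n_restarts=2, seed=3)
        b = gpr.optimize_hyperparameters(train, params, n_restarts=2, seed=3)
        assert a == b


@pytest.fixture(scope="module")
def trained():
    cfg = synthdata.GeneratorConfig(n_subjects=1, reps_per_case=1,
                                    trial_noise_sd_deg=0.0,
                                    subject_style_sd_deg=0.0, n_frames=41)
    records = synthdata.generate_database(cfg)
    sets = synthdata.training_sets(records, subsample=2)
    params = KernelParams(40.0 ** 2, (0.15, 0.6, 0.18), noise_variance=1e-8)
    return records, {n: gpr.fit_gpr(s, params) for n, s in sets.items()}


class TestSynthesis:
    def test_training_case_is_interpolated(self, trained):
        records, models = trained
        case = records[0].case
        traj = gpr.synthesize_motion(models, case, n_frames=41)
        truth = records[0].truth
        for joint in traj.angles:
            # noiseless fit on subsampled grid: near-exact on kept samples
            assert np.abs(traj.angles[joint][::2] - truth[joint][::2]).max() \
                < 1e-4

    def test_intermediate_case_between_neighbours(self, trained):
        _, models = trained
        peak = {}
        for d in (0.0, 0.07, 0.14):
            traj = gpr.synthesize_motion(models, CaseSpec(d, 0.0), n_frames=41)
            peak[d] = traj.angles["hip_R"].max()
        lo, hi = sorted((peak[0.0], peak[0.14]))
        assert lo - 1.0 <= peak[0.07] <= hi + 1.0

    def test_output_grid_size(self, trained):
        _, models = trained
        traj = gpr.synthesize_motion(models, CaseSpec(0.14, 10.0),
                                     n_frames=101)
        assert traj.n_frames == 101
        assert np.allclose(np.diff(traj.cycle_fraction),
                           traj.cycle_fraction[1])

    def test_extrapolation_warns(self):
        cfg = synthdata.GeneratorConfig(
            n_subjects=1, reps_per_case=1, trial_noise_sd_deg=0.0,
            subject_style_sd_deg=0.0, n_frames=21,
            cases=tuple(CaseSpec(d, th) for d in (0.0, 0.14)
                        for th in (0.0, 10.0)))
        sets = synthdata.training_sets(synthdata.generate_database(cfg),
                                       subsample=4)
        models = {n: gpr.fit_gpr(s) for n, s in sets.items()}
        with pytest.warns(UserWarning, match="extrapolating"):
            gpr.synthesize_motion(models, CaseSpec(0.28, 20.0), n_frames=11)

    def test_persistence_roundtrip(self, trained, tmp_path):
        _, models = trained
        path = tmp_path / "models.json"
        gpr.save_models(models, path)
        back = gpr.load_models(path)
        case = CaseSpec(0.1, 7.0)
        a = gpr.synthesize_motion(models, case, n_frames=21)
        b = gpr.synthesize_motion(back, case, n_frames=21)
        for joint in a.angles:
            assert np.allclose(a.angles[joint], b.angles[joint], atol=1e-12)
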