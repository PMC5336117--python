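"""Gaussian process regression for squat-motion synthesis.

One independent GP per driven joint angle, over the three-dimensional input
``x = (D/h, theta/20, t/T)`` -- normalised foot position, guide angle and
cycle time.  The kernel is an anisotropic squared exponential; targets are
centred so the prior mean is zero, and the centring constant is stored.
The posterior mean and covariance are

    mean(X*) = K*^T (K + sigma_n^2 I)^{-1} y
    cov(X*)  = K** - K*^T (K + sigma_n^2 I)^{-1} K*

computed through a Cholesky factorisation of the regularised Gram matrix
(with geometric jitter escalation 1e-10 -> 1e-6 if needed, recorded on the
model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .kinematics import DRIVEN_NAMES, DrivenTrajectory
from .model import CaseSpec

__all__ = [
    "KernelParams",
    "TrainingSet",
    "GPRModel",
    "kernel_matrix",
    "fit_gpr",
    "predict",
    "log_marginal_likelihood",
    "optimize_hyperparameters",
    "synthesize_motion",
    "save_models",
    "load_models",
]

#: Feature scaling used throughout: D/h in [0, 0.28], theta/20 in [0, 1], t/T in [0, 1].
THETA_SCALE = 20.0


@dataclass(frozen=True)
class KernelParams:
    """Anisotropic squared-exponential kernel hyperparameters.

    ``signal_variance`` (deg^2), per-feature ``length_scales`` in the scaled
    feature units, and observation ``noise_variance`` (deg^2).
    """

    signal_variance: float
    length_scales: tuple
    noise_variance: float = 0.0

    def __post_init__(self):
        if self.signal_variance <= 0:
            raise ValueError("signal variance must be positive")
        if any(l <= 0 for l in self.length_scales):
            raise ValueError("length scales must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be non-negative")


DEFAULT_KERNEL = KernelParams(signal_variance=40.0 ** 2,
                              length_scales=(0.15, 0.6, 0.18),
                              noise_variance=0.25)


@dataclass
class TrainingSet:
    """Inputs X (n, 3) in scaled features and targets y (n,) in degrees for
    one driven joint angle."""

    X: np.ndarray
    y: np.ndarray
    joint_name: str

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.y = np.asarray(self.y, float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y row counts differ")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite training data")

    @property
    def n(self) -> int:
        return self.y.size


def kernel_matrix(params: KernelParams, X1, X2) -> np.ndarray:
    """Gram matrix k(X1, X2) of the anisotropic squared-exponential kernel."""
    X1 = np.atleast_2d(np.asarray(X1, float))
    X2 = np.atleast_2d(np.asarray(X2, float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("feature dimensions differ")
    ls = np.asarray(params.length_scales, float)
    if ls.size != X1.shape[1]:
        raise ValueError("length-scale count does not match feature dimension")
    diff = X1[:, None, :] / ls - X2[None, :, :] / ls
    sq = np.sum(diff * diff, axis=-1)
    return params.signal_variance * np.exp(-0.5 * sq)


class SingularKernelError(np.linalg.LinAlgError):
    pass


@dataclass
class GPRModel:
    """A fitted per-joint GP posterior."""

    kernel: KernelParams
    X: np.ndarray
    alpha: np.ndarray
    y_mean: float
    joint_name: str
    jitter: float = 0.0
    _cho: tuple = field(default=None, repr=False)

    def __post_init__(self):
        if self._cho is None:
            K = kernel_matrix(self.kernel, self.X, self.X)
            K[np.diag_indices_from(K)] += self.kernel.noise_variance + self.jitter
            self._cho = cho_factor(K, lower=True)


def _factorize(K: np.ndarray, noise: float):
    """Cholesky with geometric jitter escalation 1e-10 -> 1e-6."""
    n = K.shape[0]
    jitter = 0.0
    for attempt in (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6):
        try:
            A = K + (noise + attempt) * np.eye(n)
            return cho_factor(A, lower=True), attempt
        except np.linalg.LinAlgError:
            jitter = attempt
            continue
    raise SingularKernelError(
        f"kernel matrix singular even with jitter {jitter:g}")


def fit_gpr(train: TrainingSet, params: KernelParams = DEFAULT_KERNEL,
            center: bool = True) -> GPRModel:
    """Fit the GP: factorise K + sigma_n^2 I and precompute alpha."""
    y_mean = float(np.mean(train.y)) if center else 0.0
    K = kernel_matrix(params, train.X, train.X)
    cho, jitter = _factorize(K, params.noise_variance)
    alpha = cho_solve(cho, train.y - y_mean)
    return GPRModel(kernel=params, X=train.X.copy(), alpha=alpha,
                    y_mean=y_mean, joint_name=train.joint_name,
                    jitter=jitter, _cho=cho)


def predict(model: GPRModel, Xstar, return_cov: bool = False):
    """Posterior mean (and covariance) at the test inputs."""
    Xstar = np.atleast_2d(np.asarray(Xstar, float))
    if Xstar.shape[1] != model.X.shape[1]:
        raise ValueError("test feature dimension does not match training")
    k_star = kernel_matrix(model.kernel, model.X, Xstar)  # (n, m)
    mean = k_star.T @ model.alpha + model.y_mean
    if not return_cov:
        return mean
    v = cho_solve(model._cho, k_star)
    cov = kernel_matrix(model.kernel, Xstar, Xstar) - k_star.T @ v
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def log_marginal_likelihood(train: TrainingSet, params: KernelParams,
                            center: bool = True) -> float:
    y = train.y - (np.mean(train.y) if center else 0.0)
    K = kernel_matrix(params, train.X, train.X)
    try:
        cho, _ = _factorize(K, params.noise_variance)
    except SingularKernelError:
        return -np.inf
    alpha = cho_solve(cho, y)
    L = cho[0]
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    n = train.n
    return -0.5 * float(y @ alpha) - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)


def optimize_hyperparameters(train: TrainingSet, init: KernelParams = DEFAULT_KERNEL,
                             n_restarts: int = 3, seed: int = 0,
                             optimize_noise: bool = True) -> KernelParams:
    """Maximise the log marginal likelihood over log-hyperparameters.

    Deterministic given ``seed``; returns the best of ``n_restarts``
    perturbed starts (or ``init`` unchanged if every restart fails).
    """
    if train.n < 3:
        raise ValueError("need at least 3 rows to optimise hyperparameters")
    rng = np.random.default_rng(seed)
    k = len(init.length_scales)
    noise_floor = 1e-8

    def unpack(theta):
        sv = float(np.exp(theta[0]))
        ls = tuple(np.exp(theta[1:1 + k]))
        nv = float(np.exp(theta[-1])) if optimize_noise else init.noise_variance
        return KernelParams(sv, ls, max(nv, 0.0))

    def neg_lml(theta):
        try:
            return -log_marginal_likelihood(train, unpack(theta))
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    theta0 = np.concatenate([
        [np.log(init.signal_variance)],
        np.log(init.length_scales),
        [np.log(max(init.noise_variance, noise_floor))],
    ])
    starts = [theta0] + [theta0 + rng.normal(0, 0.7, theta0.size)
                         for _ in range(max(0, n_restarts - 1))]
    best, best_val = None, np.inf
    for s in starts:
        res = minimize(neg_lml, s, method="L-BFGS-B",
                       options={"maxiter": 200})
        if res.fun < best_val and np.isfinite(res.fun):
            best, best_val = res.x, res.fun
    if best is None or best_val >= 1e12:
        return init
    base_val = neg_lml(theta0)
    if best_val > base_val:  # optimiser must not make things worse
        return init
    return unpack(best)


# ---------------------------------------------------------------------------
# Motion synthesis
# ---------------------------------------------------------------------------

def case_features(case: CaseSpec, t: np.ndarray) -> np.ndarray:
    """Scaled input rows (D/h, theta/20, t) for a case on a time grid."""
    t = np.asarray(t, float)
    out = np.empty((t.size, 3))
    out[:, 0] = case.foot_position_ratio
    out[:, 1] = case.guide_angle_deg / THETA_SCALE
    out[:, 2] = t
    return out


def training_hull(models: dict) -> tuple:
    """Axis-aligned bounds of the training cases (D/h, theta) over all models."""
    lo = np.array([np.inf, np.inf])
    hi = -lo
    for m in models.values():
        lo = np.minimum(lo, m.X[:, :2].min(axis=0))
        hi = np.maximum(hi, m.X[:, :2].max(axis=0))
    return lo, hi


def synthesize_motion(models: dict, case: CaseSpec, n_frames: int = 101,
                      cycle_duration: float = 6.0, with_sd: bool = False):
    """Evaluate all five per-joint GP means for one case.

    Returns a :class:`DrivenTrajectory` (and per-joint predictive-SD arrays
    if ``with_sd``).  A case outside the training grid's bounding box only
    triggers an extrapolation warning, not an error.
    """
    missing = set(DRIVEN_NAMES) - set(models)
    if missing:
        raise ValueError(f"missing per-joint models: {sorted(missing)}")
    t = np.linspace(0.0, 1.0, n_frames)
    X = case_features(case, t)
    lo, hi = training_hull(models)
    point = np.array([case.foot_position_ratio, case.guide_angle_deg / THETA_SCALE])
    extrapolating = bool(np.any(point < lo - 1e-12) or np.any(point > hi + 1e-12))
    if extrapolating:
        import warnings
        warnings.warn(f"case {case} outside the training grid; extrapolating",
                      stacklevel=2)

    angles, sds = {}, {}
    for name in DRIVEN_NAMES:
        model = models[name]
        if with_sd:
            mean, cov = predict(model, X, return_cov=True)
            sds[name] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        else:
            mean = predict(model, X)
        mean = np.asarray(mean)
        # enforce exact cycle closure of the synthesized channel
        mean[-1] = mean[0] = 0.5 * (mean[0] + mean[-1])
        angles[name] = mean
    traj = DrivenTrajectory(cycle_fraction=t, angles=angles,
                            cycle_duration=cycle_duration)
    return (traj, sds) if with_sd else traj


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_models(models: dict, path) -> None:
    """Persist per-joint models as a documented JSON file."""
    payload = {}
    for name, m in models.items():
        payload[name] = {
            "kernel": asdict(m.kernel),
            "X": m.X.tolist(),
            "alpha": m.alpha.tolist(),
            "y_mean": m.y_mean,
            "jitter": m.jitter,
            "joint_name": m.joint_name,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_models(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    models = {}
    for name, rec in payload.items():
        kp = rec["kernel"]
        kernel = KernelParams(signal_variance=kp["signal_variance"],
                              length_scales=tuple(kp["length_scales"]),
                              noise_variance=kp["noise_variance"])
        models[name] = GPRModel(kernel=kernel, X=np.array(rec["X"]),
                                alpha=np.array(rec["alpha"]),
                                y_mean=rec["y_mean"], jitter=rec["jitter"],
                                joint_name=rec["joint_name"])
    return models
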