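"""Ensemble Kalman filter on transformed macrostates.

The filter never touches microstates: each ensemble member is summarized to
a macrostate, mapped to filter space, and stacked into an ``(n_members, d)``
matrix.  The update is the stochastic (perturbed-observation) EnKF: each
member assimilates an independently noised copy of the observation, which
keeps the ensemble spread consistent with the Kalman posterior covariance.
After the update the posterior is fitted as a Gaussian and a fresh ensemble
is drawn from it, so the downstream microstate-synthesis step receives iid
posterior macrostate samples.

Parameter augmentation: model parameters under assimilation are appended to
the state vector (in transformed space) and receive an additive random-walk
"process noise" step of variance Q between updates, which both maintains
ensemble spread and lets the filter learn parameters from state data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaussianBelief",
    "ObservationSpec",
    "enkf_update",
    "fit_gaussian",
    "sample_posterior",
    "perturb_parameters",
    "covariance_entry_count",
]


@dataclass(frozen=True)
class GaussianBelief:
    """Multivariate Gaussian N(mean, cov) over the transformed state space."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        d = mean.shape[0]
        if cov.shape != (d, d):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass(frozen=True)
class ObservationSpec:
    """Which transformed variables are observed, with what noise, how often.

    ``observed`` are schema/parameter names selecting rows of the identity
    (the selection operator H); ``noise_var`` is the diagonal of R in
    transformed space; ``interval`` is the number of model ticks between
    observations.
    """

    observed: tuple[str, ...]
    noise_var: tuple[float, ...]
    interval: int = 50

    def __post_init__(self) -> None:
        if len(self.noise_var) != len(self.observed):
            raise ValueError("one noise variance per observed variable")
        if any(r <= 0 for r in self.noise_var):
            raise ValueError("noise variances must be positive")
        if self.interval < 1:
            raise ValueError("observation interval must be >= 1")

    def selection_matrix(self, state_names: tuple[str, ...]) -> np.ndarray:
        H = np.zeros((len(self.observed), len(state_names)))
        for row, name in enumerate(self.observed):
            H[row, state_names.index(name)] = 1.0
        return H

    @property
    def R(self) -> np.ndarray:
        return np.diag(self.noise_var)


def enkf_update(
    prior_vectors: np.ndarray,
    observation: np.ndarray,
    H: np.ndarray,
    R: np.ndarray,
    rng: np.random.Generator,
    ridge: float = 1e-10,
) -> np.ndarray:
    """Stochastic EnKF update with perturbed observations.

    For each member i the observation is perturbed, y_i = y + eta_i with
    eta_i ~ N(0, R), and the member moves by the Kalman gain applied to its
    innovation:

        K = P H' (H P H' + R)^-1,      x_i <- x_i + K (y_i - H x_i)

    with P the (ridge-regularized) ensemble sample covariance.  The solve
    goes through Cholesky of the innovation covariance, which is symmetric
    positive definite for any PSD P and positive-definite R.
    """
    X = np.asarray(prior_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (n_members >= 2, d) prior matrix")
    y = np.atleast_1d(np.asarray(observation, dtype=float))
    H = np.atleast_2d(np.asarray(H, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    n, d = X.shape
    if H.shape != (y.shape[0], d):
        raise ValueError("H shape incompatible with observation/state")

    P = np.cov(X, rowvar=False).reshape(d, d)
    P = P + ridge * np.eye(d)
    S = H @ P @ H.T + R  # innovation covariance, SPD
    PHt = P @ H.T
    # K = PHt S^-1 computed via SPD solve
    import scipy.linalg

    cho = scipy.linalg.cho_factor(S, lower=True)
    K = scipy.linalg.cho_solve(cho, PHt.T).T  # (d, m)

    eta = rng.multivariate_normal(np.zeros(y.shape[0]), R, size=n)
    innovations = (y[None, :] + eta) - X @ H.T
    return X + innovations @ K.T


def fit_gaussian(vectors: np.ndarray, ridge_scale: float = 1e-8) -> GaussianBelief:
    """Sample mean and covariance with a ridge making the belief strictly PD.

    The ridge delta = max(1e-10, ridge_scale * trace/d) handles degenerate
    (e.g. collapsed) ensembles without distorting well-spread ones.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 sample vectors")
    mean = X.mean(axis=0)
    d = X.shape[1]
    cov = np.cov(X, rowvar=False).reshape(d, d)
    delta = max(1e-10, ridge_scale * np.trace(cov) / d)
    cov = cov + delta * np.eye(d)
    return GaussianBelief(mean=mean, cov=0.5 * (cov + cov.T))


def sample_posterior(
    belief: GaussianBelief, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n iid samples from the belief via a symmetric PSD square root
    (eigendecomposition with tiny-negative clipping), so sampling never
    fails on a marginally conditioned covariance."""
    if n < 1:
        raise ValueError("n must be >= 1")
    w, V = np.linalg.eigh(belief.cov)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    z = rng.standard_normal((n, belief.dim))
    return belief.mean[None, :] + z @ root.T


def perturb_parameters(
    param_vectors: np.ndarray, Q: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive N(0, Q) random-walk step per transformed parameter per member.

    Applied only to ensemble members (never to the truth trajectory, whose
    parameters stay fixed) and in transformed space, so log-transformed
    positive parameters remain positive after inversion.
    """
    if Q < 0:
        raise ValueError("Q must be nonnegative")
    X = np.asarray(param_vectors, dtype=float)
    if Q == 0:
        return X.copy()
    return X + rng.normal(0.0, np.sqrt(Q), size=X.shape)


def covariance_entry_count(n_fields: int, rows: int, cols: int) -> int:
    """Number of distinct off-diagonal covariance entries, D(D-1)/2, for a
    naive filter state holding ``n_fields`` lattice fields of shape
    (rows, cols) — i.e. state dimension D = n_fields * rows * cols.

    Exact integer arithmetic; quantifies why filtering raw spatial
    microstates is infeasible and the filter runs on macrostates instead.
    """
    D = int(n_fields) * int(rows) * int(cols)
    return D * (D - 1) // 2
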