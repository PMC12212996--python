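"""Evaluation of assimilation runs: surprisal, Gaussian Wasserstein
distances, and trajectory phenotype clustering.

Surprisal — the negative log density of the true state under the predictive
distribution — scores a forecast while accounting for its stated
uncertainty: an overconfident wrong forecast is penalized more than a wide
one.  The predictive distribution is the Gaussian fitted to the transformed
macrostate ensemble, so surprisal is reported in nats per time point.

Phenotype analysis flattens whole macrostate trajectories into vectors,
reduces them with PCA and clusters with k-means; per-cluster Gaussians at
each time point are compared with the closed-form 2-Wasserstein distance to
locate where phenotypes diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .enkf import GaussianBelief, fit_gaussian

__all__ = [
    "TrajectoryRecord",
    "surprisal",
    "gaussian_w2",
    "cluster_trajectories",
    "cluster_divergence_series",
    "parameter_separation",
]


@dataclass
class TrajectoryRecord:
    """One simulated run: macro variables sampled at T+1 time points."""

    run_id: str
    params: dict[str, float]
    data: np.ndarray  # (T+1, V)
    role: str = "ensemble-member"  # truth | ensemble-member | ensemble-summary

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trajectory data must be (time, variables)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trajectory contains non-finite values")
        if self.role not in ("truth", "ensemble-member", "ensemble-summary"):
            raise ValueError(f"unknown role {self.role!r}")


def surprisal(truth_vec: np.ndarray, belief: GaussianBelief) -> float:
    """-log N(truth; mean, cov) in nats:
    0.5*(x-m)' P^-1 (x-m) + 0.5*log det(2*pi*P).

    Computed via Cholesky of the (strictly PD) belief covariance."""
    x = np.asarray(truth_vec, dtype=float)
    if x.shape != belief.mean.shape:
        raise ValueError("dimension mismatch between truth and belief")
    d = belief.dim
    try:
        L = np.linalg.cholesky(belief.cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("belief covariance is not positive definite") from exc
    resid = scipy.linalg.solve_triangular(L, x - belief.mean, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(0.5 * (resid @ resid) + 0.5 * (d * np.log(2.0 * np.pi) + logdet))


def _psd_sqrt(P: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(P)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def gaussian_w2(a: GaussianBelief, b: GaussianBelief) -> float:
    """Closed-form 2-Wasserstein distance between Gaussians:

    W2^2 = |m_a - m_b|^2 + Tr(P_a + P_b - 2 (P_b^1/2 P_a P_b^1/2)^1/2)
    """
    if a.dim != b.dim:
        raise ValueError("beliefs must share a dimension")
    dm = a.mean - b.mean
    rb = _psd_sqrt(b.cov)
    cross = _psd_sqrt(rb @ a.cov @ rb)
    w2sq = float(dm @ dm + np.trace(a.cov) + np.trace(b.cov) - 2.0 * np.trace(cross))
    return float(np.sqrt(max(w2sq, 0.0)))


def cluster_trajectories(
    records: list[TrajectoryRecord],
    n_components: int = 3,
    k_range: range = range(2, 7),
    n_restarts: int = 20,
    seed: int = 0,
) -> dict:
    """Flatten, standardize, PCA-project and k-means-cluster trajectories.

    Each record's (T+1, V) matrix becomes one sample; columns are
    standardized so large-magnitude variables do not dominate the principal
    axes.  k is chosen over ``k_range`` by silhouette score with
    ``n_restarts`` seeded restarts; degenerate inputs (all silhouettes
    undefined) fall back to k = min(k_range).

    Returns dict with 'labels', 'embedding', 'explained_variance_ratio',
    'k', 'silhouette'.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    shape = records[0].data.shape
    if any(r.data.shape != shape for r in records):
        raise ValueError("records must share a (time, variables) shape")
    X = np.stack([r.data.reshape(-1) for r in records])
    X = StandardScaler().fit_transform(X)
    n_comp = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_comp, random_state=seed)
    Z = pca.fit_transform(X)

    best = None
    for k in k_range:
        if k >= len(records):
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(Z)
        if len(np.unique(labels)) < 2:
            continue
        try:
            score = silhouette_score(Z, labels)
        except ValueError:
            continue
        if best is None or score > best[0]:
            best = (score, k, labels)
    if best is None:
        k = min(k_range)
        labels = KMeans(n_clusters=min(k, len(records)), n_init=n_restarts,
                        random_state=seed).fit_predict(Z)
        best = (float("nan"), k, labels)
    score, k, labels = best
    return {
        "labels": labels,
        "embedding": Z,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "k": k,
        "silhouette": score,
    }


def cluster_divergence_series(
    records: list[TrajectoryRecord], labels: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-time-point pairwise 2-Wasserstein distances between the Gaussian
    approximations of each cluster.

    Returns (series, pairs): series has shape (T+1, n_pairs) and pairs lists
    the cluster index pairs column by column.  Pairs involving a singleton
    cluster (no covariance estimate) are reported as NaN.
    """
    labels = np.asarray(labels)
    if len(labels) != len(records):
        raise ValueError("one label per record required")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    T = records[0].data.shape[0]
    stacks = {
        int(cl): np.stack([r.data for r, l in zip(records, labels) if l == cl])
        for cl in clusters
    }
    pairs = [
        (int(a), int(b)) for i, a in enumerate(clusters) for b in clusters[i + 1:]
    ]
    series = np.full((T, len(pairs)), np.nan)
    beliefs: dict[int, GaussianBelief | None] = {}
    for t in range(T):
        for cl, stack in stacks.items():
            beliefs[cl] = fit_gaussian(stack[:, t, :]) if len(stack) >= 2 else None
        for col, (a, b) in enumerate(pairs):
            if beliefs[a] is not None and beliefs[b] is not None:
                series[t, col] = gaussian_w2(beliefs[a], beliefs[b])
    return series, pairs


def parameter_separation(
    params: np.ndarray,
    labels: np.ndarray,
    clusters: tuple[int, int] = (0, 1),
    seed: int = 0,
) -> dict:
    """Fit a linear separator between two clusters in parameter space.

    Returns the unit normal vector of the separating hyperplane, the
    intercept, and training accuracy — quantifying how well parameters alone
    predict the phenotype."""
    params = np.asarray(params, dtype=float)
    labels = np.asarray(labels)
    mask = np.isin(labels, clusters)
    X, y = params[mask], labels[mask]
    if len(np.unique(y)) < 2:
        raise ValueError("need members of both requested clusters")
    clf = LinearSVC(random_state=seed)
    clf.fit(X, y)
    accuracy = float(clf.score(X, y))
    normal = clf.coef_.reshape(-1)
    norm = np.linalg.norm(normal)
    return {
        "normal": normal / norm if norm > 0 else normal,
        "intercept": float(clf.intercept_[0]),
        "accuracy": accuracy,
    }
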