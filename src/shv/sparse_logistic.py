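"""Cluster-level sparse logistic decoding models.

Two closely related estimators operate on cluster-averaged trial features
``D`` (trials x clusters):

*  the single-subject model with an l1 penalty on cluster weights,

       min_w  sum_t log(1 + exp(-y(t) (D(t,:) w + b))) + lambda * sum_j |w(j)|

*  the groupwise model that stacks all subjects' weight vectors into a
   matrix ``W`` (clusters x subjects) and penalizes the l2 norm of each
   cluster's row,

       min_W  sum_i sum_t log(1 + exp(-y_i(t) (D_i(t,:) W(:,i) + b_i)))
              + lambda * sum_j ||W(j, :)||_2

The mixed l1/l2 (group-lasso) penalty zeroes whole cluster rows jointly
across subjects, enforcing that the same clusters are selected for every
subject while allowing subject-specific weight magnitudes.  Intercepts are
never penalized.

Both problems are solved by one monotone accelerated proximal-gradient
(FISTA) routine with backtracking line search; the single-subject penalty
is the group penalty on one-column rows, so the l1 case is the same solver
with an elementwise prox.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .parcellation import Parcellation

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectFeatures",
    "ClusterFeatures",
    "GroupFit",
    "average_features",
    "group_prox",
    "fit_group_logistic",
    "fit_single_logistic",
    "predict_accuracy",
    "lambda_max",
]


@dataclass(frozen=True)
class SubjectFeatures:
    """One subject's trial-by-voxel feature matrix with +/-1 trial labels."""

    X: np.ndarray
    y: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2D (trials x voxels)")
        if X.shape[0] != y.size:
            raise ValueError(f"rows(X)={X.shape[0]} must equal len(y)={y.size}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite entries")
        if not set(np.unique(y)) <= {-1, 1} or np.unique(y).size != 2:
            raise ValueError("labels must contain both +1 and -1 and nothing else")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ClusterFeatures:
    """Cluster-averaged features: one column per active cluster."""

    D: np.ndarray
    cluster_ids: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        ids = np.asarray(self.cluster_ids, dtype=np.intp).ravel()
        trials = np.asarray(self.trial_ids, dtype=np.intp).ravel()
        if D.ndim != 2 or D.shape[1] != ids.size:
            raise ValueError("columns of D must match cluster_ids")
        if D.shape[0] != trials.size:
            raise ValueError("rows of D must match trial_ids")
        if np.unique(ids).size != ids.size:
            raise ValueError("cluster_ids must be unique")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "cluster_ids", ids)
        object.__setattr__(self, "trial_ids", trials)

    @property
    def n_trials(self) -> int:
        return self.D.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.D.shape[1]


@dataclass(frozen=True)
class GroupFit:
    """Solution of the (group-)sparse logistic problem.

    ``W`` has one row per active cluster (ids in ``cluster_ids``) and one
    column per subject; ``b`` holds the unpenalized per-subject intercepts.
    ``objective_trace`` records the accepted objective values, which are
    non-increasing by construction of the monotone solver.
    """

    W: np.ndarray
    b: np.ndarray
    lam: float
    cluster_ids: np.ndarray
    objective_trace: np.ndarray = field(repr=False)
    converged: bool = True
    penalty: str = "group"

    @property
    def n_subjects(self) -> int:
        return self.W.shape[1]

    def selected_rows(self, atol: float = 0.0) -> np.ndarray:
        """Cluster ids whose weight row is not (numerically) zero."""
        norms = np.linalg.norm(self.W, axis=1)
        return self.cluster_ids[norms > atol]


def average_features(
    subject: SubjectFeatures,
    parcellation: Parcellation,
    sampled_voxels: np.ndarray,
) -> ClusterFeatures:
    """Average sampled voxel columns within each cluster.

    Column ``j`` of the result is the mean of ``X[:, g'_j]`` where ``g'_j``
    is the intersection of cluster ``j`` with ``sampled_voxels``.  Clusters
    with no sampled voxel are omitted (their weight is treated as 0
    downstream).
    """
    sampled = np.unique(np.asarray(sampled_voxels, dtype=np.intp).ravel())
    if sampled.size == 0:
        raise ValueError("sampled_voxels is empty")
    if sampled.min() < 0 or sampled.max() >= parcellation.n_voxels:
        raise ValueError("sampled voxel indices outside the parcellation")
    if subject.n_voxels != parcellation.n_voxels:
        raise ValueError("subject features and parcellation disagree on N_V")
    labels = parcellation.labels[sampled]
    active = np.unique(labels)
    pos = np.searchsorted(active, labels)
    counts = np.bincount(pos, minlength=active.size).astype(float)
    onehot = np.zeros((sampled.size, active.size))
    onehot[np.arange(sampled.size), pos] = 1.0
    D = (subject.X[:, sampled] @ onehot) / counts
    return ClusterFeatures(D=D, cluster_ids=active, trial_ids=np.arange(subject.n_trials))


def group_prox(W: np.ndarray, threshold: float) -> np.ndarray:
    """Row-wise block soft-thresholding (prox of ``threshold * sum_j ||W_j||_2``).

    Each row ``r`` maps to ``r * max(0, 1 - threshold/||r||_2)``; rows with
    norm <= threshold map exactly to zero.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    W = np.asarray(W, dtype=float)
    if threshold == 0:
        return W.copy()
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    scale = np.maximum(0.0, 1.0 - threshold / np.maximum(norms, 1e-300))
    return W * scale


def _l1_prox(W: np.ndarray, threshold: float) -> np.ndarray:
    return np.sign(W) * np.maximum(np.abs(W) - threshold, 0.0)


def _penalty_value(W: np.ndarray, lam: float, penalty: str) -> float:
    if penalty == "group":
        return lam * float(np.linalg.norm(W, axis=1).sum())
    return lam * float(np.abs(W).sum())


class _StackedLoss:
    """Summed logistic loss over subjects, vectorized when trial counts match."""

    def __init__(self, D_list: list[np.ndarray], y_list: list[np.ndarray]):
        self.D_list = [np.asarray(D, dtype=float) for D in D_list]
        self.y_list = [np.asarray(y, dtype=float).ravel() for y in y_list]
        shapes = {D.shape for D in self.D_list}
        self.p = self.D_list[0].shape[1]
        self.n_subjects = len(self.D_list)
        self._stacked = len(shapes) == 1
        if self._stacked:
            self.D = np.stack(self.D_list)  # (S, T, P)
            self.Y = np.stack(self.y_list)  # (S, T)

    def value(self, W: np.ndarray, b: np.ndarray) -> float:
        if self._stacked:
            z = np.einsum("stp,ps->st", self.D, W) + b[:, None]
            return float(np.logaddexp(0.0, -self.Y * z).sum())
        total = 0.0
        for i, (D, y) in enumerate(zip(self.D_list, self.y_list)):
            z = D @ W[:, i] + b[i]
            total += float(np.logaddexp(0.0, -y * z).sum())
        return total

    def value_and_grad(self, W: np.ndarray, b: np.ndarray):
        if self._stacked:
            z = np.einsum("stp,ps->st", self.D, W) + b[:, None]
            m = -self.Y * z
            val = float(np.logaddexp(0.0, m).sum())
            gz = -self.Y * expit(m)
            gW = np.einsum("stp,st->ps", self.D, gz)
            gb = gz.sum(axis=1)
            return val, gW, gb
        val = 0.0
        gW = np.zeros_like(W)
        gb = np.zeros_like(b)
        for i, (D, y) in enumerate(zip(self.D_list, self.y_list)):
            z = D @ W[:, i] + b[i]
            m = -y * z
            val += float(np.logaddexp(0.0, m).sum())
            gz = -y * expit(m)
            gW[:, i] = D.T @ gz
            gb[i] = gz.sum()
        return val, gW, gb


def _fit_sparse_logistic(
    D_list,
    y_list,
    lam: float,
    penalty: str,
    tol: float,
    max_iter: int,
    W0: np.ndarray | None = None,
    b0: np.ndarray | None = None,
):
    """Monotone FISTA with backtracking for the (group-)lasso logistic objective."""
    loss = _StackedLoss(D_list, y_list)
    p, S = loss.p, loss.n_subjects
    prox = group_prox if penalty == "group" else _l1_prox

    W = np.zeros((p, S)) if W0 is None else np.array(W0, dtype=float)
    b = np.zeros(S) if b0 is None else np.array(b0, dtype=float)
    Wz, bz = W.copy(), b.copy()  # momentum point
    W_prev, b_prev = W.copy(), b.copy()
    t = 1.0
    L = 1.0
    F = loss.value(W, b) + _penalty_value(W, lam, penalty)
    trace = [F]
    converged = False
    hits = 0

    for _ in range(max_iter):
        f_y, gW, gb = loss.value_and_grad(Wz, bz)
        # backtracking on the quadratic majorization at the momentum point
        while True:
            Wc = prox(Wz - gW / L, lam / L)
            bc = bz - gb / L
            dW, db = Wc - Wz, bc - bz
            f_c = loss.value(Wc, bc)
            quad = f_y + float((gW * dW).sum()) + float(gb @ db) + 0.5 * L * (
                float((dW * dW).sum()) + float(db @ db)
            )
            if f_c <= quad + 1e-12 * max(1.0, abs(f_y)):
                break
            L *= 2.0
            if L > 1e18:
                break
        F_c = f_c + _penalty_value(Wc, lam, penalty)

        accepted = F_c <= F
        if accepted:
            W_new, b_new, F_new = Wc, bc, F_c
        else:
            W_new, b_new, F_new = W, b, F  # monotone safeguard: keep best iterate

        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Wz = W_new + (t / t_new) * (Wc - W_new) + ((t - 1.0) / t_new) * (W_new - W_prev)
        bz = b_new + (t / t_new) * (bc - b_new) + ((t - 1.0) / t_new) * (b_new - b_prev)
        if not accepted:
            # restart momentum: next step is plain proximal gradient from W
            Wz, bz, t_new = W_new.copy(), b_new.copy(), 1.0
        W_prev, b_prev = W, b
        W, b = W_new, b_new
        trace.append(F_new)
        t = t_new

        if accepted:
            if abs(F - F_new) <= tol * max(1.0, abs(F_new)):
                hits += 1
                if hits >= 2:
                    F = F_new
                    converged = True
                    break
            else:
                hits = 0
        F = F_new

    if not converged:
        warnings.warn(
            f"sparse logistic solver did not converge in {max_iter} iterations "
            f"(last objective {trace[-1]:.6g})",
            RuntimeWarning,
        )
    return W, b, np.asarray(trace), converged


def _common_clusters(features: list[ClusterFeatures]):
    ids = features[0].cluster_ids
    for f in features[1:]:
        ids = np.intersect1d(ids, f.cluster_ids)
    if ids.size == 0:
        raise ValueError("no cluster is active in all subjects")
    D_list = []
    for f in features:
        cols = np.searchsorted(f.cluster_ids, ids)
        D_list.append(f.D[:, cols])
    return ids, D_list


def fit_group_logistic(
    features: list[ClusterFeatures],
    labels: list[np.ndarray],
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 2000,
    warm_start: GroupFit | None = None,
) -> GroupFit:
    """Fit the multi-subject mixed l1/l2 model on cluster features.

    Subjects' cluster sets are intersected first so that rows of ``W`` are
    aligned across subjects; the penalty couples each cluster's row, so a
    cluster is dropped or kept for all subjects jointly.

    Parameters
    ----------
    features, labels : per-subject cluster features and +/-1 label vectors.
    lam : group-lasso penalty weight (>= 0).
    tol : relative objective-change convergence tolerance.
    max_iter : iteration cap; non-convergence returns the best iterate with
        ``converged=False`` and a warning.
    warm_start : optional previous fit on the same cluster set.
    """
    if len(features) != len(labels) or not features:
        raise ValueError("need one label vector per subject")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    ids, D_list = _common_clusters(features)
    y_list = [np.asarray(y, dtype=float).ravel() for y in labels]
    for D, y in zip(D_list, y_list):
        if D.shape[0] != y.size:
            raise ValueError("label length must match trial count")
    W0 = b0 = None
    if warm_start is not None and np.array_equal(warm_start.cluster_ids, ids):
        W0, b0 = warm_start.W, warm_start.b
    W, b, trace, conv = _fit_sparse_logistic(
        D_list, y_list, lam, "group", tol, max_iter, W0, b0
    )
    return GroupFit(
        W=W, b=b, lam=float(lam), cluster_ids=ids,
        objective_trace=trace, converged=conv, penalty="group",
    )


def fit_single_logistic(
    features: ClusterFeatures,
    labels: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> GroupFit:
    """Single-subject l1 fit (one-column case of the group model)."""
    return fit_group_logistic([features], [labels], lam, tol=tol, max_iter=max_iter)


def fit_lasso_stack(
    features: list[ClusterFeatures],
    labels: list[np.ndarray],
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 2000,
    warm_start: GroupFit | None = None,
) -> GroupFit:
    """Fit every subject's l1 model in one call.

    The l1 objective separates across subjects, so solving the stacked
    problem with an elementwise prox yields exactly the per-subject
    single-subject solutions, sharing one solver invocation.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    ids, D_list = _common_clusters(features)
    y_list = [np.asarray(y, dtype=float).ravel() for y in labels]
    W0 = b0 = None
    if warm_start is not None and np.array_equal(warm_start.cluster_ids, ids):
        W0, b0 = warm_start.W, warm_start.b
    W, b, trace, conv = _fit_sparse_logistic(D_list, y_list, lam, "l1", tol, max_iter, W0, b0)
    return GroupFit(
        W=W, b=b, lam=float(lam), cluster_ids=ids,
        objective_trace=trace, converged=conv, penalty="l1",
    )


def predict_accuracy(
    fit: GroupFit,
    features: ClusterFeatures,
    labels: np.ndarray,
    subject_index: int = 0,
) -> float:
    """Fraction of trials with sign(D w + b) == y; sign(0) counts as +1."""
    labels = np.asarray(labels, dtype=int).ravel()
    if labels.size == 0:
        raise ValueError("empty trial set")
    if not np.array_equal(features.cluster_ids, fit.cluster_ids):
        raise ValueError("feature cluster_ids do not match the fit")
    z = features.D @ fit.W[:, subject_index] + fit.b[subject_index]
    pred = np.where(z >= 0, 1, -1)
    return float(np.mean(pred == labels))


def lambda_max(
    features: list[ClusterFeatures],
    labels: list[np.ndarray],
    penalty: str = "group",
) -> float:
    """Smallest penalty weight that zeroes all cluster weights.

    At ``W = 0`` the optimal intercepts are ``b_i = log(n+_i / n-_i)``; the
    returned value is the largest row l2 norm (group) or largest absolute
    entry (l1) of the smooth-loss gradient there, which by the stationarity
    condition makes ``W = 0`` optimal for any ``lam >=`` this value.
    """
    ids, D_list = _common_clusters(features)
    G = np.zeros((ids.size, len(features)))
    for i, (D, y) in enumerate(zip(D_list, labels)):
        y = np.asarray(y, dtype=float).ravel()
        npos = float((y > 0).sum())
        nneg = float((y < 0).sum())
        b = np.log(npos / nneg)
        gz = -y * expit(-y * b)
        G[:, i] = D.T @ gz
    if penalty == "group":
        return float(np.linalg.norm(G, axis=1).max())
    return float(np.abs(G).max())
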