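"""Independent reference computations used to check the package.

Everything here is deliberately naive (loops, generic optimizers) and never
shares code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def brute_affinity(data: np.ndarray, coords: np.ndarray, sigma_d: float) -> np.ndarray:
    """Dense affinity by an explicit per-pair loop."""
    n = data.shape[1]
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                out[a, b] = 1.0
                continue
            c = np.corrcoef(data[:, a], data[:, b])[0, 1]
            d2 = float(np.sum((coords[a] - coords[b]) ** 2))
            out[a, b] = abs(c) * np.exp(-d2 / sigma_d**2)
    return out


def group_objective(D_list, y_list, W, b, lam, penalty="group") -> float:
    """Mixed l1/l2 (or l1) penalized logistic objective, computed naively."""
    total = 0.0
    for i, (D, y) in enumerate(zip(D_list, y_list)):
        for t in range(D.shape[0]):
            z = float(D[t] @ W[:, i] + b[i])
            total += np.log1p(np.exp(-abs(y[t] * z))) + max(0.0, -y[t] * z)
    if penalty == "group":
        total += lam * sum(np.linalg.norm(W[j]) for j in range(W.shape[0]))
    else:
        total += lam * float(np.abs(W).sum())
    return total


def solve_group_logistic_smoothed(D_list, y_list, lam, mu_final=1e-11):
    """Generic convex solver for the group-lasso logistic problem.

    L-BFGS-B on a smoothed objective replacing each row norm ||r|| with
    sqrt(||r||^2 + mu^2) - mu, annealing mu downward; the smoothing gap is
    bounded by lam * n_rows * mu.  Entirely independent of the package's
    proximal-gradient solver.
    """
    p = D_list[0].shape[1]
    S = len(D_list)

    def fun(theta, mu):
        W = theta[: p * S].reshape(p, S)
        b = theta[p * S:]
        val = 0.0
        gW = np.zeros_like(W)
        gb = np.zeros_like(b)
        for i, (D, y) in enumerate(zip(D_list, y_list)):
            z = D @ W[:, i] + b[i]
            m = -y * z
            val += float(np.logaddexp(0.0, m).sum())
            gz = -y * expit(m)
            gW[:, i] = D.T @ gz
            gb[i] = gz.sum()
        norms = np.sqrt((W**2).sum(axis=1) + mu**2)
        val += lam * float((norms - mu).sum())
        gW += lam * W / norms[:, None]
        return val, np.concatenate([gW.ravel(), gb])

    theta = np.zeros(p * S + S)
    mu = 1e-1
    while mu >= mu_final:
        res = minimize(
            fun, theta, args=(mu,), jac=True, method="L-BFGS-B",
            options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-14},
        )
        theta = res.x
        mu /= 100.0
    W = theta[: p * S].reshape(p, S)
    return W, theta[p * S:]


def solve_logistic_mle(D, y):
    """Unpenalized maximum-likelihood logistic fit via BFGS."""
    p = D.shape[1]

    def fun(theta):
        w, b = theta[:p], theta[p]
        z = D @ w + b
        m = -y * z
        val = float(np.logaddexp(0.0, m).sum())
        gz = -y * expit(m)
        return val, np.concatenate([D.T @ gz, [gz.sum()]])

    res = minimize(fun, np.zeros(p + 1), jac=True, method="BFGS",
                   options={"maxiter": 10000, "gtol": 1e-10})
    return res.x[:p], float(res.x[p]), float(res.fun)


def cluster_vote_rate_naive(selected_scores, n_sel):
    """Literal nested-loop transcription of the cluster vote rate."""

    def selector(vec):
        vec = np.asarray(vec, dtype=float)
        order = sorted(range(vec.size), key=lambda j: (-vec[j], j))
        out = np.zeros(vec.size)
        taken = 0
        for j in order:
            if taken == n_sel or vec[j] <= 0:
                break
            out[j] = 1.0
            taken += 1
        return out

    n_c = np.asarray(selected_scores[0]).shape[1]
    acc = np.zeros(n_c)
    for s_mat in selected_scores:
        s_mat = np.asarray(s_mat, dtype=float)
        freq = np.zeros(n_c)
        for k in range(s_mat.shape[0]):
            freq += selector(s_mat[k])
        freq /= s_mat.shape[0]
        acc += selector(freq)
    return acc / len(selected_scores)


def voxel_vote_rate_naive(subject_loops, labels):
    """Indicator-sum transcription of the per-voxel vote rate."""
    n_v = labels.size
    out = np.zeros(n_v)
    for m in range(n_v):
        num = den = 0
        for sampled, selector in subject_loops:
            sampled = set(int(s) for s in np.asarray(sampled).ravel())
            if m in sampled:
                den += 1
                if selector[labels[m]] == 1:
                    num += 1
        out[m] = num / den if den else 0.0
    return out


def overlap_naive(s1: set, s2: set, n_total: int) -> float:
    inter = len(s1 & s2)
    return abs(inter - len(s1) * len(s2) / n_total) / max(len(s1), len(s2))
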