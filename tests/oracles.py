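"""Independent brute-force oracles used by the test suite.

Each oracle takes the slow/direct route the implementation exists to avoid:
full N x N covariance eigendecomposition instead of the Gram trick, naive
double-loop scatter sums, a generic constrained-QP solve of the SVM dual,
and per-window polynomial fits for the smoothing filter.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def direct_pca(X: np.ndarray):
    """Eigendecomposition of the full N x N covariance (1/M normalized).

    Returns (eigenvalues descending, eigenvectors as columns), truncated to
    the numerically nonzero spectrum.
    """
    X = np.asarray(X, dtype=float)
    M = X.shape[0]
    Phi = X - X.mean(axis=0)
    C = (Phi.T @ Phi) / M
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(vals[0], 0) * 1e-10
    return vals[keep], vecs[:, keep]


def naive_scatter(X: np.ndarray, labels):
    """Between/within/total scatter via explicit elementwise double loops."""
    X = np.asarray(X, dtype=float)
    M, p = X.shape
    classes = list(dict.fromkeys(labels))
    mu = X.mean(axis=0)
    S_B = np.zeros((p, p))
    S_W = np.zeros((p, p))
    S_T = np.zeros((p, p))
    for lab in classes:
        idx = [i for i, l in enumerate(labels) if l == lab]
        mu_i = X[idx].mean(axis=0)
        for a in range(p):
            for b in range(p):
                S_B[a, b] += len(idx) * (mu_i[a] - mu[a]) * (mu_i[b] - mu[b])
                for i in idx:
                    S_W[a, b] += (X[i, a] - mu_i[a]) * (X[i, b] - mu_i[b])
    for k in range(M):
        for a in range(p):
            for b in range(p):
                S_T[a, b] += (X[k, a] - mu[a]) * (X[k, b] - mu[b])
    return S_B, S_W, S_T


def qp_crammer_singer(K: np.ndarray, y_idx: np.ndarray, n_classes: int,
                      C: float):
    """Solve the Crammer-Singer dual with a generic constrained-QP method.

    min  1/2 sum_{ij} K_ij alpha_i . alpha_j + sum_{i,m} e_i^m alpha_i^m
    s.t. sum_m alpha_i^m = 0,  alpha_i^m <= C delta_{y_i, m}

    Uses scipy's interior-point trust-region solver with analytic gradient
    and Hessian (SLSQP as fallback); suitable for M <= 20, c <= 4.
    Returns (alpha, objective value).
    """
    K = np.asarray(K, dtype=float)
    M = K.shape[0]
    c = n_classes
    E = np.ones((M, c))
    E[np.arange(M), y_idx] = 0.0
    cap = np.zeros((M, c))
    cap[np.arange(M), y_idx] = C

    # Hessian of the dual: block structure K (x) I_c
    H = np.kron(K, np.eye(c))

    def fun(a):
        A = a.reshape(M, c)
        G = K @ A
        return 0.5 * float(np.sum(A * G)) + float(np.sum(E * A)), (G + E).ravel()

    Aeq = np.zeros((M, M * c))
    for i in range(M):
        Aeq[i, i * c:(i + 1) * c] = 1.0
    bounds = list(zip(np.full(M * c, -np.inf), cap.ravel()))

    def slsqp(x0):
        return minimize(
            fun, x0, jac=True, method="SLSQP",
            constraints=[LinearConstraint(Aeq, 0.0, 0.0)],
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14},
        )

    candidates = [slsqp(np.zeros(M * c))]
    if not candidates[0].success:
        # interior-point pass to get near the optimum, then SLSQP to polish
        # (SLSQP may stop with a line-search status at machine precision)
        warm = minimize(
            fun, np.zeros(M * c), jac=True, hess=lambda a: H,
            method="trust-constr",
            constraints=[LinearConstraint(Aeq, 0.0, 0.0)],
            bounds=bounds,
            options={"maxiter": 3000, "gtol": 1e-10, "xtol": 1e-14},
        )
        candidates.extend([warm, slsqp(warm.x)])
    feasible = [
        r for r in candidates
        if np.max(np.abs(Aeq @ r.x)) < 1e-8
        and np.max(r.x - cap.ravel()) < 1e-8
    ]
    if not feasible:  # pragma: no cover - diagnostic aid
        raise RuntimeError("QP oracle produced no feasible solution")
    best = min(feasible, key=lambda r: fun(r.x)[0])
    return best.x.reshape(M, c), float(fun(best.x)[0])


def sg_smooth_window_fits(signal: np.ndarray, poly_order: int,
                          frame_size: int) -> np.ndarray:
    """Savitzky-Golay by explicit per-window polynomial least squares.

    For each interior sample, fit a degree-``poly_order`` polynomial to the
    centered window and take its value at the centre.  Edges are left as the
    input (only interior points are compared against this oracle).
    """
    signal = np.asarray(signal, dtype=float)
    half = frame_size // 2
    out = signal.copy()
    offsets = np.arange(-half, half + 1)
    V = np.vander(offsets, poly_order + 1, increasing=True)
    # centre value = coefficient of x^0 of the LS fit
    proj = np.linalg.lstsq(V, np.eye(frame_size), rcond=None)[0][0]
    for i in range(half, signal.shape[0] - half):
        out[i] = proj @ signal[i - half:i + half + 1]
    return out
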