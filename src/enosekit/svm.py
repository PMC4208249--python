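"""Crammer-Singer multiclass SVM on discriminant-space vectors.

Unlike one-vs-one / one-vs-rest decompositions, the Crammer-Singer machine
trains all c class functions w_m in a single optimization:

    min_{w,xi}  1/2 sum_m ||w_m||^2 + C sum_i xi_i
    s.t.        w_{y_i}.phi(x_i) - w_m.phi(x_i) >= e_i^m - xi_i  for all i, m

with e_i^m = 1 - delta_{y_i, m}.  Its dual, in the per-example blocks
alpha_i = (alpha_i^1 ... alpha_i^c):

    min_alpha  1/2 sum_m ||w_m(alpha)||^2 + sum_{i,m} e_i^m alpha_i^m
    s.t.       sum_m alpha_i^m = 0          for every i
               alpha_i^m <= C delta_{y_i,m} for every i, m

where w_m(alpha) = sum_i alpha_i^m phi(x_i); only kernel values
K_ij = phi(x_i).phi(x_j) enter.  The solver is block-coordinate descent over
examples with an exact analytic solution of each c-variable subproblem (a
clipped water-filling step), a deterministic cyclic visiting order, and a
KKT-violation stopping rule — the decomposition scheme of the original
formulation.  Prediction is argmax_m sum_i alpha_i^m K(x_i, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KernelSpec", "MulticlassSVMModel", "fit_crammer_singer", "predict",
           "decision_scores", "dual_objective"]


class SVMError(ValueError):
    pass


@dataclass
class KernelSpec:
    """Kernel for the SVM.

    ``linear``: x.y + bias; ``rbf``: exp(-gamma ||x-y||^2).  The additive
    ``bias`` term makes the linear kernel inhomogeneous, equipping every
    class score with a (regularized) intercept — without it the decision
    functions all pass through the origin and a class whose cluster lies
    between two others on a line through the origin could never win the
    argmax.  Set ``bias=0.0`` for the strictly homogeneous form.
    """

    name: str = "linear"
    gamma: float | None = None
    bias: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("linear", "rbf"):
            raise SVMError(f"unknown kernel {self.name!r}")

    def matrix(self, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
        if self.name == "linear":
            return X @ Y.T + self.bias
        gamma = self.gamma if self.gamma is not None else 1.0 / X.shape[1]
        sq = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Y**2, axis=1)[None, :]
            - 2.0 * X @ Y.T
        )
        return np.exp(-gamma * np.maximum(sq, 0.0))


@dataclass
class MulticlassSVMModel:
    """Fitted dual variables plus everything needed to score new points."""

    alpha: np.ndarray            # (M, c)
    training_points: np.ndarray  # (M, q)
    y: np.ndarray                # (M,) class indices into class_labels
    class_labels: list
    penalty: float
    kernel: KernelSpec = field(default_factory=KernelSpec)


def _solve_subproblem(A: float, b: np.ndarray, cap: np.ndarray) -> np.ndarray:
    """Exactly minimize (A/2)||a||^2 + b.a  s.t.  sum(a) = 0, a <= cap.

    The KKT solution is a_m = min(cap_m, (theta - b_m)/A) with theta the
    unique root of h(theta) = sum_m a_m(theta); h is continuous, piecewise
    linear and increasing, so the root is bracketed by evaluating h at the
    sorted breakpoints theta_m = b_m + A cap_m.
    """
    c = b.shape[0]
    t = b + A * cap
    order = np.argsort(t, kind="stable")
    t_s = t[order]
    cap_cum = np.concatenate(([0.0], np.cumsum(cap[order])))
    b_s = b[order]
    b_tail = np.concatenate((np.cumsum(b_s[::-1])[::-1], [0.0]))
    # h at breakpoint j (terms 0..j clipped, the rest linear in theta)
    n_free_at = c - np.arange(1, c + 1)
    h = cap_cum[1:] + np.where(
        n_free_at > 0, (n_free_at * t_s - b_tail[1:]) / A, 0.0
    )
    # h is non-decreasing over breakpoints and h[-1] = sum(cap) = C >= 0,
    # so the first non-negative entry brackets the root from above.
    jstar = int(np.argmax(h >= 0.0))
    theta = (b_tail[jstar] - A * cap_cum[jstar]) / (c - jstar)
    return np.minimum(cap, (theta - b) / A)


def fit_crammer_singer(
    X: np.ndarray,
    y,
    penalty: float = 1.0,
    kernel: str | KernelSpec = "linear",
    gamma: float | None = None,
    bias: float | None = None,
    tol: float = 1e-6,
    max_epochs: int = 2000,
) -> MulticlassSVMModel:
    """Train the Crammer-Singer machine by cyclic block-coordinate descent.

    Parameters
    ----------
    X, y
        ``(M, q)`` feature matrix (typically discriminant-space scores) and
        M class labels (any hashable values; >= 2 distinct).
    penalty
        Margin-violation penalty C > 0.
    bias
        Additive term of the linear kernel.  None (default) sets it to the
        mean squared norm of the training points, so the implied intercept
        stays expressive whatever the feature scale; the resolved value is
        stored in the model's kernel.
    tol
        Stop when the largest per-example KKT violation (spread of the
        subproblem gradient over non-bound coordinates) falls below this.

    The cyclic visiting order makes the fit deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = X.shape[0]
    if len(y) != M:
        raise SVMError(f"{len(y)} labels for {M} rows")
    if penalty <= 0:
        raise SVMError(f"penalty C must be > 0, got {penalty}")
    class_labels: list = []
    seen: dict = {}
    yi = np.empty(M, dtype=int)
    for i, lab in enumerate(y):
        if lab not in seen:
            seen[lab] = len(class_labels)
            class_labels.append(lab)
        yi[i] = seen[lab]
    c = len(class_labels)
    if c < 2:
        raise SVMError("need at least 2 classes")
    if M < c:
        raise SVMError(f"need M >= c, got M={M}, c={c}")

    if isinstance(kernel, KernelSpec):
        spec = kernel
    else:
        if bias is None:
            bias = float(np.mean(np.sum(X**2, axis=1))) or 1.0
        spec = KernelSpec(kernel, gamma, bias)
    K = spec.matrix(X)
    E = np.ones((M, c))
    E[np.arange(M), yi] = 0.0            # e_i^m = 1 - delta_{y_i, m}
    cap = np.zeros((M, c))
    cap[np.arange(M), yi] = penalty      # alpha_i^m <= C delta

    alpha = np.zeros((M, c))
    G = np.zeros((M, c))                 # G = K @ alpha (i.e. w_m . x_i)

    for _epoch in range(max_epochs):
        max_viol = 0.0
        for i in range(M):
            Kii = K[i, i]
            d = G[i] + E[i]              # subproblem gradient at current alpha_i
            free = alpha[i] < cap[i] - 1e-12
            viol = d.max() - d[free].min() if free.any() else 0.0
            max_viol = max(max_viol, viol)
            if viol <= tol:
                continue
            if Kii <= 1e-12:
                # phi(x_i) ~ 0: dual contribution is linear; optimum pushes
                # the true-class variable to its cap, rest spread evenly.
                new = np.full(c, -penalty / (c - 1))
                new[yi[i]] = penalty
            else:
                b = d - Kii * alpha[i]
                new = _solve_subproblem(Kii, b, cap[i])
            delta = new - alpha[i]
            alpha[i] = new
            G += np.outer(K[:, i], delta)
        if max_viol <= tol:
            break

    return MulticlassSVMModel(
        alpha=alpha,
        training_points=X,
        y=yi,
        class_labels=class_labels,
        penalty=penalty,
        kernel=spec,
    )


def decision_scores(model: MulticlassSVMModel, x: np.ndarray) -> np.ndarray:
    """Per-class scores sum_i alpha_i^m K(x_i, x) for one or many points."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xq = np.atleast_2d(x)
    if Xq.shape[1] != model.training_points.shape[1]:
        raise SVMError(
            f"point has {Xq.shape[1]} features, model expects "
            f"{model.training_points.shape[1]}"
        )
    Kq = model.kernel.matrix(Xq, model.training_points)   # (n, M)
    S = Kq @ model.alpha                                  # (n, c)
    return S[0] if single else S


def predict(model: MulticlassSVMModel, x: np.ndarray):
    """Predict class label(s): argmax of the kernel-expansion scores.

    Exact ties go to the lowest class index (first label seen in training).
    """
    S = np.atleast_2d(decision_scores(model, x))
    idx = np.argmax(S, axis=1)           # argmax returns the first maximum
    labels = [model.class_labels[j] for j in idx]
    return labels[0] if np.asarray(x).ndim == 1 else labels


def dual_objective(model: MulticlassSVMModel) -> float:
    """Value of the dual objective at the fitted alpha (lower is better)."""
    K = model.kernel.matrix(model.training_points)
    E = np.ones_like(model.alpha)
    E[np.arange(len(model.y)), model.y] = 0.0
    quad = 0.5 * float(np.sum(model.alpha * (K @ model.alpha)))
    return quad + float(np.sum(E * model.alpha))
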