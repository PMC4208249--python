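"""Two-stage Fisher discriminant in the EigenOdour subspace.

Classical Fisher LDA maximizes |W^T S_B W| / |W^T S_W W|, which requires an
invertible within-class scatter S_W.  With M measurements of N sensors and
M << N, S_W (rank at most M - c for c classes) is always singular in sensor
space.  The remedy — the same one used by the "Fisherface" method — is a
two-stage projection: first reduce to p <= M - c directions of maximal total
scatter (the EigenOdour basis), where the projected S_W is invertible, then
solve the generalized eigenproblem S_B w = lambda S_W w there.  The composed
map W_opt = W_pca W_lda takes raw N-dimensional measurements straight to the
q <= c - 1 discriminant coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import eigenodour
from .eigenodour import EigenOdourModel, fit_eigenodours

__all__ = ["DiscriminantModel", "scatter_matrices", "fit_discriminant", "transform"]


class DiscriminantError(ValueError):
    pass


def _class_index(labels) -> tuple[list, np.ndarray]:
    """Map labels to integer codes in first-occurrence order."""
    order: list = []
    seen: dict = {}
    codes = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(order)
            order.append(lab)
        codes[i] = seen[lab]
    return order, codes


def scatter_matrices(scores: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Between-, within- and total-scatter matrices of labelled score vectors.

    S_B = sum_i M_i (mu_i - mu)(mu_i - mu)^T over the c classes,
    S_W = sum_i sum_{x in class i} (x - mu_i)(x - mu_i)^T,
    S_T = sum_k (x_k - mu)(x_k - mu)^T, with mu the global mean.
    The three satisfy S_T = S_B + S_W exactly.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise DiscriminantError(f"scores must be M x p, got {X.shape}")
    if len(labels) != X.shape[0]:
        raise DiscriminantError(f"{len(labels)} labels for {X.shape[0]} rows")
    order, codes = _class_index(labels)
    mu = X.mean(axis=0)
    p = X.shape[1]
    S_B = np.zeros((p, p))
    S_W = np.zeros((p, p))
    for c_idx in range(len(order)):
        Xi = X[codes == c_idx]
        if Xi.shape[0] == 0:
            raise DiscriminantError(f"empty class {order[c_idx]!r}")
        mu_i = Xi.mean(axis=0)
        d = mu_i - mu
        S_B += Xi.shape[0] * np.outer(d, d)
        D = Xi - mu_i
        S_W += D.T @ D
    D = X - mu
    S_T = D.T @ D
    return S_B, S_W, S_T


@dataclass
class DiscriminantModel:
    """Fitted two-stage discriminant projection.

    ``w_opt`` is the composed ``(N, q)`` map applied to centered raw
    measurements; ``w_lda`` the ``(p, q)`` stage-2 map applied to EigenOdour
    scores.  Scatter matrices live in the p-dimensional EigenOdour space.
    """

    class_labels: list
    class_means: np.ndarray      # (c, p) in EigenOdour space
    global_mean: np.ndarray      # (p,)
    class_counts: np.ndarray     # (c,)
    s_b: np.ndarray
    s_w: np.ndarray
    s_t: np.ndarray
    w_lda: np.ndarray            # (p, q)
    w_opt: np.ndarray            # (N, q)
    eigenvalues: np.ndarray      # (q,) generalized eigenvalues, descending
    eigen: EigenOdourModel       # stage-1 model (mean Psi, basis)

    @property
    def n_discriminants(self) -> int:
        return self.w_lda.shape[1]


def fit_discriminant(
    responses,
    labels=None,
    p: int | None = None,
    q: int | None = None,
    variance: float = 0.90,
) -> DiscriminantModel:
    """Fit EigenOdour reduction followed by Fisher LDA.

    Parameters
    ----------
    responses
        ``(M, N)`` matrix or ResponseMatrix (its labels are used when
        ``labels`` is None).
    p
        Stage-1 dimensionality.  Default: the smaller of M - c (the rank
        bound guaranteeing an invertible projected S_W) and the component
        count reaching the ``variance`` fraction.
    q
        Number of discriminant directions retained; at most c - 1 (the rank
        of S_B).  Default c - 1.
    """
    X = np.asarray(getattr(responses, "values", responses), dtype=float)
    if labels is None:
        labels = getattr(responses, "labels", None)
    if not labels:
        raise DiscriminantError("labels are required")
    M = X.shape[0]
    order, codes = _class_index(labels)
    c = len(order)
    if c < 2:
        raise DiscriminantError("need at least 2 classes")
    if M - c < 1:
        raise DiscriminantError(f"M = {M} measurements cannot support {c} classes")

    if p is None:
        probe = fit_eigenodours(X, components=variance)
        p = min(M - c, probe.n_components)
        p = max(p, 1)
    elif p > M - c:
        raise DiscriminantError(
            f"p = {p} exceeds M - c = {M - c}: the projected within-class "
            f"scatter (rank at most M - c) would be singular"
        )
    if q is None:
        q = c - 1
    elif q > c - 1:
        raise DiscriminantError(
            f"q = {q} exceeds c - 1 = {c - 1}, the rank bound of the "
            f"between-class scatter"
        )

    eig = fit_eigenodours(X, components=int(p))
    scores = eigenodour.project(eig, X)          # (M, p_eff)
    S_B, S_W, S_T = scatter_matrices(scores, labels)

    # Generalized symmetric eigenproblem S_B w = lambda S_W w.  Jitter the
    # within-class scatter if it is marginally singular so Cholesky-based
    # reduction stays stable without changing well-posed results.
    p_eff = scores.shape[1]
    S_W_reg = S_W
    try:
        scipy.linalg.cholesky(S_W)
    except scipy.linalg.LinAlgError:
        # scale the jitter from the total scatter so a vanishing S_W (e.g.
        # duplicated measurements within classes) stays well conditioned
        scale = max(np.trace(S_W), np.trace(S_B), 1.0)
        jitter = 1e-10 * scale / max(p_eff, 1)
        S_W_reg = S_W + jitter * np.eye(p_eff)
    vals, vecs = scipy.linalg.eigh(S_B, S_W_reg)
    idx = np.argsort(vals)[::-1][: min(q, p_eff)]
    vals = np.clip(vals[idx], 0.0, None)
    W_lda = vecs[:, idx].copy()
    # eigh returns S_W-normalized vectors whose length diverges as the
    # within-class scatter degenerates; only the direction is meaningful,
    # so renormalize every discriminant direction to unit length
    norms = np.linalg.norm(W_lda, axis=0)
    norms[norms == 0] = 1.0
    W_lda /= norms
    eigenodour._fix_signs(W_lda, [])

    class_means = np.vstack([scores[codes == i].mean(axis=0) for i in range(c)])
    counts = np.bincount(codes, minlength=c)

    return DiscriminantModel(
        class_labels=order,
        class_means=class_means,
        global_mean=scores.mean(axis=0),
        class_counts=counts,
        s_b=S_B,
        s_w=S_W,
        s_t=S_T,
        w_lda=W_lda,
        w_opt=eig.basis @ W_lda,
        eigenvalues=vals,
        eigen=eig,
    )


def transform(model: DiscriminantModel, measurement: np.ndarray) -> np.ndarray:
    """Map raw sensor-space measurement(s) to discriminant coordinates.

    Equals applying the stage-2 LDA map to the EigenOdour scores:
    ``W_opt^T (y - Psi)``.
    """
    y = np.asarray(measurement, dtype=float)
    if y.shape[-1] != model.eigen.mean.shape[0]:
        raise DiscriminantError(
            f"measurement has {y.shape[-1]} sensors, model expects "
            f"{model.eigen.mean.shape[0]}"
        )
    return (y - model.eigen.mean) @ model.w_opt
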