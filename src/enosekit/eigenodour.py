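"""Snapshot PCA for sensor arrays: the EigenOdour decomposition.

With M measurements of N sensors and M << N (tens of measurements against
16k+ sensors), the N x N response covariance C = (1/M) sum_i Phi_i Phi_i^T is
rank-deficient: at most M - 1 eigenvectors carry variance after centering.
The snapshot (Gram-matrix) trick — familiar from the eigenface method in
face recognition — recovers exactly those directions from the small M x M
Gram matrix L, L_mn = Phi_m^T Phi_n: if L v = mu v then u = A v, with
A = [Phi_1 ... Phi_M], is an eigenvector of A A^T with the same eigenvalue.
The lifted vectors, renormalized to unit length, form the orthonormal
EigenOdour basis onto which measurements are projected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EigenOdourModel", "fit_eigenodours", "project", "cumulative_variance"]

#: Relative threshold below which a Gram eigenvalue is treated as numerically
#: zero (rank decisions, component retention).
_RANK_TOL = 1e-10


class EigenOdourError(ValueError):
    """Invalid parameters or degenerate spectrum in the snapshot PCA."""


@dataclass
class EigenOdourModel:
    """Fitted EigenOdour basis.

    ``mean`` is the average measurement Psi; ``basis`` the ``(N, p)`` matrix
    of orthonormal EigenOdours (descending variance); ``eigenvalues`` the
    corresponding covariance eigenvalues (Gram eigenvalues divided by M, so
    they match the 1/M-normalized covariance); ``spectrum`` the full positive
    covariance spectrum before truncation, kept so variance fractions do not
    depend on how many components were retained; ``gram_eigenvectors`` the
    ``(M, p)`` Gram-space eigenvectors the basis was lifted from.
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    basis: np.ndarray
    gram_eigenvectors: np.ndarray
    spectrum: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)


def _fix_signs(basis: np.ndarray, companions: list[np.ndarray]) -> None:
    """Flip columns in place so each one's largest-|coefficient| entry is > 0.

    Eigenvector sign is arbitrary; this convention makes serialized models
    reproducible.  ``companions`` are flipped consistently.
    """
    for j in range(basis.shape[1]):
        col = basis[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            basis[:, j] = -col
            for other in companions:
                other[:, j] = -other[:, j]


def fit_eigenodours(
    responses,
    components: int | float = 0.90,
) -> EigenOdourModel:
    """Fit the EigenOdour basis to an M x N response matrix.

    Parameters
    ----------
    responses
        ``(M, N)`` array or a :class:`~enosekit.containers.ResponseMatrix`.
    components
        Either an explicit component count (int) or a cumulative-variance
        fraction in (0, 1] — the smallest p whose retained variance reaches
        that fraction is kept.  Default 0.90: on the reference device's
        41-measurement mixture dataset ~90% of the variance sits in the
        first 15 EigenOdours, so this is the natural operating point.
    """
    X = np.asarray(getattr(responses, "values", responses), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise EigenOdourError(f"need an M x N matrix with M >= 2, got {X.shape}")
    M = X.shape[0]

    psi = X.mean(axis=0)
    Phi = X - psi                      # rows are Phi_i^T
    L = Phi @ Phi.T                    # Gram matrix, L_mn = Phi_m . Phi_n
    gram_vals, gram_vecs = np.linalg.eigh(L)
    order = np.argsort(gram_vals)[::-1]
    gram_vals = gram_vals[order]
    gram_vecs = gram_vecs[:, order]

    # Centering removes one dimension; also drop numerically-zero modes.
    cutoff = max(gram_vals[0], 0.0) * _RANK_TOL if gram_vals.size else 0.0
    rank = int(np.sum(gram_vals > cutoff))
    rank = min(rank, M - 1)
    gram_vals = np.clip(gram_vals[:rank], 0.0, None)
    gram_vecs = gram_vecs[:, :rank]
    spectrum = gram_vals / M           # covariance-scale eigenvalues

    if isinstance(components, (int, np.integer)) and not isinstance(components, bool):
        p = int(components)
        if p > M - 1:
            raise EigenOdourError(
                f"requested {p} components but only M - 1 = {M - 1} are meaningful"
            )
        if p < 0:
            raise EigenOdourError("component count must be >= 0")
        p = min(p, rank)
    else:
        frac = float(components)
        if not 0.0 < frac <= 1.0:
            raise EigenOdourError(
                f"variance fraction must be in (0, 1], got {frac}"
            )
        if rank == 0:
            p = 0
        else:
            cum = np.cumsum(spectrum) / spectrum.sum()
            p = int(np.searchsorted(cum, frac - 1e-12) + 1)
            p = min(p, rank)

    # Lift Gram eigenvectors to sensor space: u_l = sum_k v_lk Phi_k.
    basis = Phi.T @ gram_vecs[:, :p]
    norms = np.linalg.norm(basis, axis=0)
    norms[norms == 0] = 1.0
    basis /= norms
    gvec = gram_vecs[:, :p].copy()
    _fix_signs(basis, [gvec])

    return EigenOdourModel(
        mean=psi,
        eigenvalues=spectrum[:p].copy(),
        basis=basis,
        gram_eigenvectors=gvec,
        spectrum=spectrum,
        n_components=p,
    )


def project(model: EigenOdourModel, measurement: np.ndarray) -> np.ndarray:
    """Project a measurement (or ``(m, N)`` stack) into EigenOdour scores.

    Returns ``basis^T (y - Psi)``: a length-p score vector per measurement.
    """
    y = np.asarray(measurement, dtype=float)
    if y.shape[-1] != model.mean.shape[0]:
        raise EigenOdourError(
            f"measurement has {y.shape[-1]} sensors, model expects "
            f"{model.mean.shape[0]}"
        )
    return (y - model.mean) @ model.basis


def cumulative_variance(model: EigenOdourModel) -> np.ndarray:
    """Fraction of total variance captured by the first 1, 2, ... components.

    Computed over the full positive spectrum (not just retained components),
    so the sequence is non-decreasing and ends at 1.
    """
    if model.spectrum.size == 0 or model.spectrum.sum() <= 0:
        raise EigenOdourError("spectrum has no positive eigenvalues")
    return np.cumsum(model.spectrum) / model.spectrum.sum()
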