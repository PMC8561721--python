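"""Procrustes matching of two sample configurations.

Two I x K point configurations describing the same samples can differ by
translation, scale and rotation without differing in the distance structure
they encode.  Procrustes analysis removes those three nuisances by least
squares: centre the columns, scale each matrix to unit total sum of
squares, and rotate one onto the other using the SVD of their
cross-product.  The residual sum of squares E of the scaled fit lies in
[0, 1]; the Procrustes correlation R = sqrt(1 - E) = trace(D) (the sum of
the cross-product's singular values) measures how close the two geometries
are to being similar — R = 1 means one is an exact similarity transform of
the other (isometry after standardisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SampleConfiguration

__all__ = ["ProcrustesResult", "standardize", "procrustes_fit"]


@dataclass
class ProcrustesResult:
    """Outcome of fitting configuration Y to configuration X.

    R = trace(D) = sqrt(1 - E) is symmetric in the two configurations; the
    rotation Q = V U^T (which maps the standardised Y onto X) depends on the
    direction and is best-effort when singular values are tied.
    """

    R: float
    E: float
    Q: np.ndarray
    singular_values: np.ndarray
    direction: str = "Y onto X"

    @property
    def K(self) -> int:
        return self.Q.shape[0]


def _as_matrix(config) -> np.ndarray:
    if isinstance(config, SampleConfiguration):
        return np.asarray(config.coordinates, dtype=float)
    M = np.asarray(config, dtype=float)
    if M.ndim != 2:
        raise ValueError("a configuration must be a 2-D coordinate matrix")
    return M


def standardize(config) -> np.ndarray:
    """Centre the columns and scale to unit total sum of squares.

    Idempotent on already-standardised input; rejects a degenerate
    configuration whose points all coincide (zero sum of squares).
    """
    M = _as_matrix(config)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardise a configuration")
    M = M - M.mean(axis=0, keepdims=True)
    ss = np.sqrt(np.sum(M**2))
    if ss == 0:
        raise ValueError("degenerate configuration: all points coincide (zero sum of squares)")
    return M / ss


def _pad_to(M: np.ndarray, K: int) -> np.ndarray:
    if M.shape[1] == K:
        return M
    out = np.zeros((M.shape[0], K))
    out[:, : M.shape[1]] = M
    return out


def procrustes_fit(X, Y) -> ProcrustesResult:
    """Fit configuration Y to configuration X and compute the correlation R.

    With X*, Y* the standardised matrices, the SVD (X*)^T Y* = U D V^T gives
    the optimal rotation Q = V U^T of Y*; the scaled residual is
    E = 1 - (trace D)^2 and R = trace(D) = sqrt(1 - E).  R equals the
    Pearson correlation between the entries of X* and Y* Q strung out as
    IK-vectors, and is invariant to which configuration is fitted to which.
    """
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError(f"configurations have different sample counts: {Xm.shape[0]} vs {Ym.shape[0]}")
    K = max(Xm.shape[1], Ym.shape[1])
    Xs = _pad_to(standardize(Xm), K)
    Ys = _pad_to(standardize(Ym), K)
    U, d, Vt = np.linalg.svd(Xs.T @ Ys)
    Q = Vt.T @ U.T
    R = float(d.sum())
    R = min(R, 1.0)  # guard: trace(D) <= 1 analytically; clip roundoff
    return ProcrustesResult(R=R, E=1.0 - R * R, Q=Q, singular_values=d)
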