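"""Sample geometry: exact logratio geometry (LRA) and ALR geometry (PCA).

A compositional table induces an exact Euclidean geometry on its samples —
the logratio distances, computable either on all pairwise logratios or,
equivalently, on the CLR rows.  Logratio analysis (LRA) is the PCA of that
geometry; the approximate geometry of a set of additive logratios is
obtained by ordinary PCA of the (column-centred) ALR matrix.  Both live in
a space of dimensionality K = min(I-1, J-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist

from .compositions import CompositionTable, LogratioMatrix, clr

__all__ = [
    "SampleConfiguration",
    "DistanceComparison",
    "lra",
    "pca_configuration",
    "logratio_distances",
    "distance_comparison",
]

#: singular values below this fraction of the largest are treated as zero
RANK_TOL = 1e-12


@dataclass
class SampleConfiguration:
    """Principal coordinates of I samples in a K-dimensional Euclidean space.

    ``coordinates`` is I x K with K = min(I-1, J-1), zero-padded when the
    numerical rank is lower.  Inter-row Euclidean distances reproduce the
    geometry the configuration was built from (logratio distances for
    ``source='lra'``, centred-ALR distances for ``source='pca_of_alr'``).
    ``total_variance`` is sum of squared coordinates / I and equals the sum
    of squared singular values.
    """

    coordinates: np.ndarray
    singular_values: np.ndarray
    explained: np.ndarray
    source: Literal["lra", "pca_of_alr"]
    sample_ids: list[str]

    @property
    def K(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_samples(self) -> int:
        return self.coordinates.shape[0]

    @property
    def total_variance(self) -> float:
        return float(np.sum(self.coordinates**2) / self.n_samples)

    def distances(self) -> np.ndarray:
        """Condensed (i < i') inter-sample Euclidean distances."""
        return pdist(self.coordinates)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.coordinates,
            index=self.sample_ids,
            columns=[f"axis{k + 1}" for k in range(self.K)],
        )


def _orient_axes(U: np.ndarray) -> np.ndarray:
    """Sign convention: flip each axis so its largest-|u| entry is positive."""
    flip = np.ones(U.shape[1])
    for k in range(U.shape[1]):
        col = U[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            flip[k] = -1.0
    return flip


def _decompose(S: np.ndarray, K: int, I: int, sample_ids, source) -> SampleConfiguration:
    """Shared SVD -> principal-coordinate machinery.

    S is the (mass-scaled) centred matrix whose row geometry is wanted;
    principal coordinates are sqrt(I) * U * Sigma, truncated/padded to K.
    """
    U, s, _ = np.linalg.svd(S, full_matrices=False)
    if s.size and s[0] > 0:
        s = np.where(s < RANK_TOL * s[0], 0.0, s)
    r = min(K, s.size)
    U, s = U[:, :r], s[:r]
    U = U * _orient_axes(U)[None, :]
    coords = np.zeros((I, K))
    coords[:, :r] = np.sqrt(I) * U * s[None, :]
    sv = np.zeros(K)
    sv[:r] = s
    ss = float(np.sum(sv**2))
    explained = sv**2 / ss if ss > 0 else np.zeros(K)
    return SampleConfiguration(
        coordinates=coords,
        singular_values=sv,
        explained=explained,
        source=source,
        sample_ids=list(sample_ids),
    )


def lra(table: CompositionTable) -> SampleConfiguration:
    """Logratio analysis: PCA of all pairwise logratios, via the CLRs.

    The (weighted) CLR matrix is column-centred, scaled by the row masses
    1/I and the component weights c_j, and decomposed by SVD.  The
    coordinates reproduce the logratio distances exactly, the squared
    singular values are the per-axis variances, and their sum is the total
    logratio variance.  With equal weights this is plain PCA of the CLRs.
    """
    Z = clr(table).values
    Zc = Z - Z.mean(axis=0, keepdims=True)
    I, J = Zc.shape
    K = min(I - 1, J - 1)
    S = (Zc * np.sqrt(table.weights)[None, :]) / np.sqrt(I)
    return _decompose(S, K, I, table.sample_ids, "lra")


def pca_configuration(lr: LogratioMatrix) -> SampleConfiguration:
    """PCA of a logratio matrix (typically a set of ALRs).

    The matrix is column-centred with equal weighting of its J-1 variables
    and decomposed by SVD; coordinates are padded to K = min(I-1, J-1)
    columns so the configuration is directly comparable with the exact one.
    Inter-row distances equal the Euclidean distances on the centred matrix.
    """
    if lr.kind not in ("alr", "clr", "pairwise"):
        raise ValueError(f"cannot build a configuration from kind {lr.kind!r}")
    A = np.asarray(lr.values, dtype=float)
    Ac = A - A.mean(axis=0, keepdims=True)
    I, m = Ac.shape
    if lr.kind == "alr":
        K = min(I - 1, m)  # m = J - 1
    else:
        K = min(I - 1, m - 1) if m > 1 else 1
    return _decompose(Ac / np.sqrt(I), K, I, lr.sample_ids, "pca_of_alr")


def logratio_distances(table: CompositionTable) -> np.ndarray:
    """Exact logratio distances between every pair of samples.

    d(i, i') = sqrt( sum_j c_j (CLR_ij - CLR_i'j)^2 ), identical to the
    c_j c_k - weighted Euclidean distance on all pairwise logratios.
    Returned condensed, unordered pairs in (i < i') order (I(I-1)/2 values).
    """
    Z = clr(table).values
    return pdist(Z * np.sqrt(table.weights)[None, :])


@dataclass
class DistanceComparison:
    """Paired exact vs approximate inter-sample distances with summaries."""

    exact: np.ndarray
    approx: np.ndarray
    pearson_r: float
    max_relative_deviation: float

    @property
    def n_pairs(self) -> int:
        return self.exact.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"exact": self.exact, "approx": self.approx})


def distance_comparison(exact: np.ndarray, approx: np.ndarray) -> DistanceComparison:
    """Pair up two condensed distance vectors over the same samples.

    Diagnostic companion to the distance-vs-distance scatter: reports the
    Pearson correlation of the paired distances and the maximum relative
    deviation |approx - exact| / max(exact).
    """
    exact = np.asarray(exact, dtype=float).ravel()
    approx = np.asarray(approx, dtype=float).ravel()
    if exact.shape != approx.shape:
        raise ValueError(f"mismatched lengths: {exact.size} exact vs {approx.size} approximate")
    if exact.size == 0:
        raise ValueError("no distance pairs to compare")
    if np.ptp(exact) == 0 or np.ptp(approx) == 0:
        r = 1.0 if np.allclose(exact, approx) else 0.0
    else:
        r = float(np.corrcoef(exact, approx)[0, 1])
    scale = float(exact.max())
    maxdev = float(np.max(np.abs(approx - exact)) / scale) if scale > 0 else 0.0
    return DistanceComparison(exact=exact, approx=approx, pearson_r=r, max_relative_deviation=maxdev)
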