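"""Compositional data containers and logratio transforms.

A composition is a vector of non-negative parts carrying only relative
information: multiplying a sample by any positive constant changes nothing
of interest.  All analysis therefore goes through logratios, which are
invariant to such rescaling (and to closure, the normalisation of each
sample to unit sum).

This module provides the :class:`CompositionTable` container, the closure,
CLR (centred logratio), ALR (additive logratio) and pairwise-logratio
transforms, multiplicative/Bayesian zero replacement, and the total
logratio variance computed by three equivalent routes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CompositionTable",
    "LogratioMatrix",
    "VarianceDecomposition",
    "ZeroReplacementInfo",
    "close",
    "clr",
    "alr",
    "pairwise_logratios",
    "total_logratio_variance",
    "replace_zeros",
    "abundance_weights",
]

#: default cap on J for the explicit pairwise expansion (J(J-1)/2 columns)
PAIRWISE_CAP = 200

_LOG_BASES = {"e": 1.0, "2": math.log(2.0), "10": math.log(10.0)}


def _log_scale(base: str | float) -> float:
    """Return ln(base); logratios in base b are natural logratios / ln(b)."""
    if isinstance(base, str):
        try:
            return _LOG_BASES[base]
        except KeyError:
            raise ValueError(f"unknown log base {base!r}; use 'e', '2' or '10'") from None
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    return math.log(base)


@dataclass
class CompositionTable:
    """An I x J table of strictly positive relative abundances.

    Parameters
    ----------
    values
        I x J matrix of abundances (counts or intensities).  Zeros are
        tolerated on construction so that raw data can be loaded before
        :func:`replace_zeros`, but every logratio transform requires
        strict positivity.
    sample_ids, component_labels
        Unique row / column labels.
    weights
        J positive component weights c_j summing to 1.  Defaults to equal
        weighting c_j = 1/J.
    """

    values: np.ndarray
    sample_ids: list[str]
    component_labels: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        I, J = self.values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.component_labels = [str(c) for c in self.component_labels]
        if len(self.sample_ids) != I:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {I} rows")
        if len(self.component_labels) != J:
            raise ValueError(f"{len(self.component_labels)} component labels for {J} columns")
        if len(set(self.sample_ids)) != I:
            raise ValueError("duplicate sample IDs")
        if len(set(self.component_labels)) != J:
            raise ValueError("duplicate component labels")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"component {self.component_labels[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value {self.values[i, j]} at sample {self.sample_ids[i]!r}, "
                f"component {self.component_labels[j]!r}; abundances must be non-negative"
            )
        if self.weights is None:
            self.weights = np.full(J, 1.0 / J)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (J,):
                raise ValueError(f"weights must have length J={J}")
            if np.any(self.weights <= 0):
                raise ValueError("all component weights must be positive")
            if abs(self.weights.sum() - 1.0) > 1e-12:
                raise ValueError("component weights must sum to 1 (within 1e-12)")

    # -- basic descriptors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def has_zeros(self) -> bool:
        return bool(np.any(self.values == 0))

    def component_index(self, ref: str | int) -> int:
        """Resolve a component given by label or 0-based integer position."""
        if isinstance(ref, (int, np.integer)):
            j = int(ref)
            if not 0 <= j < self.n_components:
                raise KeyError(f"component index {j} out of range [0, {self.n_components})")
            return j
        try:
            return self.component_labels.index(ref)
        except ValueError:
            raise KeyError(f"unknown component label {ref!r}") from None

    def _require_positive(self, op: str) -> None:
        if self.has_zeros():
            raise ValueError(
                f"{op} requires strictly positive values; the table contains zeros "
                "(run replace_zeros first)"
            )

    # -- convenience -------------------------------------------------------
    def relative_abundances(self) -> np.ndarray:
        """Closed values: each row divided by its sum."""
        sums = self.values.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("a sample row sums to zero; cannot close")
        return self.values / sums[:, None]

    def subset_components(self, which: Sequence[str | int]) -> "CompositionTable":
        """Restrict to a subcomposition; weights are renormalised."""
        idx = [self.component_index(w) for w in which]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate components in subset")
        w = self.weights[idx]
        return CompositionTable(
            self.values[:, idx],
            list(self.sample_ids),
            [self.component_labels[j] for j in idx],
            w / w.sum(),
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.component_labels)

    @classmethod
    def from_dataframe(cls, df, weights=None) -> "CompositionTable":
        return cls(df.to_numpy(dtype=float), list(map(str, df.index)), list(map(str, df.columns)), weights)


@dataclass
class LogratioMatrix:
    """A derived matrix of logratios.

    ``kind`` is one of ``clr`` (I x J, weighted row sums zero), ``alr``
    (I x (J-1) with a named reference) or ``pairwise`` (I x J(J-1)/2, each
    unordered pair once in j<k order).  Column labels encode the ratio as
    ``"num/den"`` for alr/pairwise columns.
    """

    values: np.ndarray
    kind: Literal["clr", "alr", "pairwise"]
    sample_ids: list[str]
    numerator_labels: list[str]
    denominator_labels: list[str] | None = None
    reference: str | None = None
    log_base: str | float = "e"

    @property
    def column_labels(self) -> list[str]:
        if self.kind == "clr":
            return list(self.numerator_labels)
        return [f"{n}/{d}" for n, d in zip(self.numerator_labels, self.denominator_labels)]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.column_labels)


@dataclass
class VarianceDecomposition:
    """Total logratio variance and its per-part decomposition.

    ``total`` is the weight-averaged variance in squared-log units; routes
    ``pairwise`` (sum over c_j c_k Var log(X_j/X_k)), ``clr`` (sum over
    c_j Var CLR_j) and ``transpose`` (the same computation on the closed
    transpose) agree to numerical precision.
    """

    total: float
    route: Literal["pairwise", "clr", "transpose"]
    per_clr: np.ndarray | None = None
    per_pair: np.ndarray | None = None
    pair_labels: list[tuple[str, str]] | None = None


@dataclass
class ZeroReplacementInfo:
    method: str
    n_zeros: int
    zeros_per_component: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def close(table: CompositionTable) -> CompositionTable:
    """Normalise every sample to unit sum (closure).

    Logratios are invariant to closure, so this is presentational: it puts
    all samples on the relative-abundance scale.
    """
    table._require_positive("close")
    return _dc_replace(table, values=table.relative_abundances())


def clr(table: CompositionTable, log_base: str | float = "e") -> LogratioMatrix:
    """Centred logratio transform.

    CLR(j) = log X_j - sum_k c_k log X_k, the log of each part relative to
    the weighted geometric mean of all parts.  With equal weights this is
    the ordinary CLR; rows satisfy sum_j c_j CLR(i, j) = 0.
    """
    table._require_positive("clr")
    scale = _log_scale(log_base)
    L = np.log(table.values) / scale
    row_means = L @ table.weights
    return LogratioMatrix(
        values=L - row_means[:, None],
        kind="clr",
        sample_ids=list(table.sample_ids),
        numerator_labels=list(table.component_labels),
        log_base=log_base,
    )


def alr(table: CompositionTable, ref: str | int, log_base: str | float = "e") -> LogratioMatrix:
    """Additive logratio transform with respect to a reference component.

    ALR(j | ref) = log(X_j / X_ref) for the J-1 components j != ref.
    Invariant to closure and to any per-sample rescaling.
    """
    table._require_positive("alr")
    r = table.component_index(ref)
    scale = _log_scale(log_base)
    L = np.log(table.values) / scale
    keep = [j for j in range(table.n_components) if j != r]
    ref_label = table.component_labels[r]
    return LogratioMatrix(
        values=L[:, keep] - L[:, [r]],
        kind="alr",
        sample_ids=list(table.sample_ids),
        numerator_labels=[table.component_labels[j] for j in keep],
        denominator_labels=[ref_label] * len(keep),
        reference=ref_label,
        log_base=log_base,
    )


def pairwise_logratios(
    table: CompositionTable,
    cap: int = PAIRWISE_CAP,
    force: bool = False,
    log_base: str | float = "e",
) -> LogratioMatrix:
    """All J(J-1)/2 pairwise logratios log(X_j / X_k), unordered pairs j<k.

    The expansion is quadratic in J and only intended for small tables;
    tables with J > ``cap`` are refused unless ``force`` is set (the CLR
    representation carries the same geometry in J columns).
    """
    table._require_positive("pairwise_logratios")
    J = table.n_components
    if J > cap and not force:
        raise ValueError(
            f"pairwise expansion refused for J={J} > cap={cap} "
            f"({J * (J - 1) // 2} columns); pass force=True to override"
        )
    scale = _log_scale(log_base)
    L = np.log(table.values) / scale
    jj, kk = np.triu_indices(J, k=1)
    labels = table.component_labels
    return LogratioMatrix(
        values=L[:, jj] - L[:, kk],
        kind="pairwise",
        sample_ids=list(table.sample_ids),
        numerator_labels=[labels[j] for j in jj],
        denominator_labels=[labels[k] for k in kk],
        log_base=log_base,
    )


# ---------------------------------------------------------------------------
# total logratio variance
# ---------------------------------------------------------------------------

def _popvar(M: np.ndarray) -> np.ndarray:
    """Column variances with the population divisor I.

    The population form makes the transpose shortcut an exact identity:
    the double-centred log matrix yields TotVar = ||.||_F^2 / (I*J)
    symmetrically in rows and columns.
    """
    return M.var(axis=0, ddof=0)


def total_logratio_variance(
    table: CompositionTable,
    route: Literal["pairwise", "clr", "transpose"] = "clr",
    cap: int = PAIRWISE_CAP,
    force: bool = False,
    log_base: str | float = "e",
) -> VarianceDecomposition:
    """Total logratio variance, the dispersion of the samples in logratio space.

    Routes:

    ``pairwise``
        TotVar = sum_{j<k} c_j c_k Var log(X_j/X_k) — the defining form.
    ``clr``
        TotVar = sum_j c_j Var CLR_j — algebraically identical, linear in J.
    ``transpose``
        Close the transposed matrix over component totals and apply the clr
        route with the samples as equally weighted parts; valid for equal
        component weights, where the computation is row/column symmetric.

    All routes use the population variance divisor and agree to ~1e-10
    relative.  Being weight-averaged, TotVar is comparable across datasets
    of different sizes.
    """
    if route == "pairwise":
        lr = pairwise_logratios(table, cap=cap, force=force, log_base=log_base)
        per_pair = _popvar(lr.values)
        jj, kk = np.triu_indices(table.n_components, k=1)
        w = table.weights
        total = float(np.sum(w[jj] * w[kk] * per_pair))
        return VarianceDecomposition(
            total=total,
            route="pairwise",
            per_pair=per_pair,
            pair_labels=list(zip(lr.numerator_labels, lr.denominator_labels)),
        )
    if route == "clr":
        per_clr = _popvar(clr(table, log_base=log_base).values)
        total = float(per_clr @ table.weights)
        return VarianceDecomposition(total=total, route="clr", per_clr=per_clr)
    if route == "transpose":
        if not np.allclose(table.weights, 1.0 / table.n_components, atol=1e-12):
            raise ValueError("the transpose shortcut applies to equally weighted components only")
        table._require_positive("total_logratio_variance")
        vt = table.values.T  # J x I, rows are components
        flipped = CompositionTable(
            vt / vt.sum(axis=1, keepdims=True),
            sample_ids=list(table.component_labels),
            component_labels=list(table.sample_ids),
        )
        per_clr_samples = _popvar(clr(flipped, log_base=log_base).values)
        total = float(per_clr_samples.mean())
        return VarianceDecomposition(total=total, route="transpose", per_clr=per_clr_samples)
    raise ValueError(f"unknown route {route!r}")


# ---------------------------------------------------------------------------
# zero replacement
# ---------------------------------------------------------------------------

def replace_zeros(
    table: CompositionTable,
    method: Literal["multiplicative", "bayes"] = "multiplicative",
    delta_fraction: float = 0.65,
    prior_strength: float = 1.0,
) -> tuple[CompositionTable, ZeroReplacementInfo]:
    """Replace zero counts so logratios become defined.

    ``multiplicative``
        Each zero cell in column j is imputed at delta_j = ``delta_fraction``
        times the smallest positive relative abundance observed for that
        component, expressed on the row's own total; the nonzero parts of the
        row are shrunk by a common factor so the row total is preserved.
        Because the adjustment of the nonzero parts is a single multiplier
        per row, all pairwise logratios among nonzero parts are untouched.
    ``bayes``
        Bayesian-multiplicative replacement: zeros are imputed at the
        posterior expected proportion under a Dirichlet prior with strength
        ``prior_strength`` and prior means equal to the observed mean
        relative abundances; nonzeros are again adjusted multiplicatively.
        Provided for closer agreement with count-based replacement methods;
        both are deterministic.

    Returns the strictly positive table and a :class:`ZeroReplacementInfo`
    recording the input's zero counts (per component and overall).
    """
    X = table.values
    zero_mask = X == 0
    info = ZeroReplacementInfo(
        method=method,
        n_zeros=int(zero_mask.sum()),
        zeros_per_component=zero_mask.sum(axis=0).astype(int),
    )
    if info.n_zeros == 0:
        return table, info
    if np.any(zero_mask.all(axis=1)):
        i = int(np.argwhere(zero_mask.all(axis=1))[0, 0])
        raise ValueError(f"sample {table.sample_ids[i]!r} is all zeros; no information to impute")
    if np.any(zero_mask.all(axis=0)):
        j = int(np.argwhere(zero_mask.all(axis=0))[0, 0])
        raise ValueError(
            f"component {table.component_labels[j]!r} is zero in every sample; drop it first"
        )

    row_sums = X.sum(axis=1)
    P = X / row_sums[:, None]
    if method == "multiplicative":
        col_min_pos = np.where(zero_mask, np.inf, P).min(axis=0)
        delta = delta_fraction * col_min_pos  # per-component imputed proportion
        D = np.where(zero_mask, delta[None, :], 0.0)
    elif method == "bayes":
        prior_mean = P.mean(axis=0)
        prior_mean = prior_mean / prior_mean.sum()
        s = prior_strength
        post_zero = (s * prior_mean[None, :]) / (row_sums[:, None] + s)
        D = np.where(zero_mask, post_zero, 0.0)
    else:
        raise ValueError(f"unknown zero-replacement method {method!r}")

    imputed_total = D.sum(axis=1)
    if np.any(imputed_total >= 1):
        raise ValueError("imputed proportions exceed the row total; lower delta_fraction")
    # shrink nonzeros by a common per-row factor: ratios among them unchanged
    newP = P * (1.0 - imputed_total)[:, None] + D
    new_values = newP * row_sums[:, None]
    return _dc_replace(table, values=new_values), info


def abundance_weights(table: CompositionTable) -> np.ndarray:
    """Lewi's default weights: mean relative abundances of the components."""
    w = table.relative_abundances().mean(axis=0)
    return w / w.sum()
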