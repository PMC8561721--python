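"""Deterministic synthetic compositions for testing and simulation.

The generator emulates the structure the reference-selection method
assumes: a high-dimensional composition whose components have log-normal
abundances with heterogeneous baseline levels, among which a few
"planted" components are nearly constant in relative abundance and hence
make good ALR references.  Optional structural zeros (confined to
low-abundance components) and a two-group mean shift let the I/O, zero
replacement and ordination layers be exercised without any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compositions import CompositionTable

__all__ = ["SyntheticSpec", "SyntheticGroundTruth", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of the log-normal abundance model.

    X_ij = exp(mu_j + delta_gj + eps_ij) with mu_j ~ N(mu0, log_mean_spread^2)
    fixed per component, eps_ij ~ N(0, noise_sd^2) per cell, and the planted
    reference components given per-cell noise noise_sd / 20 so their log
    relative abundances have (by far) the smallest variances.

    Defaults describe a moderate-size omics table: 30 samples by 300
    components, component baselines spread over 1 natural-log unit
    (abundances spanning roughly two to three orders of magnitude), per-cell
    biological noise of 0.5 on the log scale, and 3 planted near-constant
    references.  The baseline spread is kept moderate so that no single
    component dominates the sample totals: a dominant part's own relative
    abundance is pinned near 1 and hence artificially constant, which is a
    different phenomenon from the low-variance references the model plants.
    """

    I: int = 30
    J: int = 300
    log_mean_spread: float = 1.0
    noise_sd: float = 0.5
    near_constant_refs: int = 3
    zero_fraction: float = 0.0
    group_shift: float | None = None
    group_shift_fraction: float = 0.2
    baseline_log_mean: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.I < 2 or self.J < 3:
            raise ValueError("need I >= 2 samples and J >= 3 components")
        if self.log_mean_spread < 0 or self.noise_sd <= 0:
            raise ValueError("log_mean_spread must be >= 0 and noise_sd > 0")
        if not 0 <= self.near_constant_refs <= self.J:
            raise ValueError("near_constant_refs outside [0, J]")
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValueError("zero_fraction must be in [0, 1)")
        if not 0.0 < self.group_shift_fraction <= 1.0:
            raise ValueError("group_shift_fraction must be in (0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Sidecar recording what was planted in a generated table."""

    planted_indices: list[int]  # 1-based input positions of planted references
    planted_labels: list[str]
    group_labels: list[str] = field(default_factory=list)
    shifted_indices: list[int] = field(default_factory=list)
    n_zeroed_cells: int = 0

    def as_dict(self) -> dict:
        return {
            "planted_indices": self.planted_indices,
            "planted_labels": self.planted_labels,
            "group_labels": self.group_labels,
            "shifted_indices": self.shifted_indices,
            "n_zeroed_cells": self.n_zeroed_cells,
        }


def generate(spec: SyntheticSpec) -> tuple[CompositionTable, SyntheticGroundTruth]:
    """Draw one synthetic table; identical output for identical spec (incl. seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    I, J = spec.I, spec.J

    mu = spec.baseline_log_mean + spec.log_mean_spread * rng.standard_normal(J)
    planted = np.sort(rng.choice(J, size=spec.near_constant_refs, replace=False)) if spec.near_constant_refs else np.array([], dtype=int)
    cell_sd = np.full(J, spec.noise_sd)
    cell_sd[planted] = spec.noise_sd / 20.0
    # planted references sit at a mid-range baseline: good references are
    # neither rare (occupancy problems) nor dominant
    mu[planted] = spec.baseline_log_mean

    logX = mu[None, :] + cell_sd[None, :] * rng.standard_normal((I, J))

    group_labels: list[str] = []
    shifted: np.ndarray = np.array([], dtype=int)
    if spec.group_shift is not None:
        half = I // 2
        group_labels = ["A"] * half + ["B"] * (I - half)
        candidates = np.setdiff1d(np.arange(J), planted)
        n_shift = max(1, int(round(spec.group_shift_fraction * J)))
        shifted = np.sort(rng.choice(candidates, size=min(n_shift, candidates.size), replace=False))
        logX[half:, :][:, shifted] += spec.group_shift

    X = np.exp(logX)

    n_zeroed = 0
    if spec.zero_fraction > 0:
        # zeros happen where the assay runs out of sensitivity: restrict to
        # the low-abundance quartile of components (planted refs excluded)
        low = np.argsort(mu)
        low = np.array([j for j in low if j not in set(planted.tolist())])
        low = low[: max(1, J // 4)]
        cells = np.array([(i, j) for j in low for i in range(I)])
        n_zeroed = int(round(spec.zero_fraction * I * J))
        n_zeroed = min(n_zeroed, len(cells) - len(low))  # keep no column all-zero
        if n_zeroed > 0:
            pick = rng.choice(len(cells), size=n_zeroed, replace=False)
            X[cells[pick, 0], cells[pick, 1]] = 0.0
            # repair any column the draw emptied
            for j in low:
                if np.all(X[:, j] == 0):
                    X[rng.integers(I), j] = np.exp(mu[j])

    table = CompositionTable(
        X,
        sample_ids=[f"s{i + 1}" for i in range(I)],
        component_labels=[f"c{j + 1}" for j in range(J)],
    )
    truth = SyntheticGroundTruth(
        planted_indices=[int(j) + 1 for j in planted],
        planted_labels=[table.component_labels[j] for j in planted],
        group_labels=group_labels,
        shifted_indices=[int(j) + 1 for j in shifted],
        n_zeroed_cells=n_zeroed,
    )
    return table, truth
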