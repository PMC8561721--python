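"""Embedded toy datasets with frozen brute-force oracle values.

Three small hand-fixed tables ship with the package together with oracle
statistics (total logratio variance by the explicit pairwise summation,
the full logratio distance vector via the pairwise-logratio expansion,
and every candidate's Procrustes correlation by the literal
ALR -> centre -> standardise -> rotate -> Pearson route).  The oracles are
computed by ``scripts/compute_toy_oracles.py`` — a standalone brute-force
implementation that shares no code with this package — run once and
committed, so tests compare two genuinely independent computations.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .compositions import CompositionTable

__all__ = ["toy_dataset", "TOY_NAMES", "toy_table"]

# fmt: off
_TOY_TABLES: dict[str, dict] = {
    # 4 samples x 3 components: smallest table where the scan is non-vacuous
    "tiny4x3": {
        "values": [
            [10, 2, 5],
            [8, 3, 6],
            [12, 1, 4],
            [9, 2, 7],
        ],
    },
    # 6 samples x 10 components: moderately wide counts
    "mid6x10": {
        "values": [
            [59, 14, 29, 13, 15, 15, 49, 7, 59, 42],
            [46, 28, 17, 18, 18, 5, 36, 30, 7, 43],
            [54, 7, 59, 31, 58, 7, 54, 55, 11, 25],
            [17, 20, 14, 6, 17, 29, 15, 33, 6, 23],
            [47, 14, 42, 28, 2, 13, 4, 46, 38, 10],
            [44, 1, 21, 52, 59, 25, 21, 28, 20, 20],
        ],
    },
    # 12 samples x 8 components: intensities with a two-group level shift in
    # components 1 and 4 (samples 7-12 form the second group)
    "grouped12x8": {
        "values": [
            [10.23, 2.84, 12.06, 17.41, 16.9, 11.77, 8.71, 15.63],
            [9.66, 7.64, 16.71, 10.65, 25.22, 11.28, 5.52, 8.67],
            [16.66, 14.47, 16.95, 11.97, 4.7, 7.89, 8.86, 8.75],
            [10.28, 11.02, 12.0, 14.2, 6.01, 15.18, 6.78, 10.78],
            [9.42, 6.68, 15.26, 4.64, 12.67, 9.1, 12.22, 14.01],
            [28.45, 30.21, 20.43, 15.74, 4.4, 10.4, 7.16, 9.06],
            [14.92, 2.49, 8.65, 5.4, 1.42, 16.81, 16.18, 15.98],
            [68.51, 3.01, 11.23, 3.93, 18.08, 17.45, 3.79, 11.86],
            [24.77, 7.15, 11.94, 4.2, 17.74, 7.93, 7.43, 5.66],
            [55.84, 4.07, 10.4, 1.93, 6.29, 41.78, 12.63, 19.31],
            [38.03, 7.85, 11.0, 5.15, 16.86, 11.56, 60.78, 13.51],
            [85.04, 8.54, 6.71, 5.38, 25.53, 12.96, 9.71, 7.98],
        ],
        "group_labels": ["A"] * 6 + ["B"] * 6,
    },
}
# fmt: on

TOY_NAMES = tuple(_TOY_TABLES)


def toy_table(name: str) -> CompositionTable:
    """The raw table of one embedded toy dataset (no oracle values)."""
    try:
        entry = _TOY_TABLES[name]
    except KeyError:
        raise KeyError(f"unknown toy dataset {name!r}; available: {', '.join(TOY_NAMES)}") from None
    values = np.asarray(entry["values"], dtype=float)
    I, J = values.shape
    return CompositionTable(
        values,
        sample_ids=[f"s{i + 1}" for i in range(I)],
        component_labels=[f"c{j + 1}" for j in range(J)],
    )


def _load_oracles() -> dict:
    with resources.files("alrscan").joinpath("data/toy_oracles.json").open() as fh:
        return json.load(fh)


def toy_dataset(name: str) -> tuple[CompositionTable, dict]:
    """Return a toy table plus its frozen brute-force oracle bundle.

    The oracle dict has keys ``totvar`` (explicit pairwise-summation total
    logratio variance, equal weights), ``distances`` (condensed logratio
    distances from the pairwise expansion, i < i' order), ``procrustes_R``
    (per-candidate R by the literal naive route, input column order) and
    ``log_var`` (per-candidate variance of log relative abundance).
    """
    table = toy_table(name)
    oracles = _load_oracles()
    if name not in oracles:
        raise KeyError(f"no frozen oracle bundle for {name!r}")
    return table, oracles[name]
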