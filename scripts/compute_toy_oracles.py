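#!/usr/bin/env python
"""Brute-force oracle computation for the embedded toy datasets.

Standalone on purpose: everything here is computed by the most literal
route available — the explicit pairwise-logratio expansion for the total
variance and the distances, and an element-by-element Procrustes fit whose
correlation is taken as the Pearson correlation of the strung-out rotated
matrices.  No code is shared with the alrscan implementation modules; only
the raw table values are imported.  Run once; the JSON output is committed
as package data and frozen into the tests.

Usage:  python scripts/compute_toy_oracles.py
"""

import json
import sys
from itertools import combinations
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from alrscan.datasets import _TOY_TABLES  # raw values only


def totvar_bruteforce(X):
    """Equal-weight total logratio variance by explicit double summation."""
    I, J = X.shape
    total = 0.0
    for j, k in combinations(range(J), 2):
        lr = np.log(X[:, j] / X[:, k])
        total += (1.0 / J) * (1.0 / J) * float(np.mean((lr - lr.mean()) ** 2))
    return total


def distances_bruteforce(X):
    """Condensed logratio distances from the explicit pairwise expansion."""
    I, J = X.shape
    pairs = list(combinations(range(J), 2))
    out = []
    for i1, i2 in combinations(range(I), 2):
        d2 = 0.0
        for j, k in pairs:
            a = np.log(X[i1, j] / X[i1, k])
            b = np.log(X[i2, j] / X[i2, k])
            d2 += (1.0 / J**2) * (a - b) ** 2
        out.append(float(np.sqrt(d2)))
    return out


def _standardize(M):
    M = M - M.mean(axis=0, keepdims=True)
    return M / np.sqrt(np.sum(M**2))


def procrustes_R_pearson(A, B):
    """R via the rotate-then-correlate route (not via trace of D)."""
    K = max(A.shape[1], B.shape[1])
    X = np.zeros((A.shape[0], K))
    Y = np.zeros((B.shape[0], K))
    X[:, : A.shape[1]] = _standardize(A)
    Y[:, : B.shape[1]] = _standardize(B)
    U, d, Vt = np.linalg.svd(X.T @ Y)
    Q = Vt.T @ U.T
    YQ = Y @ Q
    x, y = X.ravel(), YQ.ravel()
    return float(np.corrcoef(x, y)[0, 1])


def scan_bruteforce(X):
    """Every candidate's R: explicit CLR and ALR matrices as configurations."""
    I, J = X.shape
    L = np.log(X)
    clr = L - L.mean(axis=1, keepdims=True)  # equal weights
    Rs = []
    for r in range(J):
        cols = [j for j in range(J) if j != r]
        alr = L[:, cols] - L[:, [r]]
        # the CLR and ALR matrices carry the exact/approximate geometries;
        # Procrustes R is invariant to expressing them in principal axes
        Rs.append(procrustes_R_pearson(clr / np.sqrt(J), alr))
    return Rs


def log_var_bruteforce(X):
    P = X / X.sum(axis=1, keepdims=True)
    return [float(np.mean((np.log(P[:, j]) - np.log(P[:, j]).mean()) ** 2)) for j in range(X.shape[1])]


def main():
    out = {}
    for name, entry in _TOY_TABLES.items():
        X = np.asarray(entry["values"], dtype=float)
        out[name] = {
            "totvar": totvar_bruteforce(X),
            "distances": distances_bruteforce(X),
            "procrustes_R": scan_bruteforce(X),
            "log_var": log_var_bruteforce(X),
        }
    dest = Path(__file__).resolve().parents[1] / "src" / "alrscan" / "data" / "toy_oracles.json"
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_text(json.dumps(out, indent=1))
    print(f"wrote {dest}")


if __name__ == "__main__":
    main()
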