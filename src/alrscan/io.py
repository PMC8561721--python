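"""Reading abundance tables and writing scan reports.

Delimited tables are read with pandas: a header row of component labels,
first column sample IDs, samples in rows (a transpose option handles
components-in-rows files).  BIOM tables are accepted in the JSON dialect
(version 1.0) and the HDF5 layout (version 2.1, via h5py); by BIOM
convention rows are observations (components) and columns samples, which
the reader normalises to samples-in-rows.

Scan reports are written as TSV (one candidate per row) or schema-versioned
JSON; all numbers carry 17 significant digits so that a report round-trips
to full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .compositions import CompositionTable
from .scan import CandidateRecord, ReferenceScanResult

__all__ = [
    "read_abundance",
    "write_abundance",
    "write_scan_report",
    "read_scan_report",
    "write_logratio_matrix",
    "write_configuration",
    "write_distances",
]

REPORT_SCHEMA_VERSION = "1.0"
_FLOAT_FMT = "%.17g"

_RECORD_COLUMNS = [
    "label", "index", "R", "log_var",
    "log_min", "log_q1", "log_median", "log_q3", "log_max",
    "iqr", "zero_count", "mean_rel_abundance", "abundance_rank",
]


def _detect_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".biom":
        return "biom"
    raise ValueError(f"cannot infer format from {path!r}; pass format='tsv'|'csv'|'biom'")


def read_abundance(
    path: str | Path,
    format: str | None = None,
    orientation: str = "samples-in-rows",
    id_column: str | int = 0,
    weights: np.ndarray | None = None,
) -> CompositionTable:
    """Read an abundance table into a :class:`CompositionTable`.

    Zeros are preserved (zero replacement is a separate, explicit step).
    Negative, non-numeric or non-finite cells and duplicate labels are
    rejected with the offending cell/label named.
    """
    fmt = _detect_format(path, format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if fmt == "biom":
        df = _read_biom(path)  # samples in rows already
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        dupes = {h for h in header[1:] if header.count(h) > 1}
        if dupes:
            raise ValueError(f"duplicate component labels in header: {sorted(dupes)}")
        df = pd.read_csv(path, sep=sep, index_col=id_column)
        if orientation == "samples-in-columns":
            df = df.T
        elif orientation != "samples-in-rows":
            raise ValueError(f"unknown orientation {orientation!r}")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    # reject non-numeric cells with a location
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric cell at sample {bad!r}, component {col!r}: {df.loc[bad, col]!r}")
    values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing value at sample {df.index[i]!r}, component {df.columns[j]!r}")
    return CompositionTable(values, list(map(str, df.index)), list(map(str, df.columns)), weights)


def _read_biom(path: Path) -> pd.DataFrame:
    """Minimal BIOM reader (JSON 1.0 and HDF5 2.1 dialects).

    Returns a samples-in-rows DataFrame; BIOM stores observations in rows.
    """
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head.startswith(b"\x89HDF"):
        return _read_biom_hdf5(path)
    data = json.loads(Path(path).read_text())
    n_obs, n_samp = data["shape"]
    obs_ids = [r["id"] for r in data["rows"]]
    samp_ids = [c["id"] for c in data["columns"]]
    M = np.zeros((n_obs, n_samp))
    if data.get("matrix_type") == "dense":
        M = np.asarray(data["data"], dtype=float)
    else:  # sparse: [row, col, value] triples
        for r, c, v in data["data"]:
            M[int(r), int(c)] = v
    return pd.DataFrame(M.T, index=samp_ids, columns=obs_ids)


def _read_biom_hdf5(path: Path) -> pd.DataFrame:
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        samp_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        g = f["observation/matrix"]
        M = csr_matrix(
            (g["data"][:], g["indices"][:], g["indptr"][:]),
            shape=(len(obs_ids), len(samp_ids)),
        ).toarray()
    return pd.DataFrame(M.T, index=samp_ids, columns=obs_ids)


def write_abundance(table: CompositionTable, path: str | Path, format: str | None = None) -> Path:
    """Write a table as TSV/CSV (header of component labels, ID first column)."""
    fmt = _detect_format(path, format)
    if fmt not in ("tsv", "csv"):
        raise ValueError("write_abundance supports tsv/csv output")
    path = Path(path)
    table.to_dataframe().to_csv(path, sep="\t" if fmt == "tsv" else ",", index_label="sample_id", float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# scan reports
# ---------------------------------------------------------------------------

def write_scan_report(result: ReferenceScanResult, path: str | Path, format: str = "tsv") -> Path:
    """Write a scan report; numeric content round-trips at full precision."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "tsv":
        df = result.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# alrscan report schema={REPORT_SCHEMA_VERSION} mode={result.mode} "
                     f"total_variance={result.total_variance:.17g}\n")
            df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif fmt == "json":
        doc = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "mode": result.mode,
            "metadata": result.metadata,
            "total_variance": result.total_variance,
            "best_by_R": result.best_by_R,
            "best_by_var": result.best_by_var,
            "records": [rec.as_dict() for rec in result.records],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_scan_report(path: str | Path) -> ReferenceScanResult:
    """Parse a report written by :func:`write_scan_report` (tsv or json)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        doc = json.loads(text)
        records = [
            CandidateRecord(
                label=r["label"], index=int(r["index"]), R=float(r["R"]), log_var=float(r["log_var"]),
                five_number=(r["log_min"], r["log_q1"], r["log_median"], r["log_q3"], r["log_max"]),
                iqr=float(r["iqr"]), zero_count=int(r["zero_count"]),
                mean_rel_abundance=float(r["mean_rel_abundance"]), abundance_rank=int(r["abundance_rank"]),
            )
            for r in doc["records"]
        ]
        return ReferenceScanResult(
            records=records,
            total_variance=float(doc["total_variance"]),
            best_by_R=int(doc["best_by_R"]),
            best_by_var=int(doc["best_by_var"]),
            mode=doc["mode"],
            metadata=doc.get("metadata", {}),
        )
    header, _, body = text.partition("\n")
    meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split() if "=" in kv)
    from io import StringIO

    df = pd.read_csv(StringIO(body), sep="\t")
    records = [
        CandidateRecord(
            label=str(row["label"]), index=int(row["index"]), R=float(row["R"]), log_var=float(row["log_var"]),
            five_number=(row["log_min"], row["log_q1"], row["log_median"], row["log_q3"], row["log_max"]),
            iqr=float(row["iqr"]), zero_count=int(row["zero_count"]),
            mean_rel_abundance=float(row["mean_rel_abundance"]), abundance_rank=int(row["abundance_rank"]),
        )
        for _, row in df.iterrows()
    ]
    from .scan import _ranking_order

    return ReferenceScanResult(
        records=records,
        total_variance=float(meta["total_variance"]),
        best_by_R=_ranking_order(records, "R")[0],
        best_by_var=_ranking_order(records, "var")[0],
        mode=meta.get("mode", "unknown"),
    )


# ---------------------------------------------------------------------------
# auxiliary writers
# ---------------------------------------------------------------------------

def write_logratio_matrix(lr, path: str | Path) -> Path:
    """Write a logratio matrix as TSV; ratio columns are labelled "num/den"."""
    path = Path(path)
    lr.to_dataframe().to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)
    return path


def write_configuration(config, path: str | Path) -> Path:
    """Write sample coordinates plus a header of per-axis explained variance."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# explained_variance\t" + "\t".join(_FLOAT_FMT % e for e in config.explained) + "\n")
        config.to_dataframe().to_csv(fh, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)
    return path


def write_distances(distances: np.ndarray, sample_ids: list[str], path: str | Path) -> Path:
    """Write condensed distances as a 3-column (id_i, id_j, distance) TSV."""
    path = Path(path)
    I = len(sample_ids)
    if distances.size != I * (I - 1) // 2:
        raise ValueError(f"{distances.size} distances do not match {I} samples")
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tdistance\n")
        k = 0
        for i in range(I - 1):
            for j in range(i + 1, I):
                fh.write(f"{sample_ids[i]}\t{sample_ids[j]}\t{_FLOAT_FMT % distances[k]}\n")
                k += 1
    return path
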