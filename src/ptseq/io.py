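"""Reading and writing count matrices and result tables.

Delimited text uses tab separation by default ('.' decimal, no quoting,
UTF-8) with '#'-prefixed provenance comment lines; missing values are
serialized as "NA".  Sparse input is accepted as matrix-market triplets
with side-car gene/sample identifier lists.
"""

from __future__ import annotations

import hashlib
import io as _io
import json

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from . import __version__
from .de_test import RESULT_COLUMNS
from .normalization import CountMatrix

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "write_results",
    "read_results",
]

_NA = "NA"


def _infer_format(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".csv"):
        return "csv"
    if p.endswith(".mtx"):
        return "mtx"
    return "tsv"


def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = str(path)
    if stem.lower().endswith(".mtx"):
        stem = stem[:-4]
    return stem + ".genes.txt", stem + ".samples.txt"


def read_count_matrix(path, fmt: str | None = None) -> CountMatrix:
    """Read a gene x sample count matrix.

    Delimited text must carry a header row of sample identifiers and gene
    identifiers in the first column; matrix-market files read their
    identifiers from ``<stem>.genes.txt`` and ``<stem>.samples.txt``.
    Non-integer cells and duplicate gene identifiers are rejected.
    """
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        genes_path, samples_path = _sidecar_paths(path)
        mat = mmread(str(path)).toarray()
        gene_ids = [l.strip() for l in open(genes_path) if l.strip()]
        sample_ids = [l.strip() for l in open(samples_path) if l.strip()]
        if not np.all(np.equal(np.mod(mat, 1), 0)):
            raise ValueError(f"non-integer values in matrix-market file {path}")
        return CountMatrix(mat.astype(np.int64), gene_ids, sample_ids)
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"non-numeric cells in {path}")
    bad = ~np.equal(np.mod(arr, 1), 0) | ~np.isfinite(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer cell at gene '{df.index[i]}', sample '{df.columns[j]}' "
            f"in {path}: {arr[i, j]!r}"
        )
    return CountMatrix.from_frame(df)


def write_count_matrix(m: CountMatrix, path, fmt: str | None = None) -> None:
    """Write a count matrix as delimited text or matrix-market triplets."""
    fmt = fmt or _infer_format(path)
    if fmt == "mtx":
        genes_path, samples_path = _sidecar_paths(path)
        mmwrite(str(path), coo_matrix(m.counts))
        with open(genes_path, "w") as fh:
            fh.write("\n".join(m.gene_ids) + "\n")
        with open(samples_path, "w") as fh:
            fh.write("\n".join(m.sample_ids) + "\n")
        return
    sep = "," if fmt == "csv" else "\t"
    m.to_frame().to_csv(path, sep=sep, index_label="gene")


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for provenance lines."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(table: pd.DataFrame, path, seed: int | None = None,
                  config: dict | None = None, timestamp: bool = False) -> None:
    """Write a differential-expression result table.

    Column order is fixed; '#'-prefixed header lines record the package
    version, the seed and a hash of the run configuration.  The timestamp
    line is off by default so identical runs produce byte-identical files.
    """
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    out = table[cols + extra]
    buf = _io.StringIO()
    buf.write(f"# ptseq {__version__}\n")
    if seed is not None:
        buf.write(f"# seed: {seed}\n")
    if config is not None:
        buf.write(f"# config: {config_hash(config)}\n")
    if timestamp:
        buf.write(f"# written: {pd.Timestamp.now().isoformat()}\n")
    out.to_csv(buf, sep="\t", index=False, na_rep=_NA, float_format="%.6g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=[_NA])
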