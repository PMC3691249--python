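"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel as tab-delimited text (features in rows, header =
sample ids; transparently gzipped when the path ends in ``.gz``) or as
MatrixMarket files with side-car row/column id lists. Annotation tables are
tab-delimited with an index column; configs are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "read_yaml",
    "write_yaml",
]


def _sidecars(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return base.with_suffix(".rows.txt"), base.with_suffix(".cols.txt")


def write_matrix(expr: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write a features x samples matrix as TSV(.gz) or MTX with id side-cars."""
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        expr.to_csv(path, sep="\t", float_format="%.10g")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.csr_matrix(expr.to_numpy(dtype=float)))
        rows, cols = _sidecars(path)
        rows.write_text("\n".join(map(str, expr.index)) + "\n")
        cols.write_text("\n".join(map(str, expr.columns)) + "\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix`."""
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        import gzip

        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise ValueError(f"duplicate sample ids in {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.duplicated().any():
            raise ValueError(f"duplicate feature ids in {path}")
        return df
    if fmt == "mtx":
        m = spio.mmread(path)
        rows_f, cols_f = _sidecars(path)
        if not rows_f.exists() or not cols_f.exists():
            raise FileNotFoundError(f"missing id side-car files for {path}")
        rows = rows_f.read_text().splitlines()
        cols = cols_f.read_text().splitlines()
        arr = np.asarray(m.todense() if sparse.issparse(m) else m, dtype=float)
        if arr.shape != (len(rows), len(cols)):
            raise ValueError(
                f"matrix shape {arr.shape} does not match id lists "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
        return pd.DataFrame(arr, index=rows, columns=cols)
    raise ValueError(f"unknown matrix format {fmt!r}")


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_annotation(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
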