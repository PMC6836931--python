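"""Readers and writers for the plain-text formats the pipeline consumes.

Counts travel as TSV (transcripts as rows) or MatrixMarket triplets with
side files of row/column names; gene sets as GMT; PPI edges as a three
column TSV with a confidence in (0, 1].  Every reader validates and reports
offending line numbers, every writer round-trips through its reader.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (term TAB description TAB gene ...) into term -> gene set."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
                )
            term = fields[0]
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = set(fields[2:])
    return sets


def write_gmt(
    sets: Mapping[str, set[str]], path: str | Path, descriptions: Mapping[str, str] | None = None
) -> None:
    with open(path, "w") as fh:
        for term in sets:
            desc = descriptions.get(term, "na") if descriptions else "na"
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# term -> category map


def read_category_map(path: str | Path) -> dict[str, str]:
    cats: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'term<TAB>category'")
            term, cat = fields
            if term in cats:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            cats[term] = cat
    return cats


def write_category_map(cats: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, cat in cats.items():
            fh.write(f"{term}\t{cat}\n")


# ---------------------------------------------------------------------------
# weighted edge lists


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read 'node TAB node TAB confidence' lines; rejects self-loops, duplicate
    edges (in either orientation) and confidences outside (0, 1]."""
    edges: list[tuple[str, str, float]] = []
    seen: dict[frozenset, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'node<TAB>node<TAB>confidence'")
            u, v, conf_s = fields
            try:
                conf = float(conf_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: confidence {conf_s!r} is not a number")
            if u == v:
                raise FormatError(f"{path}:{lineno}: self-loop on {u!r}")
            if not (0.0 < conf <= 1.0):
                raise FormatError(f"{path}:{lineno}: confidence {conf} outside (0, 1]")
            key = frozenset((u, v))
            if key in seen:
                raise FormatError(
                    f"{path}:{lineno}: edge {u}-{v} duplicates line {seen[key]}"
                )
            seen[key] = lineno
            edges.append((u, v, conf))
    return edges


def write_edge_list(edges, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, conf in edges:
            fh.write(f"{u}\t{v}\t{conf:.6g}\n")


# ---------------------------------------------------------------------------
# count matrices and sample metadata


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Transcript-by-sample integer counts; first column = transcript id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate transcript id {dup!r}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample id")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric count values")
    if (values < 0).any():
        raise FormatError(f"{path}: negative count values")
    if not np.allclose(values, np.round(values)):
        raise FormatError(f"{path}: counts must be integers")
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript")


def read_counts_mtx(mtx_path: str | Path, rows_path: str | Path, cols_path: str | Path) -> pd.DataFrame:
    """MatrixMarket counts plus one-name-per-line row and column files."""
    mat = scipy.io.mmread(str(mtx_path))
    rows = [l.strip() for l in open(rows_path) if l.strip()]
    cols = [l.strip() for l in open(cols_path) if l.strip()]
    mat = scipy.sparse.coo_matrix(mat).toarray()
    if mat.shape != (len(rows), len(cols)):
        raise FormatError(
            f"{mtx_path}: matrix is {mat.shape} but names give ({len(rows)}, {len(cols)})"
        )
    df = pd.DataFrame(mat, index=rows, columns=cols)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index_label="transcript")
    buf.seek(0)
    return read_counts_tsv_like(buf, label=str(mtx_path))


def read_counts_tsv_like(buf, label: str = "<buffer>") -> pd.DataFrame:
    df = pd.read_csv(buf, sep="\t", index_col=0)
    values = df.to_numpy()
    if (values < 0).any():
        raise FormatError(f"{label}: negative count values")
    return df.astype(np.int64)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with at least (sample, time); surgeon/batch optional."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "time" not in meta.columns:
        raise FormatError(f"{path}: metadata needs a 'time' column")
    if meta.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample id")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")
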