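"""Reading coordinate tables, distance matrices and label files.

Two distance layouts are accepted: a full square delimited matrix
(optionally with a header row and/or a leading row-name column) and a
lower-triangle listing (row i holding the i distances to objects
0..i-1, the first line being empty or absent).  Coordinates are plain
delimited numeric tables; labels are a single column, either their own
file or a named column of the coordinate table.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .silhouette import validate_dissimilarity

__all__ = [
    "read_coordinates",
    "read_distance_matrix",
    "read_labels",
    "coords_to_distances",
]


def _sniff_sep(path) -> str:
    head = Path(path).read_text().splitlines()[0]
    return "\t" if "\t" in head else ","


def read_coordinates(path, label_column: str | None = None):
    """Read a delimited numeric table; optionally split off a label column.

    Returns ``(coords, labels)`` where labels is None unless
    ``label_column`` is given.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in {list(df.columns)}")
        labels = df[label_column].to_numpy()
        df = df.drop(columns=[label_column])
    return df.to_numpy(dtype=float), labels


def coords_to_distances(coords) -> np.ndarray:
    """Euclidean distance matrix from an (n, d) coordinate array."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(coords, dtype=float)))


def _read_lower_triangle(text: str) -> np.ndarray:
    rows = []
    for line in text.splitlines():
        parts = line.replace(",", " ").split()
        rows.append([float(v) for v in parts])
    if rows and not rows[0]:
        rows = rows[1:]  # leading empty line for object 0
    n = len(rows) + 1
    if any(len(r) != i + 1 for i, r in enumerate(rows)):
        raise ValueError("malformed lower-triangle distance file")
    D = np.zeros((n, n))
    for i, r in enumerate(rows, start=1):
        D[i, :i] = r
        D[:i, i] = r
    return D


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_distance_matrix(path) -> np.ndarray:
    """Read a square or lower-triangle delimited distance matrix.

    Square layouts may carry a header row and/or a leading row-name
    column; both are detected and dropped.
    """
    text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ValueError("empty distance file")
    sep = "\t" if "\t" in lines[0] else ("," if "," in lines[0] else None)
    rows = [[t.strip() for t in (l.split(sep) if sep else l.split())] for l in lines]

    if len(rows) > 1 and all(len(r) == i + 1 for i, r in enumerate(rows)):
        return validate_dissimilarity(_read_lower_triangle(text))

    # header row: non-numeric tokens, or one more row than columns
    if (not all(_is_number(t) for t in rows[0] if t)
            or len(rows) == len(rows[1]) + 1):
        rows = rows[1:]
    # row-name column: one more column than rows
    if all(len(r) == len(rows) + 1 for r in rows):
        rows = [r[1:] for r in rows]
    if any(len(r) != len(rows) for r in rows):
        raise ValueError("distance file is neither square nor lower-triangle")
    D = np.array([[float(t) for t in r] for r in rows])
    return validate_dissimilarity(D)


def read_labels(path) -> np.ndarray:
    """Read one label per line (an optional single header line is skipped)."""
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if lines and lines[0].lower() in ("label", "labels", "cluster"):
        lines = lines[1:]
    arr = np.array(lines)
    try:
        return arr.astype(int)
    except ValueError:
        return arr
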