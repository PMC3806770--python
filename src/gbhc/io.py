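"""Delimited-text matrix I/O, partition files, and Newick dendrograms."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import DendroNode
from .partition import Partition
from .preprocess import ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "read_annotations",
    "write_dendrogram",
]


def _detect_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(
    path,
    delimiter: str | None = None,
    orientation: str = "samples",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a labelled numeric matrix from delimited text.

    Expects a header row of variable names and a first column of observation
    ids.  The delimiter is auto-detected between tab and comma unless given.
    Ragged rows, duplicate ids and non-numeric cells raise errors naming the
    offending line.
    """
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and at least one data row")
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])
    header = lines[0].rstrip("\n").split(delimiter)
    col_ids = [h.strip() for h in header[1:]]
    n_cols = len(col_ids)
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(delimiter)
        if len(parts) != n_cols + 1:
            raise ValueError(
                f"{path}: line {lineno} has {len(parts)} fields, "
                f"expected {n_cols + 1}"
            )
        row_ids.append(parts[0].strip())
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValueError(
                f"{path}: non-numeric cell at line {lineno}: {exc}"
            ) from None
    if len(set(row_ids)) != len(row_ids):
        dupes = sorted({r for r in row_ids if row_ids.count(r) > 1})
        raise ValueError(f"{path}: duplicate row ids {dupes}")
    if len(set(col_ids)) != len(col_ids):
        raise ValueError(f"{path}: duplicate column ids in header")
    M = ExpressionMatrix(np.asarray(rows), row_ids, col_ids, orientation)
    return M.transposed() if transpose else M


def write_matrix(M: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["id"] + [str(c) for c in M.col_ids]) + "\n")
        for rid, row in zip(M.row_ids, M.values):
            fh.write(delimiter.join([str(rid)]
                                    + [repr(float(v)) for v in row]) + "\n")


def write_partition(P: Partition, path, delimiter: str = "\t") -> None:
    """Two-column (id, cluster) file, rows in observation order."""
    with open(path, "w") as fh:
        fh.write(f"id{delimiter}cluster\n")
        for i, lab in zip(P.ids, P.labels):
            fh.write(f"{i}{delimiter}{lab}\n")


def read_partition(path, delimiter: str | None = None) -> Partition:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])
    body = lines[1:] if lines[0].split(delimiter)[0].strip() == "id" else lines
    ids, labels = [], []
    for line in body:
        parts = line.split(delimiter)
        if len(parts) != 2:
            raise ValueError(f"{path}: expected two columns, got {line!r}")
        ids.append(parts[0].strip())
        labels.append(parts[1].strip())
    return Partition(labels, ids)


def read_annotations(path, delimiter: str | None = None) -> dict:
    """Item -> set-of-classes map from two-column (id, class) text."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        return {}
    if delimiter is None:
        delimiter = _detect_delimiter(lines[0])
    out: dict = {}
    for line in lines:
        parts = line.split(delimiter)
        if len(parts) != 2:
            raise ValueError(f"{path}: expected two columns, got {line!r}")
        out.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return out


def _newick(node: DendroNode, leaf_names, parent_height: float) -> str:
    height = 0.0 if node.is_leaf else 1.0 - node.r
    branch = max(parent_height - height, 0.0)
    if node.is_leaf:
        return f"{leaf_names[int(node.members[0])]}:{branch:.6f}"
    left = _newick(node.left, leaf_names, height)
    right = _newick(node.right, leaf_names, height)
    return f"({left},{right})[&r={node.r:.6f}]:{branch:.6f}"


def write_dendrogram(root: DendroNode, path, leaf_names=None) -> None:
    """Serialize the dendrogram as Newick.

    Leaves carry observation ids; every internal node is annotated with its
    merge probability in a ``[&r=...]`` comment, and branch lengths derive
    from the dissimilarity 1 - r (clipped at zero so the file stays a valid
    ultrametric-ish tree even when r is not monotone along a path).
    """
    if leaf_names is None:
        leaf_names = {int(i): f"obs{int(i)}" for i in root.members}
    else:
        leaf_names = {int(i): str(leaf_names[int(i)]) for i in root.members}
    height = 0.0 if root.is_leaf else 1.0 - root.r
    with open(path, "w") as fh:
        fh.write(_newick(root, leaf_names, height) + ";\n")
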