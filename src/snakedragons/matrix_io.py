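"""Reading, validating, and writing collections of correlation matrices.

A correlation matrix here is the structural fingerprint of one object
(a subject's brain connectivity matrix, one student's week-by-week
microbiome correlation matrix, one economy's indicator correlation
matrix, ...).  Collections of such matrices, all sharing the same node
set and ordering, are the input to vectorization and clustering.

Two text formats are supported:

* **per-file square**: one delimited numeric grid per object, with an
  optional header row/column of node labels;
* **long format**: a single table with columns
  ``(object, row_label, col_label, value)``; each unordered pair is
  stored once and mirrored, the diagonal is implied to be 1.

Delimiters (comma, tab, whitespace) are auto-detected and can be
overridden.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-8
DIAGONAL_TOL = 1e-8
RANGE_CLAMP = 1e-12  # overshoots of |r|>1 by at most this much are clamped


class MatrixIOError(Exception):
    """Base class for matrix input/output problems."""


class MatrixParseError(MatrixIOError):
    """Malformed delimited text (ragged rows, non-numeric cells...)."""


class AlignmentError(MatrixIOError):
    """Objects in a collection do not share node labels/ordering."""


class ConflictError(MatrixIOError):
    """Duplicate long-format entries with conflicting values."""


class ValidationError(MatrixIOError):
    """A matrix violates correlation-matrix invariants."""


@dataclass
class CorrelationMatrix:
    """A square symmetric unit-diagonal matrix with node labels.

    Parameters
    ----------
    labels : ordered node identifiers, length ``q``.
    values : ``q x q`` array of correlations in ``[-1, 1]``.
    name : optional object identifier carried through vectorization.
    """

    labels: list[str]
    values: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(f"matrix is not square: shape {self.values.shape}")
        if len(self.labels) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for a {self.values.shape[0]}-node matrix"
            )

    @property
    def q(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "CorrelationMatrix":
        return CorrelationMatrix(list(self.labels), self.values.copy(), self.name)


@dataclass
class MatrixCollection:
    """One CorrelationMatrix per object, identically labelled."""

    object_ids: list[str]
    matrices: list[CorrelationMatrix]

    def __post_init__(self) -> None:
        if len(self.object_ids) != len(self.matrices):
            raise AlignmentError("object_ids and matrices differ in length")
        if len(self.matrices) >= 1:
            ref = self.matrices[0].labels
            bad = [
                oid
                for oid, m in zip(self.object_ids, self.matrices)
                if m.labels != ref
            ]
            if bad:
                raise AlignmentError(
                    "objects with labels differing from the first object: "
                    + ", ".join(bad)
                )

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    @property
    def q(self) -> int:
        return self.matrices[0].q

    @property
    def labels(self) -> list[str]:
        return self.matrices[0].labels

    def stacked(self) -> np.ndarray:
        """N x q x q array of the member matrices."""
        return np.stack([m.values for m in self.matrices])


@dataclass
class Violation:
    kind: str  # symmetry | diagonal | range | psd | shape
    index: tuple
    magnitude: float
    is_warning: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        sev = "warning" if self.is_warning else "violation"
        return f"{self.kind} {sev} at {self.index}: {self.magnitude:.3g}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(not v.is_warning for v in self.violations)

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.is_warning]


def synth_labels(q: int) -> list[str]:
    width = max(3, len(str(q)))
    return [f"v{i + 1:0{width}d}" for i in range(q)]


def validate_matrix(M: CorrelationMatrix, strict_psd: bool = False) -> ValidationReport:
    """Check correlation-matrix invariants.

    Symmetry, unit diagonal, and the ``[-1, 1]`` range are hard
    requirements; positive semidefiniteness is reported as a warning
    unless ``strict_psd`` is set (the smallest eigenvalue may legally
    dip slightly below zero through rounding, so the threshold is
    ``-1e-8 * q``).
    """
    V = M.values
    report = ValidationReport()
    asym = np.abs(V - V.T)
    for i, j in zip(*np.nonzero(np.triu(asym > SYMMETRY_TOL, 1))):
        report.violations.append(Violation("symmetry", (int(i), int(j)), float(asym[i, j])))
    ddev = np.abs(np.diag(V) - 1.0)
    for i in np.nonzero(ddev > DIAGONAL_TOL)[0]:
        report.violations.append(Violation("diagonal", (int(i), int(i)), float(ddev[i])))
    over = np.abs(V) - 1.0
    for i, j in zip(*np.nonzero(over > RANGE_CLAMP)):
        report.violations.append(Violation("range", (int(i), int(j)), float(over[i, j])))
    lam_min = float(np.linalg.eigvalsh((V + V.T) / 2.0)[0])
    if lam_min < -1e-8 * M.q:
        report.violations.append(
            Violation("psd", (), lam_min, is_warning=not strict_psd)
        )
    return report


def _sniff_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # generic whitespace


def _tokenize(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        return line.split()
    return [t.strip() for t in line.split(delimiter)]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _clamp(values: np.ndarray, context: str) -> np.ndarray:
    over = np.abs(values) - 1.0
    if np.any(over > RANGE_CLAMP):
        i, j = np.unravel_index(int(np.argmax(over)), values.shape)
        raise ValidationError(
            f"{context}: entry ({i},{j}) = {values[i, j]} outside [-1, 1]"
        )
    return np.clip(values, -1.0, 1.0)


def read_square_matrix_file(
    path: str | Path, delimiter: str | None = None, name: str | None = None
) -> CorrelationMatrix:
    """Read one delimited square grid, with optional label header row/column."""
    path = Path(path)
    raw = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not raw:
        raise MatrixParseError(f"{path}: empty file")
    delim = delimiter if delimiter is not None else _sniff_delimiter(raw[0])
    rows = [_tokenize(ln, delim) for ln in raw]

    header = not all(_is_number(t) for t in rows[0][1:] or rows[0])
    labels: list[str] | None = None
    if header:
        labels = [t for t in rows[0] if t != ""]
        rows = rows[1:]
        # a header row over q columns may carry q or q+1 tokens (corner cell)
    has_label_col = rows and not _is_number(rows[0][0])
    data: list[list[float]] = []
    row_labels: list[str] = []
    for k, toks in enumerate(rows):
        if has_label_col:
            row_labels.append(toks[0])
            toks = toks[1:]
        if not all(_is_number(t) for t in toks):
            raise MatrixParseError(f"{path}, line {k + 1 + int(header)}: non-numeric cell")
        data.append([float(t) for t in toks])
    widths = {len(r) for r in data}
    if len(widths) != 1:
        raise MatrixParseError(
            f"{path}: ragged rows (lengths {sorted(widths)})"
        )
    values = np.asarray(data)
    if values.shape[0] != values.shape[1]:
        raise MatrixParseError(
            f"{path}: grid is {values.shape[0]}x{values.shape[1]}, not square"
        )
    q = values.shape[0]
    if labels is not None and len(labels) == q + 1:
        labels = labels[1:]
    if labels is not None and len(labels) != q:
        raise MatrixParseError(f"{path}: {len(labels)} header labels for q={q}")
    if labels is None:
        labels = row_labels if len(row_labels) == q else synth_labels(q)
    values = _clamp(values, str(path))
    return CorrelationMatrix(labels, values, name=name or path.stem)


def read_long_format(
    path: str | Path, delimiter: str | None = None
) -> MatrixCollection:
    """Read a long-format table ``(object, row_label, col_label, value)``.

    Each unordered pair must appear at least once per object; entries
    are mirrored, the diagonal defaults to 1.  Conflicting duplicates
    and missing off-diagonal cells are errors (no imputation).
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else r"[,\t\s]+"
    df = pd.read_csv(path, sep=sep, engine="python", header=None, comment="#")
    if df.shape[1] != 4:
        # maybe a header line
        df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    if df.shape[1] != 4:
        raise MatrixParseError(f"{path}: expected 4 columns, found {df.shape[1]}")
    if not pd.api.types.is_numeric_dtype(df.iloc[:, 3]):
        df = df.iloc[1:]  # drop header row read as data
        df.iloc[:, 3] = df.iloc[:, 3].astype(float)
    df.columns = ["object", "row", "col", "value"]
    df["object"] = df["object"].astype(str)
    df["row"] = df["row"].astype(str)
    df["col"] = df["col"].astype(str)

    object_ids = list(dict.fromkeys(df["object"]))
    label_order = list(dict.fromkeys(pd.concat([df["row"], df["col"]])))
    q = len(label_order)
    pos = {lab: i for i, lab in enumerate(label_order)}

    matrices = []
    for oid in object_ids:
        sub = df[df["object"] == oid]
        labs = set(sub["row"]) | set(sub["col"])
        if labs != set(label_order):
            raise AlignmentError(
                f"object {oid}: label set {sorted(labs)} differs from collection labels"
            )
        V = np.full((q, q), np.nan)
        np.fill_diagonal(V, 1.0)
        for _, rec in sub.iterrows():
            i, j, val = pos[rec["row"]], pos[rec["col"]], float(rec["value"])
            for a, b in ((i, j), (j, i)):
                if not np.isnan(V[a, b]) and abs(V[a, b] - val) > SYMMETRY_TOL and (a, b) != (a, a):
                    raise ConflictError(
                        f"object {oid}: conflicting values for pair "
                        f"({label_order[min(a,b)]},{label_order[max(a,b)]}): "
                        f"{V[a, b]} vs {val}"
                    )
                if a != b:
                    V[a, b] = val
        if np.isnan(V).any():
            i, j = map(int, np.argwhere(np.isnan(V))[0])
            raise MatrixParseError(
                f"object {oid}: missing off-diagonal cell "
                f"({label_order[i]},{label_order[j]})"
            )
        V = _clamp(V, f"object {oid}")
        matrices.append(CorrelationMatrix(list(label_order), V, name=oid))
    return MatrixCollection(object_ids, matrices)


def read_matrix_collection(
    paths_or_table: Sequence[str | Path] | str | Path,
    format_tag: str = "per-file-square",
    delimiter: str | None = None,
) -> MatrixCollection:
    """Read a collection of correlation matrices.

    ``format_tag`` is ``per-file-square`` (a sequence of file paths,
    one grid per object) or ``long-format`` (a single table path).
    """
    if format_tag == "long-format":
        if isinstance(paths_or_table, (list, tuple)):
            if len(paths_or_table) != 1:
                raise MatrixIOError("long-format expects a single table path")
            paths_or_table = paths_or_table[0]
        return read_long_format(paths_or_table, delimiter)
    if format_tag != "per-file-square":
        raise MatrixIOError(f"unknown format_tag {format_tag!r}")
    if isinstance(paths_or_table, (str, Path)):
        paths_or_table = [paths_or_table]
    matrices = [read_square_matrix_file(p, delimiter) for p in paths_or_table]
    ref = matrices[0].labels
    for m in matrices:
        if len(m.labels) != len(ref):
            raise AlignmentError(
                f"object {m.name}: q={m.q} differs from q={len(ref)}"
            )
        if m.labels != ref:
            if set(m.labels) == set(ref):  # same nodes, different order: realign
                perm = [m.labels.index(lab) for lab in ref]
                m.values = m.values[np.ix_(perm, perm)]
                m.labels = list(ref)
            else:
                raise AlignmentError(
                    f"object {m.name}: label set differs from first object"
                )
    return MatrixCollection([m.name or f"obj{i}" for i, m in enumerate(matrices)], matrices)


def write_matrix(M: CorrelationMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(M.values, index=M.labels, columns=M.labels)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def write_matrix_collection(
    collection: MatrixCollection, out_dir: str | Path, delimiter: str = "\t"
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for oid, m in zip(collection.object_ids, collection.matrices):
        safe = re.sub(r"[^\w.-]", "_", oid)
        p = out_dir / f"{safe}.tsv"
        write_matrix(m, p, delimiter)
        paths.append(p)
    return paths


def write_vectors(
    object_ids: Sequence[str], vectors: np.ndarray, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write an N x L matrix of feature vectors, one row per object."""
    df = pd.DataFrame(np.asarray(vectors), index=list(object_ids))
    df.to_csv(path, sep=delimiter, header=False, float_format="%.17g")


def read_vectors(path: str | Path, delimiter: str = "\t") -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep=delimiter, header=None, index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)


def write_labels(object_ids: Sequence[str], labels: Sequence[int], path: str | Path) -> None:
    pd.DataFrame({"object_id": list(object_ids), "cluster": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_covariates(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a per-object covariate table; first column is the object id."""
    sep = delimiter if delimiter is not None else r"[,\t]+"
    df = pd.read_csv(path, sep=sep, engine="python")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df
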