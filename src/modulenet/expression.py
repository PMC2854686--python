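"""Expression matrix I/O, row filtering and row standardization.

The central container is :class:`ExpressionMatrix`: a dense genes x samples
matrix of log-scale expression values in which mRNA and miRNA rows live side
by side, distinguished only by a per-row ``kind`` label.  Everything
downstream (clustering, regulator scoring) treats rows uniformly; the kind
label exists so that miRNA regulators, which are measured on a different
absolute scale than mRNAs, can be tracked through the analysis.

File formats
------------
* Expression matrix: tab-separated, UTF-8.  First header column is ``id``,
  optionally followed by a ``kind`` column (``mrna``/``mirna``), then one
  column per sample.  Scientific notation is accepted.
* Regulator list: one identifier per line, ``#`` starts a comment.
* Gene sets: standard GMT (set name, description, then member ids).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

ROW_KINDS = ("mrna", "mirna")


class ExpressionIOError(ValueError):
    """Raised for malformed expression/regulator/gene-set files."""


@dataclass
class ExpressionMatrix:
    """Dense expression matrix with named rows and columns.

    Parameters
    ----------
    row_ids
        Ordered, unique gene/miRNA identifiers.
    col_ids
        Ordered, unique sample identifiers.
    values
        Real matrix of shape ``(len(row_ids), len(col_ids))``; log-scale
        expression intensities, no missing entries.
    row_kind
        Per-row label in ``{"mrna", "mirna"}``.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    row_kind: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        self.values = np.asarray(self.values, dtype=float)
        if not self.row_kind:
            self.row_kind = ["mrna"] * len(self.row_ids)
        self.row_kind = list(self.row_kind)
        _check_unique(self.row_ids, "row")
        _check_unique(self.col_ids, "column")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ExpressionIOError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} columns"
            )
        if len(self.row_kind) != len(self.row_ids):
            raise ExpressionIOError("row_kind length does not match row_ids")
        bad_kind = sorted(set(self.row_kind) - set(ROW_KINDS))
        if bad_kind:
            raise ExpressionIOError(f"unknown row kinds: {bad_kind}")
        if not np.all(np.isfinite(self.values)):
            raise ExpressionIOError("matrix contains non-finite entries")
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}
        self._col_index = {c: j for j, c in enumerate(self.col_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    def row_index(self, row_id: str) -> int:
        return self._row_index[row_id]

    def col_index(self, col_id: str) -> int:
        return self._col_index[col_id]

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self._row_index[row_id]]

    def kind_of(self, row_id: str) -> str:
        return self.row_kind[self._row_index[row_id]]

    def subset_rows(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._row_index[r] for r in ids]
        return ExpressionMatrix(
            [self.row_ids[i] for i in idx],
            list(self.col_ids),
            self.values[idx].copy(),
            [self.row_kind[i] for i in idx],
        )


@dataclass(frozen=True)
class CandidateRegulatorSet:
    """Identifiers of rows eligible for regulator assignment.

    Regulators are ordinary measured rows (TFs, signal transducers, miRNAs)
    and may overlap module gene membership.
    """

    ids: frozenset[str]

    def __init__(self, ids: Iterable[str]):
        object.__setattr__(self, "ids", frozenset(ids))

    def validate(self, matrix: ExpressionMatrix) -> None:
        missing = sorted(self.ids - set(matrix.row_ids))
        if missing:
            raise ExpressionIOError(
                f"candidate regulators absent from matrix: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )

    def sorted_ids(self) -> list[str]:
        return sorted(self.ids)


@dataclass
class GeneSetCollection:
    """Named gene sets over a common identifier universe."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for name, members in self.sets.items():
            extra = set(members) - uni
            if extra:
                raise ExpressionIOError(
                    f"gene set {name!r} contains ids outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ExpressionIOError(f"duplicate {what} identifiers: {dups}")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, strict: bool = True) -> ExpressionMatrix:
    """Read an expression matrix from TSV.

    Rows containing non-numeric or missing values are a hard error when
    ``strict`` is true; otherwise they are dropped, with the offending row
    ids recorded in ``matrix.meta["dropped_rows"]`` and reported via a
    warning.  Duplicate ids and ragged rows are always hard errors.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ExpressionIOError(f"{path}: empty file") from None
        if not header or header[0].strip().lower() != "id":
            raise ExpressionIOError(
                f"{path}: first header column must be 'id', got {header[:1]!r}"
            )
        has_kind = len(header) > 1 and header[1].strip().lower() == "kind"
        first_value_col = 2 if has_kind else 1
        col_ids = [c.strip() for c in header[first_value_col:]]
        if not col_ids:
            raise ExpressionIOError(f"{path}: no sample columns in header")

        row_ids: list[str] = []
        kinds: list[str] = []
        rows: list[list[float]] = []
        dropped: list[str] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != len(col_ids) + first_value_col:
                raise ExpressionIOError(
                    f"{path}:{lineno}: expected {len(col_ids) + first_value_col} "
                    f"fields, got {len(rec)}"
                )
            rid = rec[0].strip()
            kind = rec[1].strip().lower() if has_kind else "mrna"
            vals: list[float] = []
            ok = True
            for tok in rec[first_value_col:]:
                try:
                    v = float(tok)
                except ValueError:
                    ok = False
                    break
                if not math.isfinite(v):
                    ok = False
                    break
                vals.append(v)
            if not ok:
                if strict:
                    raise ExpressionIOError(
                        f"{path}:{lineno}: non-numeric value in row {rid!r}"
                    )
                dropped.append(rid)
                continue
            row_ids.append(rid)
            kinds.append(kind)
            rows.append(vals)

    if dropped:
        warnings.warn(
            f"{path}: dropped {len(dropped)} rows with missing/non-numeric "
            f"values: {dropped[:10]}",
            stacklevel=2,
        )
    matrix = ExpressionMatrix(
        row_ids, col_ids, np.array(rows, dtype=float).reshape(len(row_ids), len(col_ids)), kinds
    )
    matrix.meta["dropped_rows"] = dropped
    return matrix


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (with a ``kind`` column); 17 significant digits
    so that a read/write/read round trip is lossless."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\tkind\t" + "\t".join(matrix.col_ids) + "\n")
        for rid, kind, row in zip(matrix.row_ids, matrix.row_kind, matrix.values):
            fh.write(rid + "\t" + kind + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_regulator_list(path: str | Path) -> CandidateRegulatorSet:
    """Read a candidate-regulator id list (one id per line, ``#`` comments)."""
    ids: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        tok = line.split("#", 1)[0].strip()
        if tok:
            ids.append(tok)
    return CandidateRegulatorSet(ids)


def write_regulator_list(regs: CandidateRegulatorSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(regs.sorted_ids()) + "\n", encoding="utf-8")


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Read gene sets in GMT format.

    When ``universe`` is not given it defaults to the union of all set
    members.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ExpressionIOError(f"{path}:{lineno}: GMT line needs name, "
                                    "description and at least one member")
        name = parts[0].strip()
        if name in sets:
            raise ExpressionIOError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = [p.strip() for p in parts[2:] if p.strip()]
        sets[name] = members
    if universe is None:
        uni: list[str] = []
        seen: set[str] = set()
        for members in sets.values():
            for g in members:
                if g not in seen:
                    seen.add(g)
                    uni.append(g)
        universe = uni
    return GeneSetCollection(sets, list(universe))


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in sets.sets.items():
            fh.write(name + "\tna\t" + "\t".join(members) + "\n")


# ---------------------------------------------------------------------------
# Row filtering and standardization
# ---------------------------------------------------------------------------

def filter_rows(
    matrix: ExpressionMatrix,
    keep_ids: Iterable[str] | None = None,
    min_sd: float = 0.0,
) -> ExpressionMatrix:
    """Remove rows not in ``keep_ids`` (if given) and rows whose sample
    standard deviation falls below ``min_sd``.

    This generalizes the usual annotation-based pre-filtering of expression
    matrices (dropping unannotated probesets) to a caller-supplied keep-list
    plus a variance floor.  The column set is unchanged.  An empty result is
    a hard error.
    """
    if min_sd < 0:
        raise ValueError("min_sd must be >= 0")
    keep = None if keep_ids is None else set(keep_ids)
    row_sd = np.std(matrix.values, axis=1)  # population SD
    mask = np.ones(matrix.n_rows, dtype=bool)
    if keep is not None:
        mask &= np.array([r in keep for r in matrix.row_ids])
    if min_sd > 0:
        mask &= row_sd >= min_sd
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ExpressionIOError("row filtering removed every row")
    return ExpressionMatrix(
        [matrix.row_ids[i] for i in idx],
        list(matrix.col_ids),
        matrix.values[idx].copy(),
        [matrix.row_kind[i] for i in idx],
    )


def standardize_row(x: Sequence[float] | np.ndarray, return_constant: bool = False):
    """Standardize a vector to mean 0, population SD 1.

    A constant input maps to the all-zero vector (flagged when
    ``return_constant`` is true) rather than erroring, so that degenerate
    regulator profiles score as uninformative instead of crashing the
    scoring pipeline.  Standardization is what puts miRNA and mRNA
    regulators, measured on different absolute scales, on equal footing:
    only the shape of the profile across samples survives.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize_row needs a 1-D vector of length >= 2")
    mu = x.mean()
    sd = x.std()  # population (1/n) convention
    if sd == 0.0:
        z = np.zeros_like(x)
        return (z, True) if return_constant else z
    z = (x - mu) / sd
    return (z, False) if return_constant else z


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise :func:`standardize_row` for a 2-D array (constant rows -> 0)."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    safe = np.where(sd == 0.0, 1.0, sd)
    z = (values - mu) / safe
    z[np.squeeze(sd == 0.0, axis=1)] = 0.0
    return z
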