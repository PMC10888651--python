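"""Readers and writers for the text formats the pipeline exchanges.

Supported formats:

* GCT 1.2 (``#1.2`` header) and GCT 1.3 (``#1.3``) dense matrices, plus a plain
  TSV dialect (header row of column ids, one row per gene). The HDF5-backed
  GCTX dialect is available read-only through the same interface.
* GMT gene-set collections (one set per tab-separated line).
* Tab-separated metadata tables following the GSE92742 column conventions
  (``sig_info``: sig_id, pert_id, pert_iname, pert_type, cell_id;
  ``gene_info``: pr_gene_id, pr_gene_symbol, pr_is_lm, pr_is_bing).

All identifiers are opaque, case-sensitive strings; no symbol normalization is
attempted. Missing values are written as ``NA`` and any of NA / NaN / empty is
accepted on read. Round trips are lossless: ids reproduce exactly and values to
better than 1e-9 relative error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

_NA_STRINGS = {"", "NA", "NaN", "nan", "na"}

GCT12 = "gct1.2"
GCT13 = "gct1.3"
TSV = "tsv"
GCTX = "gctx"


def _parse_value(token: str) -> float:
    if token in _NA_STRINGS:
        return math.nan
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"non-numeric value {token!r}") from exc


def _format_value(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return format(x, ".10g")


@dataclass
class DenseMatrixFile:
    """A dense genes x columns matrix with optional keyed annotations.

    ``row_meta`` / ``col_meta`` are DataFrames indexed by ``row_ids`` /
    ``col_ids``. Invariants: unique ids, matching shapes.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    row_meta: pd.DataFrame | None = None
    col_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValidationError("duplicate column ids")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        for meta, ids, axis in (
            (self.row_meta, self.row_ids, "row"),
            (self.col_meta, self.col_ids, "column"),
        ):
            if meta is not None and list(meta.index) != ids:
                raise ValidationError(f"{axis}_meta index does not match {axis}_ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        row_meta: pd.DataFrame | None = None,
        col_meta: pd.DataFrame | None = None,
    ) -> "DenseMatrixFile":
        return cls(
            row_ids=list(map(str, frame.index)),
            col_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            row_meta=row_meta,
            col_meta=col_meta,
        )

    def subset(
        self, rows: Sequence[str] | None = None, cols: Sequence[str] | None = None
    ) -> "DenseMatrixFile":
        frame = self.to_frame()
        if rows is not None:
            frame = frame.loc[list(rows)]
        if cols is not None:
            frame = frame[list(cols)]
        row_meta = self.row_meta.loc[frame.index] if self.row_meta is not None else None
        col_meta = self.col_meta.loc[frame.columns] if self.col_meta is not None else None
        return DenseMatrixFile.from_frame(frame, row_meta=row_meta, col_meta=col_meta)


# ---------------------------------------------------------------------------
# GCT / TSV matrices
# ---------------------------------------------------------------------------


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if first == "#1.2":
        return GCT12
    if first == "#1.3":
        return GCT13
    if path.suffix.lower() == ".gctx":
        return GCTX
    return TSV


def read_gct(path, dialect: str | None = None) -> DenseMatrixFile:
    """Read a dense matrix from GCT 1.2 / 1.3 / TSV text (or GCTX HDF5).

    ``dialect`` is auto-detected from the header line when omitted. A header
    inconsistent with the declared dialect raises :class:`FormatError` naming
    the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect == GCTX:
        return read_gctx(path)
    lines = path.read_text().splitlines()
    if dialect == GCT12:
        return _read_gct12(lines)
    if dialect == GCT13:
        return _read_gct13(lines)
    if dialect == TSV:
        return _read_tsv_matrix(lines)
    raise ValueError(f"unknown dialect {dialect!r}")


def _split(line: str) -> list[str]:
    return line.split("\t")


def _read_dims(lines: list[str], expected: int) -> list[int]:
    if len(lines) < 2:
        raise FormatError("line 2: missing dimension line")
    tokens = _split(lines[1])
    if len(tokens) != expected:
        raise FormatError(
            f"line 2: expected {expected} dimension fields, got {len(tokens)}"
        )
    try:
        return [int(t) for t in tokens]
    except ValueError as exc:
        raise FormatError(f"line 2: non-integer dimension in {tokens!r}") from exc


def _read_gct12(lines: list[str]) -> DenseMatrixFile:
    if not lines or lines[0] != "#1.2":
        raise FormatError("line 1: expected '#1.2' version tag")
    n_rows, n_cols = _read_dims(lines, 2)
    if len(lines) < 3:
        raise FormatError("line 3: missing column header")
    header = _split(lines[2])
    if len(header) != n_cols + 2:
        raise FormatError(
            f"line 3: expected {n_cols + 2} header fields, got {len(header)}"
        )
    col_ids = header[2:]
    row_ids, descriptions, rows = [], [], []
    for i, line in enumerate(lines[3 : 3 + n_rows], start=4):
        fields = _split(line)
        if len(fields) != n_cols + 2:
            raise FormatError(f"line {i}: expected {n_cols + 2} fields, got {len(fields)}")
        row_ids.append(fields[0])
        descriptions.append(fields[1])
        rows.append([_parse_value(v) for v in fields[2:]])
    if len(rows) != n_rows:
        raise FormatError(f"expected {n_rows} data rows, found {len(rows)}")
    row_meta = pd.DataFrame({"Description": descriptions}, index=row_ids)
    return DenseMatrixFile(row_ids, col_ids, np.array(rows, dtype=float).reshape(n_rows, n_cols), row_meta=row_meta)


def _read_gct13(lines: list[str]) -> DenseMatrixFile:
    if not lines or lines[0] != "#1.3":
        raise FormatError("line 1: expected '#1.3' version tag")
    n_rows, n_cols, n_rmeta, n_cmeta = _read_dims(lines, 4)
    header = _split(lines[2])
    if len(header) != 1 + n_rmeta + n_cols:
        raise FormatError(
            f"line 3: expected {1 + n_rmeta + n_cols} header fields, got {len(header)}"
        )
    rmeta_names = header[1 : 1 + n_rmeta]
    col_ids = header[1 + n_rmeta :]
    cmeta: dict[str, list[str]] = {}
    for k in range(n_cmeta):
        line_no = 4 + k
        fields = _split(lines[3 + k])
        if len(fields) != 1 + n_rmeta + n_cols:
            raise FormatError(f"line {line_no}: ragged column-metadata row")
        cmeta[fields[0]] = fields[1 + n_rmeta :]
    row_ids, rmeta_rows, rows = [], [], []
    start = 3 + n_cmeta
    for i, line in enumerate(lines[start : start + n_rows], start=start + 1):
        fields = _split(line)
        if len(fields) != 1 + n_rmeta + n_cols:
            raise FormatError(f"line {i}: ragged data row")
        row_ids.append(fields[0])
        rmeta_rows.append(fields[1 : 1 + n_rmeta])
        rows.append([_parse_value(v) for v in fields[1 + n_rmeta :]])
    if len(rows) != n_rows:
        raise FormatError(f"expected {n_rows} data rows, found {len(rows)}")
    row_meta = (
        pd.DataFrame(rmeta_rows, index=row_ids, columns=rmeta_names) if n_rmeta else None
    )
    col_meta = pd.DataFrame(cmeta, index=col_ids) if n_cmeta else None
    return DenseMatrixFile(
        row_ids, col_ids, np.array(rows, dtype=float).reshape(n_rows, n_cols),
        row_meta=row_meta, col_meta=col_meta,
    )


def _read_tsv_matrix(lines: list[str]) -> DenseMatrixFile:
    if not lines:
        raise FormatError("line 1: empty file")
    header = _split(lines[0])
    col_ids = header[1:]
    row_ids, rows = [], []
    for i, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = _split(line)
        if len(fields) != len(header):
            raise FormatError(f"line {i}: ragged row")
        row_ids.append(fields[0])
        rows.append([_parse_value(v) for v in fields[1:]])
    return DenseMatrixFile(row_ids, col_ids, np.array(rows, dtype=float).reshape(len(row_ids), len(col_ids)))


def read_gctx(path) -> DenseMatrixFile:
    """Read the HDF5 GCTX dialect (cmap conventions: 0/DATA/0/matrix etc.)."""
    import h5py

    def _decode(arr) -> list[str]:
        return [x.decode() if isinstance(x, bytes) else str(x) for x in arr]

    with h5py.File(path, "r") as fh:
        matrix = np.asarray(fh["0/DATA/0/matrix"], dtype=float)
        row_ids = _decode(fh["0/META/ROW/id"][...])
        col_ids = _decode(fh["0/META/COL/id"][...])
        # GCTX stores the matrix as columns x rows
        if matrix.shape == (len(col_ids), len(row_ids)):
            matrix = matrix.T
    return DenseMatrixFile(row_ids, col_ids, matrix)


def write_gct(m: DenseMatrixFile, path, dialect: str | None = None) -> Path:
    """Write ``m`` as GCT text; :func:`read_gct` inverts it.

    When ``dialect`` is omitted, GCT 1.2 is used unless the matrix carries
    column metadata or row metadata beyond a Description field.
    """
    path = Path(path)
    if dialect is None:
        plain_row_meta = m.row_meta is None or list(m.row_meta.columns) == ["Description"]
        dialect = GCT12 if (m.col_meta is None and plain_row_meta) else GCT13
    if dialect == GCT12:
        text = _write_gct12(m)
    elif dialect == GCT13:
        text = _write_gct13(m)
    elif dialect == TSV:
        text = _write_tsv_matrix(m)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text(text)
    return path


def _write_gct12(m: DenseMatrixFile) -> str:
    n_rows, n_cols = m.shape
    desc = (
        list(m.row_meta["Description"].astype(str))
        if m.row_meta is not None and "Description" in m.row_meta.columns
        else list(m.row_ids)
    )
    out = ["#1.2", f"{n_rows}\t{n_cols}", "\t".join(["Name", "Description", *m.col_ids])]
    for rid, d, row in zip(m.row_ids, desc, m.values):
        out.append("\t".join([rid, d, *(_format_value(v) for v in row)]))
    return "\n".join(out) + "\n"


def _write_gct13(m: DenseMatrixFile) -> str:
    n_rows, n_cols = m.shape
    rmeta = m.row_meta if m.row_meta is not None else pd.DataFrame(index=m.row_ids)
    cmeta = m.col_meta if m.col_meta is not None else pd.DataFrame(index=m.col_ids)
    n_rmeta, n_cmeta = rmeta.shape[1], cmeta.shape[1]
    out = [
        "#1.3",
        f"{n_rows}\t{n_cols}\t{n_rmeta}\t{n_cmeta}",
        "\t".join(["id", *map(str, rmeta.columns), *m.col_ids]),
    ]
    for name in cmeta.columns:
        out.append(
            "\t".join([str(name), *(["na"] * n_rmeta), *cmeta[name].astype(str)])
        )
    for rid, meta_row, row in zip(m.row_ids, rmeta.astype(str).to_numpy().tolist() if n_rmeta else [[]] * n_rows, m.values):
        out.append("\t".join([rid, *meta_row, *(_format_value(v) for v in row)]))
    return "\n".join(out) + "\n"


def _write_tsv_matrix(m: DenseMatrixFile) -> str:
    out = ["\t".join(["id", *m.col_ids])]
    for rid, row in zip(m.row_ids, m.values):
        out.append("\t".join([rid, *(_format_value(v) for v in row)]))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            # dedupe preserving order
            object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))


@dataclass
class GeneSetCollection:
    """A keyed collection of gene sets (GMT contents)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self):
        for sid, s in self.sets.items():
            if sid != s.set_id:
                raise ValidationError(f"set key {sid!r} != set_id {s.set_id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id].genes


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``set_id, description, member...`` lines.

    Duplicate members within a line are collapsed; a line with fewer than three
    fields is a format error.
    """
    sets: dict[str, GeneSet] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {i}: GMT line needs >=3 tab-separated fields")
        set_id, description = fields[0], fields[1]
        if set_id in sets:
            raise ValidationError(f"line {i}: duplicate set_id {set_id!r}")
        genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
        sets[set_id] = GeneSet(set_id, description, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([s.set_id, s.description, *s.genes]) for s in collection
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

_FLAG_COLUMNS = ("pr_is_lm", "pr_is_bing")


def read_metadata_table(path, required_columns: Iterable[str] = ()) -> pd.DataFrame:
    """Read a TSV metadata table (sig_info / gene_info conventions).

    The presence of each name in ``required_columns`` is validated; a missing
    column raises :class:`ValidationError` naming it. The 0/1 landmark and BING
    flag columns are coerced to boolean.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required_columns:
        if col not in table.columns:
            raise ValidationError(f"metadata table {path} missing required column '{col}'")
    for col in _FLAG_COLUMNS:
        if col in table.columns:
            table[col] = table[col].map(lambda v: v.strip() in {"1", "True", "true"})
    return table


def write_metadata_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = table.copy()
    for col in _FLAG_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)
    return path
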