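"""Reading and writing IMPUTE/HAPGEN-dialect legend and haplotype files.

A *legend* is a headered, whitespace-delimited table with one row per
variant; a *haplotype* file is a headerless 0/1 matrix, one row per variant
and one column per haplotype, whitespace-delimited.  Both may be
gzip-compressed; compression is detected from magic bytes on read and from a
``.gz`` suffix on write.

Positions are 1-based and the alternate allele is always treated as the
minor (counted) allele, so a variant's minor allele count is its row sum.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, LegendParseError, PairingError

FUNCTIONAL_CLASSES = ("functional", "synonymous", "other")
CAUSAL_LABELS = ("none", "risk", "protective")

#: canonical legend columns and their defaults when absent on disk
REQUIRED_COLUMNS = ("id", "position", "ref", "alt")
DEFAULT_COLUMNS = {
    "fun": "other",
    "protected": False,
    "prune_weight": 1.0,
    "causal_label": "none",
    "pruned": False,
}
_CANONICAL_ORDER = list(REQUIRED_COLUMNS) + list(DEFAULT_COLUMNS)

_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no", ""}


def _open_maybe_gzip(path) -> io.TextIOBase:
    """Open a text file, transparently decompressing gzip (detected by magic bytes)."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _coerce_bool(series: pd.Series, name: str) -> pd.Series:
    vals = series.astype(str).str.strip().str.lower()
    bad = ~(vals.isin(_TRUTHY) | vals.isin(_FALSY))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise LegendParseError(f"column '{name}' has non-boolean value {series.iloc[i]!r}", line=i + 2)
    return vals.isin(_TRUTHY)


@dataclass
class LegendTable:
    """Per-variant metadata paired with a haplotype matrix.

    Wraps a :class:`pandas.DataFrame` whose canonical columns are
    ``id, position, ref, alt, fun, protected, prune_weight, causal_label,
    pruned``; any extra columns are carried along verbatim.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.df.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"legend is missing mandatory column '{col}'")
        for col, default in DEFAULT_COLUMNS.items():
            if col not in df.columns:
                df[col] = default
        extras = [c for c in df.columns if c not in _CANONICAL_ORDER]
        df = df[_CANONICAL_ORDER + extras]

        pos = pd.to_numeric(df["position"], errors="coerce")
        if pos.isna().any():
            i = int(np.flatnonzero(pos.isna().to_numpy())[0])
            raise LegendParseError(
                f"non-numeric position {df['position'].iloc[i]!r}", line=i + 2
            )
        df["position"] = pos.astype(np.int64)
        if len(df) > 1 and (np.diff(df["position"].to_numpy()) < 0).any():
            raise FormatError("positions must be non-decreasing")

        for col in ("id", "ref", "alt", "fun", "causal_label"):
            df[col] = df[col].astype(str)
        for col in ("protected", "pruned"):
            if df[col].dtype != bool:
                df[col] = _coerce_bool(df[col], col)
        df["prune_weight"] = pd.to_numeric(df["prune_weight"], errors="raise").astype(float)
        if (df["prune_weight"].to_numpy() < 0).any():
            raise DomainError("prune_weight must be >= 0")

        df = df.reset_index(drop=True)
        object.__setattr__(self, "df", df)

    # -- convenient array views ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def position(self) -> np.ndarray:
        return self.df["position"].to_numpy()

    @property
    def fun(self) -> np.ndarray:
        return self.df["fun"].to_numpy()

    @property
    def protected(self) -> np.ndarray:
        return self.df["protected"].to_numpy(dtype=bool)

    @property
    def prune_weight(self) -> np.ndarray:
        return self.df["prune_weight"].to_numpy(dtype=float)

    @property
    def causal_label(self) -> np.ndarray:
        return self.df["causal_label"].to_numpy()

    @property
    def pruned(self) -> np.ndarray:
        return self.df["pruned"].to_numpy(dtype=bool)

    def copy(self) -> "LegendTable":
        return LegendTable(self.df.copy())

    def subset(self, rows) -> "LegendTable":
        return LegendTable(self.df.iloc[np.asarray(rows)].reset_index(drop=True))

    def equals(self, other: "LegendTable") -> bool:
        return self.df.equals(other.df)


class HaplotypeMatrix:
    """Binary variants x haplotypes matrix.

    Rows are variants, columns are haplotypes; entry 1 means the haplotype
    carries the alternate (minor) allele.  The per-row sum is the variant's
    minor allele count (MAC).
    """

    __slots__ = ("data",)

    def __init__(self, entries, validate: bool = True):
        a = np.asarray(entries)
        if a.ndim != 2:
            raise DomainError("haplotype matrix must be two-dimensional")
        if validate and a.size and not ((a == 0) | (a == 1)).all():
            raise DomainError("haplotype entries must be 0 or 1")
        self.data = np.ascontiguousarray(a, dtype=np.uint8)

    @property
    def n_variants(self) -> int:
        return self.data.shape[0]

    @property
    def M(self) -> int:
        """Number of haplotype columns (2N for N diploid individuals)."""
        return self.data.shape[1]

    @property
    def mac(self) -> np.ndarray:
        """Per-variant minor allele count (row sum)."""
        return self.data.sum(axis=1, dtype=np.int64)

    def copy(self) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.data.copy(), validate=False)

    def column_subset(self, indices) -> "HaplotypeMatrix":
        idx = np.asarray(indices, dtype=np.int64)
        return HaplotypeMatrix(self.data[:, idx], validate=False)

    def row_subset(self, rows) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.data[np.asarray(rows)], validate=False)

    def equals(self, other: "HaplotypeMatrix") -> bool:
        return self.data.shape == other.data.shape and np.array_equal(self.data, other.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"HaplotypeMatrix({self.n_variants} variants x {self.M} haplotypes)"


def check_paired(matrix: HaplotypeMatrix, legend: LegendTable) -> None:
    """Raise :class:`PairingError` unless legend rows match matrix rows."""
    if len(legend) != matrix.n_variants:
        raise PairingError(
            f"legend has {len(legend)} rows but haplotype matrix has {matrix.n_variants}"
        )


# ---------------------------------------------------------------------------
# legend I/O
# ---------------------------------------------------------------------------

def read_legend(path) -> LegendTable:
    """Read a headered legend file (plain or gzip)."""
    with _open_maybe_gzip(path) as fh:
        df = pd.read_csv(fh, sep=r"\s+", dtype=str)
    return LegendTable(df)


def write_legend(table: LegendTable, path, delimiter: str = " ") -> None:
    """Write a legend; booleans serialize as 0/1, gzip when the path ends in .gz."""
    df = table.df.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# haplotype I/O
# ---------------------------------------------------------------------------

def read_haplotypes(path) -> HaplotypeMatrix:
    """Read a whitespace-delimited 0/1 haplotype matrix (plain or gzip)."""
    with _open_maybe_gzip(path) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows:
        return HaplotypeMatrix(np.zeros((0, 0), dtype=np.uint8), validate=False)
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise FormatError(f"inconsistent column counts: {sorted(widths)}")
    arr = np.array(rows, dtype=object)
    bad = (arr != "0") & (arr != "1")
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"token {arr[r, c]!r} at row {r + 1}, column {c + 1} is not 0/1"
        )
    return HaplotypeMatrix((arr == "1").astype(np.uint8), validate=False)


def write_haplotypes(
    matrix: HaplotypeMatrix,
    path,
    drop_pruned: bool = False,
    legend: LegendTable | None = None,
    delimiter: str = " ",
) -> None:
    """Write a haplotype matrix; optionally omit rows flagged pruned in the legend.

    When ``drop_pruned`` is set the paired legend must be supplied (the pruned
    flag lives there); the caller is responsible for writing the legend with
    the same rows dropped.
    """
    data = matrix.data
    if drop_pruned:
        if legend is None:
            raise DomainError("drop_pruned requires the paired legend")
        check_paired(matrix, legend)
        data = data[~legend.pruned]
    np.savetxt(path, data, fmt="%d", delimiter=delimiter)
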