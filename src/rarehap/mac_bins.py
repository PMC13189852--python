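"""Minor-allele-count (MAC) bin schemas and allele-frequency-spectrum summaries.

Rare variants are binned by MAC rather than continuous MAF so that expected
counts can be matched bin-by-bin.  The default schema follows the standard
seven-bin layout: singletons, doubletons, 3-5, 6-10, 11-20, 21 to MAF 0.5%,
and MAF 0.5% to MAF 1%.  "Rare" means MAC <= round(0.01 * M), inclusive of
the boundary, where M is the haplotype count.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_up
from .errors import DomainError, SchemaError
from .io_formats import HaplotypeMatrix, LegendTable, check_paired


@dataclass(frozen=True)
class MACBinSchema:
    """Ordered, disjoint, contiguous closed MAC intervals [lo, hi] for one M."""

    bins: tuple[tuple[int, int], ...]
    M: int

    def __post_init__(self):
        prev_hi = 0
        for lo, hi in self.bins:
            if lo > hi:
                raise SchemaError(f"empty bin [{lo}, {hi}]")
            if lo != prev_hi + 1:
                raise SchemaError("bins must be contiguous starting at MAC 1")
            prev_hi = hi

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def rare_cap(self) -> int:
        """Largest MAC still considered rare (upper bound of the last bin)."""
        return self.bins[-1][1]

    @property
    def lows(self) -> np.ndarray:
        return np.array([b[0] for b in self.bins], dtype=np.int64)

    @property
    def his(self) -> np.ndarray:
        return np.array([b[1] for b in self.bins], dtype=np.int64)

    def assign(self, mac: int):
        """Bin index containing ``mac``; None when mac is 0 or above the cap."""
        return assign_bin(mac, self)

    def assign_array(self, macs) -> np.ndarray:
        """Vectorized bin assignment; -1 marks MACs outside every bin."""
        macs = np.asarray(macs, dtype=np.int64)
        if (macs < 0).any():
            raise DomainError("MAC must be non-negative")
        idx = np.searchsorted(self.his, macs)
        out = np.full(macs.shape, -1, dtype=np.int64)
        inside = (macs >= 1) & (macs <= self.rare_cap)
        out[inside] = idx[inside]
        return out


#: nominal upper bounds of the seven default bins, the last two expressed as
#: fractions of the haplotype count (MAF 0.5% and 1%)
_FIXED_UPPERS = (1, 2, 5, 10, 20)


def default_bins(M: int) -> MACBinSchema:
    """Default MAC bin schema for ``M`` haplotypes.

    For M = 20,000 this yields the seven bins
    [1,1], [2,2], [3,5], [6,10], [11,20], [21,100], [101,200].
    For small M, bins whose nominal bounds collapse are dropped and the
    remaining bins stay contiguous up to the rare cap round(0.01*M).
    """
    if M < 2:
        raise DomainError("M must be >= 2")
    cap = max(round_half_up(0.01 * M), 1)
    half = round_half_up(0.005 * M)
    bins: list[tuple[int, int]] = []
    lo = 1
    for upper in (*_FIXED_UPPERS, half, cap):
        hi = min(upper, cap)
        if hi >= lo:
            bins.append((lo, hi))
            lo = hi + 1
        if lo > cap:
            break
    return MACBinSchema(tuple(bins), M)


def assign_bin(mac: int, schema: MACBinSchema):
    """Index of the schema bin containing ``mac`` (None if common or absent)."""
    if mac < 0:
        raise DomainError("MAC must be non-negative")
    if mac == 0 or mac > schema.rare_cap:
        return None
    his = [b[1] for b in schema.bins]
    j = bisect_left(his, mac)
    lo, hi = schema.bins[j]
    assert lo <= mac <= hi
    return j


@dataclass(eq=False)
class AFSSummary:
    """Per-bin proportions of (rare) variants for one annotation class."""

    proportions: np.ndarray
    M: int
    fun_class: str | None = None
    n_variants: int = 0
    empty: bool = False
    schema: MACBinSchema | None = field(default=None, repr=False)

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)


def compute_afs(
    matrix: HaplotypeMatrix,
    legend: LegendTable,
    schema: MACBinSchema,
    fun_class: str | None = None,
) -> AFSSummary:
    """Observed AFS of non-pruned variants of one class (or all classes).

    Proportions are normalized over the rare bins; a class with no rare
    variants yields an all-zero vector with ``empty=True``.
    """
    check_paired(matrix, legend)
    mask = ~legend.pruned
    if fun_class is not None:
        mask &= legend.fun == fun_class
    idx = schema.assign_array(matrix.mac[mask])
    idx = idx[idx >= 0]
    counts = np.bincount(idx, minlength=schema.n_bins).astype(float)
    total = counts.sum()
    if total == 0:
        return AFSSummary(np.zeros(schema.n_bins), schema.M, fun_class, 0, True, schema)
    return AFSSummary(counts / total, schema.M, fun_class, int(total), False, schema)


def afs_difference(simulated: AFSSummary, target: AFSSummary) -> np.ndarray:
    """Element-wise simulated - target bin proportions."""
    if len(simulated.proportions) != len(target.proportions):
        raise SchemaError("AFS summaries have different bin counts")
    return simulated.proportions - target.proportions


# ---------------------------------------------------------------------------
# text interchange (CLI)
# ---------------------------------------------------------------------------

def write_afs_summary(summary: AFSSummary, path, delimiter: str = "\t") -> None:
    import pandas as pd

    schema = summary.schema or default_bins(summary.M)
    pd.DataFrame(
        {"lo": schema.lows, "hi": schema.his, "proportion": summary.proportions}
    ).to_csv(path, sep=delimiter, index=False)


def read_afs_summary(path, M: int) -> AFSSummary:
    import pandas as pd

    df = pd.read_csv(path, sep=r"\s+")
    schema = MACBinSchema(tuple(zip(df["lo"].astype(int), df["hi"].astype(int))), M)
    props = df["proportion"].to_numpy(dtype=float)
    return AFSSummary(props, M, None, 0, bool(props.sum() == 0), schema)
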