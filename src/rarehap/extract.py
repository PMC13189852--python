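"""Seeded extraction of haplotype column subsets (the *extract* step).

Groups (cases, controls, external panels, batches) are formed by drawing
columns uniformly without replacement from one shared pool.  The chosen
index list is returned so it can be reused verbatim on a differently pruned
matrix of the same width — the mechanism behind paired case/control arms —
and ``exclude`` lets successive draws stay disjoint.
"""

from __future__ import annotations

import numpy as np

from .errors import CapacityError, DomainError
from .io_formats import HaplotypeMatrix


def extract_haplotypes(
    matrix: HaplotypeMatrix,
    count: int | None = None,
    seed=None,
    indices=None,
    exclude=None,
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Take ``count`` random columns (seeded) or the explicit ``indices``.

    Exactly one of (count, indices) must be given; ``count`` must be even
    (haplotypes come in diploid pairs).  Columns are returned in ascending
    index order regardless of draw order, so outputs are canonical.
    """
    if (count is None) == (indices is None):
        raise DomainError("give exactly one of count(+seed) or indices")

    excl = np.asarray(exclude, dtype=np.int64) if exclude is not None else np.empty(0, np.int64)
    if excl.size and ((excl < 0) | (excl >= matrix.M)).any():
        raise IndexError("exclude indices out of range")

    if indices is not None:
        idx = np.asarray(indices, dtype=np.int64)
        if idx.size and ((idx < 0) | (idx >= matrix.M)).any():
            raise IndexError("requested column index out of range")
        if np.intersect1d(idx, excl).size:
            raise DomainError("requested indices overlap the exclude list")
        chosen = np.sort(idx)
    else:
        if count <= 0 or count % 2 != 0:
            raise DomainError("count must be a positive even number of haplotypes")
        pool = np.setdiff1d(np.arange(matrix.M, dtype=np.int64), excl, assume_unique=False)
        if count > pool.size:
            raise CapacityError(
                f"requested {count} haplotypes but only {pool.size} are available"
            )
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(pool, size=count, replace=False))

    return matrix.column_subset(chosen), chosen
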