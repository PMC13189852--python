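"""Synthetic over-simulated haplotype pools.

A statistical stand-in for a population-genetic haplotype simulator: it
draws ``inflation`` times the expected number of rare variants (so every MAC
bin is over-abundant and pruning always has material to remove), samples each
variant's MAC from the AFS decay, and assigns carriers uniformly at random
across haplotype columns.

Variants are generated independently — there is **no linkage disequilibrium**
and no demography.  The pruning/extraction/scenario engine is LD-agnostic,
so these pools exercise it fully, but they are fixtures for the engine, not
realistic haplotypes; LD realism comes from simulating real reference panels
upstream.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError
from .expect import AFSParams, NvarParams
from .io_formats import HaplotypeMatrix, LegendTable
from .mac_bins import default_bins
from .prune import stochastic_round

_BASES = np.array(list("ACGT"))


def generate_haplotypes(
    M: int,
    region_kb: float,
    nvar: NvarParams,
    afs: AFSParams,
    inflation: float = 1.6,
    prop_fun: float = 0.6,
    seed=None,
) -> tuple[HaplotypeMatrix, LegendTable]:
    """Generate an over-simulated pool of M haplotypes over ``region_kb`` kilobases.

    The number of variants is stochastic_round(inflation * Nvar(M/2) * region_kb);
    each variant's MAC is an independent draw from the normalized AFS decay on
    [1, round(0.01*M)], each variant is functional with probability
    ``prop_fun`` (synonymous otherwise), and positions are strictly
    increasing.  A fixed seed makes the output bit-identical.
    """
    if M < 2 or M % 2 != 0:
        raise DomainError("M must be an even number >= 2")
    if inflation < 1:
        raise DomainError("inflation must be >= 1 (the pool must be over-abundant)")
    if not (0 <= prop_fun <= 1):
        raise DomainError("prop_fun must be in [0, 1]")

    rng = np.random.default_rng(seed)
    cap = default_bins(M).rare_cap
    pmf = afs.mac_pmf(cap)

    n_variants = stochastic_round(inflation * nvar.total(M // 2, region_kb), rng)
    macs = rng.choice(np.arange(1, cap + 1), size=n_variants, p=pmf)

    data = np.zeros((n_variants, M), dtype=np.uint8)
    for i, m in enumerate(macs):
        data[i, rng.choice(M, size=int(m), replace=False)] = 1

    is_fun = rng.random(n_variants) < prop_fun

    region_bp = max(int(round(region_kb * 1000)), n_variants)
    positions = np.sort(rng.choice(region_bp, size=n_variants, replace=False)) + 1

    ref_i = rng.integers(0, 4, size=n_variants)
    alt_i = (ref_i + rng.integers(1, 4, size=n_variants)) % 4

    import pandas as pd

    legend = LegendTable(
        pd.DataFrame(
            {
                "id": [f"var{i + 1:06d}" for i in range(n_variants)],
                "position": positions,
                "ref": _BASES[ref_i],
                "alt": _BASES[alt_i],
                "fun": np.where(is_fun, "functional", "synonymous"),
            }
        )
    )
    return HaplotypeMatrix(data, validate=False), legend
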