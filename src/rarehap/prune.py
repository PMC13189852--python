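"""Pruning an over-simulated haplotype dataset to match expected counts (the *sim* step).

For each annotation class being pruned and each MAC bin, the observed number
of surviving variants is reduced to the (stochastically rounded) expected
count by zeroing whole variant rows.  Protected variants are never selected;
per-variant prune weights bias the selection.  Pruned rows are retained as
all-zero rows and flagged in the legend so that haplotype column indices stay
aligned across nested prunes; the writer drops them on request.

Bins are processed from the largest MAC down to singletons, functional class
before synonymous, purely to fix the order in which the random stream is
consumed — whole-row removal makes bins independent, so the order does not
affect the distribution of outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InfeasibleSelectionError, SchemaError
from .expect import ExpectedCounts
from .io_formats import CAUSAL_LABELS, HaplotypeMatrix, LegendTable, check_paired
from .mac_bins import MACBinSchema

PRUNABLE_CLASSES = ("functional", "synonymous")


@dataclass
class PruneConfig:
    """Everything that determines one prune: targets, selection rules, seed."""

    expected: ExpectedCounts
    seed: int
    classes_to_prune: tuple[str, ...] = PRUNABLE_CLASSES
    respect_protected: bool = True
    use_prune_weights: bool = True
    label_pruned_as: str = "none"

    def __post_init__(self):
        if not self.classes_to_prune:
            raise DomainError("classes_to_prune must be non-empty")
        unknown = set(self.classes_to_prune) - set(PRUNABLE_CLASSES)
        if unknown:
            raise DomainError(f"unknown classes {sorted(unknown)}")
        if self.label_pruned_as not in CAUSAL_LABELS:
            raise DomainError(f"label_pruned_as must be one of {CAUSAL_LABELS}")


def stochastic_round(x: float, rng: np.random.Generator) -> int:
    """Round x down or up at random so the expectation equals x exactly.

    Always consumes one uniform draw, keeping the random stream layout
    independent of whether x happens to be an integer.
    """
    if x < 0:
        raise DomainError("stochastic_round requires x >= 0")
    f = math.floor(x)
    return int(f + (rng.random() < (x - f)))


def select_prune_set(pool, k: int, weights, rng: np.random.Generator) -> np.ndarray:
    """Sample ``k`` indices from ``pool`` without replacement, draws proportional
    to the remaining weights (zero-weight entries are never selected).

    Uses exponential keys (Efraimidis-Spirakis), which realizes exactly the
    successive weighted-draw distribution.  Returns the chosen indices sorted.
    """
    pool = np.asarray(pool, dtype=np.int64)
    w = np.asarray(weights, dtype=float)
    if w.shape != pool.shape:
        raise DomainError("weights must match the pool length")
    if (w < 0).any():
        raise DomainError("selection weights must be >= 0")
    n_pos = int((w > 0).sum())
    if k < 0:
        raise DomainError("k must be >= 0")
    if k > n_pos:
        raise InfeasibleSelectionError(
            f"requested {k} variants but only {n_pos} have positive weight",
            shortfall=k - n_pos,
        )
    if k == 0:
        return np.empty(0, dtype=np.int64)
    u = rng.random(pool.shape[0])
    keys = np.full(pool.shape[0], np.inf)
    pos = w > 0
    keys[pos] = -np.log(u[pos]) / w[pos]
    order = np.argsort(keys, kind="stable")
    return np.sort(pool[order[:k]])


def prune_dataset(
    matrix: HaplotypeMatrix,
    legend: LegendTable,
    schema: MACBinSchema,
    config: PruneConfig,
) -> tuple[HaplotypeMatrix, LegendTable, list[dict]]:
    """Prune per (class, bin) so surviving counts match the expected targets.

    Returns a new matrix (pruned rows zeroed), an updated legend (pruned flag
    and optional causal label set), and a per-(class, bin) report listing the
    observed count, the realized integer target, the number pruned, and any
    warning (under-simulation or a protected/zero-weight shortfall — both
    non-fatal: the dataset is never up-sampled).
    """
    check_paired(matrix, legend)
    if schema.M != matrix.M:
        raise SchemaError(
            f"schema is for M={schema.M} haplotypes but matrix has M={matrix.M}"
        )
    if config.expected.schema.bins != schema.bins:
        raise SchemaError("expected counts were computed on a different bin schema")

    rng = np.random.default_rng(config.seed)
    data = matrix.data.copy()
    fun = legend.fun
    protected = legend.protected
    weights_col = legend.prune_weight
    pruned = legend.pruned.copy()
    causal = legend.causal_label.copy()
    bin_idx = schema.assign_array(matrix.mac)

    report: list[dict] = []
    for cls in (c for c in PRUNABLE_CLASSES if c in config.classes_to_prune):
        targets = config.expected.by_class(cls)
        for j in range(schema.n_bins - 1, -1, -1):
            in_bin = np.flatnonzero((fun == cls) & ~pruned & (bin_idx == j))
            observed = in_bin.size
            target = min(observed, stochastic_round(targets[j], rng))
            warning = None
            n_pruned = 0
            if observed > target:
                need = observed - target
                eligible = in_bin[~protected[in_bin]] if config.respect_protected else in_bin
                w = weights_col[eligible] if config.use_prune_weights else np.ones(eligible.size)
                available = int((w > 0).sum())
                if need > available:
                    warning = (
                        f"shortfall: needed to prune {need} but only {available} "
                        f"eligible (protected/zero-weight variants excluded)"
                    )
                    need = available
                chosen = select_prune_set(eligible, need, w, rng)
                data[chosen, :] = 0
                pruned[chosen] = True
                if config.label_pruned_as != "none":
                    causal[chosen] = config.label_pruned_as
                n_pruned = chosen.size
            elif observed < targets[j]:
                warning = (
                    f"under-simulated: observed {observed} < expected {targets[j]:.2f}"
                )
            lo, hi = schema.bins[j]
            report.append(
                {
                    "fun_class": cls,
                    "bin": j,
                    "lo": lo,
                    "hi": hi,
                    "observed": observed,
                    "target": target,
                    "expected": float(targets[j]),
                    "n_pruned": n_pruned,
                    "surviving": observed - n_pruned,
                    "warning": warning,
                }
            )

    new_legend = legend.copy()
    new_legend.df["pruned"] = pruned
    new_legend.df["causal_label"] = causal
    return HaplotypeMatrix(data, validate=False), new_legend, report


def report_frame(report: list[dict]) -> pd.DataFrame:
    """Prune report as a DataFrame (one row per class and bin)."""
    return pd.DataFrame(report)
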