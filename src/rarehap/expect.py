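"""Expected numbers of rare variants per MAC bin (the *calc* step).

Two small parametric curves drive the expectation:

* ``Nvar(n) = phi * n**omega`` — rare variants per kilobase as a function of
  the diploid sample size n (a saturating power law, 0 < omega <= 1);
* ``f(z) = alpha * (z + beta)**(-gamma)`` — the MAC decay, normalized over
  z in [1, rare cap], which splits the total across MAC bins.

Both can be supplied directly or fitted from summary-level target data
(calibration points for Nvar, a target AFS for f).  Class weights scale the
functional and synonymous expectations independently, and a per-bin minimum
threshold guarantees a floor on the number of observed variants per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DomainError, FitError, SchemaError
from .mac_bins import AFSSummary, MACBinSchema, default_bins


@dataclass(frozen=True)
class NvarParams:
    """Parameters of the variants-per-kilobase growth curve Nvar(n) = phi * n**omega."""

    phi: float
    omega: float
    rss: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.phi <= 0:
            raise DomainError("phi must be > 0")
        if not (0 < self.omega <= 1):
            raise DomainError("omega must be in (0, 1]")

    def __call__(self, n):
        """Expected rare variants per kb at diploid sample size n (scalar or array)."""
        out = self.phi * np.asarray(n, dtype=float) ** self.omega
        return out if out.ndim else float(out)

    def total(self, n: int, region_kb: float) -> float:
        return self(n) * region_kb


@dataclass(frozen=True)
class AFSParams:
    """Parameters of the MAC decay f(z) = alpha * (z + beta)**(-gamma).

    alpha cancels under normalization and is kept for completeness; beta
    flattens the head of the spectrum and gamma controls how singleton-heavy
    it is (gamma -> 0 is uniform).
    """

    alpha: float = 1.0
    beta: float = 0.0
    gamma: float = 1.5
    residual: float | None = field(default=None, compare=False)
    at_boundary: bool = field(default=False, compare=False)

    def __post_init__(self):
        if self.alpha <= 0:
            raise DomainError("alpha must be > 0")
        if self.beta < 0:
            raise DomainError("beta must be >= 0")
        if self.gamma <= 0:
            raise DomainError("gamma must be > 0")

    def mac_pmf(self, cap: int) -> np.ndarray:
        """Normalized probability of each MAC z in [1, cap]."""
        z = np.arange(1, cap + 1, dtype=float)
        f = self.alpha * (z + self.beta) ** (-self.gamma)
        return f / f.sum()

    def bin_proportions(self, schema: MACBinSchema) -> np.ndarray:
        """Model proportion of rare variants falling in each schema bin."""
        pmf = self.mac_pmf(schema.rare_cap)
        return np.array([pmf[lo - 1 : hi].sum() for lo, hi in schema.bins])


def fit_nvar(points) -> NvarParams:
    """Least-squares fit of log(variants/kb) = log(phi) + omega*log(n).

    ``points`` is an iterable of (n, variants_per_kb) calibration pairs with
    at least two distinct n.  The residual sum of squares (on the log scale)
    is reported on the returned parameters.
    """
    pts = [(float(n), float(v)) for n, v in points]
    if any(n <= 0 or v <= 0 for n, v in pts):
        raise DomainError("sample sizes and variant densities must be positive")
    ns = np.array([p[0] for p in pts])
    vs = np.array([p[1] for p in pts])
    if len(np.unique(ns)) < 2:
        raise FitError("need at least two calibration points with distinct n")
    x, y = np.log(ns), np.log(vs)
    omega, logphi = np.polyfit(x, y, 1)
    rss = float(np.sum((y - (logphi + omega * x)) ** 2))
    if not (0 < omega <= 1):
        raise FitError(f"fitted omega={omega:.4g} outside (0, 1]")
    return NvarParams(phi=float(np.exp(logphi)), omega=float(omega), rss=rss)


_AFS_STARTS = [(b, g) for b in (0.0, 0.5, 2.0, 8.0) for g in (0.3, 0.8, 1.5, 3.0)]
_GAMMA_FLOOR = 1e-6


def fit_afs(target: AFSSummary, schema: MACBinSchema | None = None) -> AFSParams:
    """Nonlinear least squares of model bin proportions against a target AFS.

    Multi-start from a fixed grid of (beta, gamma); alpha is unidentifiable
    under normalization and returned as 1.  A fit driven to the gamma lower
    bound (an essentially uniform target) is flagged ``at_boundary``.
    """
    schema = schema or target.schema or default_bins(target.M)
    props = np.asarray(target.proportions, dtype=float)
    if len(props) != schema.n_bins:
        raise SchemaError("target AFS length does not match the schema")
    if int((props > 0).sum()) < 3:
        raise FitError("need at least three bins with positive mass")
    props = props / props.sum()

    def residuals(theta):
        beta, gamma = theta
        model = AFSParams(1.0, max(beta, 0.0), max(gamma, _GAMMA_FLOOR))
        return model.bin_proportions(schema) - props

    best = None
    for x0 in _AFS_STARTS:
        sol = optimize.least_squares(
            residuals, x0=x0, bounds=([0.0, _GAMMA_FLOOR], [100.0, 12.0])
        )
        if best is None or sol.cost < best.cost:
            best = sol
    beta, gamma = best.x
    return AFSParams(
        alpha=1.0,
        beta=float(beta),
        gamma=float(max(gamma, _GAMMA_FLOOR)),
        residual=float(2 * best.cost),
        at_boundary=bool(gamma <= 5e-3),
    )


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected rare-variant counts per MAC bin and annotation class.

    ``base_fun``/``base_syn`` are the pre-weighting expectations whose sum is
    Nvar(n) * region_kb; the effective targets used for pruning apply the
    class weight and then the per-bin minimum threshold.
    """

    schema: MACBinSchema
    n: int
    region_kb: float
    base_fun: np.ndarray = field(repr=False)
    base_syn: np.ndarray = field(repr=False)
    w_fun: float = 1.0
    w_syn: float = 1.0
    min_per_bin: int = 0

    @property
    def fun(self) -> np.ndarray:
        """Effective per-bin functional targets (weighted then thresholded)."""
        return np.maximum(self.w_fun * self.base_fun, self.min_per_bin)

    @property
    def syn(self) -> np.ndarray:
        return np.maximum(self.w_syn * self.base_syn, self.min_per_bin)

    def by_class(self, fun_class: str) -> np.ndarray:
        if fun_class == "functional":
            return self.fun
        if fun_class == "synonymous":
            return self.syn
        raise DomainError(f"no expectations for class {fun_class!r}")

    def rescaled(
        self,
        w_fun: float | None = None,
        w_syn: float | None = None,
        min_per_bin: int | None = None,
    ) -> "ExpectedCounts":
        """Same base expectations under different weights/thresholds."""
        kw = {}
        if w_fun is not None:
            kw["w_fun"] = _check_weight(w_fun, "w_fun")
        if w_syn is not None:
            kw["w_syn"] = _check_weight(w_syn, "w_syn")
        if min_per_bin is not None:
            kw["min_per_bin"] = min_per_bin
        return replace(self, **kw)

    def to_frame(self) -> pd.DataFrame:
        """Effective targets as a per-bin table (CLI interchange format)."""
        return pd.DataFrame(
            {
                "lo": self.schema.lows,
                "hi": self.schema.his,
                "e_fun": self.fun,
                "e_syn": self.syn,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, M: int) -> "ExpectedCounts":
        """Rebuild from a per-bin table; the stored values become the base."""
        schema = MACBinSchema(tuple(zip(df["lo"].astype(int), df["hi"].astype(int))), M)
        return cls(
            schema=schema,
            n=M // 2,
            region_kb=float("nan"),
            base_fun=df["e_fun"].to_numpy(dtype=float),
            base_syn=df["e_syn"].to_numpy(dtype=float),
        )


def _check_weight(w: float, name: str) -> float:
    if w < 0:
        raise DomainError(f"{name} must be >= 0")
    return float(w)


def expected_counts(
    nvar: NvarParams,
    afs: AFSParams,
    n: int,
    region_kb: float,
    schema: MACBinSchema,
    prop_fun: float = 0.6,
    w_fun: float = 1.0,
    w_syn: float = 1.0,
    min_per_bin: int = 0,
) -> ExpectedCounts:
    """Expected functional/synonymous rare variants per MAC bin for n individuals.

    The total Nvar(n) * region_kb is split across bins by the AFS model and
    across classes by the scalar functional share ``prop_fun``; class weights
    are applied afterwards and the per-bin minimum last, so thresholds hold
    regardless of weights.
    """
    _check_weight(w_fun, "w_fun")
    _check_weight(w_syn, "w_syn")
    if not (0 <= prop_fun <= 1):
        raise DomainError("prop_fun must be in [0, 1]")
    if region_kb <= 0:
        raise DomainError("region_kb must be > 0")
    if min_per_bin < 0:
        raise DomainError("min_per_bin must be >= 0")
    if schema.M != 2 * n:
        raise SchemaError(
            f"schema built for M={schema.M} haplotypes but n={n} individuals implies M={2 * n}"
        )
    total = nvar.total(n, region_kb)
    props = afs.bin_proportions(schema)
    return ExpectedCounts(
        schema=schema,
        n=n,
        region_kb=region_kb,
        base_fun=total * props * prop_fun,
        base_syn=total * props * (1.0 - prop_fun),
        w_fun=float(w_fun),
        w_syn=float(w_syn),
        min_per_bin=int(min_per_bin),
    )
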