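"""End-to-end type-I-error / power benchmark over the full pipeline.

Each replicate synthesizes an over-abundant pool, runs the three-arm
case-control workflow, filters the chosen arm to rare functional variants
(MAF <= cap in the combined sample), and applies the Burden/SKAT/SKAT-O
tests to the same dataset, so method comparisons are paired within
replicates.

The default configuration is the package's desk-scale study condition: a
2.0 kb region, 1,000 cases and 1,000 controls drawn from a pool of exactly
2(Ncase + Nctrl) haplotypes, inflation 1.6, functional share 0.6, pruning
weights w_fun_a = 1.4 and w_fun_b1 = 1, risk proportion p = 0.5 for the
opposite-direction arm, and flat test weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._util import child_seed
from .assoc import (
    DEFAULT_RHO_GRID,
    GenotypeMatrix,
    burden_test,
    haplotypes_to_genotypes,
    skat_test,
    skato_test,
    variant_weights,
)
from .errors import ConfigError
from .expect import AFSParams, NvarParams, expected_counts
from .mac_bins import default_bins
from .scenarios import filter_variants, make_weights, run_case_control_workflow
from .synth import generate_haplotypes

SCENARIOS = ("null", "same", "opposite")
METHODS = ("burden", "skat", "skato")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for one benchmark experiment."""

    n_case: int = 1000
    n_ctrl: int = 1000
    region_kb: float = 2.0
    inflation: float = 1.6
    prop_fun: float = 0.6
    nvar: NvarParams = field(default_factory=lambda: NvarParams(phi=1.0, omega=0.45))
    afs: AFSParams = field(default_factory=lambda: AFSParams(alpha=1.0, beta=0.0, gamma=1.5))
    w_fun_a: float = 1.4
    w_fun_b1: float = 1.0
    p_risk: float = 0.5
    maf_cap: float = 0.01
    weight_scheme: str = "flat"
    rho_grid: tuple = DEFAULT_RHO_GRID
    n_perm: int = 500

    @property
    def pool_m(self) -> int:
        return 2 * (self.n_case + self.n_ctrl)


def simulate_replicate(
    scenario: str, config: BenchmarkConfig, seed: int
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """One synth -> prune -> extract replicate; returns (genotypes, phenotype, weights).

    Cases occupy the first n_case individuals.  The returned weights follow
    ``config.weight_scheme`` evaluated at the combined-sample MAF.
    """
    if scenario not in SCENARIOS:
        raise ConfigError(f"scenario must be one of {SCENARIOS}")
    m = config.pool_m
    matrix, legend = generate_haplotypes(
        M=m,
        region_kb=config.region_kb,
        nvar=config.nvar,
        afs=config.afs,
        inflation=config.inflation,
        prop_fun=config.prop_fun,
        seed=child_seed(seed, 1),
    )
    schema = default_bins(m)
    expected = expected_counts(
        config.nvar, config.afs, n=m // 2, region_kb=config.region_kb,
        schema=schema, prop_fun=config.prop_fun,
    )
    # p = 1 is the same-direction limit; the opposite arm uses p_risk.
    p = config.p_risk if scenario == "opposite" else 1.0
    weights = make_weights(p=p, w_fun_a=config.w_fun_a, w_fun_b1=config.w_fun_b1)
    bundle = run_case_control_workflow(
        matrix, legend, schema, expected, weights,
        n_case=config.n_case, n_ctrl=config.n_ctrl, seed=child_seed(seed, 2),
    )
    if scenario == "null":
        cases, ctrls = bundle.cases_null, bundle.controls
    elif scenario == "same":
        cases, ctrls = bundle.cases_power, bundle.controls
    else:
        cases, ctrls = bundle.cases_opp, bundle.controls_opp

    from .io_formats import HaplotypeMatrix

    combined = HaplotypeMatrix(
        np.hstack([cases.data, ctrls.data]), validate=False
    )
    filtered, _ = filter_variants(
        combined, bundle.legend_a, maf_cap=config.maf_cap, classes=("functional",)
    )
    geno = haplotypes_to_genotypes(filtered)
    y = np.concatenate(
        [np.ones(config.n_case, dtype=np.int8), np.zeros(config.n_ctrl, dtype=np.int8)]
    )
    w = variant_weights(geno.maf, scheme=config.weight_scheme)
    return geno, y, w


def replicate_pvalues(
    scenario: str, config: BenchmarkConfig, seed: int, methods=METHODS
) -> dict[str, float]:
    """P-values of the requested tests on one shared replicate dataset."""
    geno, y, w = simulate_replicate(scenario, config, seed)
    out = {}
    if geno.n_variants == 0:
        return {m: 1.0 for m in methods}
    for m in methods:
        if m == "burden":
            out[m] = burden_test(geno, y, w).p_value
        elif m == "skat":
            out[m] = skat_test(geno, y, w).p_value
        elif m == "skato":
            out[m] = skato_test(
                geno, y, w, rho_grid=config.rho_grid, n_perm=config.n_perm,
                seed=child_seed(seed, 3),
            ).p_value
        else:
            raise ConfigError(f"unknown method {m!r}")
    return out


def run_benchmark(
    scenario: str,
    reps: int,
    seed: int,
    config: BenchmarkConfig | None = None,
    methods=METHODS,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Rejection rate per method over ``reps`` pipeline replicates.

    All methods see the same replicate datasets (paired comparison).  Returns
    ``{method: {"rate", "ci", "k", "reps"}}`` with exact binomial 95% CIs.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    config = config or BenchmarkConfig()
    rejections = {m: 0 for m in methods}
    for r in range(reps):
        ps = replicate_pvalues(scenario, config, seed=child_seed(seed, 1000 + r), methods=methods)
        for m in methods:
            rejections[m] += ps[m] <= alpha
    results = {}
    for m in methods:
        k = rejections[m]
        ci = stats.binomtest(k, reps).proportion_ci(confidence_level=0.95, method="exact")
        results[m] = {
            "rate": k / reps,
            "ci": (float(ci.low), float(ci.high)),
            "k": int(k),
            "reps": reps,
        }
    return results
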