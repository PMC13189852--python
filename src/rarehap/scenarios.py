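"""Case-control scenario algebra and orchestration.

Three benchmark arms are built from one over-simulated pool:

* **same direction** — cases carry extra functional (risk) variants
  (pruned at weight ``w_fun_a > 1``), controls at the expected level
  (``w_fun_b1 = 1``);
* **null** — cases and controls are disjoint column subsets of the *same*
  pruned matrix, so no variant separates the groups;
* **opposite direction** — risk variants present only in cases and
  protective variants present only in controls, with arm weights derived
  from the risk proportion p by

      w_fun_b2 = p*w_fun_a + (1-p)*w_fun_b1
      w_fun_b3 = (1-p)*w_fun_a + p*w_fun_b1

  which keeps the total causal excess (w_fun_a - w_fun_b1) constant across
  scenarios.

The same case/control column index lists are reused across all arms, so
power and type-I-error datasets are paired by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import child_seed, round_half_up
from .errors import CapacityError, ConstraintError, DomainError
from .expect import ExpectedCounts
from .extract import extract_haplotypes
from .io_formats import HaplotypeMatrix, LegendTable, check_paired
from .mac_bins import MACBinSchema
from .prune import PruneConfig, prune_dataset

_TOL = 1e-9


@dataclass(frozen=True)
class ScenarioWeights:
    """Pruning weights for the three-arm workflow plus the risk proportion p."""

    w_fun_a: float
    w_fun_b1: float
    w_fun_b2: float
    w_fun_b3: float
    w_syn: float
    p: float


def opposite_effect_weights(p: float, w_fun_a: float, w_fun_b1: float) -> tuple[float, float]:
    """Case/control arm weights for the opposite-direction scenario.

    p is the proportion of causal variants that are risk (1-p protective);
    p = 1 is allowed as the same-direction limit, returning (w_fun_a, w_fun_b1).
    """
    if not (0 < p <= 1):
        raise ConstraintError("p must be in (0, 1]")
    if not (w_fun_a > w_fun_b1 > 0):
        raise ConstraintError("need w_fun_a > w_fun_b1 > 0")
    w_b2 = p * w_fun_a + (1 - p) * w_fun_b1
    w_b3 = (1 - p) * w_fun_a + p * w_fun_b1
    return w_b2, w_b3


def make_weights(
    p: float, w_fun_a: float, w_fun_b1: float = 1.0, w_syn: float | None = None
) -> ScenarioWeights:
    """Build a full, constraint-satisfying weight set from (p, w_fun_a, w_fun_b1)."""
    w_b2, w_b3 = opposite_effect_weights(p, w_fun_a, w_fun_b1)
    return ScenarioWeights(
        w_fun_a=w_fun_a,
        w_fun_b1=w_fun_b1,
        w_fun_b2=w_b2,
        w_fun_b3=w_b3,
        w_syn=w_fun_b1 if w_syn is None else w_syn,
        p=p,
    )


def validate_weights(w: ScenarioWeights) -> list[str]:
    """Return the list of violated constraints (empty iff the weights are valid)."""
    violations = []
    if not (0 < w.p <= 1):
        violations.append("p must be in (0, 1]")
    if abs(w.w_fun_b1 - w.w_syn) > _TOL:
        violations.append("w_fun_b1 = w_syn violated")
    if abs((w.w_fun_b2 + w.w_fun_b3) - (w.w_fun_a + w.w_fun_b1)) > _TOL:
        violations.append("w_fun_b2 + w_fun_b3 = w_fun_a + w_fun_b1 violated")
    if 0 < w.p < 1:
        if not (w.w_fun_a > w.w_fun_b2 >= w.w_fun_b1):
            violations.append("ordering w_fun_a > w_fun_b2 >= w_fun_b1 violated")
        if not (w.w_fun_a > w.w_fun_b3 >= w.w_fun_b1):
            violations.append("ordering w_fun_a > w_fun_b3 >= w_fun_b1 violated")
    else:
        if not (w.w_fun_a > w.w_fun_b1):
            violations.append("w_fun_a > w_fun_b1 violated")
    return violations


@dataclass
class ScenarioBundle:
    """All artifacts of one three-arm run: pruned matrices, legends, reports,
    the shared case/control column indices, and the six extracted datasets."""

    weights: ScenarioWeights
    i_case: np.ndarray
    i_ctrl: np.ndarray
    h_a: HaplotypeMatrix
    legend_a: LegendTable
    h_b1: HaplotypeMatrix
    legend_b1: LegendTable
    h_b2: HaplotypeMatrix
    legend_b2: LegendTable
    h_b3: HaplotypeMatrix
    legend_b3: LegendTable
    reports: dict = field(repr=False, default_factory=dict)

    # extracted datasets (columns of the matrices above)
    cases_power: HaplotypeMatrix = None
    controls: HaplotypeMatrix = None
    cases_null: HaplotypeMatrix = None
    cases_opp: HaplotypeMatrix = None
    controls_opp: HaplotypeMatrix = None

    @property
    def datasets(self) -> dict[str, HaplotypeMatrix]:
        return {
            "cases_power": self.cases_power,
            "controls": self.controls,
            "cases_null": self.cases_null,
            "cases_opp": self.cases_opp,
            "controls_opp": self.controls_opp,
        }


# fixed sub-stream ids for seed derivation (one master seed reproduces the bundle)
_STREAM_I_CASE, _STREAM_I_CTRL = 1, 2
_STREAM_2A, _STREAM_2B1, _STREAM_2B2, _STREAM_2B3 = 3, 4, 5, 6


def run_case_control_workflow(
    matrix: HaplotypeMatrix,
    legend: LegendTable,
    schema: MACBinSchema,
    expected: ExpectedCounts,
    weights: ScenarioWeights,
    n_case: int,
    n_ctrl: int,
    seed: int,
) -> ScenarioBundle:
    """Run the full three-arm workflow and return every intermediate product.

    ``expected`` must be the weight-1 expectations; each pruning step rescales
    it by its arm weight.  Step layout (prunes are nested — each arm prunes
    the step-2a output):

    * 2a  : prune to (w_fun_a, w_syn)                         -> H_a
    * 3a  : cases_power = H_a[:, I_case]
    * 2b1 : prune H_a functional to w_fun_b1                  -> H_b1
    * 3b/3c: controls = H_b1[:, I_ctrl]; cases_null = H_b1[:, I_case]
    * 2b2 : prune H_a functional to w_fun_b2, label pruned "protective" -> H_b2
    * 3d  : cases_opp = H_b2[:, I_case]
    * 2b3 : prune H_a functional to w_fun_b3 with the protective-labeled
            variants protected, label pruned "risk"           -> H_b3
    * 3e  : controls_opp = H_b3[:, I_ctrl]

    Risk variants therefore survive in H_b2 (cases) and are absent from H_b3
    (controls); protective variants are absent from H_b2 and survive in H_b3.
    """
    check_paired(matrix, legend)
    violations = validate_weights(weights)
    if violations:
        raise ConstraintError("; ".join(violations))
    if matrix.M < 2 * (n_case + n_ctrl):
        raise CapacityError(
            f"pool has {matrix.M} haplotypes; need {2 * (n_case + n_ctrl)}"
        )

    _, i_case = extract_haplotypes(matrix, count=2 * n_case, seed=child_seed(seed, _STREAM_I_CASE))
    _, i_ctrl = extract_haplotypes(
        matrix, count=2 * n_ctrl, seed=child_seed(seed, _STREAM_I_CTRL), exclude=i_case
    )

    # Step 2a: over-express functional variants in the shared pool.
    e_a = expected.rescaled(w_fun=weights.w_fun_a, w_syn=weights.w_syn)
    h_a, leg_a, rep_a = prune_dataset(
        matrix, legend, schema,
        PruneConfig(e_a, seed=child_seed(seed, _STREAM_2A)),
    )

    # Step 2b1: bring functional variants back to their expected level.
    e_b1 = expected.rescaled(w_fun=weights.w_fun_b1, w_syn=weights.w_syn)
    h_b1, leg_b1, rep_b1 = prune_dataset(
        h_a, leg_a, schema,
        PruneConfig(e_b1, seed=child_seed(seed, _STREAM_2B1), classes_to_prune=("functional",)),
    )

    # Step 2b2: case arm of the opposite-direction scenario; variants removed
    # here are the protective set (present in controls, absent in cases).
    e_b2 = expected.rescaled(w_fun=weights.w_fun_b2, w_syn=weights.w_syn)
    h_b2, leg_b2, rep_b2 = prune_dataset(
        h_a, leg_a, schema,
        PruneConfig(
            e_b2,
            seed=child_seed(seed, _STREAM_2B2),
            classes_to_prune=("functional",),
            label_pruned_as="protective",
        ),
    )

    # Step 2b3: control arm; the protective set is shielded from selection so
    # the prunable pool is exactly the variants surviving 2b2, and variants
    # removed here are the risk set (present in cases, absent in controls).
    protective_mask = leg_b2.causal_label == "protective"
    leg_for_b3 = leg_a.copy()
    leg_for_b3.df.loc[protective_mask, "protected"] = True
    leg_for_b3.df.loc[protective_mask, "causal_label"] = "protective"
    e_b3 = expected.rescaled(w_fun=weights.w_fun_b3, w_syn=weights.w_syn)
    h_b3, leg_b3, rep_b3 = prune_dataset(
        h_a, leg_for_b3, schema,
        PruneConfig(
            e_b3,
            seed=child_seed(seed, _STREAM_2B3),
            classes_to_prune=("functional",),
            label_pruned_as="risk",
        ),
    )

    return ScenarioBundle(
        weights=weights,
        i_case=i_case,
        i_ctrl=i_ctrl,
        h_a=h_a, legend_a=leg_a,
        h_b1=h_b1, legend_b1=leg_b1,
        h_b2=h_b2, legend_b2=leg_b2,
        h_b3=h_b3, legend_b3=leg_b3,
        reports={"2a": rep_a, "2b1": rep_b1, "2b2": rep_b2, "2b3": rep_b3},
        cases_power=h_a.column_subset(i_case),
        controls=h_b1.column_subset(i_ctrl),
        cases_null=h_b1.column_subset(i_case),
        cases_opp=h_b2.column_subset(i_case),
        controls_opp=h_b3.column_subset(i_ctrl),
    )


def filter_variants(
    matrix: HaplotypeMatrix,
    legend: LegendTable,
    maf_cap: float = 0.01,
    classes=("functional",),
    exonic_only: bool = False,
) -> tuple[HaplotypeMatrix, LegendTable]:
    """Keep variants of the given classes with 0 < MAC <= round(maf_cap * M).

    The cap is inclusive, matching the bin convention (MAC exactly at the
    MAF boundary is still rare).  ``exonic_only`` filters on an optional
    ``exonic`` legend column when present and is a no-op otherwise.
    """
    check_paired(matrix, legend)
    if not (0 < maf_cap <= 0.5):
        raise DomainError("maf_cap must be in (0, 0.5]")
    cap = round_half_up(maf_cap * matrix.M)
    mac = matrix.mac
    keep = (mac > 0) & (mac <= cap) & np.isin(legend.fun, list(classes))
    if exonic_only and "exonic" in legend.df.columns:
        keep &= legend.df["exonic"].astype(str).isin(["1", "true", "True"]).to_numpy()
    rows = np.flatnonzero(keep)
    return matrix.row_subset(rows), legend.subset(rows)
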