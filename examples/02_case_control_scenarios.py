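"""Build the three case-control arms (same / null / opposite direction of effect).

One pool is pruned along nested branches and the same case/control column
indices are reused everywhere, so the arms are paired: the null arm differs
from the power arm only in which pruned matrix the case columns come from.
"""

import numpy as np

from rarehap import (
    AFSParams,
    NvarParams,
    default_bins,
    expected_counts,
    generate_haplotypes,
    make_weights,
    run_case_control_workflow,
    validate_weights,
)

N_CASE = N_CTRL = 500
M = 2 * (N_CASE + N_CTRL)
nvar, afs = NvarParams(1.0, 0.45), AFSParams(1.0, 0.0, 1.5)

weights = make_weights(p=0.5, w_fun_a=1.4, w_fun_b1=1.0)
print("scenario weights:", weights)
print("constraint violations:", validate_weights(weights) or "none")
# w_fun_b2 = w_fun_b3 = 1.2: at p = 0.5 both opposite-direction arms carry the
# same expected count, and the causal excess 0.2 + 0.2 matches the
# same-direction excess 0.4.

matrix, legend = generate_haplotypes(M, 2.0, nvar, afs, inflation=1.6,
                                     prop_fun=0.6, seed=3)
schema = default_bins(M)
expected = expected_counts(nvar, afs, M // 2, 2.0, schema, prop_fun=0.6)

bundle = run_case_control_workflow(
    matrix, legend, schema, expected, weights,
    n_case=N_CASE, n_ctrl=N_CTRL, seed=21,
)

fun = legend.fun == "functional"
for name, ds in bundle.datasets.items():
    present = int((ds.mac[fun] > 0).sum())
    print(f"{name:>13}: {ds.M} haplotype columns, {present} functional variants present")

risk = bundle.legend_b3.causal_label == "risk"
protective = bundle.legend_b2.causal_label == "protective"
print(f"\nrisk variants: {int(risk.sum())} (in cases only), "
      f"protective: {int(protective.sum())} (in controls only), overlap: "
      f"{int((risk & protective).sum())}")
assert (bundle.h_b3.mac[risk] == 0).all() and (bundle.h_b2.mac[protective] == 0).all()
# cases_power carries ~40% more functional variants than controls; the null
# pair draws cases and controls from the same matrix, so it is balanced.
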