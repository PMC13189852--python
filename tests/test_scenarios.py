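import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rarehap import (
    AFSParams,
    HaplotypeMatrix,
    LegendTable,
    NvarParams,
    ScenarioWeights,
    default_bins,
    expected_counts,
    filter_variants,
    generate_haplotypes,
    make_weights,
    opposite_effect_weights,
    run_case_control_workflow,
    validate_weights,
)
from rarehap.errors import CapacityError, ConstraintError, DomainError


class TestOppositeEffectWeights:
    @pytest.mark.parametrize(
        "p, w_a, w_b1, expected",
        [
            (0.5, 1.2, 1.0, (1.1, 1.1)),
            (0.75, 1.2, 1.0, (1.15, 1.05)),
            (0.5, 1.4, 1.0, (1.2, 1.2)),
            (1.0, 1.3, 1.0, (1.3, 1.0)),  # same-direction limit
        ],
    )
    def test_worked_examples(self, p, w_a, w_b1, expected):
        w_b2, w_b3 = opposite_effect_weights(p, w_a, w_b1)
        assert w_b2 == pytest.approx(expected[0], abs=1e-12)
        assert w_b3 == pytest.approx(expected[1], abs=1e-12)

    def test_constraint_errors(self):
        with pytest.raises(ConstraintError):
            opposite_effect_weights(0.0, 1.2, 1.0)
        with pytest.raises(ConstraintError):
            opposite_effect_weights(1.5, 1.2, 1.0)
        with pytest.raises(ConstraintError):
            opposite_effect_weights(0.5, 1.0, 1.2)  # w_a <= w_b1

    @given(
        st.floats(min_value=0.01, max_value=1.0),
        st.floats(min_value=1.01, max_value=3.0),
        st.floats(min_value=0.1, max_value=1.0),
    )
    def test_sum_identity_and_causal_conservation(self, p, excess, w_b1):
        w_a = w_b1 + excess * w_b1
        w_b2, w_b3 = opposite_effect_weights(p, w_a, w_b1)
        assert w_b2 + w_b3 == pytest.approx(w_a + w_b1, rel=1e-12)
        # risk + protective excess equals the same-direction excess
        assert (w_a - w_b3) + (w_a - w_b2) == pytest.approx(w_a - w_b1, rel=1e-9)


class TestValidateWeights:
    def test_valid_worked_example(self):
        w = ScenarioWeights(1.2, 1.0, 1.1, 1.1, 1.0, 0.5)
        assert validate_weights(w) == []

    def test_syn_mismatch_flagged(self):
        w = ScenarioWeights(1.2, 1.0, 1.1, 1.1, 0.9, 0.5)
        assert any("w_syn" in v for v in validate_weights(w))

    def test_ordering_violation_flagged(self):
        w = ScenarioWeights(1.2, 1.0, 1.25, 0.95, 1.0, 0.5)
        violations = validate_weights(w)
        assert any("ordering" in v for v in violations)

    def test_make_weights_always_valid(self):
        for p in (0.25, 0.5, 0.75, 1.0):
            assert validate_weights(make_weights(p, 1.4)) == []


@pytest.fixture(scope="module")
def workflow_bundle():
    nvar, afs = NvarParams(1.0, 0.45), AFSParams(1.0, 0.0, 1.5)
    matrix, legend = generate_haplotypes(
        M=800, region_kb=2.0, nvar=nvar, afs=afs, inflation=1.6, prop_fun=0.6, seed=17
    )
    schema = default_bins(800)
    expected = expected_counts(nvar, afs, 400, 2.0, schema, prop_fun=0.6)
    weights = make_weights(p=0.5, w_fun_a=1.4, w_fun_b1=1.0)
    bundle = run_case_control_workflow(
        matrix, legend, schema, expected, weights, n_case=100, n_ctrl=100, seed=23
    )
    return matrix, bundle


class TestWorkflow:
    def test_output_widths_and_disjoint_indices(self, workflow_bundle):
        _, bundle = workflow_bundle
        assert bundle.cases_power.M == 200
        assert bundle.controls.M == 200
        assert np.intersect1d(bundle.i_case, bundle.i_ctrl).size == 0

    def test_null_arm_shares_one_pruned_matrix(self, workflow_bundle):
        _, bundle = workflow_bundle
        assert bundle.cases_null.equals(bundle.h_b1.column_subset(bundle.i_case))
        assert bundle.controls.equals(bundle.h_b1.column_subset(bundle.i_ctrl))

    def test_risk_and_protective_sets_are_disjoint_and_directional(self, workflow_bundle):
        _, bundle = workflow_bundle
        risk = bundle.legend_b3.causal_label == "risk"
        protective = bundle.legend_b2.causal_label == "protective"
        assert risk.any() and protective.any()
        assert not (risk & protective).any()
        # risk variants survive in the case-arm matrix and are zeroed in the control arm
        assert (bundle.h_b2.mac[risk] > 0).all()
        assert (bundle.h_b3.mac[risk] == 0).all()
        # protective variants: the reverse
        assert (bundle.h_b2.mac[protective] == 0).all()
        assert (bundle.h_b3.mac[protective] > 0).all()

    def test_nested_prunes_preserve_row_space(self, workflow_bundle):
        matrix, bundle = workflow_bundle
        for h in (bundle.h_a, bundle.h_b1, bundle.h_b2, bundle.h_b3):
            assert h.n_variants == matrix.n_variants
            assert h.M == matrix.M

    def test_capacity_error(self, workflow_bundle):
        matrix, bundle = workflow_bundle
        schema = default_bins(800)
        expected = expected_counts(
            NvarParams(1.0, 0.45), AFSParams(1.0, 0.0, 1.5), 400, 2.0, schema, 0.6
        )
        with pytest.raises(CapacityError):
            run_case_control_workflow(
                matrix, bundle.legend_a, schema, expected, bundle.weights,
                n_case=300, n_ctrl=300, seed=1,
            )

    def test_invalid_weights_rejected(self, workflow_bundle):
        matrix, bundle = workflow_bundle
        schema = default_bins(800)
        expected = expected_counts(
            NvarParams(1.0, 0.45), AFSParams(1.0, 0.0, 1.5), 400, 2.0, schema, 0.6
        )
        bad = ScenarioWeights(1.4, 1.0, 1.5, 0.9, 1.0, 0.5)
        with pytest.raises(ConstraintError):
            run_case_control_workflow(
                matrix, bundle.legend_a, schema, expected, bad,
                n_case=50, n_ctrl=50, seed=1,
            )

    def test_same_direction_arm_enriches_functional_variants(self):
        # over seeds, cases (w=1.4) carry more surviving functional variants
        # than controls (w=1), and the null arm is balanced
        nvar, afs = NvarParams(1.0, 0.45), AFSParams(1.0, 0.0, 1.5)
        diffs_power, diffs_null = [], []
        for seed in range(15):
            matrix, legend = generate_haplotypes(
                M=1200, region_kb=2.0, nvar=nvar, afs=afs,
                inflation=1.6, prop_fun=0.6, seed=1000 + seed,
            )
            schema = default_bins(1200)
            expected = expected_counts(nvar, afs, 600, 2.0, schema, 0.6)
            bundle = run_case_control_workflow(
                matrix, legend, schema, expected, make_weights(1.0, 1.4),
                n_case=300, n_ctrl=300, seed=seed,
            )
            fun = legend.fun == "functional"
            diffs_power.append(
                (bundle.cases_power.mac[fun] > 0).sum()
                - (bundle.controls.mac[fun] > 0).sum()
            )
            diffs_null.append(
                (bundle.cases_null.mac[fun] > 0).sum()
                - (bundle.controls.mac[fun] > 0).sum()
            )
        assert np.mean(diffs_power) > 3 * np.std(diffs_power) / np.sqrt(15)
        assert abs(np.mean(diffs_null)) <= 4 * np.std(diffs_null) / np.sqrt(15) + 1e-9


class TestFilterVariants:
    def _pair(self, macs, classes, m):
        data = np.zeros((len(macs), m), dtype=np.uint8)
        for i, mac in enumerate(macs):
            data[i, :mac] = 1
        legend = LegendTable(
            pd.DataFrame(
                {
                    "id": [f"v{i}" for i in range(len(macs))],
                    "position": np.arange(1, len(macs) + 1),
                    "ref": "A",
                    "alt": "T",
                    "fun": classes,
                }
            )
        )
        return HaplotypeMatrix(data), legend

    def test_class_mac_zero_and_boundary(self):
        matrix, legend = self._pair(
            [200, 1, 0, 201], ["functional", "synonymous", "functional", "functional"], 20000
        )
        filtered, fl = filter_variants(matrix, legend, maf_cap=0.01, classes=("functional",))
        # MAC=200 at M=20,000 sits exactly on the 1% cap and is kept (inclusive);
        # the synonymous, absent, and common variants are removed
        assert fl.df["id"].tolist() == ["v0"]
        assert filtered.mac.tolist() == [200]

    def test_cap_domain(self):
        matrix, legend = self._pair([1], ["functional"], 200)
        with pytest.raises(DomainError):
            filter_variants(matrix, legend, maf_cap=0.6)
        with pytest.raises(DomainError):
            filter_variants(matrix, legend, maf_cap=0.0)
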