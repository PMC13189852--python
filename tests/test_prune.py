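import numpy as np
import pandas as pd
import pytest

from rarehap import (
    ExpectedCounts,
    HaplotypeMatrix,
    LegendTable,
    PruneConfig,
    default_bins,
    prune_dataset,
    select_prune_set,
    stochastic_round,
)
from rarehap.errors import DomainError, InfeasibleSelectionError, SchemaError


class TestStochasticRound:
    def test_integer_passthrough(self):
        rng = np.random.default_rng(0)
        assert all(stochastic_round(4.0, rng) == 4 for _ in range(50))
        assert stochastic_round(0.0, rng) == 0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            stochastic_round(-0.1, np.random.default_rng(0))

    def test_mean_is_unbiased(self):
        rng = np.random.default_rng(12345)
        draws = [stochastic_round(4.3, rng) for _ in range(100_000)]
        assert set(draws) == {4, 5}
        assert abs(np.mean(draws) - 4.3) <= 0.01


class TestSelectPruneSet:
    def test_k_zero_and_full_pool(self):
        rng = np.random.default_rng(1)
        assert select_prune_set([3, 7, 9], 0, [1, 1, 1], rng).size == 0
        full = select_prune_set([3, 7, 9], 3, [1, 1, 1], rng)
        assert full.tolist() == [3, 7, 9]

    def test_first_draw_probability_proportional_to_weight(self):
        # pool {a,b,c}, weights (2,1,1): P(a chosen | k=1) = 2/4 exactly
        rng = np.random.default_rng(777)
        hits = sum(
            select_prune_set([0, 1, 2], 1, [2.0, 1.0, 1.0], rng)[0] == 0
            for _ in range(100_000)
        )
        assert abs(hits / 100_000 - 0.5) <= 0.01

    def test_zero_weight_never_selected(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            chosen = select_prune_set([0, 1, 2], 2, [1.0, 0.0, 1.0], rng)
            assert 1 not in chosen

    def test_infeasible_carries_shortfall(self):
        rng = np.random.default_rng(3)
        with pytest.raises(InfeasibleSelectionError) as err:
            select_prune_set([0, 1, 2], 3, [1.0, 0.0, 1.0], rng)
        assert err.value.shortfall == 1


def _singleton_dataset(n_fun, n_syn, m=200):
    """n_fun functional + n_syn synonymous singleton variants over m haplotypes."""
    v = n_fun + n_syn
    data = np.zeros((v, m), dtype=np.uint8)
    data[np.arange(v), np.arange(v) % m] = 1
    legend = LegendTable(
        pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(v)],
                "position": np.arange(1, v + 1),
                "ref": "A",
                "alt": "T",
                "fun": ["functional"] * n_fun + ["synonymous"] * n_syn,
            }
        )
    )
    return HaplotypeMatrix(data), legend


def _expected(schema, fun_by_bin, syn_by_bin):
    return ExpectedCounts(
        schema=schema,
        n=schema.M // 2,
        region_kb=1.0,
        base_fun=np.asarray(fun_by_bin, dtype=float),
        base_syn=np.asarray(syn_by_bin, dtype=float),
    )


class TestPruneDataset:
    def test_integer_target_is_hit_exactly(self):
        matrix, legend = _singleton_dataset(10, 0)
        schema = default_bins(200)  # bins [1,1],[2,2]
        expected = _expected(schema, [6.0, 0.0], [0.0, 0.0])
        pruned, new_legend, report = prune_dataset(
            matrix, legend, schema, PruneConfig(expected, seed=4)
        )
        surviving = int((~new_legend.pruned).sum())
        assert surviving == 6
        assert (pruned.data[new_legend.pruned] == 0).all()
        row = next(r for r in report if r["fun_class"] == "functional" and r["bin"] == 0)
        assert row["observed"] == 10 and row["target"] == 6 and row["n_pruned"] == 4

    def test_under_simulated_bin_left_unchanged_with_warning(self):
        matrix, legend = _singleton_dataset(4, 0)
        schema = default_bins(200)
        expected = _expected(schema, [6.0, 0.0], [0.0, 0.0])
        pruned, new_legend, report = prune_dataset(
            matrix, legend, schema, PruneConfig(expected, seed=4)
        )
        assert not new_legend.pruned.any()
        assert pruned.equals(matrix)
        row = next(r for r in report if r["fun_class"] == "functional" and r["bin"] == 0)
        assert row["warning"] and "under-simulated" in row["warning"]

    def test_protected_variants_never_pruned(self):
        matrix, legend = _singleton_dataset(10, 0)
        legend.df.loc[[0, 1], "protected"] = True
        schema = default_bins(200)
        expected = _expected(schema, [3.0, 0.0], [0.0, 0.0])
        for seed in range(100):
            _, new_legend, _ = prune_dataset(
                matrix, legend, schema, PruneConfig(expected, seed=seed)
            )
            assert not new_legend.pruned[[0, 1]].any()

    def test_protected_shortfall_prunes_all_eligible_and_warns(self):
        matrix, legend = _singleton_dataset(5, 0)
        legend.df.loc[[0, 1, 2, 3], "protected"] = True
        schema = default_bins(200)
        expected = _expected(schema, [1.0, 0.0], [0.0, 0.0])  # want 1, must prune 4
        _, new_legend, report = prune_dataset(
            matrix, legend, schema, PruneConfig(expected, seed=0)
        )
        assert new_legend.pruned.sum() == 1  # only the unprotected one
        row = next(r for r in report if r["bin"] == 0 and r["fun_class"] == "functional")
        assert "shortfall" in row["warning"]

    def test_untouched_class_is_bit_identical(self):
        matrix, legend = _singleton_dataset(10, 8)
        schema = default_bins(200)
        expected = _expected(schema, [2.0, 0.0], [1.0, 0.0])
        pruned, new_legend, _ = prune_dataset(
            matrix, legend, schema,
            PruneConfig(expected, seed=9, classes_to_prune=("functional",)),
        )
        syn_rows = np.flatnonzero(legend.fun == "synonymous")
        assert np.array_equal(pruned.data[syn_rows], matrix.data[syn_rows])
        assert not new_legend.pruned[syn_rows].any()
        # non-pruned functional rows are bit-identical too
        keep = np.flatnonzero(~new_legend.pruned)
        assert np.array_equal(pruned.data[keep], matrix.data[keep])

    def test_determinism_and_seed_sensitivity(self):
        matrix, legend = _singleton_dataset(12, 6)
        schema = default_bins(200)
        expected = _expected(schema, [5.0, 0.0], [3.0, 0.0])
        out1 = prune_dataset(matrix, legend, schema, PruneConfig(expected, seed=42))
        out2 = prune_dataset(matrix, legend, schema, PruneConfig(expected, seed=42))
        assert out1[0].equals(out2[0]) and out1[1].equals(out2[1])
        out3 = prune_dataset(matrix, legend, schema, PruneConfig(expected, seed=43))
        assert not out1[1].equals(out3[1])

    def test_label_pruned_as_sets_causal_label(self):
        matrix, legend = _singleton_dataset(10, 0)
        schema = default_bins(200)
        expected = _expected(schema, [6.0, 0.0], [0.0, 0.0])
        _, new_legend, _ = prune_dataset(
            matrix, legend, schema,
            PruneConfig(expected, seed=4, label_pruned_as="protective"),
        )
        assert (new_legend.causal_label[new_legend.pruned] == "protective").all()
        assert (new_legend.causal_label[~new_legend.pruned] == "none").all()

    def test_schema_mismatch_rejected(self):
        matrix, legend = _singleton_dataset(4, 0)
        schema_wrong = default_bins(400)
        expected = _expected(schema_wrong, [2, 0, 0], [0, 0, 0])
        with pytest.raises(SchemaError):
            prune_dataset(matrix, legend, schema_wrong, PruneConfig(expected, seed=0))

    def test_fractional_target_mean_matches_expectation(self):
        # E = 6.4 with 10 observed: mean surviving over seeds must be 6.4
        matrix, legend = _singleton_dataset(10, 0)
        schema = default_bins(200)
        expected = _expected(schema, [6.4, 0.0], [0.0, 0.0])
        survived = [
            int((~prune_dataset(matrix, legend, schema, PruneConfig(expected, seed=s))[1].pruned).sum())
            for s in range(400)
        ]
        se = np.std(survived, ddof=1) / np.sqrt(len(survived))
        assert abs(np.mean(survived) - 6.4) <= 3 * se + 1e-9

    def test_nested_prune_matches_smaller_weight(self):
        # pruning to 1.4*E then to 1.0*E leaves counts matching 1.0*E
        matrix, legend = _singleton_dataset(40, 0)
        schema = default_bins(200)
        e_hi = _expected(schema, [20.0, 0.0], [0.0, 0.0]).rescaled(w_fun=1.4)
        e_lo = _expected(schema, [20.0, 0.0], [0.0, 0.0])
        h1, l1, _ = prune_dataset(matrix, legend, schema, PruneConfig(e_hi, seed=1))
        h2, l2, _ = prune_dataset(h1, l1, schema, PruneConfig(e_lo, seed=2))
        assert int((~l1.pruned).sum()) == 28  # 1.4 * 20
        assert int((~l2.pruned).sum()) == 20
        # everything pruned in step 1 stays pruned in step 2
        assert l2.pruned[l1.pruned].all()


def test_config_validation():
    schema = default_bins(200)
    expected = _expected(schema, [1, 0], [0, 0])
    with pytest.raises(DomainError):
        PruneConfig(expected, seed=0, classes_to_prune=())
    with pytest.raises(DomainError):
        PruneConfig(expected, seed=0, classes_to_prune=("exotic",))
    with pytest.raises(DomainError):
        PruneConfig(expected, seed=0, label_pruned_as="causal")
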