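"""FPKM arithmetic, tests, FDR, and DE calling."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncforge.expression import (
    DEThresholds,
    ExpressionMatrix,
    bh_fdr,
    call_de,
    compute_fpkm,
    log2_fold_change,
    moderated_t_test,
    prune_all_zero,
    welch_t_test,
)


def _matrix(counts, conds, lengths, libs):
    return ExpressionMatrix(
        counts=counts,
        conditions=conds,
        lengths=pd.Series(lengths),
        library_sizes=pd.Series(libs),
    )


class TestFpkm:
    def test_formula_identity(self):
        counts = pd.DataFrame({"s1": [10]}, index=["t1"])
        fpkm = compute_fpkm(counts, pd.Series({"t1": 1000.0}),
                            pd.Series({"s1": 1e6}))
        assert fpkm.loc["t1", "s1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s1": [0]}, index=["t1"])
        fpkm = compute_fpkm(counts, pd.Series({"t1": 500.0}),
                            pd.Series({"s1": 1e6}))
        assert fpkm.loc["t1", "s1"] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(50, 4)),
            index=[f"t{i}" for i in range(50)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(200, 5000, 50).astype(float),
                            index=counts.index)
        libs = pd.Series(rng.integers(1_000_000, 9_000_000, 4).astype(float),
                         index=counts.columns)
        f1 = compute_fpkm(counts, lengths, libs)
        f2 = compute_fpkm(counts * 7, lengths, libs * 7)
        assert np.allclose(f1.values, f2.values)

    def test_zero_length_or_library_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["t1"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"t1": 0.0}),
                         pd.Series({"s1": 1e6}))
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"t1": 100.0}),
                         pd.Series({"s1": 0.0}))


class TestPrune:
    def test_all_zero_row_pruned_partial_row_kept(self):
        fpkm = pd.DataFrame(
            {"a": [0.0, 0.0], "b": [0.0, 1.5]}, index=["z", "k"]
        )
        kept, pruned = prune_all_zero(fpkm)
        assert pruned == ["z"]
        assert list(kept.index) == ["k"]


class TestLog2FoldChange:
    def test_doubling_without_pseudocount(self):
        assert log2_fold_change(1.0, 2.0, pseudocount=0.0) == pytest.approx(1.0)

    def test_equal_means_give_zero(self):
        assert log2_fold_change(3.3, 3.3) == pytest.approx(0.0)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.uniform(0, 100, 2)
            assert log2_fold_change(a, b) == pytest.approx(
                -log2_fold_change(b, a)
            )


class TestWelch:
    def test_identical_groups_p_one(self):
        assert welch_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_textbook_instance_matches_independent_formula(self):
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        expected = 2 * stats.t.sf(abs(t), df)
        assert welch_t_test(a, b) == pytest.approx(expected, abs=1e-10)

    def test_type_one_error_controlled_under_null(self):
        # at n=3/group the Satterthwaite df is ~2-4 and Welch runs
        # conservative: the rate must stay at or below nominal (plus Monte
        # Carlo slack) without collapsing to zero
        rng = np.random.default_rng(100)
        a = rng.normal(size=(10_000, 3))
        b = rng.normal(size=(10_000, 3))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = (p < 0.01).mean()
        assert 0.001 <= rate <= 0.012

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])


class TestModeratedT:
    def test_null_rejection_near_nominal(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10_000, 3))
        b = rng.normal(size=(10_000, 3))
        p, d0, _ = moderated_t_test(a, b)
        assert 0.005 <= (p < 0.01).mean() <= 0.02
        assert d0 > 4  # homoscedastic null -> strong shrinkage

    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(500, 3))
        p, _, _ = moderated_t_test(a, a)
        assert np.allclose(p, 1.0)


class TestBhFdr:
    def test_closed_form_triple(self):
        q = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_step_up_oracle_on_random_vectors(self):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            prev = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = n - rank_from_top
                prev = min(prev, p[idx] * n / rank)
                q[idx] = prev
            return q

        rng = np.random.default_rng(12)
        for _ in range(25):
            p = rng.uniform(size=int(rng.integers(1, 400)))
            assert np.allclose(bh_fdr(p), oracle(p))

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=500)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _simulated_matrix(rng, n_null=500, n_de=60, lfc=2.0, disp=0.05, reps=3):
    n = n_null + n_de
    ids = [f"t{i}" for i in range(n)]
    base = rng.lognormal(np.log(200), 1.0, size=n)
    lfc_vec = np.zeros(n)
    lfc_vec[n_null:] = np.where(rng.random(n_de) < 0.5, lfc, -lfc)
    mean_s = base * 2.0 ** (-lfc_vec / 2)
    mean_r = base * 2.0 ** (lfc_vec / 2)
    r = 1.0 / disp
    cols = {}
    for i in range(reps):
        cols[f"S{i}"] = rng.negative_binomial(r, r / (r + mean_s))
        cols[f"R{i}"] = rng.negative_binomial(r, r / (r + mean_r))
    counts = pd.DataFrame(cols, index=ids)
    m = ExpressionMatrix(
        counts=counts,
        conditions={c: c[0] for c in counts.columns},
        lengths=pd.Series(1000.0, index=ids),
        library_sizes=pd.Series(1e6, index=counts.columns),
    )
    return m, lfc_vec


class TestCallDe:
    def test_null_simulation_controls_false_calls(self):
        rng = np.random.default_rng(20)
        m, _ = _simulated_matrix(rng, n_null=2000, n_de=0)
        table = call_de(m)
        called = (~table["call"].isin(["not_DE", "pruned_all_zero"])).sum()
        assert called / len(table) <= 0.01

    def test_power_and_direction_on_planted_effects(self):
        rng = np.random.default_rng(21)
        m, lfc_vec = _simulated_matrix(rng, n_null=2000, n_de=200)
        table = call_de(m).set_index("transcript_id")
        planted = [f"t{i}" for i in range(2000, 2200)]
        calls = table.loc[planted, "call"]
        truth = np.where(lfc_vec[2000:] > 0, "up_in_R", "up_in_S")
        recall = (calls.values == truth).mean()
        assert recall >= 0.8
        called_mask = ~table["call"].isin(["not_DE", "pruned_all_zero"])
        called = table[called_mask]
        signs_ok = (
            np.sign(called["log2fc_R_vs_S"])
            == np.where(called["call"] == "up_in_R", 1, -1)
        ).mean()
        assert signs_ok >= 0.95

    def test_degenerate_thresholds_call_every_unpruned_row(self):
        rng = np.random.default_rng(22)
        m, _ = _simulated_matrix(rng, n_null=200, n_de=0)
        table = call_de(m, DEThresholds(lfc=0.0, p=1.1, q=1.1))
        unpruned = table[table["call"] != "pruned_all_zero"]
        assert (unpruned["call"] != "not_DE").all()

    def test_partition_and_threshold_monotonicity(self):
        rng = np.random.default_rng(23)
        m, _ = _simulated_matrix(rng, n_null=800, n_de=80)
        # plant some all-zero rows
        m.counts.iloc[:15] = 0
        m.fpkm = None
        strict = call_de(m, DEThresholds(lfc=1, p=0.01, q=0.01))
        loose = call_de(m, DEThresholds(lfc=0.5, p=0.05, q=0.05))
        assert len(strict) == len(m.counts)
        assert (strict["call"] == "pruned_all_zero").sum() == 15
        strict_calls = set(
            strict.loc[~strict["call"].isin(["not_DE", "pruned_all_zero"]),
                       "transcript_id"]
        )
        loose_calls = set(
            loose.loc[~loose["call"].isin(["not_DE", "pruned_all_zero"]),
                      "transcript_id"]
        )
        assert strict_calls <= loose_calls
        ok = strict.dropna(subset=["p_value"])
        assert (ok["q_value"] >= ok["p_value"] - 1e-12).all()

    def test_orientation_columns_are_negatives(self):
        rng = np.random.default_rng(24)
        m, _ = _simulated_matrix(rng, n_null=100, n_de=10)
        t = call_de(m)
        assert np.allclose(t["log2fc_R_vs_S"].dropna(),
                           -t["log2fc_S_vs_R"].dropna())

    def test_planted_counts_recovered_on_default_synthetic(self, small_sim):
        truth = small_sim.truth.set_index("transcript_id")
        lnc_ids = truth[truth["category"] == "lncRNA"].index.tolist()
        m = ExpressionMatrix(
            counts=small_sim.counts.loc[lnc_ids],
            conditions=small_sim.conditions,
            lengths=small_sim.lengths,
            library_sizes=small_sim.library_sizes,
        )
        table = call_de(m).set_index("transcript_id").join(
            truth[["de_status"]]
        )
        assert (table["call"] == "pruned_all_zero").sum() == \
            small_sim.config.n_all_zero
        planted = table[table["de_status"].isin(["up_in_S", "up_in_R"])]
        assert (planted["call"] == planted["de_status"]).mean() >= 0.8
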