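import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bh_step_up
from tillermir.expression import (
    call_de,
    call_tissue_specific,
    call_valid_genes,
    compute_fpkm,
    compute_tpm,
    log2_fold_change,
    replicate_pcc,
)
from tillermir.io import ExpressionMatrix, TillermirError, make_design
from tillermir.synthetic import PlantedDe, generate_expression


def _matrix(values, replicates=3, unit="FPKM", feature_ids=None):
    design = make_design(replicates=replicates)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = feature_ids or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=list(design.index)),
        design=design,
        unit=unit,
    )


class TestNormalization:
    def test_tpm_closed_form(self):
        design = make_design(replicates=1)
        m = ExpressionMatrix(
            values=pd.DataFrame(
                {"TP_r1": [10.0, 30.0, 60.0], "ST_r1": [1, 1, 2], "YS_r1": [5, 0, 5]},
                index=["a", "b", "c"],
            ),
            design=design,
            unit="counts",
        )
        tpm = compute_tpm(m)
        assert tpm.unit == "TPM"
        np.testing.assert_allclose(tpm.values["TP_r1"], [1e5, 3e5, 6e5])

    def test_all_zero_sample_is_an_error(self):
        m = _matrix(np.ones((3, 9)), unit="counts")
        m.values.iloc[:, 4] = 0.0
        with pytest.raises(TillermirError, match="ST_r2"):
            compute_tpm(m)

    def test_tpm_column_sums_conserved(self):
        rng = np.random.default_rng(42)
        m = _matrix(rng.integers(0, 500, size=(50, 9)), unit="counts")
        tpm = compute_tpm(m)
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_fpkm_formula_and_zero_count(self):
        m = _matrix([[10.0] + [0.0] * 8], unit="counts", feature_ids=["g0"])
        fpkm = compute_fpkm(m, {"g0": 1000.0}, {s: 1e6 for s in m.sample_ids})
        assert fpkm.values.iloc[0, 0] == pytest.approx(10.0)
        assert (fpkm.values.iloc[0, 1:] == 0).all()

    def test_fpkm_matches_independent_recomputation(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.integers(0, 1000, size=(20, 9)), unit="counts")
        lengths = {f: float(rng.integers(200, 3000)) for f in m.feature_ids}
        libs = {s: float(rng.integers(10**5, 10**7)) for s in m.sample_ids}
        fpkm = compute_fpkm(m, lengths, libs)
        for f in m.feature_ids:
            for s in m.sample_ids:
                expected = m.values.loc[f, s] * 1e9 / (lengths[f] * libs[s])
                assert fpkm.values.loc[f, s] == pytest.approx(expected, rel=1e-12)

    def test_fpkm_missing_length_names_feature(self):
        m = _matrix(np.ones((2, 9)), unit="counts")
        with pytest.raises(TillermirError, match="g1"):
            compute_fpkm(m, {"g0": 100.0}, {s: 1e6 for s in m.sample_ids})


class TestReplicatePcc:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 3, size=20)
        m = _matrix(
            np.column_stack([base, base, 2 * base.mean() - base] + [rng.normal(10, 3, 20)] * 6)
        )
        pcc = replicate_pcc(m)
        assert pcc.iloc[0, 1] == pytest.approx(1.0)
        assert pcc.iloc[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.lognormal(2, 1, size=(30, 9)))
        pcc = replicate_pcc(m)
        x = m.values.to_numpy()
        for i in range(9):
            for j in range(9):
                xi, xj = x[:, i], x[:, j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = math.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
                assert pcc.iloc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_sample_flagged_undefined(self):
        m = _matrix(np.column_stack([np.ones(5) * 2] + [np.arange(5.0) + 1] * 8))
        pcc = replicate_pcc(m)
        assert pcc.iloc[0, 1:].isna().all()


class TestLog2FoldChange:
    def test_examples(self):
        assert log2_fold_change(2, 8, epsilon=1e-12) == pytest.approx(2.0, abs=1e-9)
        assert log2_fold_change(5, 5) == 0.0

    @given(
        a=st.floats(min_value=0, max_value=1e6),
        b=st.floats(min_value=0, max_value=1e6),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a), abs=1e-12)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(TillermirError):
            log2_fold_change(1, 2, epsilon=0)


class TestCallDe:
    def test_planted_effect_is_called(self):
        m, _ = generate_expression(
            [f"g{i}" for i in range(100)],
            planted_de=[PlantedDe("g0", "TP", "YS", 3.0)],
            noise_sd=0.1,
            seed=11,
        )
        recs = {r.feature_id: r for r in call_de(m, "TP", "YS")}
        assert recs["g0"].is_de
        assert recs["g0"].direction == "up_in_b"
        assert recs["g0"].log2fc == pytest.approx(3.0, abs=0.7)

    def test_identical_groups_give_p_one(self):
        vals = np.tile(np.arange(1.0, 4.0), (3, 3))  # TP reps == YS reps
        m = _matrix(vals)
        recs = call_de(m, "TP", "YS")
        for r in recs:
            assert r.p_value == 1.0
            assert not r.is_de
            assert r.direction == "none"

    def test_de_flags_respect_gene_thresholds(self):
        m, _ = generate_expression(
            [f"g{i}" for i in range(200)],
            planted_de=[PlantedDe(f"g{i}", "TP", "YS", 4.0) for i in range(20)],
            noise_sd=0.2,
            seed=5,
        )
        recs = call_de(m, "TP", "YS", lfc_min=1.0, alpha=0.01, criterion="fdr")
        called = [r for r in recs if r.is_de]
        assert called, "expected some DE calls"
        for r in called:
            assert abs(r.log2fc) >= 1.0
            assert r.fdr <= 0.01

    def test_fdr_matches_bh_step_up_oracle(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.lognormal(3, 0.5, size=(80, 9)))
        recs = call_de(m, "TP", "YS")
        expected = bh_step_up([r.p_value for r in recs])
        for r, e in zip(recs, expected):
            assert r.fdr == pytest.approx(e, abs=1e-12)

    def test_single_replicate_group_is_an_error(self):
        m = _matrix(np.ones((3, 3)), replicates=1)
        with pytest.raises(TillermirError, match="replicates"):
            call_de(m, "TP", "YS")


class TestFilterRules:
    def test_valid_gene_strict_all_replicates(self):
        vals = np.array(
            [
                [1.5, 2.0, 3.0] + [5.0] * 6,  # valid in TP
                [1.5, 0.9, 3.0] + [5.0] * 6,  # one replicate at 0.9: not valid in TP
            ]
        )
        vgs = call_valid_genes(_matrix(vals))
        assert "g0" in vgs.by_tissue["TP"]
        assert "g1" not in vgs.by_tissue["TP"]
        assert vgs.by_tissue["ST"] == frozenset({"g0", "g1"})

    def test_valid_genes_agree_with_bruteforce(self):
        rng = np.random.default_rng(21)
        m = _matrix(rng.lognormal(0.3, 1.2, size=(60, 9)))
        vgs = call_valid_genes(m)
        for t in m.tissues():
            cols = m.samples_for(t)
            expected = {
                f for f in m.feature_ids
                if all(m.values.loc[f, c] > 1.0 for c in cols)
            }
            assert set(vgs.by_tissue[t]) == expected

    def test_tissue_specific_strict_double_rule(self):
        vals = np.array(
            [
                [10.0] * 3 + [4.0] * 3 + [4.0] * 3,  # 10 > 8: TP-specific
                [8.0] * 3 + [4.0] * 3 + [4.0] * 3,  # 8 = 2x4: no call (strict)
                [0.0] * 9,  # all-zero: no call
            ]
        )
        calls = call_tissue_specific(_matrix(vals))
        assert [(c.feature_id, c.tissue) for c in calls] == [("g0", "TP")]
        assert calls[0].ratios == pytest.approx((2.5, 2.5))

    def test_tissue_specific_agrees_with_bruteforce_and_is_unique(self):
        rng = np.random.default_rng(33)
        m = _matrix(rng.lognormal(1, 1.5, size=(120, 9)))
        calls = call_tissue_specific(m)
        seen = [c.feature_id for c in calls]
        assert len(seen) == len(set(seen)), "at most one call per feature"
        means = m.tissue_means()
        expected = set()
        for f in m.feature_ids:
            for t in ("TP", "ST", "YS"):
                others = [u for u in ("TP", "ST", "YS") if u != t]
                if all(means.loc[f, t] > 2 * means.loc[f, u] for u in others):
                    expected.add((f, t))
        assert {(c.feature_id, c.tissue) for c in calls} == expected
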