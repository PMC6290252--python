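"""The two-stage multi-locus association engine."""

import numpy as np
import pandas as pd
import pytest

from soyqtl import rtmgwas
from soyqtl.rtmgwas import MarkerData


def _null_markers(n_acc, n_markers, rng, allele_range=(2, 4)):
    out = []
    for i in range(n_markers):
        k = int(rng.integers(*allele_range, endpoint=True))
        freqs = rng.dirichlet(np.full(k, 5.0))
        alle = rng.choice(k, size=n_acc, p=freqs)
        while len(np.unique(alle)) < 2:
            alle = rng.choice(k, size=n_acc, p=freqs)
        out.append(MarkerData(f"M{i}", f"c{i % 5}", 1000 * (i + 1), k, alle))
    return out


class TestStage1:
    def test_constant_phenotype_is_null(self):
        rng = np.random.default_rng(0)
        markers = _null_markers(100, 5, rng)
        res = rtmgwas.stage1_scan(markers, np.full(100, 3.0))
        assert (res.table["p"] > 0.99).all()
        assert (res.table["r2"] == 0).all()

    def test_perfect_signal_saturates_r2(self):
        rng = np.random.default_rng(1)
        alle = rng.integers(0, 2, 100)
        m = MarkerData("M", "c1", 100, 2, alle)
        res = rtmgwas.stage1_scan([m], alle.astype(float))
        assert res.table.loc["M", "r2"] == pytest.approx(1.0)
        assert res.table.loc["M", "p"] < 1e-100

    def test_monomorphic_marker_skipped(self):
        m = MarkerData("M", "c1", 100, 2, np.zeros(50, int))
        res = rtmgwas.stage1_scan([m], np.random.default_rng(0).normal(size=50))
        assert res.table.empty

    def test_type_i_calibration_under_permutation(self):
        """Null marker scan rejects at ~5% with alpha 0.05 (10 seeds)."""
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            markers = _null_markers(200, 1000, rng)
            y = rng.normal(size=200)
            res = rtmgwas.stage1_scan(markers, y)
            fracs.append((res.table["p"] < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) < 0.02

    def test_covariates_absorb_structure(self):
        """A trait aligned with a covariate shows no marker signal on top."""
        rng = np.random.default_rng(2)
        cov = rng.normal(size=(150, 1))
        markers = _null_markers(150, 20, rng)
        y = 2.0 * cov[:, 0] + 0.1 * rng.normal(size=150)
        res = rtmgwas.stage1_scan(markers, y, cov)
        assert (res.table["p"] < 0.01).sum() <= 1


class TestPreselect:
    @pytest.mark.parametrize("threshold,expect", [(1.0, 3), (0.0, 0)])
    def test_boundaries(self, threshold, expect):
        s1 = rtmgwas.Stage1Result(pd.DataFrame(
            {"p": [0.001, 0.04, 0.2]}, index=["a", "b", "c"]))
        assert len(rtmgwas.preselect(s1, threshold)) == expect

    def test_filter_orders_by_p(self):
        s1 = rtmgwas.Stage1Result(pd.DataFrame(
            {"p": [0.04, 0.001, 0.2]}, index=["a", "b", "c"]))
        assert rtmgwas.preselect(s1, 0.05) == ["b", "a"]


def _planted(n, r2_list, rng, n_null=50):
    """Markers with planted bi-allelic effects reaching the given R2 shares."""
    markers = _null_markers(n, n_null, rng)
    y = np.zeros(n)
    true_ids = []
    for t, r2 in enumerate(r2_list):
        alle = rng.integers(0, 2, n)
        mid = f"Q{t}"
        markers.append(MarkerData(mid, f"q{t}", 10, 2, alle))
        true_ids.append(mid)
        contrib = (alle - alle.mean())
        contrib = contrib / contrib.std() * np.sqrt(r2)
        y = y + contrib
    resid_var = max(1.0 - sum(r2_list), 0.0)
    y = y + rng.normal(0, np.sqrt(resid_var), n)
    return markers, y, true_ids


class TestStage2:
    def test_planted_qtl_selected_first(self):
        rng = np.random.default_rng(3)
        markers, y, true_ids = _planted(200, [0.5], rng)
        s1 = rtmgwas.stage1_scan(markers, y)
        model = rtmgwas.stage2_stepwise(rtmgwas.preselect(s1), markers, y)
        assert model.selected[0] == true_ids[0]

    def test_two_orthogonal_qtls_recovered_with_r2(self):
        rng = np.random.default_rng(4)
        markers, y, true_ids = _planted(400, [0.3, 0.2], rng, n_null=30)
        s1 = rtmgwas.stage1_scan(markers, y)
        model = rtmgwas.stage2_stepwise(rtmgwas.preselect(s1), markers, y)
        assert set(true_ids) <= set(model.selected)
        r2 = {mid: model.partial_r2[mid] for mid in true_ids}
        assert abs(r2["Q0"] - 0.3) < 0.05
        assert abs(r2["Q1"] - 0.2) < 0.05

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        markers, y, _ = _planted(200, [0.3, 0.15], rng, n_null=40)
        s1 = rtmgwas.stage1_scan(markers, y)
        cand = rtmgwas.preselect(s1)
        a = rtmgwas.stage2_stepwise(cand, markers, y)
        b = rtmgwas.stage2_stepwise(cand[::-1], markers, y)
        assert a.selected == b.selected

    def test_collinear_candidate_skipped(self):
        rng = np.random.default_rng(6)
        markers, y, true_ids = _planted(200, [0.4], rng, n_null=10)
        dup = MarkerData("DUP", "z", 99, 2,
                         markers[-1].allele_of.copy())
        markers.append(dup)
        model = rtmgwas.stage2_stepwise([m.id for m in markers], markers, y)
        assert not {"Q0", "DUP"} <= set(model.selected)

    def test_retained_markers_significant(self):
        rng = np.random.default_rng(7)
        markers, y, _ = _planted(300, [0.3, 0.2, 0.1], rng, n_null=60)
        s1 = rtmgwas.stage1_scan(markers, y)
        model = rtmgwas.stage2_stepwise(rtmgwas.preselect(s1), markers, y)
        assert all(p < model.alpha_enter for p in model.partial_p.values())

    def test_empty_candidates_covariates_only(self):
        rng = np.random.default_rng(8)
        markers = _null_markers(100, 5, rng)
        model = rtmgwas.stage2_stepwise([], markers, rng.normal(size=100))
        assert model.selected == []
        assert model.model_r2 == pytest.approx(0.0, abs=1e-12)


class TestPartition:
    def test_single_marker_sequential_equals_marginal(self):
        rng = np.random.default_rng(9)
        markers, y, true_ids = _planted(200, [0.4], rng, n_null=5)
        s1 = rtmgwas.stage1_scan(markers, y)
        model = rtmgwas.stage2_stepwise(rtmgwas.preselect(s1), markers, y)
        if model.selected == true_ids:
            assert model.seq_r2[true_ids[0]] == pytest.approx(
                s1.table.loc[true_ids[0], "r2"], abs=1e-10)

    def test_sequential_sums_to_model_r2(self):
        rng = np.random.default_rng(10)
        markers, y, _ = _planted(300, [0.3, 0.2], rng, n_null=40)
        s1 = rtmgwas.stage1_scan(markers, y)
        model = rtmgwas.stage2_stepwise(rtmgwas.preselect(s1), markers, y)
        total = sum(model.seq_r2.values()) + model.covariate_r2
        assert total == pytest.approx(model.model_r2, abs=1e-8)

    def test_orthogonal_design_sequential_equals_partial(self):
        # two markers on disjoint balanced halves -> exactly orthogonal coding
        n = 200
        a1 = np.tile([0, 1], n // 2)
        a2 = np.repeat([0, 1], n // 2)
        m1 = MarkerData("A", "c1", 1, 2, a1)
        m2 = MarkerData("B", "c2", 1, 2, a2)
        rng = np.random.default_rng(11)
        y = a1 * 1.0 + a2 * 0.5 + rng.normal(0, 0.3, n)
        model = rtmgwas.stage2_stepwise(["A", "B"], [m1, m2], y)
        for mid in model.selected:
            assert model.seq_r2[mid] == pytest.approx(model.partial_r2[mid],
                                                      abs=1e-10)


class TestAlleleEffects:
    def test_hand_biallelic_effects(self):
        """Balanced classes with means 21/19 -> effects +1/-1 around mean 20."""
        alle = np.tile([0, 1], 50)
        y = np.where(alle == 0, 21.0, 19.0)
        m = MarkerData("M", "c1", 1, 2, alle)
        model = rtmgwas.stage2_stepwise(["M"], [m], y)
        eff = rtmgwas.allele_effects(model)
        assert eff.mu == pytest.approx(20.0)
        assert eff.effects["M"][0] == pytest.approx(1.0)
        assert eff.effects["M"][1] == pytest.approx(-1.0)

    def test_zero_sum_per_locus(self):
        rng = np.random.default_rng(12)
        markers, y, _ = _planted(300, [0.3, 0.2], rng, n_null=30)
        s1 = rtmgwas.stage1_scan(markers, y)
        model = rtmgwas.stage2_stepwise(rtmgwas.preselect(s1), markers, y)
        eff = rtmgwas.allele_effects(model)
        for mid, e in eff.effects.items():
            assert sum(e.values()) == pytest.approx(0.0, abs=1e-8)

    def test_absent_allele_gets_no_effect(self):
        # declared 3 alleles but only 2 observed
        alle = np.tile([0, 2], 40)
        y = np.where(alle == 0, 1.0, -1.0) + \
            np.random.default_rng(13).normal(0, 0.1, 80)
        m = MarkerData("M", "c1", 1, 3, alle)
        model = rtmgwas.stage2_stepwise(["M"], [m], y)
        eff = rtmgwas.allele_effects(model)
        assert set(eff.effects["M"]) == {0, 2}


def test_qtl_table_naming_convention():
    rng = np.random.default_rng(14)
    markers, y, _ = _planted(300, [0.3, 0.2], rng, n_null=20)
    s1 = rtmgwas.stage1_scan(markers, y)
    model = rtmgwas.stage2_stepwise(rtmgwas.preselect(s1), markers, y)
    tab = rtmgwas.qtl_table(model, trait="Oil")
    assert len(tab) == len(model.selected)
    assert tab["qtl"].str.startswith("Oil-a-").all()
    assert (tab["n_alleles"] >= 2).all()
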