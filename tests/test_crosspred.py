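"""Cross prediction: map functions, RIL simulation, exact oracle, ranking."""

import numpy as np
import pandas as pd
import pytest

from soyqtl import crosspred
from soyqtl.genio import GroupPartition
from soyqtl.rtmgwas import AlleleEffects


def _map(positions_cm, chroms=None):
    L = len(positions_cm)
    chroms = chroms or ["c1"] * L
    ids = [f"L{i}" for i in range(L)]
    df = pd.DataFrame({"id": ids, "chromosome": chroms,
                       "position_bp": (np.asarray(positions_cm) * 4e5).astype(int)})
    return crosspred.build_genetic_map(df, cm_per_mb=2.5)


class TestMap:
    def test_haldane_closed_forms(self):
        assert crosspred.haldane_r(0.0) == 0.0
        assert crosspred.haldane_r(100.0) == pytest.approx(0.4323, abs=1e-4)

    def test_unlinked_chromosomes_half(self):
        gmap = _map([0.0, 10.0], chroms=["c1", "c2"])
        assert gmap.rec_fraction[1] == 0.5

    def test_cm_from_bp_rate(self):
        gmap = _map([0.0, 10.0])  # 4 Mb apart at 2.5 cM/Mb = 10 cM
        assert gmap.position_cm[1] - gmap.position_cm[0] == pytest.approx(10.0)
        assert gmap.rec_fraction[1] == pytest.approx(
            crosspred.haldane_r(10.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            crosspred.build_genetic_map(
                pd.DataFrame({"id": ["a"], "chromosome": ["c"],
                              "position_bp": [1]}), cm_per_mb=-1)

    def test_ril_switch_closed_form(self):
        assert crosspred.ril_switch_prob(0.2) == pytest.approx(0.2857, abs=1e-4)
        assert crosspred.ril_switch_prob(0.0) == 0.0
        assert crosspred.ril_switch_prob(0.5) == 0.5


@pytest.fixture
def eff2():
    return AlleleEffects(mu=20.0, effects={"L0": {0: 1.0, 1: -1.0},
                                           "L1": {0: 0.5, 1: -0.5}})


class TestProgenySim:
    def test_identical_parents_breed_true(self, eff2):
        gmap = _map([0.0, 10.0])
        p = np.array([0, 1])
        prog = crosspred.simulate_inbred_progeny(p, p, gmap, n=50,
                                                 rng=np.random.default_rng(0))
        assert (prog == p).all()

    def test_complete_linkage_only_parental_classes(self, eff2):
        gmap = _map([5.0, 5.0])  # d = 0 -> r = 0 -> R = 0
        rng = np.random.default_rng(1)
        prog = crosspred.simulate_inbred_progeny(
            np.array([0, 0]), np.array([1, 1]), gmap, n=4000, rng=rng)
        classes = {tuple(r) for r in prog}
        assert classes == {(0, 0), (1, 1)}
        frac = (prog[:, 0] == 0).mean()
        assert abs(frac - 0.5) < 0.03

    def test_haldane_waddington_parental_frequency(self):
        """r=0.2 -> R=2r/(1+2r)=0.2857; parental class freq (1-R)/2=0.3571."""
        d = -50.0 * np.log(1 - 2 * 0.2)  # invert Haldane for r = 0.2
        gmap = _map([0.0, d])
        assert gmap.rec_fraction[1] == pytest.approx(0.2, abs=1e-6)
        rng = np.random.default_rng(2)
        prog = crosspred.simulate_inbred_progeny(
            np.array([0, 0]), np.array([1, 1]), gmap, n=10_000, rng=rng)
        f00 = ((prog[:, 0] == 0) & (prog[:, 1] == 0)).mean()
        assert f00 == pytest.approx(0.3571, abs=0.02)

    def test_independent_model_forces_half(self):
        gmap = _map([0.0, 0.001])  # almost fully linked physically
        rng = np.random.default_rng(3)
        prog = crosspred.simulate_inbred_progeny(
            np.array([0, 0]), np.array([1, 1]), gmap, model="independent",
            n=10_000, rng=rng)
        f00 = ((prog[:, 0] == 0) & (prog[:, 1] == 0)).mean()
        assert f00 == pytest.approx(0.25, abs=0.02)

    def test_missing_parent_allele_errors(self, eff2):
        gmap = _map([0.0, 10.0])
        with pytest.raises(ValueError, match="L1"):
            crosspred.simulate_inbred_progeny(
                np.array([0, -1]), np.array([1, 1]), gmap, n=10)


class TestGenotypicValue:
    def test_zero_effects_give_mu(self):
        eff = AlleleEffects(20.0, {"L0": {0: 0.0, 1: 0.0}})
        prog = np.array([[0], [1]])
        vals = crosspred.genotypic_value(prog, eff, ["L0"])
        assert np.allclose(vals, 20.0)

    def test_two_locus_arithmetic(self, eff2):
        vals = crosspred.genotypic_value(np.array([[0, 1]]), eff2, ["L0", "L1"])
        assert vals[0] == pytest.approx(20.0 + 1.0 - 0.5)

    def test_progeny_mean_matches_midparent(self, eff2):
        """Additive model: cross mean equals midparent value within 2 SE."""
        gmap = _map([0.0, 30.0])
        p1, p2 = np.array([0, 0]), np.array([1, 1])
        rng = np.random.default_rng(4)
        prog = crosspred.simulate_inbred_progeny(p1, p2, gmap, n=2000, rng=rng)
        vals = crosspred.genotypic_value(prog, eff2, gmap.locus_ids)
        midparent = 20.0  # (21.5 + 18.5) / 2
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - midparent) < 2 * se + 1e-9


class TestNearestRank:
    def test_rank_definition(self):
        x = np.arange(1, 2001)  # 1..2000
        assert crosspred.nearest_rank_percentile(x, 0.99) == 1980
        assert crosspred.nearest_rank_percentile(x, 0.01) == 20


class TestExactOracle:
    def test_single_locus_fair_coin(self, eff2):
        gmap = _map([0.0, 10.0])
        v, p = crosspred.exact_small_cross(np.array([0, 0]), np.array([1, 0]),
                                           eff2, gmap)
        assert len(v) == 2
        assert np.allclose(p, 0.5)

    def test_two_locus_chain_probabilities(self, eff2):
        d = -50.0 * np.log(1 - 2 * 0.2)
        gmap = _map([0.0, d])
        v, p = crosspred.exact_small_cross(np.array([0, 0]), np.array([1, 1]),
                                           eff2, gmap)
        assert np.allclose(sorted(p), sorted([0.3571, 0.1429, 0.1429, 0.3571]),
                           atol=1e-3)

    def test_distribution_normalizes(self, eff2):
        rng = np.random.default_rng(5)
        for _ in range(10):
            L = int(rng.integers(1, 8))
            ids = [f"L{i}" for i in range(L)]
            eff = AlleleEffects(0.0, {i: {0: float(rng.normal()),
                                          1: float(rng.normal())} for i in ids})
            gmap = _map(np.sort(rng.uniform(0, 100, L)).tolist())
            p1 = rng.integers(0, 2, L)
            p2 = rng.integers(0, 2, L)
            v, p = crosspred.exact_small_cross(p1, p2, eff, gmap)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_locus_cap(self, eff2):
        L = 14
        ids = [f"L{i}" for i in range(L)]
        eff = AlleleEffects(0.0, {i: {0: 0.1, 1: -0.1} for i in ids})
        gmap = _map(list(np.linspace(0, 100, L)))
        with pytest.raises(ValueError, match="exceed"):
            crosspred.exact_small_cross(np.zeros(L, int), np.ones(L, int),
                                        eff, gmap, max_loci=12)

    def test_monte_carlo_matches_exact_percentile(self, eff2):
        gmap = _map([0.0, 25.0])
        p1, p2 = np.array([0, 0]), np.array([1, 1])
        v, p = crosspred.exact_small_cross(p1, p2, eff2, gmap)
        exact = crosspred.exact_percentile(v, p, 0.99)
        cp = crosspred.predict_cross("a", "b", p1, p2, eff2, gmap,
                                     rng=np.random.default_rng(6))
        gaps = np.diff(np.unique(v))
        assert abs(cp.predicted - exact) <= gaps.min() / 2


class TestPredictCross:
    def test_identical_parents_predict_parental_value(self, eff2):
        gmap = _map([0.0, 10.0])
        p = np.array([0, 1])
        cp = crosspred.predict_cross("a", "a2", p, p, eff2, gmap,
                                     rng=np.random.default_rng(7))
        assert cp.predicted == pytest.approx(20.0 + 1.0 - 0.5)

    def test_pyramiding_upper_bound(self, eff2):
        gmap = _map([0.0, 10.0])
        rng = np.random.default_rng(8)
        for _ in range(5):
            p1 = rng.integers(0, 2, 2)
            p2 = rng.integers(0, 2, 2)
            cp = crosspred.predict_cross("a", "b", p1, p2, eff2, gmap, rng=rng)
            bound = 20.0 + sum(
                max(eff2.effects[l][int(a)], eff2.effects[l][int(b)])
                for l, a, b in zip(["L0", "L1"], p1, p2))
            assert cp.predicted <= bound + 1e-9
            assert cp.predicted >= cp.progeny_mean - 1e-9  # 99th pct >= mean


class TestEnumerateRank:
    def _panel(self, n=6, L=4, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"P{i}" for i in range(n)]
        loci = [f"L{i}" for i in range(L)]
        df = pd.DataFrame({"id": loci, "chromosome": ["c1", "c1", "c2", "c2"],
                           "position_bp": [1000, 400_000, 1000, 900_000]})
        gmap = crosspred.build_genetic_map(df)
        alle = pd.DataFrame(rng.integers(0, 2, (L, n)), index=loci, columns=ids)
        eff = AlleleEffects(20.0, {l: {0: float(rng.normal(0, 0.5)),
                                       1: float(rng.normal(0, 0.5))}
                                   for l in loci})
        part = GroupPartition(pd.Series(["I", "I", "I", "II", "II", "II"],
                                        index=ids))
        return ids, alle, eff, gmap, part

    def test_cross_counts(self):
        assert crosspred.count_crosses(3) == 3
        assert len(list(crosspred.enumerate_pairs(["a", "b", "c"]))) == 3

    def test_group_counts_partition_pairs(self):
        ids, alle, eff, gmap, part = self._panel()
        out = crosspred.enumerate_and_rank(ids, alle, eff, gmap, part,
                                           n_progeny=200, seed=1)
        s = out["group_summary"].set_index("scope")["crosses"]
        assert s["entire"] == crosspred.count_crosses(6)
        assert s.drop("entire").sum() == s["entire"]

    def test_enumeration_order_independent(self):
        ids, alle, eff, gmap, part = self._panel()
        a = crosspred.enumerate_and_rank(ids, alle, eff, gmap, part,
                                         n_progeny=200, seed=1)
        b = crosspred.enumerate_and_rank(ids[::-1], alle, eff, gmap, part,
                                         n_progeny=200, seed=1)
        key = ["parent1", "parent2"]
        am = {tuple(sorted(t)): v for *t, v in
              a["crosses"][key + ["predicted_linkage"]].itertuples(index=False)}
        bm = {tuple(sorted(t)): v for *t, v in
              b["crosses"][key + ["predicted_linkage"]].itertuples(index=False)}
        assert am == bm

    def test_transgression_property(self):
        """Best predicted cross >= best parental genotypic value."""
        ids, alle, eff, gmap, part = self._panel(seed=2)
        out = crosspred.enumerate_and_rank(ids, alle, eff, gmap, part,
                                           n_progeny=500, seed=3)
        parent_vals = []
        for pid in ids:
            v = crosspred.genotypic_value(
                alle[pid].to_numpy()[None, :], eff, gmap.locus_ids)[0]
            parent_vals.append(v)
        assert out["crosses"]["predicted_linkage"].max() >= max(parent_vals) - 1e-9

    def test_needs_two_parents(self):
        ids, alle, eff, gmap, part = self._panel()
        with pytest.raises(ValueError):
            crosspred.enumerate_and_rank(ids[:1], alle, eff, gmap, part)


class TestMultiTrait:
    def _preds(self, scores):
        rows = [{"parent1": f"P{i}", "parent2": f"Q{i}",
                 "predicted_linkage": s} for i, s in enumerate(scores)]
        return pd.DataFrame(rows)

    def test_single_trait_reduces_to_trait_ranking(self):
        t = self._preds([1.0, 3.0, 2.0])
        out = crosspred.multi_trait_select({"A": t}, {"A": "max"}, top_k=3)
        assert out["A"].tolist() == [3.0, 2.0, 1.0]

    def test_opposite_directions_cancel(self):
        t = self._preds([1.0, 3.0, 2.0])
        out = crosspred.multi_trait_select({"A": t, "B": t.copy()},
                                           {"A": "max", "B": "min"}, top_k=3)
        assert np.allclose(out["score"], 0.0)

    def test_hand_standardization(self):
        a = self._preds([10.0, 20.0, 30.0])
        b = self._preds([5.0, 5.0, 2.0])
        out = crosspred.multi_trait_select({"A": a, "B": b},
                                           {"A": "max", "B": "min"}, top_k=3)
        # hand z-scores: A -> (-1.22, 0, 1.22); B(min) -> (-0.71, -0.71, +1.41)
        assert out.iloc[0]["parent1"] == "P2"  # 1.22 + 1.41 wins
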