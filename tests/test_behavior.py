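"""Behavioral endpoints, factorial ANOVA, and SNK post hoc tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import probescore as ps
from probescore.behavior import DataError
from probescore.probe_io import ValidationError


class TestEndpoints:
    @pytest.mark.parametrize(
        "t_novel,t_familiar,expected",
        [(10.0, 10.0, 0.0), (15.0, 5.0, 0.5), (0.0, 10.0, -1.0), (10.0, 0.0, 1.0)],
    )
    def test_discrimination_index_values(self, t_novel, t_familiar, expected):
        assert ps.discrimination_index(t_novel, t_familiar) == pytest.approx(expected)

    def test_zero_total_time_is_an_error(self):
        with pytest.raises(DataError):
            ps.discrimination_index(0.0, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(0.0, 1e4), st.floats(0.0, 1e4)
    )
    def test_discrimination_index_bounded_and_antisymmetric(self, a, b):
        if a + b <= 0:
            return
        di = ps.discrimination_index(a, b)
        assert -1.0 <= di <= 1.0
        assert di == pytest.approx(-ps.discrimination_index(b, a))

    def test_nor_exclusion_boundary(self):
        table = pd.DataFrame(
            dict(animal_id=["m1", "m2", "m3", "m4"],
                 training_investigation_s=[10.0, 10.01, 25.0, 3.0],
                 di=[0.1, 0.2, 0.3, 0.4])
        )
        kept, excluded = ps.apply_nor_exclusion(table)
        assert excluded == ["m1", "m4"]  # exactly 10 s is excluded
        assert list(kept["animal_id"]) == ["m2", "m3"]
        all_ok, none_out = ps.apply_nor_exclusion(kept)
        assert none_out == [] and len(all_ok) == 2

    @pytest.mark.parametrize("onset,recovery,expected", [(300.0, 2100.0, 1800.0), (50.0, 50.0, 0.0)])
    def test_lorr_duration(self, onset, recovery, expected):
        assert ps.lorr_duration(onset, recovery) == expected

    def test_lorr_negative_duration_rejected(self):
        with pytest.raises(DataError):
            ps.lorr_duration(100.0, 50.0)

    @pytest.mark.parametrize(
        "args,expected",
        [((30.0, 300.0, 10.0, 100.0), (10.0, 10.0)),
         ((0.0, 300.0, 0.0, 50.0), (0.0, 0.0)),
         ((300.0, 300.0, 50.0, 50.0), (100.0, 100.0))],
    )
    def test_lightdark_metrics(self, args, expected):
        assert ps.lightdark_metrics(*args) == pytest.approx(expected)

    def test_lightdark_part_exceeding_total_rejected(self):
        with pytest.raises(DataError):
            ps.lightdark_metrics(400.0, 300.0, 1.0, 10.0)


def _balanced_table(n, seed=0, effects=None, sd=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    effects = effects or {}
    for trt in (1, -1):
        for sex in (1, -1):
            mu = (10.0 + effects.get("treatment", 0) * trt
                  + effects.get("sex", 0) * sex
                  + effects.get("interaction", 0) * trt * sex)
            for _ in range(n):
                rows.append(dict(
                    treatment="ethanol" if trt == 1 else "control",
                    sex="M" if sex == 1 else "F",
                    y=mu + rng.normal(0, sd),
                ))
    return pd.DataFrame(rows)


class TestAnova:
    def test_balanced_two_way_matches_hand_computation(self):
        df = _balanced_table(6, seed=3, effects={"treatment": 1.0, "sex": 0.4})
        res = ps.anova(df, "y", ["treatment", "sex"])
        # closed-form balanced two-way ANOVA
        y = df["y"].to_numpy()
        trt = np.where(df["treatment"] == "ethanol", 1, -1)
        sex = np.where(df["sex"] == "M", 1, -1)
        grand = y.mean()
        n_cell = 6
        for term, code in [("treatment", trt), ("sex", sex), ("treatment:sex", trt * sex)]:
            ss = sum(
                2 * n_cell * (y[code == lv].mean() - grand) ** 2 for lv in (1, -1)
            )
            cell_means = {
                (a, b): y[(trt == a) & (sex == b)].mean() for a in (1, -1) for b in (1, -1)
            }
            sse = sum(
                ((y[(trt == a) & (sex == b)] - cell_means[(a, b)]) ** 2).sum()
                for a in (1, -1) for b in (1, -1)
            )
            f_hand = ss / (sse / (len(y) - 4))
            assert res.loc[term, "F"] == pytest.approx(f_hand, abs=1e-10)

    def test_affine_rescaling_invariance(self):
        df = _balanced_table(5, seed=4, effects={"treatment": 0.7})
        res1 = ps.anova(df, "y", ["treatment", "sex"])
        df2 = df.assign(y=3.0 * df["y"] + 100.0)
        res2 = ps.anova(df2, "y", ["treatment", "sex"])
        np.testing.assert_allclose(res1["F"], res2["F"], rtol=1e-9)

    def test_constant_response_all_f_zero(self):
        df = _balanced_table(4, sd=0.0)
        df["y"] = 7.0
        res = ps.anova(df, "y", ["treatment", "sex"])
        assert (res["F"] == 0).all() and (res["p"] == 1).all()

    def test_three_way_interaction_only(self):
        rng = np.random.default_rng(11)
        rows = []
        for a in (1, -1):
            for b in (1, -1):
                for c in (1, -1):
                    for _ in range(30):
                        rows.append(dict(
                            f1="p" if a == 1 else "q",
                            f2="p" if b == 1 else "q",
                            f3="p" if c == 1 else "q",
                            y=1.0 * a * b * c + rng.normal(0, 0.5),
                        ))
        df = pd.DataFrame(rows)
        res = ps.anova(df, "y", ["f1", "f2", "f3"])
        assert res.loc["f1:f2:f3", "p"] < 1e-10
        others = res.drop(index="f1:f2:f3")
        assert (others["p"] > 0.01).all()


class TestSNK:
    def test_two_groups_equals_q_based_t(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "g": ["A"] * 8 + ["B"] * 8,
            "y": np.r_[rng.normal(0, 1, 8), rng.normal(2.5, 1, 8)],
        })
        res = ps.snk_posthoc(df, "y", "g", require_omnibus=False)
        row = res.comparisons.iloc[0]
        crit_hand = ps.snk_critical(0.05, 2, 14) * np.sqrt(res.mse / 8)
        assert row["critical"] == pytest.approx(crit_hand)
        assert bool(row["significant"]) == (row["diff"] > crit_hand)

    @pytest.mark.parametrize(
        "alpha,r,df,table_value",
        [(0.05, 2, 10, 3.151), (0.05, 3, 10, 3.877), (0.05, 4, 10, 4.327),
         (0.05, 2, 20, 2.950), (0.05, 5, 20, 4.232), (0.01, 2, 10, 4.482)],
    )
    def test_critical_values_match_published_tables(self, alpha, r, df, table_value):
        assert ps.snk_critical(alpha, r, df) == pytest.approx(table_value, abs=5e-4)

    def test_displaced_mean_yields_its_three_comparisons(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "g": np.repeat(list("ABCD"), 40),
            "y": rng.normal(0, 1, 160),
        })
        df.loc[df["g"] == "D", "y"] += 2.0
        res = ps.snk_posthoc(df, "y", "g")
        sig = res.comparisons[res.comparisons["significant"]]
        assert len(sig) == 3
        assert (sig[["group_a", "group_b"]].apply(lambda r: "D" in set(r), axis=1)).all()

    def test_protection_blocks_inner_pair(self):
        # construct means 0 / 1.0 / 1.05 with MSE such that the span-2 gap
        # (0 vs 1.0) exceeds its own critical value but the enclosing span-3
        # range does not exceed its larger one
        s = np.sqrt(0.535 * 5 / 6)
        vals, gs = [], []
        for g, mu in zip("ABC", [0.0, 1.0, 1.05]):
            vals += [mu - s, mu + s] * 3
            gs += [g] * 6
        df = pd.DataFrame({"g": gs, "y": vals})
        res = ps.snk_posthoc(df, "y", "g", require_omnibus=False)
        comp = res.comparisons.set_index(["group_a", "group_b"])
        span3 = comp.loc[("A", "C")]
        span2 = comp.loc[("A", "B")]
        assert not span3["significant"]
        assert span2["diff"] > span2["critical"]  # would pass in isolation
        assert not span2["significant"]           # but protection blocks it

    def test_single_group_rejected(self):
        df = pd.DataFrame({"g": ["A"] * 5, "y": range(5)})
        with pytest.raises(ValidationError):
            ps.snk_posthoc(df, "y", "g", require_omnibus=False)

    def test_omnibus_gate(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"g": np.repeat(list("AB"), 10), "y": rng.normal(0, 1, 20)})
        with pytest.raises(ValidationError, match="omnibus"):
            ps.snk_posthoc(df, "y", "g")
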