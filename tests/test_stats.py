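"""Mixed ANOVA: oracle agreement, identities, calibration, t-tests."""

import math

import numpy as np
import pandas as pd
import pytest

from prespeech.errors import DesignError, ValidationError
from prespeech.stats import (
    melt_pos,
    mixed_anova,
    partial_eta_from_F,
    two_sample_t,
)


# ---------------------------------------------------------------------------
# independent oracle: sequential projection on explicit design matrices
# ---------------------------------------------------------------------------

def projection_ss(data, dv, within, between="group", subject="participant_id"):
    """Hierarchical (Type-I) sums of squares via ordered model blocks.

    Builds dummy design matrices for intercept, group, subject, each
    within term and its interactions with group and subject, fits the
    growing models by least squares, and reads each term's SS as the
    drop in residual sum of squares. Error strata come from the
    factor-by-subject blocks.
    """
    y = data[dv].to_numpy(float)

    def dummies(cols):
        key = data[list(cols)].astype(str).agg("|".join, axis=1)
        return pd.get_dummies(key).to_numpy(float)

    blocks = [("1", np.ones((len(y), 1))), ("G", dummies([between])), ("S", dummies([subject]))]
    if len(within) == 1:
        w = within[0]
        blocks += [
            (w, dummies([w])),
            (f"{w}:G", dummies([w, between])),
            (f"{w}:S", dummies([w, subject])),
        ]
    else:
        w1, w2 = within
        blocks += [
            (w1, dummies([w1])),
            (f"{w1}:G", dummies([w1, between])),
            (w2, dummies([w2])),
            (f"{w2}:G", dummies([w2, between])),
            (f"{w1}:{w2}", dummies([w1, w2])),
            (f"{w1}:{w2}:G", dummies([w1, w2, between])),
            (f"{w1}:S", dummies([w1, subject])),
            (f"{w2}:S", dummies([w2, subject])),
            (f"{w1}:{w2}:S", dummies([w1, w2, subject])),
        ]

    ss = {}
    X = np.empty((len(y), 0))
    rss_prev = float(y @ y)
    for name, cols in blocks:
        X = np.hstack([X, cols])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(resid @ resid)
        ss[name] = rss_prev - rss
        rss_prev = rss
    return ss


def random_design(rng, n1=5, n2=4, within=("picture_id",), effects=True):
    levels = {"picture_id": ["beach", "han_river"], "pos": ["noun", "verb"]}
    rows = []
    for group, n in (("younger", n1), ("older", n2)):
        for i in range(n):
            sid = f"{group}{i}"
            b = rng.normal(0, 1)
            for cell in _cells(within, levels):
                mu = b
                if effects:
                    mu += 0.4 * (group == "older")
                    mu += sum(0.3 * (cell[f] == levels[f][1]) for f in within)
                rows.append({"participant_id": sid, "group": group, **cell,
                             "y": mu + rng.normal(0, 1)})
    return pd.DataFrame(rows)


def _cells(within, levels):
    if len(within) == 1:
        return [{within[0]: lv} for lv in levels[within[0]]]
    return [
        {within[0]: a, within[1]: b}
        for a in levels[within[0]]
        for b in levels[within[1]]
    ]


class TestMixedAnovaOracle:
    def test_balanced_toy_example_matches_hand_computation(self):
        toy = pd.DataFrame(
            [
                ("Y1", "younger", "beach", 10), ("Y1", "younger", "han_river", 12),
                ("Y2", "younger", "beach", 11), ("Y2", "younger", "han_river", 13),
                ("O1", "older", "beach", 8), ("O1", "older", "han_river", 9),
                ("O2", "older", "beach", 7), ("O2", "older", "han_river", 10),
            ],
            columns=["participant_id", "group", "picture_id", "y"],
        )
        table = mixed_anova(toy, dv="y", within=["picture_id"])
        assert table["group"].ss_effect == pytest.approx(18.0)
        assert table["group"].ss_error == pytest.approx(1.0)
        assert table["group"].F == pytest.approx(36.0)
        assert table["picture_id"].ss_effect == pytest.approx(8.0)
        assert table["picture_id"].ss_error == pytest.approx(1.0)
        assert table["picture_id"].F == pytest.approx(16.0)
        assert table["picture_id:group"].ss_effect == pytest.approx(0.0)

    @pytest.mark.parametrize("within", [("picture_id",), ("picture_id", "pos")])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_projection_oracle(self, within, seed):
        rng = np.random.default_rng(seed)
        data = random_design(rng, within=within)
        table = mixed_anova(data, dv="y", within=list(within))
        oracle = projection_ss(data, "y", list(within))
        assert table["group"].ss_effect == pytest.approx(oracle["G"], rel=1e-9)
        assert table["group"].ss_error == pytest.approx(oracle["S"], rel=1e-9)
        for w in within:
            assert table[w].ss_effect == pytest.approx(oracle[w], rel=1e-9)
            assert table[f"{w}:group"].ss_effect == pytest.approx(oracle[f"{w}:G"], rel=1e-9)
            assert table[w].ss_error == pytest.approx(oracle[f"{w}:S"], rel=1e-9)
        if len(within) == 2:
            w1, w2 = within
            assert table[f"{w1}:{w2}"].ss_effect == pytest.approx(
                oracle[f"{w1}:{w2}"], rel=1e-9
            )
            assert table[f"{w1}:{w2}:group"].ss_effect == pytest.approx(
                oracle[f"{w1}:{w2}:G"], rel=1e-9
            )
            assert table[f"{w1}:{w2}"].ss_error == pytest.approx(
                oracle[f"{w1}:{w2}:S"], rel=1e-9
            )

    def test_matches_pingouin_on_unbalanced_two_by_two(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        data = random_design(rng, n1=24, n2=22)
        mine = mixed_anova(data, dv="y", within=["picture_id"])
        theirs = pg.mixed_anova(
            data=data, dv="y", within="picture_id", between="group",
            subject="participant_id",
        ).set_index("Source")
        assert mine["group"].F == pytest.approx(theirs.loc["group", "F"])
        assert mine["picture_id"].F == pytest.approx(theirs.loc["picture_id", "F"])
        assert mine["picture_id:group"].F == pytest.approx(theirs.loc["Interaction", "F"])
        assert mine["group"].partial_eta_sq == pytest.approx(theirs.loc["group", "np2"])


class TestAnovaInvariants:
    def test_ss_partition_is_exact(self):
        rng = np.random.default_rng(3)
        data = random_design(rng, n1=24, n2=22)
        table = mixed_anova(data, dv="y", within=["picture_id"])
        total = float(((data.y - data.y.mean()) ** 2).sum())
        parts = (
            table["group"].ss_effect
            + table["group"].ss_error
            + table["picture_id"].ss_effect
            + table["picture_id:group"].ss_effect
            + table["picture_id"].ss_error
        )
        assert parts == pytest.approx(total, rel=1e-10)

    def test_between_f_equals_squared_pooled_t_on_subject_means(self):
        rng = np.random.default_rng(4)
        data = random_design(rng, n1=24, n2=22)
        table = mixed_anova(data, dv="y", within=["picture_id"])
        means = data.groupby(["participant_id", "group"]).y.mean().reset_index()
        res = two_sample_t(
            means[means.group == "younger"].y, means[means.group == "older"].y
        )
        assert table["group"].F == pytest.approx(res.t**2)
        assert table["group"].df_error == res.df

    def test_partial_eta_identity_for_one_df_effects(self):
        rng = np.random.default_rng(5)
        data = random_design(rng, within=("picture_id", "pos"))
        table = mixed_anova(data, dv="y", within=["picture_id", "pos"])
        for effect in table.effects:
            assert effect.partial_eta_sq == pytest.approx(
                partial_eta_from_F(effect.F, effect.df_effect, effect.df_error)
            )

    def test_degenerate_constant_dv_reports_missing_f(self):
        rng = np.random.default_rng(6)
        data = random_design(rng)
        data["y"] = 7.5
        table = mixed_anova(data, dv="y", within=["picture_id"])
        for effect in table.effects:
            assert effect.ss_effect == pytest.approx(0.0)
            assert math.isnan(effect.F) and math.isnan(effect.p)

    def test_incomplete_subject_is_named(self):
        rng = np.random.default_rng(8)
        data = random_design(rng)
        data = data.drop(data[(data.participant_id == "older1") & (data.picture_id == "beach")].index)
        with pytest.raises(DesignError, match="older1"):
            mixed_anova(data, dv="y", within=["picture_id"])

    def test_three_level_factor_unsupported(self):
        rng = np.random.default_rng(9)
        data = random_design(rng)
        extra = data[data.picture_id == "beach"].assign(picture_id="third")
        with pytest.raises(DesignError, match="unsupported"):
            mixed_anova(pd.concat([data, extra]), dv="y", within=["picture_id"])


class TestPartialEtaFromF:
    def test_zero_f(self):
        assert partial_eta_from_F(0.0, 1, 44) == 0.0

    def test_negative_f_rejected(self):
        with pytest.raises(ValidationError):
            partial_eta_from_F(-1.0, 1, 44)

    def test_agrees_with_definition(self):
        # eta = SS_e/(SS_e+SS_err) and F = (SS_e/df1)/(SS_err/df2)
        ss_e, ss_err, df1, df2 = 12.0, 30.0, 2, 40
        F = (ss_e / df1) / (ss_err / df2)
        assert partial_eta_from_F(F, df1, df2) == pytest.approx(ss_e / (ss_e + ss_err))


class TestTwoSampleT:
    def test_identical_samples(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_pooled_df_for_study_sample_sizes(self, rng):
        x, y = rng.normal(size=24), rng.normal(size=22)
        assert two_sample_t(x, y, pooled=True).df == 44

    def test_welch_df_is_fractional_and_below_pooled(self, rng):
        x = rng.normal(0, 1, size=24)
        y = rng.normal(0, 4, size=22)
        res = two_sample_t(x, y, pooled=False)
        assert res.df < 44 and res.df != int(res.df)

    def test_zero_variance_equal_means_reported_missing(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert math.isnan(res.t) and math.isnan(res.p)

    def test_null_calibration(self, rng):
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            res = two_sample_t(rng.normal(size=24), rng.normal(size=22))
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07
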