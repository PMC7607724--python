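"""Repeated-measures statistics against independent oracles.

Oracles used: squared paired/one-sample t statistics (scipy), textbook
cell-mean sums-of-squares formulas computed from scratch, closed-form
split-plot error partitions, and pingouin's ANOVA / partial-correlation
routines on long-format data.
"""

import numpy as np
import pandas as pd
import pingouin
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pupilgaze.metrics import CELL_LABELS, ConditionTable
from pupilgaze.stats import (effect_magnitude_contrast, partial_correlation,
                             pooled_mixed_anova, rmanova_2x2, simple_effect)


def make_table(values, prefix="P"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(values, columns=list(CELL_LABELS),
                      index=[f"{prefix}{i:03d}" for i in range(len(values))])
    return ConditionTable(measure="m", values=df,
                          n_trials=df.notna().astype(int))


def random_table(rng, n=8, prefix="P"):
    return make_table(rng.normal(0, 1, (n, 4))
                      + rng.normal(0, 1, (n, 1)), prefix=prefix)


def long_format(values, prefix="P"):
    rows = []
    for i, row in enumerate(np.asarray(values, float)):
        for cell, v in zip(CELL_LABELS, row):
            amb, cla = cell.split("_")
            rows.append({"subject": f"{prefix}{i:03d}", "clarity": cla,
                         "ambiguity": amb, "value": v})
    return pd.DataFrame(rows)


class TestRmAnova2x2:
    def test_within_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            table = random_table(rng, n=int(rng.integers(3, 15)))
            v = table.values
            results = {r.effect: r for r in rmanova_2x2(table)}
            contrasts = {
                "Clarity": (v[["LA_low", "HA_low"]].mean(axis=1)
                            - v[["LA_high", "HA_high"]].mean(axis=1)),
                "Ambiguity": (v[["HA_high", "HA_low"]].mean(axis=1)
                              - v[["LA_high", "LA_low"]].mean(axis=1)),
                "Clarity x Ambiguity": (
                    (v["HA_low"] - v["LA_low"])
                    - (v["HA_high"] - v["LA_high"])),
            }
            for effect, scores in contrasts.items():
                t, p = sps.ttest_1samp(scores.to_numpy(), 0.0)
                r = results[effect]
                assert r.F == pytest.approx(t ** 2, rel=1e-10)
                assert r.p == pytest.approx(p, rel=1e-8)
                assert r.df_den == len(v) - 1

    def test_matches_textbook_cell_mean_decomposition(self):
        # brute-force SS formulas on a small hand-built table
        rng = np.random.default_rng(1)
        y = rng.normal(10, 2, (3, 4))
        table = make_table(y)
        res = {r.effect: r for r in rmanova_2x2(table)}
        n = 3
        # cells ordered LA_high, HA_high, LA_low, HA_low
        subj = y.mean(axis=1)
        grand = y.mean()
        mean_high, mean_low = y[:, :2].mean(), y[:, 2:].mean()
        ss_c = 2 * n * ((mean_high - grand) ** 2 + (mean_low - grand) ** 2)
        # clarity x subject interaction error
        ss_cs = 2 * sum(
            (y[i, c * 2:c * 2 + 2].mean() - subj[i]
             - (mean_high, mean_low)[c] + grand) ** 2
            for i in range(n) for c in (0, 1))
        f_c = ss_c / (ss_cs / (n - 1))
        assert res["Clarity"].F == pytest.approx(f_c, rel=1e-10)
        assert res["Clarity"].partial_eta_sq == pytest.approx(
            ss_c / (ss_c + ss_cs), rel=1e-10)

    def test_matches_pingouin_two_way_rm_anova(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, (12, 4))
        table = make_table(y)
        ours = {r.effect: r for r in rmanova_2x2(table)}
        pg = pingouin.rm_anova(data=long_format(y), dv="value",
                               within=["clarity", "ambiguity"],
                               subject="subject", detailed=True)
        mapping = {"clarity": "Clarity", "ambiguity": "Ambiguity",
                   "clarity * ambiguity": "Clarity x Ambiguity"}
        for pg_name, our_name in mapping.items():
            row = pg[pg["Source"] == pg_name].iloc[0]
            assert ours[our_name].F == pytest.approx(row["F"], rel=1e-8)
            assert ours[our_name].p == pytest.approx(row["p_unc"], rel=1e-6)

    def test_identical_cells_degenerate_f_zero_p_one(self):
        table = make_table(np.tile([[1.0, 1.0, 1.0, 1.0]], (4, 1)))
        for r in rmanova_2x2(table):
            assert r.F == 0.0 and r.p == 1.0

    def test_incomplete_table_names_participant_and_cell(self):
        y = np.ones((3, 4))
        table = make_table(y)
        table.values.loc["P001", "HA_low"] = np.nan
        with pytest.raises(ValueError, match="P001.*HA_low"):
            rmanova_2x2(table)

    def test_p_monotone_decreasing_in_f(self):
        fs = [0.1, 1.0, 5.0, 25.0]
        ps = [float(sps.f.sf(F, 1, 10)) for F in fs]
        # sanity anchor for the engine: our p values use this same tail
        table = make_table(np.random.default_rng(3).normal(0, 1, (11, 4)))
        for r in rmanova_2x2(table):
            assert r.p == pytest.approx(float(sps.f.sf(r.F, 1, 10)),
                                        rel=1e-12)
        assert ps == sorted(ps, reverse=True)

    def test_eta_invariant_to_per_participant_constant(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, (8, 4))
        shifted = y + rng.normal(0, 5, (8, 1))
        for a, b in zip(rmanova_2x2(make_table(y)),
                        rmanova_2x2(make_table(shifted))):
            assert b.partial_eta_sq == pytest.approx(a.partial_eta_sq,
                                                     rel=1e-9)
            assert b.F == pytest.approx(a.F, rel=1e-9)


class TestSimpleEffect:
    def test_identical_cells_give_zero_f(self):
        y = np.tile([[2.0, 2.0, 5.0, 7.0]], (5, 1))
        r = simple_effect(make_table(y), "clarity", "high_snr", "ambiguity")
        assert r.F == 0.0

    def test_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, (9, 4))
        table = make_table(y)
        r = simple_effect(table, "clarity", "low_snr", "ambiguity")
        t, p = sps.ttest_rel(y[:, 3], y[:, 2])  # HA_low vs LA_low
        assert r.F == pytest.approx(t ** 2, rel=1e-10)
        assert r.p == pytest.approx(p, rel=1e-8)

    def test_reduces_to_main_effect_of_duplicated_factor_table(self):
        # duplicating the fixed level into both levels of the fixed factor
        # makes the full-design main effect equal the simple effect
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, (7, 4))
        table = make_table(y)
        r_simple = simple_effect(table, "clarity", "high_snr", "ambiguity")
        dup = y.copy()
        dup[:, 2:] = y[:, :2]  # low cells replaced by high cells
        r_main = {r.effect: r for r in rmanova_2x2(make_table(dup))}
        assert r_simple.F == pytest.approx(r_main["Ambiguity"].F, rel=1e-10)


class TestPooledMixedAnova:
    def _closed_form(self, y1, y2):
        """Independent split-plot oracle via explicit error partitions."""
        def scores(y, coef):
            return y @ coef

        coefs = {
            "Clarity": np.array([-0.5, -0.5, 0.5, 0.5]),
            "Ambiguity": np.array([-0.5, 0.5, -0.5, 0.5]),
            "Clarity x Ambiguity": np.array([1.0, -1.0, -1.0, 1.0]),
        }
        n1, n2 = len(y1), len(y2)
        N = n1 + n2
        out = {}
        # between effect: one-way ANOVA on subject means
        m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
        sse_b = ((m1 - m1.mean()) ** 2).sum() + ((m2 - m2.mean()) ** 2).sum()
        # Type III hypothesis SS for unbalanced two-group design
        diff = m2.mean() - m1.mean()
        ss_hyp = diff ** 2 / (1 / n1 + 1 / n2)
        out["Experiment"] = ss_hyp / (sse_b / (N - 2))
        for name, coef in coefs.items():
            s1, s2 = scores(y1, coef), scores(y2, coef)
            sse = ((s1 - s1.mean()) ** 2).sum() + \
                  ((s2 - s2.mean()) ** 2).sum()
            mse = sse / (N - 2)
            grand = 0.5 * (s1.mean() + s2.mean())  # unweighted (Type III)
            ss_main = grand ** 2 / (0.25 * (1 / n1 + 1 / n2))
            ss_int = (s2.mean() - s1.mean()) ** 2 / (1 / n1 + 1 / n2)
            out[name] = ss_main / mse
            out[f"{name} x Experiment"] = ss_int / mse
        return out

    def test_identical_groups_give_zero_experiment_f(self):
        y = np.random.default_rng(7).normal(0, 1, (5, 4))
        res = {r.effect: r for r in pooled_mixed_anova(
            [make_table(y, "A"), make_table(y, "B")])}
        assert res["Experiment"].F == pytest.approx(0.0, abs=1e-20)

    def test_matches_closed_form_split_plot_oracle(self):
        rng = np.random.default_rng(8)
        y1 = rng.normal(0, 1, (6, 4)) + rng.normal(0, 1, (6, 1))
        y2 = 0.5 + rng.normal(0, 1, (4, 4)) + rng.normal(0, 1, (4, 1))
        res = {r.effect: r for r in pooled_mixed_anova(
            [make_table(y1, "A"), make_table(y2, "B")])}
        oracle = self._closed_form(y1, y2)
        assert len(res) == 7
        for name, f in oracle.items():
            assert res[name].F == pytest.approx(f, rel=1e-9)
            assert res[name].df_den == 8  # N - 2

    def test_within_fs_differ_from_collapsed_only_via_error_term(self):
        # concatenating the groups and running the plain rmANOVA uses the
        # total contrast variance as error; the split plot partitions out
        # the group difference, so SS_effect agrees but error terms differ
        rng = np.random.default_rng(9)
        y1 = rng.normal(0, 1, (5, 4))
        y2 = rng.normal(0, 1, (5, 4))
        pooled = {r.effect: r for r in pooled_mixed_anova(
            [make_table(y1, "A"), make_table(y2, "B")])}
        collapsed = {r.effect: r for r in rmanova_2x2(
            make_table(np.vstack([y1, y2])))}
        coef = np.array([-0.5, -0.5, 0.5, 0.5])
        s = np.vstack([y1, y2]) @ coef
        s1, s2 = y1 @ coef, y2 @ coef
        # balanced groups: hypothesis SS coincide; error SS differ by the
        # between-group component of the scores
        n = len(s)
        ss_hyp = n * s.mean() ** 2
        sse_total = ((s - s.mean()) ** 2).sum()
        sse_within = ((s1 - s1.mean()) ** 2).sum() + \
                     ((s2 - s2.mean()) ** 2).sum()
        assert collapsed["Clarity"].F == pytest.approx(
            ss_hyp / (sse_total / (n - 1)), rel=1e-9)
        assert pooled["Clarity"].F == pytest.approx(
            ss_hyp / (sse_within / (n - 2)), rel=1e-9)

    def test_three_groups_rejected(self):
        t = make_table(np.ones((3, 4)))
        with pytest.raises(ValueError, match="2 groups"):
            pooled_mixed_anova([t, t, t])


class TestEffectMagnitudeContrast:
    def test_equal_effects_give_zero_f(self):
        rng = np.random.default_rng(10)
        base = rng.normal(0, 1, (6, 1))
        d = rng.normal(2, 1, (6, 1))
        # clarity and ambiguity effects are identical (d) per participant
        y = np.hstack([base, base + d, base + d, base + 2 * d])
        r = effect_magnitude_contrast(make_table(y))
        assert r.F == pytest.approx(0.0, abs=1e-18)

    def test_equals_squared_one_sample_t(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, (10, 4))
        r = effect_magnitude_contrast(make_table(y))
        d_c = y[:, 2:].mean(axis=1) - y[:, :2].mean(axis=1)
        d_a = y[:, [1, 3]].mean(axis=1) - y[:, [0, 2]].mean(axis=1)
        t, p = sps.ttest_1samp(d_c - d_a, 0.0)
        assert r.F == pytest.approx(t ** 2, rel=1e-10)
        assert r.p == pytest.approx(p, rel=1e-8)
        assert r.df_den == 9

    def test_factor_swap_preserves_f(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, (8, 4))
        # swapping the roles of the factors flips the sign of the mean
        # difference but not the F statistic
        swapped = y[:, [0, 2, 1, 3]]
        r1 = effect_magnitude_contrast(make_table(y))
        r2 = effect_magnitude_contrast(make_table(swapped))
        assert r2.F == pytest.approx(r1.F, rel=1e-10)

    def test_pooled_tables_concatenate_participants(self):
        rng = np.random.default_rng(13)
        y1, y2 = rng.normal(0, 1, (6, 4)), rng.normal(0, 1, (5, 4))
        r = effect_magnitude_contrast([make_table(y1, "A"),
                                       make_table(y2, "B")])
        assert r.df_den == 10  # 11 participants - 1


class TestPartialCorrelation:
    def test_perfect_dependence(self):
        x = np.arange(10.0)
        z = np.r_[np.zeros(5), np.ones(5)]
        r = partial_correlation(x, x.copy(), z)
        assert r.r == pytest.approx(1.0)
        assert r.p == pytest.approx(0.0, abs=1e-12)

    def test_group_shift_confound_removed(self):
        # x and y are independent within groups but share a large group
        # offset: the raw correlation is inflated, the partial one is not
        rng = np.random.default_rng(14)
        z = np.r_[np.zeros(40), np.ones(40)]
        x = rng.normal(0, 1, 80) + 10 * z
        y = rng.normal(0, 1, 80) + 10 * z
        raw = np.corrcoef(x, y)[0, 1]
        part = partial_correlation(x, y, z)
        assert raw > 0.9
        assert abs(part.r) < 0.3
        # residualization oracle
        rx = x - np.where(z == 0, x[z == 0].mean(), x[z == 1].mean())
        ry = y - np.where(z == 0, y[z == 0].mean(), y[z == 1].mean())
        assert part.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], rel=1e-9)

    def test_df_is_n_minus_3(self):
        rng = np.random.default_rng(15)
        z = (np.arange(73) < 38).astype(float)
        r = partial_correlation(rng.normal(0, 1, 73),
                                rng.normal(0, 1, 73), z)
        assert r.df == 70

    def test_matches_pingouin(self):
        rng = np.random.default_rng(16)
        n = 30
        z = (np.arange(n) < 15).astype(float)
        x = rng.normal(0, 1, n) + z
        y = 0.4 * x + rng.normal(0, 1, n)
        ours = partial_correlation(x, y, z)
        pg = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z")
        assert ours.r == pytest.approx(float(pg["r"].iloc[0]), rel=1e-8)
        assert ours.p == pytest.approx(float(pg["p_val"].iloc[0]), rel=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(np.arange(5.0), np.arange(5.0), np.ones(5))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 2 ** 20), n=st.integers(3, 20))
def test_property_within_f_is_paired_t_squared(seed, n):
    rng = np.random.default_rng(seed)
    y = rng.normal(0, 1, (n, 4))
    results = {r.effect: r for r in rmanova_2x2(make_table(y))}
    scores = 0.5 * (y[:, 2] + y[:, 3]) - 0.5 * (y[:, 0] + y[:, 1])
    t, _ = sps.ttest_1samp(scores, 0.0)
    assert results["Clarity"].F == pytest.approx(t ** 2, rel=1e-10)
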