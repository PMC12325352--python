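import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from romocap import (RomocapError, check_assumptions, cohens_d_from_summary,
                     cohens_d_paired, cohens_d_pooled, effect_band,
                     fatigue_analysis, holm_posthoc, mixed_rm_anova,
                     paired_prepost, rm_anova_within, side_comparison)
from romocap.stats import holm_adjust


def _wg_table(x, sessions=("PRE", "ACUTE", "POST")):
    """(n, k) array -> tidy rows."""
    n, k = x.shape
    rows = [dict(participant=f"P{i:02d}", group="WG", session=sessions[j],
                 value=x[i, j]) for i in range(n) for j in range(k)]
    return pd.DataFrame(rows)


def _mixed_table(wg, cg):
    rows = []
    for g, x in (("WG", wg), ("CG", cg)):
        for i in range(len(x)):
            rows.append(dict(participant=f"{g}{i:02d}", group=g,
                             session="PRE", value=x[i, 0]))
            rows.append(dict(participant=f"{g}{i:02d}", group=g,
                             session="POST", value=x[i, 1]))
    return pd.DataFrame(rows)


class TestHolm:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.03, 0.04]),
                                   [0.03, 0.06, 0.06])

    def test_single_comparison_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_adjusted_monotone_and_not_below_raw(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(size=8)
        adj = holm_adjust(raw)
        assert (adj >= raw - 1e-15).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_posthoc_wrapper_returns_paired_effects(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=20)
        pairs = {"A-vs-B": (base + 1.0 + rng.normal(0, 0.5, 20), base),
                 "A-vs-C": (base + rng.normal(0, 0.5, 20), base)}
        res = holm_posthoc(pairs)
        assert len(res) == 2
        big = next(r for r in res if r.name == "posthoc[A-vs-B]")
        assert big.adjusted_p >= big.p_value - 1e-15
        assert big.effect_size > 0.8 and big.effect_band == "very large"


class TestCohensD:
    def test_identical_samples_zero_small(self):
        x = np.arange(10.0)
        assert cohens_d_paired(x, x) == 0.0
        assert effect_band(0.0) == "small"

    def test_printed_summary_value(self):
        d = cohens_d_from_summary(29.92, 15.67, 38.73, 17.70)
        assert d == pytest.approx(0.527, abs=5e-4)
        # closed form to machine precision
        assert d == pytest.approx(
            (38.73 - 29.92) / np.sqrt((15.67 ** 2 + 17.70 ** 2) / 2),
            abs=1e-12)

    def test_unit_mean_unit_sd_diff(self):
        rng = np.random.default_rng(2)
        diff = rng.normal(size=500)
        diff = (diff - diff.mean()) / diff.std(ddof=1) + 1.0
        d = cohens_d_paired(diff, np.zeros_like(diff))
        assert d == pytest.approx(1.0, abs=1e-9)
        assert effect_band(d) == "very large"

    def test_band_boundaries_left_closed(self):
        assert effect_band(0.19) == "small"
        assert effect_band(0.20) == "moderate"
        assert effect_band(0.50) == "large"
        assert effect_band(0.80) == "very large"

    def test_zero_variance_rejected(self):
        with pytest.raises(RomocapError):
            cohens_d_paired([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(RomocapError):
            cohens_d_pooled([1.0, 1.0], [2.0, 2.0])


class TestAssumptions:
    def test_normal_sample_rarely_rejected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            df = pd.DataFrame(dict(
                participant=range(50), group="WG", session="PRE",
                task="twist", parameter="SRL_ROM",
                value=rng.normal(size=50)))
            res = check_assumptions(df)
            hits += res[0].p_value > 0.05
        assert hits >= 90

    def test_constant_cell_skipped(self):
        df = pd.DataFrame(dict(participant=range(5), group="WG",
                               session="PRE", task="twist",
                               parameter="SRL_ROM", value=1.0))
        assert check_assumptions(df) == []

    def test_levene_null_p_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(500):
            rows = []
            for g in ("WG", "CG"):
                for i in range(15):
                    rows.append(dict(participant=f"{g}{i}", group=g,
                                     session="PRE", task="twist",
                                     parameter="SRL_ROM",
                                     value=rng.normal()))
            res = check_assumptions(pd.DataFrame(rows))
            ps.append([r for r in res if r.name.startswith("levene")][0].p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestSideComparison:
    def _table(self, left, right):
        rows = []
        for i, (l, r) in enumerate(zip(left, right)):
            for side, v in (("left", l), ("right", r)):
                rows.append(dict(participant=f"P{i}", session="PRE",
                                 task="twist", parameter="SRL_ROM",
                                 side=side, value=v))
        return pd.DataFrame(rows)

    def test_identical_sides_give_t0_p1(self):
        v = np.arange(10.0) + 20.0
        res = side_comparison(self._table(v, v))[("twist", "SRL_ROM")]
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_systematic_difference_detected(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(200):
            base = rng.normal(30, 10, 21)
            res = side_comparison(self._table(
                base, base + 5.0 + rng.normal(0, 3, 21)))
            hits += res[("twist", "SRL_ROM")].p_value < 0.05
        assert hits >= 0.95 * 200

    def test_single_pair_rejected(self):
        with pytest.raises(RomocapError):
            side_comparison(self._table([1.0], [2.0]))


class TestRmAnova:
    def test_no_session_effect_gives_zero_f(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))  # subjects differ only
        res = rm_anova_within(_wg_table(x))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 3)) + np.array([0.0, 0.5, 1.0])
        table = _wg_table(x)
        ours = rm_anova_within(table)
        ref = AnovaRM(table, depvar="value", subject="participant",
                      within=["session"]).fit().anova_table
        assert ours.statistic == pytest.approx(ref["F Value"].iloc[0],
                                               rel=1e-8)
        assert ours.p_value == pytest.approx(ref["Pr > F"].iloc[0], abs=1e-10)

    def test_session_shift_detected_with_power(self):
        """Session means following the treated group's shoulder-extension
        trajectory are detected in most correlated-normal replicates."""
        rng = np.random.default_rng(7)
        means = np.array([29.92, 32.63, 38.73])
        sds = np.array([15.67, 17.54, 17.70])
        cov = 0.8 * np.outer(sds, sds)
        np.fill_diagonal(cov, sds ** 2)
        chol = np.linalg.cholesky(cov)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            x = means + rng.standard_normal((21, 3)) @ chol.T
            hits += rm_anova_within(_wg_table(x)).p_value < 0.05
        assert hits > n_rep / 2

    def test_too_few_participants_rejected(self):
        with pytest.raises(RomocapError):
            rm_anova_within(_wg_table(np.ones((1, 3))))


class TestMixedAnova:
    def test_identical_trajectories_no_interaction(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(21, 1))
        x = np.hstack([base, base + 2.0])
        res = mixed_rm_anova(_mixed_table(x, x.copy()))
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_interaction_matches_split_plot_closed_form(self):
        """Cross-check the interaction F against hand-computed split-plot
        sums of squares on a balanced 2x2 design."""
        rng = np.random.default_rng(9)
        wg = rng.normal(size=(10, 2)) + np.array([0.0, 3.0])
        cg = rng.normal(size=(10, 2))
        res = mixed_rm_anova(_mixed_table(wg, cg))

        x = np.stack([wg, cg])  # (group, subject, session)
        grand = x.mean()
        cell = x.mean(axis=1)                      # (2, 2)
        g_mean = x.mean(axis=(1, 2))               # per group
        t_mean = x.mean(axis=(0, 1))               # per session
        subj = x.mean(axis=2)                      # (2, 10)
        n, k, g = 10, 2, 2
        ss_int = n * ((cell - g_mean[:, None] - t_mean[None, :] + grand) ** 2
                      ).sum()
        resid = x - cell[:, None, :] - subj[:, :, None] + g_mean[:, None, None]
        ss_err = (resid ** 2).sum()
        f_ref = (ss_int / ((g - 1) * (k - 1))) / (ss_err / ((2 * n - g) * (k - 1)))
        assert res["interaction"].statistic == pytest.approx(f_ref, rel=1e-8)

    def test_group_with_single_session_rejected(self):
        df = _mixed_table(np.ones((3, 2)), np.ones((3, 2)))
        df = df[~((df.group == "CG") & (df.session == "POST"))]
        with pytest.raises(RomocapError):
            mixed_rm_anova(df)


class TestPairedPrePost:
    def test_no_change_gives_p1_d0(self):
        x = np.hstack([np.arange(5.0)[:, None]] * 2)
        table = _mixed_table(x, x)
        res = paired_prepost(table[table.group == "CG"])
        assert res.p_value == 1.0 and res.effect_size == 0.0

    def test_uniform_shift_detected(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(200):
            pre = rng.normal(30, 6, 21)
            post = pre - 3.0 + rng.normal(0, 2, 21)
            table = _mixed_table(np.zeros((2, 2)),
                                 np.column_stack([pre, post]))
            hits += paired_prepost(table[table.group == "CG"]).p_value < 0.05
        assert hits >= 0.95 * 200

    def test_single_participant_rejected(self):
        table = _mixed_table(np.ones((2, 2)), np.ones((1, 2)))
        with pytest.raises(RomocapError):
            paired_prepost(table[table.group == "CG"])


class TestFatigue:
    def _per_rep(self, profile_fn, n=12, reps=5):
        rows = []
        for i in range(n):
            for r in range(reps):
                rows.append(dict(participant=f"P{i}", repetition=r + 2,
                                 value=profile_fn(i, r)))
        return pd.DataFrame(rows)

    def test_flat_profile_null(self):
        out = fatigue_analysis(self._per_rep(lambda i, r: 30.0 + i))
        assert out["percent_change"] == pytest.approx(0.0, abs=1e-12)
        assert out["anova"].p_value == pytest.approx(1.0)

    def test_decreasing_profile_negative_change(self):
        out = fatigue_analysis(self._per_rep(lambda i, r: 30.0 - r))
        assert out["percent_change"] < 0
        assert out["first_vs_last"].significant

    def test_single_repetition_rejected(self):
        with pytest.raises(RomocapError):
            fatigue_analysis(self._per_rep(lambda i, r: 30.0, reps=1))
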