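"""Group-level statistical workflow for cohort ROM/duration tables.

The workflow mirrors common practice in longitudinal movement studies:

1. assumption checks — Shapiro-Wilk normality per cell, Levene
   homogeneity of variances across groups;
2. preliminary paired t-test between right and left sides of bilateral
   tasks; non-significance justifies pooling the sides;
3. a 2 (group) x 2 (session: PRE/POST) mixed repeated-measures ANOVA
   whose session-by-group interaction is the headline test of a
   treatment-specific change;
4. within the treated group, a one-way repeated-measures ANOVA across
   PRE/ACUTE/POST (Greenhouse-Geisser corrected p reported alongside),
   followed by Holm-corrected paired t-tests between session pairs with
   Cohen's d effect sizes;
5. paired PRE-POST t-tests in the control group;
6. a per-repetition fatigue analysis: repeated-measures ANOVA across
   repetitions plus a first-vs-last contrast and the mean per-subject
   percent change.

Cohen's d uses mean(diff)/SD(diff) for paired contrasts and the
average-variance denominator (m2 - m1) / sqrt((s1^2 + s2^2)/2) for
independent/pooled contrasts, banded small < 0.20 <= moderate < 0.50
<= large < 0.80 <= very large.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import RomocapError

log = logging.getLogger(__name__)

ALPHA = 0.05

EFFECT_BANDS = ((0.20, "small"), (0.50, "moderate"), (0.80, "large"))


@dataclass
class TestResult:
    """One hypothesis test: statistic, p, optional adjustment and effect."""

    name: str
    statistic: float
    df: tuple
    p_value: float
    adjusted_p: float | None = None
    effect_size: float | None = None
    effect_band: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        for p in (self.p_value, self.adjusted_p):
            if p is not None and not (np.isnan(p) or 0.0 <= p <= 1.0):
                raise ValueError(f"p-value {p} outside [0, 1]")

    @property
    def significant(self) -> bool:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return bool(p < ALPHA)

    def to_row(self) -> dict:
        return {
            "test": self.name, "statistic": self.statistic, "df": str(self.df),
            "p": self.p_value, "p_adjusted": self.adjusted_p,
            "effect_size_d": self.effect_size, "effect_band": self.effect_band,
            **self.extra,
        }


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def effect_band(d: float) -> str:
    """Band |d| into small / moderate / large / very large."""
    mag = abs(d)
    if np.isnan(mag):
        return None
    for bound, name in EFFECT_BANDS:
        if mag < bound:
            return name
    return "very large"


def cohens_d_paired(x, y) -> float:
    """mean(x - y) / SD(x - y), the paired-contrast definition."""
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if len(diff) < 2:
        raise RomocapError("paired d needs >= 2 pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0
        raise RomocapError("zero-variance differences; d undefined")
    return float(diff.mean() / sd)


def cohens_d_pooled(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise RomocapError("pooled d needs >= 2 per sample")
    return cohens_d_from_summary(x.mean(), x.std(ddof=1),
                                 y.mean(), y.std(ddof=1))


def cohens_d_from_summary(m1: float, s1: float, m2: float, s2: float) -> float:
    """(m2 - m1) / sqrt((s1^2 + s2^2) / 2) from printed summary statistics."""
    denom = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if denom == 0:
        raise RomocapError("zero-variance samples; d undefined")
    return float((m2 - m1) / denom)


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def check_assumptions(table: pd.DataFrame, min_n: int = 3) -> list:
    """Shapiro-Wilk per (group, session, task, parameter) cell and Levene
    across groups per (session, task, parameter).

    Degenerate or undersized cells are skipped with a log entry.
    """
    results = []
    for keys, cell in table.groupby(["group", "session", "task", "parameter"]):
        v = cell["value"].to_numpy(dtype=float)
        label = "shapiro[" + "/".join(map(str, keys)) + "]"
        if len(v) < min_n or np.ptp(v) == 0:
            log.info("skipping %s (n=%d, degenerate=%s)", label, len(v),
                     np.ptp(v) == 0)
            continue
        w, p = sps.shapiro(v)
        results.append(TestResult(label, float(w), (len(v),), float(p)))
    for keys, cell in table.groupby(["session", "task", "parameter"]):
        groups = [g["value"].to_numpy(dtype=float)
                  for _, g in cell.groupby("group")]
        label = "levene[" + "/".join(map(str, keys)) + "]"
        if len(groups) < 2 or any(len(g) < min_n for g in groups):
            log.info("skipping %s", label)
            continue
        w, p = sps.levene(*groups)
        results.append(TestResult(label, float(w),
                                  (len(groups) - 1, sum(map(len, groups))),
                                  float(p)))
    return results


# ---------------------------------------------------------------------------
# side comparison
# ---------------------------------------------------------------------------

def side_comparison(table: pd.DataFrame) -> dict:
    """Paired t-test right vs left per (task, parameter).

    ``table`` must carry a ``side`` column with left/right values paired
    on (participant, session).  Returns {(task, parameter): TestResult};
    pooling sides is justified when no comparison is significant.
    """
    out = {}
    bilateral = table[table["side"].isin(["left", "right"])]
    for (task, param), sub in bilateral.groupby(["task", "parameter"]):
        wide = sub.pivot_table(index=["participant", "session"],
                               columns="side", values="value")
        wide = wide.dropna(subset=["left", "right"])
        if len(wide) < 2:
            raise RomocapError(
                f"side comparison for {task}/{param}: fewer than 2 pairs")
        left = wide["left"].to_numpy()
        right = wide["right"].to_numpy()
        if np.allclose(left, right):
            res = TestResult(f"side[{task}/{param}]", 0.0, (len(wide) - 1,),
                             1.0, effect_size=0.0, effect_band="small")
        else:
            t, p = sps.ttest_rel(right, left)
            d = cohens_d_paired(right, left)
            res = TestResult(f"side[{task}/{param}]", float(t),
                             (len(wide) - 1,), float(p), effect_size=d,
                             effect_band=effect_band(d))
        out[(task, param)] = res
    return out


def pooling_justified(side_results: dict, alpha: float = ALPHA) -> bool:
    return all(r.p_value > alpha for r in side_results.values())


# ---------------------------------------------------------------------------
# ANOVA layer
# ---------------------------------------------------------------------------

def _pcol(aov) -> str:
    """Uncorrected-p column name across pingouin versions."""
    return "p_unc" if "p_unc" in aov.columns else "p-unc"


def _rm_pvalues(aov, row):
    p_unc = float(row[_pcol(aov)])
    for col in ("p_GG_corr", "p-GG-corr"):
        if col in aov.columns and np.isfinite(row[col]):
            return p_unc, float(row[col])
    return p_unc, p_unc


def _complete_cases(table: pd.DataFrame, sessions) -> pd.DataFrame:
    """Keep participants observed in every requested session (listwise)."""
    sub = table[table["session"].isin(sessions)]
    counts = sub.groupby("participant")["session"].nunique()
    keep = counts[counts == len(sessions)].index
    dropped = sorted(set(sub["participant"]) - set(keep))
    if dropped:
        log.info("dropping incomplete participants: %s", dropped)
    return sub[sub["participant"].isin(keep)]


def rm_anova_within(table: pd.DataFrame,
                    sessions=("PRE", "ACUTE", "POST")) -> TestResult:
    """One-way repeated-measures ANOVA on session within one group.

    ``table``: tidy rows (participant, session, value) for a single
    group/task/parameter.  Reports the uncorrected F-test with the
    Greenhouse-Geisser corrected p alongside (``extra['p_gg']``).
    """
    sub = _complete_cases(table, sessions)
    n = sub["participant"].nunique()
    if n < 2:
        raise RomocapError("rm_anova_within needs >= 2 complete participants")
    if sub.groupby("participant")["value"].std(ddof=1).max() == 0 and \
            sub.groupby("session")["value"].mean().std(ddof=1) == 0:
        k = len(sessions)
        return TestResult("rm_anova[session]", 0.0,
                          (k - 1, (n - 1) * (k - 1)), 1.0,
                          extra={"p_gg": 1.0, "n": n})
    correction = n > len(sessions)  # sphericity stats need n > k
    aov = pg.rm_anova(data=sub, dv="value", within="session",
                      subject="participant", correction=correction,
                      detailed=False)
    row = aov.iloc[0]
    p_unc, p_gg = _rm_pvalues(aov, row)
    return TestResult("rm_anova[session]", float(row["F"]),
                      (float(row["ddof1"]), float(row["ddof2"])),
                      p_unc, extra={"p_gg": p_gg, "n": n})


def _split_plot_ss(wide: pd.DataFrame):
    """Within-subject residual and interaction sums of squares of a
    balanced-cells two-group repeated-measures design."""
    resid_ss = 0.0
    int_ss_parts = []
    grand = wide.to_numpy().mean()
    t_mean = wide.to_numpy().mean(axis=0)
    for _, gw in wide.groupby(level="group"):
        x = gw.to_numpy()
        cell = x.mean(axis=0)
        subj = x.mean(axis=1)
        g_mean = x.mean()
        resid = x - cell[None, :] - subj[:, None] + g_mean
        resid_ss += float((resid ** 2).sum())
        int_ss_parts.append(len(x) * ((cell - g_mean - t_mean + grand) ** 2).sum())
    return resid_ss, float(sum(int_ss_parts))


def mixed_rm_anova(table: pd.DataFrame, sessions=("PRE", "POST")) -> dict:
    """2 x 2 mixed ANOVA (between: group, within: session).

    Returns {'session': ..., 'group': ..., 'interaction': ...}; the
    interaction is the headline treatment-specific-change test.
    """
    sub = _complete_cases(table, sessions)
    for g in ("WG", "CG"):
        got = set(sub.loc[sub["group"] == g, "session"])
        if not set(sessions) <= got:
            raise RomocapError(f"group {g} lacks sessions {set(sessions) - got}")
    # degenerate designs (zero within-subject residual variance) break
    # the F ratio; resolve them from the sums of squares directly
    wide = sub.pivot_table(index=["group", "participant"], columns="session",
                           values="value")[list(sessions)]
    n_tot = len(wide)
    resid_ss, int_ss = _split_plot_ss(wide)
    scale = max(float(sub["value"].var(ddof=0)), 1.0)
    if resid_ss < 1e-12 * scale * n_tot:
        p_int = 1.0 if int_ss < 1e-12 * scale * n_tot else 0.0
        f_int = 0.0 if p_int == 1.0 else np.inf
        df = (1.0, float(n_tot - 2))
        return {"session": TestResult("mixed[session]", f_int, df, p_int),
                "group": TestResult("mixed[group]", f_int, df, p_int),
                "interaction": TestResult("mixed[interaction]", f_int, df,
                                          p_int)}
    aov = pg.mixed_anova(data=sub, dv="value", within="session",
                         between="group", subject="participant")
    out = {}
    namemap = {"session": "Session", "group": "Group",
               "interaction": "Interaction"}
    for key, src in namemap.items():
        row = aov[aov["Source"].str.lower() == src.lower()].iloc[0]
        p = float(row[_pcol(aov)])
        out[key] = TestResult(f"mixed[{key}]", float(row["F"]),
                              (float(row["DF1"]), float(row["DF2"])),
                              min(max(p, 0.0), 1.0))
    return out


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 1:
        return pvals.copy()
    return multipletests(pvals, method="holm")[1]


def holm_posthoc(pairs: dict) -> list:
    """Paired t-tests with Holm step-down adjustment.

    ``pairs``: {comparison name: (x, y)} of paired arrays.  Adjusted
    p-values are monotone non-decreasing in the sorted order and never
    below the raw p.
    """
    if len(pairs) < 1:
        raise RomocapError("no comparisons supplied")
    names, raw_p, stats_ = [], [], []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 2:
            raise RomocapError(f"comparison {name!r}: invalid pairing")
        if np.allclose(x, y):
            t, p, d = 0.0, 1.0, 0.0
        else:
            t, p = sps.ttest_rel(x, y)
            try:
                d = cohens_d_paired(x, y)
            except RomocapError:
                d = np.nan  # constant non-zero difference
            if np.isnan(p):  # zero-variance differences: exact shift
                t, p = np.inf, 0.0
        names.append(name)
        raw_p.append(float(p))
        stats_.append((float(t), len(x) - 1, d))
    adj = holm_adjust(raw_p)
    out = []
    for name, p, padj, (t, df, d) in zip(names, raw_p, adj, stats_):
        out.append(TestResult(f"posthoc[{name}]", t, (df,), p,
                              adjusted_p=float(padj), effect_size=d,
                              effect_band=effect_band(d)))
    return out


def paired_prepost(table: pd.DataFrame,
                   sessions=("PRE", "POST")) -> TestResult:
    """Paired PRE-POST t-test with paired Cohen's d (control group)."""
    wide = table.pivot_table(index="participant", columns="session",
                             values="value").dropna(subset=list(sessions))
    if len(wide) < 2:
        raise RomocapError("paired_prepost needs >= 2 complete participants")
    a = wide[sessions[0]].to_numpy()
    b = wide[sessions[1]].to_numpy()
    if np.allclose(a, b):
        return TestResult("paired[PRE-POST]", 0.0, (len(wide) - 1,), 1.0,
                          effect_size=0.0, effect_band="small")
    t, p = sps.ttest_rel(b, a)
    d = cohens_d_paired(b, a)
    return TestResult("paired[PRE-POST]", float(t), (len(wide) - 1,),
                      float(p), effect_size=d, effect_band=effect_band(d))


# ---------------------------------------------------------------------------
# fatigue / repetition progression
# ---------------------------------------------------------------------------

def fatigue_analysis(per_rep: pd.DataFrame) -> dict:
    """Progression of per-repetition ROM within one session.

    ``per_rep``: tidy rows (participant, repetition, value) for one
    group/session/task; repetitions must be ordered integers.  Returns
    the repetition RM-ANOVA, the first-vs-last paired contrast, and two
    percent-change summaries: ``percent_change`` is the mean of the
    per-participant 100*(last-first)/first, ``percent_change_of_means``
    the same ratio computed on the group means.
    """
    reps = np.sort(per_rep["repetition"].unique())
    if len(reps) < 2:
        raise RomocapError("fatigue analysis needs >= 2 repetitions")
    wide = per_rep.pivot_table(index="participant", columns="repetition",
                               values="value").dropna()
    first = wide[reps[0]].to_numpy()
    last = wide[reps[-1]].to_numpy()
    if np.allclose(wide.to_numpy().std(axis=1), 0):
        k, n = len(reps), len(wide)
        anova = TestResult("rm_anova[repetition]", 0.0,
                           (k - 1, (n - 1) * (k - 1)), 1.0)
    else:
        tidy = wide.reset_index().melt(id_vars="participant",
                                       var_name="repetition", value_name="value")
        aov = pg.rm_anova(data=tidy, dv="value", within="repetition",
                          subject="participant",
                          correction=len(wide) > len(reps))
        row = aov.iloc[0]
        p_unc, p_gg = _rm_pvalues(aov, row)
        anova = TestResult("rm_anova[repetition]", float(row["F"]),
                           (float(row["ddof1"]), float(row["ddof2"])),
                           p_unc, extra={"p_gg": p_gg})
    if np.allclose(first, last):
        contrast = TestResult("posthoc[first-vs-last]", 0.0,
                              (len(wide) - 1,), 1.0, effect_size=0.0,
                              effect_band="small")
    else:
        t, p = sps.ttest_rel(last, first)
        try:
            d = cohens_d_paired(last, first)
        except RomocapError:
            d = np.nan  # constant non-zero difference
        if np.isnan(p):  # zero-variance differences: exact shift
            t = np.inf if last.mean() > first.mean() else -np.inf
            p = 0.0
        contrast = TestResult("posthoc[first-vs-last]", float(t),
                              (len(wide) - 1,), float(p), effect_size=d,
                              effect_band=effect_band(d))
    pct_subj = float(np.mean(100.0 * (last - first) / first))
    pct_means = float(100.0 * (last.mean() - first.mean()) / first.mean())
    return {"anova": anova, "first_vs_last": contrast,
            "percent_change": pct_subj,
            "percent_change_of_means": pct_means}


# ---------------------------------------------------------------------------
# whole-cohort workflow
# ---------------------------------------------------------------------------

def analyze_cohort(table: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Run the full session/group workflow on a participant-level table.

    ``table``: long-format rows (participant, group, session, task,
    parameter, value), already side- and set-pooled.  Returns a tidy
    results table with one row per test.
    """
    rows = []

    def add(task, param, res: TestResult):
        rows.append({"task": task, "parameter": param, **res.to_row()})

    for res in check_assumptions(table):
        rows.append({"task": "", "parameter": "", **res.to_row()})

    for (task, param), sub in table.groupby(["task", "parameter"]):
        wg = sub[sub["group"] == "WG"]
        cg = sub[sub["group"] == "CG"]

        for mres in mixed_rm_anova(sub).values():
            add(task, param, mres)

        wg_sessions = [s for s in ("PRE", "ACUTE", "POST")
                       if s in set(wg["session"])]
        if len(wg_sessions) >= 2:
            anova = rm_anova_within(wg, sessions=wg_sessions)
            add(task, param, anova)
            if anova.p_value < alpha and len(wg_sessions) >= 2:
                wide = wg.pivot_table(index="participant", columns="session",
                                      values="value").dropna()
                pairs = {}
                for i in range(len(wg_sessions)):
                    for j in range(i + 1, len(wg_sessions)):
                        a, b = wg_sessions[i], wg_sessions[j]
                        pairs[f"{a}-vs-{b}"] = (wide[b].to_numpy(),
                                                wide[a].to_numpy())
                for res in holm_posthoc(pairs):
                    add(task, param, res)
        if {"PRE", "POST"} <= set(cg["session"]):
            add(task, param, paired_prepost(cg))
    return pd.DataFrame(rows)
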