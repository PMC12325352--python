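"""Validation experiments: oracle checks, recovery, power and type-I error.

This module packages the experiments used to validate the pipeline
end-to-end:

* a brute-force geometric oracle for every measured angle, written as
  direct arccos/atan2 evaluations of the angle *definitions* on
  explicit vectors — an independent computation path from the
  vectorised kinematics layer;
* forward/inverse recovery of ground-truth ROM and duration on
  noiseless and noisy synthetic trials;
* marker-level power/type-I experiments for the session-by-group
  interaction and the repetition (fatigue) contrast.

Every experiment takes an explicit seed and returns plain numbers, so
the same functions back both the test suite and the reproduction
script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_formats import MarkerTrajectorySet, TrialMetadata
from .kinematics import PRIMARY_ANGLE_BY_TASK, build_local_frame, compute_angles
from .preprocessing import FilterSpec, lowpass_filter
from .segmentation import segment_trial
from .stats import fatigue_analysis, mixed_rm_anova
from .synthetic_data import (BodyModel, CohortSpec, TaskProfile,
                             equalized_spec, simulate_cohort, simulate_trial)

#: Markers sufficient for the shoulder tasks (pelvis cluster + arms).
ARM_TASK_MARKERS = ("RASIS", "LASIS", "RPSIS", "LPSIS",
                    "RACR", "RELB", "LACR", "LELB")

#: The per-task true-ROM values used for recovery experiments: the
#: treated group's baseline means of each primary parameter.
BASELINE_TRUE_ROM = {
    "frontal_rise": 111.22,
    "lateral_rise": 107.29,
    "backward_push": 29.92,
    "lateral_bending": 37.60,
    "twist": 27.03,
    "anterior_flexion": 88.52,
}


# ---------------------------------------------------------------------------
# brute-force angle oracle
# ---------------------------------------------------------------------------

def _oracle_unsigned(v, axis):
    v = np.asarray(v, dtype=float)
    axis = np.asarray(axis, dtype=float)
    c = np.dot(v, axis) / (np.linalg.norm(v) * np.linalg.norm(axis))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def _oracle_signed_in_plane(v, zero_dir, pos_dir):
    v = np.asarray(v, dtype=float)
    return np.degrees(np.arctan2(np.dot(v, pos_dir), np.dot(v, zero_dir)))


def oracle_angles_sample(markers: dict, side: str = "right") -> dict:
    """Every measured angle for a single marker configuration, computed
    directly from the definitions with scalar dot products."""
    rasis, lasis = markers["RASIS"], markers["LASIS"]
    psis = 0.5 * (markers["RPSIS"] + markers["LPSIS"])
    normal = np.cross(lasis - psis, rasis - psis)
    y = normal / np.linalg.norm(normal)
    if y[1] < 0:
        y = -y
    x0 = rasis - lasis
    x = x0 - np.dot(x0, y) * y
    x = x / np.linalg.norm(x)
    z = np.cross(x, y)

    Y, Z = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
    out = {}

    acr, elb = ("RACR", "RELB") if side == "right" else ("LACR", "LELB")
    a = markers[elb] - markers[acr]
    a_loc = np.array([np.dot(a, x), np.dot(a, y), np.dot(a, z)])
    ex, ey, ez = np.eye(3)
    out["SF"] = _oracle_signed_in_plane(a_loc, -ey, ez)
    out["SE"] = _oracle_signed_in_plane(a_loc, -ey, -ez)
    lat = ex if side == "right" else -ex
    out["SA"] = _oracle_signed_in_plane(a_loc, -ey, lat)

    s = markers["RACR"] - markers["LACR"]
    s_loc = np.array([np.dot(s, x), np.dot(s, y), np.dot(s, z)])
    out["SIA"] = _oracle_unsigned(s, Y)
    out["SIL"] = _oracle_unsigned(s_loc, ey)
    out["SRA"] = _oracle_unsigned(s, Z)
    out["SRL"] = _oracle_unsigned(np.array([s_loc[0], 0.0, s_loc[2]]), ez)

    for lbl, (lo, hi) in (("S1L1", ("S1", "L1")), ("S1L3", ("S1", "L3")),
                          ("L1T1", ("L1", "T1")), ("L1T6", ("L1", "T6")),
                          ("T6T1", ("T6", "T1"))):
        out[lbl] = _oracle_unsigned(markers[hi] - markers[lo], Y)

    lower = markers["L1"] - markers["S1"]
    lower_loc = np.array([np.dot(lower, x), np.dot(lower, y), np.dot(lower, z)])
    out["PELVIS"] = _oracle_signed_in_plane(lower_loc, ey, ez)
    trunk = markers["T1"] - markers["S1"]
    out["TRUNK"] = _oracle_signed_in_plane(trunk, Y, Z)
    upper = markers["T1"] - markers["L1"]
    upper_loc = np.array([np.dot(upper, x), np.dot(upper, y), np.dot(upper, z)])
    u2, l2 = upper_loc[[1, 2]], lower_loc[[1, 2]]
    out["THORAX"] = np.degrees(np.arctan2(l2[0] * u2[1] - l2[1] * u2[0],
                                          np.dot(l2, u2)))
    return out


def random_configuration(rng, body: BodyModel | None = None) -> dict:
    """A plausibly posed random marker configuration: the neutral body
    perturbed by a random rigid transform plus independent random
    rotations of trunk and arms."""
    from .synthetic_data import _rotation_matrices, _TRUNK_MARKERS

    body = body or BodyModel()
    m = body.neutral_markers()

    def rot(axis, ang):
        return _rotation_matrices(np.asarray(axis, float), np.array([ang]))[0]

    # trunk posture: pitch/roll/yaw up to +-60 deg about S1
    pivot = m["S1"].copy()
    Rt = (rot([1, 0, 0], rng.uniform(-1.0, 1.0))
          @ rot([0, 0, 1], rng.uniform(-1.0, 1.0))
          @ rot([0, 1, 0], rng.uniform(-1.0, 1.0)))
    for lbl in _TRUNK_MARKERS:
        m[lbl] = Rt @ (m[lbl] - pivot) + pivot
    # arms: independent swing about each acromion
    for acr, elb in (("RACR", "RELB"), ("LACR", "LELB")):
        Ra = (rot([1, 0, 0], rng.uniform(-2.0, 2.0))
              @ rot([0, 0, 1], rng.uniform(-1.5, 1.5)))
        m[elb] = Ra @ (m[elb] - m[acr]) + m[acr]
    # whole-body rigid transform: yaw + small tilt + translation
    Rw = (rot([0, 1, 0], rng.uniform(-np.pi, np.pi))
          @ rot([1, 0, 0], rng.uniform(-0.3, 0.3)))
    t = rng.uniform(-500, 500, 3)
    return {lbl: Rw @ p + t for lbl, p in m.items()}


def angle_oracle_max_error(n_configs: int = 1000, seed: int = 0) -> float:
    """Max |implementation - oracle| (deg) over random configurations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_configs):
        cfg = random_configuration(rng)
        for side in ("right", "left"):
            traj = MarkerTrajectorySet(
                positions={k: v[None, :].copy() for k, v in cfg.items()},
                sample_rate=100.0)
            impl = compute_angles(traj, side=side)
            ref = oracle_angles_sample(cfg, side=side)
            for lbl, series in impl.items():
                if not series.valid[0]:
                    continue
                worst = max(worst, abs(float(series.values[0]) - ref[lbl]))
    return worst


# ---------------------------------------------------------------------------
# forward/inverse recovery
# ---------------------------------------------------------------------------

def recovery_experiment(noise_sd: float = 0.0, n_trials: int = 1,
                        seed: int = 0, filter_spec: FilterSpec | None = None,
                        tasks=None) -> pd.DataFrame:
    """Simulate trials of every task and recover ROM/duration.

    Returns one row per trial with the worst per-repetition ROM error,
    the pooled-ROM error, the repetition-count match and the duration
    error (samples) against the generator's ground truth.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for task in (tasks or BASELINE_TRUE_ROM):
        for k in range(n_trials):
            profile = TaskProfile(task=task, true_rom=BASELINE_TRUE_ROM[task],
                                  rep_rom_sd=2.0)
            s = int(rng.integers(0, 2 ** 31 - 1))
            traj, truth = simulate_trial(profile, noise_sd=noise_sd, seed=s,
                                         side="right")
            if noise_sd > 0 or filter_spec is not None:
                traj = lowpass_filter(traj, filter_spec or FilterSpec())
            label = PRIMARY_ANGLE_BY_TASK[task]
            series = compute_angles(traj, labels=[label], side="right")[label]
            res = segment_trial(series)
            n_match = len(res.repetitions) == len(truth.rep_roms)
            rep_err = (np.abs(res.rep_roms - truth.rep_roms).max()
                       if n_match else np.inf)
            rows.append(dict(
                task=task, trial=k, n_reps_detected=len(res.repetitions),
                n_reps_true=len(truth.rep_roms), rep_count_match=n_match,
                max_rep_rom_error_deg=rep_err,
                pooled_rom_error_deg=abs(res.pooled_rom
                                         - truth.rep_roms[1:].mean()),
                duration_error_samples=abs(res.duration_s - truth.duration_s)
                * series.sample_rate))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-level experiments
# ---------------------------------------------------------------------------

def _power_spec(seed: int, equalize: bool) -> CohortSpec:
    spec = CohortSpec(seed=seed, tasks=("backward_push",), sides=("right",),
                      n_sets=1, markers=ARM_TASK_MARKERS)
    return equalized_spec(spec) if equalize else spec


def run_cohort_replicate(spec: CohortSpec, parameter: str = "SE_ROM"):
    """Simulate one cohort, run the marker-level pipeline, and return the
    mixed-ANOVA interaction p-value for ``parameter``."""
    from .pipeline import PipelineConfig, build_cohort_tables, process_trial

    trials, _ = simulate_cohort(spec)
    cfg = PipelineConfig()
    results = [process_trial(m, tr, cfg) for m, tr in trials]
    table, _, _ = build_cohort_tables(results)
    sub = table[table["parameter"] == parameter]
    return mixed_rm_anova(sub)["interaction"].p_value


def interaction_power(n_replicates: int, seed: int = 0,
                      equalize: bool = False, alpha: float = 0.05) -> float:
    """Fraction of replicates detecting the session-by-group interaction.

    Each replicate simulates a 21 + 21 cohort of the shoulder-extension
    task (one side, one set per session) at the default marker noise and
    runs the full marker-level pipeline.  With ``equalize=True`` the
    control group receives the same session shift as the treated group,
    so rejections estimate the type-I error.
    """
    master = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        rep_seed = int(master.integers(0, 2 ** 31 - 1))
        p = run_cohort_replicate(_power_spec(rep_seed, equalize))
        hits += p < alpha
    return hits / n_replicates


def fatigue_experiment(n_subjects: int = 21, percent_increase: float = 29.1,
                       first_rep_rom: float = 29.66, rom_sd: float = 10.59,
                       seed: int = 0) -> dict:
    """Per-repetition progression recovery on simulated twist trials.

    Each subject performs one twist set whose amplitude rises linearly
    so that the *last considered* repetition exceeds the first considered
    one by ``percent_increase`` percent (the first repetition of the set
    is excluded as in the pooling protocol).  The marker-level pipeline
    extracts per-repetition ROMs and the repetition contrast is tested
    on the considered ones.  Returns the fatigue-analysis results; with
    noise, the recovered mean percent change estimates the simulated
    one.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_considered = 5  # repetitions 2..6 of a six-repetition set
    for i in range(n_subjects):
        rom_i = max(float(rng.normal(first_rep_rom, rom_sd)), 5.0)
        trend = rom_i * (percent_increase / 100.0) / (n_considered - 1)
        profile = TaskProfile(task="twist", true_rom=rom_i - trend,
                              rep_rom_sd=1.0, trend_deg_per_rep=trend)
        traj, _ = simulate_trial(profile, noise_sd=2.0,
                                 seed=int(rng.integers(0, 2 ** 31 - 1)),
                                 side="right")
        traj = lowpass_filter(traj)
        series = compute_angles(traj, labels=["SRL"], side="right")["SRL"]
        res = segment_trial(series)
        for r_idx, rep in enumerate(res.repetitions, start=1):
            if r_idx == 1:
                continue  # settling-in exclusion
            rows.append(dict(participant=f"P{i:02d}", repetition=r_idx,
                             value=rep.rom))
    table = pd.DataFrame(rows)
    return fatigue_analysis(table)


def type1_error_rm_anova(n_sim: int = 1000, n: int = 21, sd: float = 16.0,
                         corr: float = 0.8, seed: int = 0,
                         alpha: float = 0.05) -> float:
    """Empirical rejection rate of the session RM-ANOVA under the null."""
    import pingouin as pg

    rng = np.random.default_rng(seed)
    k = 3
    cov = corr * sd ** 2 * np.ones((k, k))
    np.fill_diagonal(cov, sd ** 2)
    chol = np.linalg.cholesky(cov)
    hits = 0
    subj = np.repeat(np.arange(n), k)
    sess = np.tile(np.arange(k), n)
    for _ in range(n_sim):
        x = rng.standard_normal((n, k)) @ chol.T
        df = pd.DataFrame({"value": x.ravel(), "participant": subj,
                           "session": sess})
        aov = pg.rm_anova(data=df, dv="value", within="session",
                          subject="participant")
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        hits += float(aov.iloc[0][pcol]) < alpha
    return hits / n_sim


def type1_error_interaction(n_sim: int = 1000, n: int = 21, sd: float = 16.0,
                            corr: float = 0.8, seed: int = 0,
                            alpha: float = 0.05) -> float:
    """Empirical rejection rate of the mixed-ANOVA interaction under the
    null (both groups share the same session effect)."""
    rng = np.random.default_rng(seed)
    cov = np.array([[sd ** 2, corr * sd ** 2], [corr * sd ** 2, sd ** 2]])
    chol = np.linalg.cholesky(cov)
    hits = 0
    rows_template = []
    for g in ("WG", "CG"):
        for i in range(n):
            rows_template.append((f"{g}{i:02d}", g))
    for _ in range(n_sim):
        x = rng.standard_normal((2 * n, 2)) @ chol.T
        recs = []
        for (pid, g), (pre, post) in zip(rows_template, x):
            recs.append((pid, g, "PRE", pre))
            recs.append((pid, g, "POST", post))
        df = pd.DataFrame(recs, columns=["participant", "group", "session",
                                         "value"])
        res = mixed_rm_anova(df)
        hits += res["interaction"].p_value < alpha
    return hits / n_sim


def cohort_mean_convergence(n_per_group: int = 2000, seed: int = 0,
                            task: str = "backward_push",
                            session: str = "POST") -> dict:
    """Empirical mean of the simulated treated-group latent ROM vs the
    generating mean, in standard-error units (truth level, no markers)."""
    spec = CohortSpec(seed=seed, n_per_group=n_per_group, tasks=(task,),
                      sides=("right",), n_sets=1)
    spec = dataclasses.replace(spec)
    _, truth = simulate_cohort(spec, keep_trajectories=False)
    label = PRIMARY_ANGLE_BY_TASK[task]
    sub = truth[(truth["group"] == "WG") & (truth["session"] == session)
                & (truth["parameter"] == f"{label}_ROM")]["value"]
    mean_target, sd_target = spec.rom_params[task]["WG"][session]
    se = sd_target / np.sqrt(n_per_group)
    return {"empirical_mean": float(sub.mean()),
            "target_mean": mean_target,
            "deviation_se_units": float(abs(sub.mean() - mean_target) / se)}
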