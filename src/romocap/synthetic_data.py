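"""Forward-kinematic synthetic trials and cohorts with known ground truth.

A rigid-segment body model places the canonical markers in a neutral
upright posture.  Each task drives a single rotational degree of
freedom with a raised-cosine profile per repetition,

    theta_r(tau) = (ROM_r / 2) * (1 - cos(2 pi tau / T)),   tau in [0, T],

with ROM_r = true_rom + trend * (r - 1) + N(0, rep_rom_sd^2), separated
by rest plateaus at the neutral angle.  Because the markers are placed
by exact forward kinematics, the task's primary measured angle equals
theta by construction, which makes the generator a ground-truth oracle
for the whole downstream pipeline.  Soft-tissue artifact is modelled
only as i.i.d. Gaussian noise per marker coordinate.

Cohorts draw each participant's latent per-session true ROM (and task
duration) from session-specific normal distributions with a common
between-session correlation, emulating a two-group longitudinal design
in which the treated group (WG) is measured at PRE/ACUTE/POST and the
control group (CG) at PRE/POST.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import RomocapError
from .io_formats import (
    MarkerTrajectorySet,
    TrialMetadata,
    SESSIONS_BY_GROUP,
    TASKS,
    UNILATERAL_TASKS,
)
from .kinematics import PRIMARY_ANGLE_BY_TASK


# ---------------------------------------------------------------------------
# Body model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BodyModel:
    """Rigid-segment landmark geometry (mm), neutral upright posture.

    Spinal landmarks sit on a vertical posterior midline, acromia lateral
    to T1, arms hanging along -y.  All lengths are positive and the
    spine is ordered caudally to cranially.
    """

    pelvis_width: float = 240.0        # inter-ASIS
    pelvis_depth: float = 180.0        # ASIS to PSIS, anterior-posterior
    psis_width: float = 120.0
    pelvis_height: float = 1000.0      # ASIS height above the floor
    s1_rise: float = 40.0              # ASIS plane to S1
    s1_l3: float = 100.0
    l3_l1: float = 100.0
    l1_t6: float = 150.0
    t6_t1: float = 100.0
    shoulder_half_width: float = 180.0
    acromion_anterior: float = 50.0    # spine line to acromion, anterior
    upper_arm: float = 300.0           # acromion to elbow

    def __post_init__(self):
        for name in ("pelvis_width", "pelvis_depth", "psis_width", "s1_l3",
                     "l3_l1", "l1_t6", "t6_t1", "shoulder_half_width",
                     "upper_arm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def neutral_markers(self) -> dict:
        w2, d2, pw2 = self.pelvis_width / 2, self.pelvis_depth / 2, self.psis_width / 2
        h = self.pelvis_height
        zs = -d2  # spine line sits at the posterior pelvis depth
        s1 = h + self.s1_rise
        l3 = s1 + self.s1_l3
        l1 = l3 + self.l3_l1
        t6 = l1 + self.l1_t6
        t1 = t6 + self.t6_t1
        za = zs + self.acromion_anterior
        m = {
            "RASIS": [w2, h, d2], "LASIS": [-w2, h, d2],
            "RPSIS": [pw2, h, -d2], "LPSIS": [-pw2, h, -d2],
            "S1": [0.0, s1, zs], "L3": [0.0, l3, zs], "L1": [0.0, l1, zs],
            "T6": [0.0, t6, zs], "T1": [0.0, t1, zs],
            "RACR": [self.shoulder_half_width, t1, za],
            "LACR": [-self.shoulder_half_width, t1, za],
        }
        m["RELB"] = [m["RACR"][0], m["RACR"][1] - self.upper_arm, m["RACR"][2]]
        m["LELB"] = [m["LACR"][0], m["LACR"][1] - self.upper_arm, m["LACR"][2]]
        return {k: np.asarray(v, dtype=float) for k, v in m.items()}


# ---------------------------------------------------------------------------
# Task profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskProfile:
    """One set of one task: repetition count, amplitude and timing."""

    task: str
    true_rom: float                  # deg, mean amplitude over repetitions
    rep_rom_sd: float = 2.0          # deg, i.i.d. per-repetition deviation
    n_reps: int = 6
    rep_period_s: float = 4.0
    rest_s: float = 1.0              # plateau between repetitions
    trend_deg_per_rep: float = 0.0   # fatigue/facilitation slope
    lead_s: float = 1.0              # rest before first / after last rep

    def __post_init__(self):
        if self.task not in TASKS:
            raise RomocapError(f"unsupported task {self.task!r}")
        if self.true_rom <= 0:
            raise ValueError("true_rom must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.rep_period_s <= 0:
            raise ValueError("rep_period_s must be positive")
        if self.rep_rom_sd < 0 or self.rest_s < 0 or self.lead_s < 0:
            raise ValueError("negative timing/variability parameter")


@dataclass
class TrialGroundTruth:
    """What the generator actually produced for one set."""

    rep_roms: np.ndarray      # realized per-repetition max-min excursion, deg
    duration_s: float         # first-rep start to last-rep end
    start_index: int
    end_index: int
    primary_label: str


def _angle_profile(profile: TaskProfile, rep_roms, sample_rate: float):
    """Sampled primary-angle curve (deg) and the true rep boundaries."""
    T = int(round(profile.rep_period_s * sample_rate))
    rest = int(round(profile.rest_s * sample_rate))
    lead = int(round(profile.lead_s * sample_rate))
    if T < 4:
        raise ValueError("rep_period too short for the sample rate")
    n = profile.n_reps
    # rep r occupies samples [s_r, s_r + T]; consecutive reps are separated
    # by `rest` plateau samples.
    theta = np.zeros(2 * lead + n * T + (n - 1) * rest + 1)
    starts = []
    pos = lead
    k = np.arange(T + 1)
    shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / T))
    for r in range(n):
        starts.append(pos)
        theta[pos:pos + T + 1] = rep_roms[r] * shape
        pos += T + rest
    end = starts[-1] + T
    realized = np.array([theta[s:s + T + 1].max() - theta[s:s + T + 1].min()
                         for s in starts])
    return theta, starts[0], end, realized


def _rotation_matrices(axis, theta_rad: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices (n, 3, 3) about a unit axis."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    c = np.cos(theta_rad)[:, None, None]
    s = np.sin(theta_rad)[:, None, None]
    eye = np.eye(3)
    return c * eye + s * K + (1 - c) * np.outer(ax, ax)


_TRUNK_MARKERS = ("S1", "L3", "L1", "T6", "T1", "RACR", "LACR", "RELB", "LELB")


def _task_motion(task: str, side: str):
    """(moving markers, rotation axis, pivot marker, sign) for a task.

    Sign encodes the anatomical direction of the movement for the given
    side; the primary angle's excursion magnitude is side-independent.
    """
    right = side != "left"
    if task == "frontal_rise":
        return (("RELB",) if right else ("LELB",)), (1, 0, 0), \
            ("RACR" if right else "LACR"), -1.0
    if task == "backward_push":
        return (("RELB",) if right else ("LELB",)), (1, 0, 0), \
            ("RACR" if right else "LACR"), +1.0
    if task == "lateral_rise":
        return (("RELB",) if right else ("LELB",)), (0, 0, 1), \
            ("RACR" if right else "LACR"), (1.0 if right else -1.0)
    if task == "lateral_bending":
        return _TRUNK_MARKERS, (0, 0, 1), "S1", (-1.0 if right else 1.0)
    if task == "twist":
        return _TRUNK_MARKERS, (0, 1, 0), "S1", (-1.0 if right else 1.0)
    if task == "anterior_flexion":
        return _TRUNK_MARKERS, (1, 0, 0), "S1", +1.0
    raise RomocapError(f"unsupported task {task!r}")


def simulate_trial(profile: TaskProfile, body: BodyModel | None = None,
                   noise_sd: float = 0.0, seed: int = 0,
                   sample_rate: float = 100.0, side: str = "right",
                   markers=None):
    """Generate one set of one task by forward kinematics.

    Returns ``(MarkerTrajectorySet, TrialGroundTruth)``.  With
    ``noise_sd=0`` the primary measured angle reproduces the generated
    curve exactly, so the ground-truth per-repetition excursions are
    recoverable to numerical precision.  ``markers`` restricts the
    output to a subset of the canonical marker set (default: all).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    body = body or BodyModel()
    rng = np.random.default_rng(seed)

    rep_roms = (profile.true_rom
                + profile.trend_deg_per_rep * np.arange(profile.n_reps)
                + rng.normal(0.0, profile.rep_rom_sd, profile.n_reps))
    rep_roms = np.maximum(rep_roms, 1.0)  # active ROM cannot vanish

    theta_deg, start, end, realized = _angle_profile(profile, rep_roms,
                                                     sample_rate)
    theta = np.radians(theta_deg)
    n = len(theta)

    neutral = body.neutral_markers()
    if markers is not None:
        neutral = {m: neutral[m] for m in markers}
    moving, axis, pivot_name, sign = _task_motion(profile.task, side)
    R = _rotation_matrices(axis, sign * theta)
    pivot = neutral.get(pivot_name, None)
    if pivot is None:
        pivot = body.neutral_markers()[pivot_name]

    labels = list(neutral)
    noise = (rng.normal(0.0, noise_sd, (n, 3 * len(labels)))
             if noise_sd > 0 else None)
    pos = {}
    for j, m in enumerate(labels):
        p0 = neutral[m]
        if m in moving:
            p = np.einsum("nij,j->ni", R, p0 - pivot) + pivot
        elif noise is None:
            p = np.tile(p0, (n, 1))
        else:
            p = np.broadcast_to(p0, (n, 3))
        if noise is not None:
            p = p + noise[:, 3 * j:3 * j + 3]
        pos[m] = p

    traj = MarkerTrajectorySet(positions=pos, sample_rate=sample_rate,
                               validate=False)
    truth = TrialGroundTruth(
        rep_roms=realized,
        duration_s=(end - start) / sample_rate,
        start_index=start,
        end_index=end,
        primary_label=PRIMARY_ANGLE_BY_TASK[profile.task],
    )
    return traj, truth


def inject_gaps(t: MarkerTrajectorySet, rate: float, max_len: int = 10,
                seed: int = 0, markers=None) -> MarkerTrajectorySet:
    """Mark random per-sample gaps (Bernoulli ``rate``), runs capped at
    ``max_len`` and never touching the trial boundaries."""
    if not 0 <= rate < 1:
        raise ValueError("gap rate must be in [0, 1)")
    out = t.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    for m in (markers or out.markers):
        mask = rng.random(out.n_samples) < rate
        mask[0] = mask[-1] = False
        # cap runs at max_len
        run = 0
        for i in range(len(mask)):
            run = run + 1 if mask[i] else 0
            if run > max_len:
                mask[i] = False
                run = 0
        out.gap_mask[m] |= mask
        out.positions[m][mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Default per-session distributions of the primary-angle ROM (deg) and
#: task duration (s): {task: {group: {session: (mean, sd)}}}.  These are
#: the study conditions the cohort generator emulates.
DEFAULT_ROM_PARAMS = {
    "frontal_rise": {
        "WG": {"PRE": (111.22, 14.38), "ACUTE": (110.47, 14.76), "POST": (116.13, 13.18)},
        "CG": {"PRE": (116.27, 13.95), "POST": (115.20, 12.86)},
    },
    "lateral_rise": {
        "WG": {"PRE": (107.29, 19.52), "ACUTE": (105.92, 21.33), "POST": (114.39, 20.86)},
        "CG": {"PRE": (109.57, 21.76), "POST": (113.46, 19.36)},
    },
    "backward_push": {
        "WG": {"PRE": (29.92, 15.67), "ACUTE": (32.63, 17.54), "POST": (38.73, 17.70)},
        "CG": {"PRE": (30.08, 10.94), "POST": (31.07, 8.55)},
    },
    "lateral_bending": {
        "WG": {"PRE": (37.60, 10.88), "ACUTE": (38.73, 10.67), "POST": (41.93, 11.26)},
        "CG": {"PRE": (37.28, 7.59), "POST": (36.99, 7.99)},
    },
    "twist": {
        "WG": {"PRE": (27.03, 10.32), "ACUTE": (31.30, 11.29), "POST": (31.85, 11.74)},
        "CG": {"PRE": (25.17, 9.09), "POST": (25.79, 8.81)},
    },
    "anterior_flexion": {
        "WG": {"PRE": (88.52, 17.53), "ACUTE": (88.25, 17.53), "POST": (90.84, 16.16)},
        "CG": {"PRE": (86.71, 15.77), "POST": (87.32, 15.23)},
    },
}

DEFAULT_DURATION_PARAMS = {
    "frontal_rise": {
        "WG": {"PRE": (34.76, 5.66), "ACUTE": (29.71, 6.13), "POST": (31.35, 5.03)},
        "CG": {"PRE": (36.18, 6.93), "POST": (34.68, 8.00)},
    },
    "lateral_rise": {
        "WG": {"PRE": (30.95, 6.05), "ACUTE": (27.21, 6.21), "POST": (28.10, 5.19)},
        "CG": {"PRE": (32.21, 7.41), "POST": (30.55, 7.77)},
    },
    "backward_push": {
        "WG": {"PRE": (26.75, 6.82), "ACUTE": (24.81, 5.56), "POST": (24.69, 4.18)},
        "CG": {"PRE": (27.22, 4.95), "POST": (25.40, 4.99)},
    },
    "lateral_bending": {
        "WG": {"PRE": (30.67, 7.05), "ACUTE": (25.25, 5.38), "POST": (27.47, 4.81)},
        "CG": {"PRE": (34.66, 7.10), "POST": (30.83, 5.13)},
    },
    "twist": {
        "WG": {"PRE": (31.83, 8.28), "ACUTE": (27.91, 5.93), "POST": (28.86, 4.68)},
        "CG": {"PRE": (34.51, 8.10), "POST": (32.35, 5.59)},
    },
    "anterior_flexion": {
        "WG": {"PRE": (22.26, 6.57), "ACUTE": (19.72, 5.07), "POST": (19.30, 3.82)},
        "CG": {"PRE": (25.54, 5.69), "POST": (22.77, 3.80)},
    },
}

#: Facilitation slope (deg per repetition) by (task, session): during the
#: acute session the twist task shows a progressive increase across the
#: analysed repetitions (2..6 of each set), roughly +2.4 deg/rep between
#: a first-considered-repetition ROM near 29.7 deg and a last near
#: 39.3 deg; all other cells are flat.
DEFAULT_TREND = {("twist", "ACUTE"): 2.41}


@dataclass
class CohortSpec:
    """Everything needed to simulate a full two-group cohort."""

    n_per_group: int = 21
    seed: int = 0
    tasks: tuple = TASKS
    sides: tuple = ("left", "right")
    n_sets: int = 2
    n_reps: int = 6
    rep_rom_sd: float = 2.0
    rest_s: float = 1.0
    marker_noise_sd_mm: float = 2.0
    within_subject_corr: float = 0.8
    sample_rate: float = 100.0
    #: optional marker subset to generate (None = full canonical set)
    markers: tuple | None = None
    rom_params: dict = field(default_factory=lambda: DEFAULT_ROM_PARAMS)
    duration_params: dict = field(default_factory=lambda: DEFAULT_DURATION_PARAMS)
    trend: dict = field(default_factory=lambda: dict(DEFAULT_TREND))

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 <= self.within_subject_corr <= 1:
            raise ValueError("within_subject_corr must be in [0, 1]")
        if self.marker_noise_sd_mm < 0:
            raise ValueError("marker noise SD must be >= 0")
        for task in self.tasks:
            if task not in self.rom_params or task not in self.duration_params:
                raise ValueError(f"no distribution parameters for task {task!r}")


def _draw_latents(rng, params, sessions, n, corr):
    """Per-subject latent values across sessions, equicorrelated normals."""
    means = np.array([params[s][0] for s in sessions])
    sds = np.array([params[s][1] for s in sessions])
    k = len(sessions)
    cov = corr * np.outer(sds, sds)
    cov[np.diag_indices(k)] = sds ** 2
    # svd handles the degenerate zero-variance case as well
    return rng.multivariate_normal(means, cov, size=n, method="svd")


def simulate_cohort(spec: CohortSpec, body: BodyModel | None = None,
                    keep_trajectories: bool = True):
    """Simulate a whole cohort; returns ``(trials, truth)``.

    ``trials`` is a list of ``(TrialMetadata, MarkerTrajectorySet)`` in a
    deterministic enumeration order; ``truth`` is a long-format table of
    the latent per-participant session values (parameter ``<LABEL>_ROM``
    in degrees and ``duration`` in seconds).  Per-trial random streams
    are spawned from the master seed in enumeration order, so a fixed
    spec and seed reproduce the cohort bit-for-bit.
    """
    body = body or BodyModel()
    master = np.random.default_rng(spec.seed)
    trials, truth_rows = [], []

    for group in ("WG", "CG"):
        sessions = SESSIONS_BY_GROUP[group]
        for task in spec.tasks:
            rom_lat = _draw_latents(master, spec.rom_params[task][group],
                                    sessions, spec.n_per_group,
                                    spec.within_subject_corr)
            dur_lat = _draw_latents(master, spec.duration_params[task][group],
                                    sessions, spec.n_per_group,
                                    spec.within_subject_corr)
            rom_lat = np.maximum(rom_lat, 2.0)
            label = PRIMARY_ANGLE_BY_TASK[task]
            sides = ("none",) if task in UNILATERAL_TASKS else spec.sides
            for i in range(spec.n_per_group):
                pid = f"{group}{i + 1:02d}"
                for j, session in enumerate(sessions):
                    true_rom = float(rom_lat[i, j])
                    true_dur = max(float(dur_lat[i, j]), spec.n_reps * 0.5)
                    rep_period = ((true_dur - (spec.n_reps - 1) * spec.rest_s)
                                  / spec.n_reps)
                    rep_period = max(rep_period, 0.5)
                    truth_rows.append(dict(
                        participant=pid, group=group, session=session,
                        task=task, parameter=f"{label}_ROM", value=true_rom))
                    truth_rows.append(dict(
                        participant=pid, group=group, session=session,
                        task=task, parameter="duration", value=true_dur))
                    # centre any repetition trend on the analysed
                    # repetitions (2..n) so the latent value stays the
                    # expected pooled ROM
                    trend = spec.trend.get((task, session), 0.0)
                    profile = TaskProfile(
                        task=task,
                        true_rom=max(true_rom - trend * spec.n_reps / 2.0,
                                     1.0),
                        rep_rom_sd=spec.rep_rom_sd, n_reps=spec.n_reps,
                        rep_period_s=rep_period, rest_s=spec.rest_s,
                        trend_deg_per_rep=spec.trend.get((task, session), 0.0),
                    )
                    if not keep_trajectories:
                        continue
                    for side in sides:
                        for set_index in (range(1, spec.n_sets + 1)):
                            trial_seed = int(master.integers(0, 2 ** 31 - 1))
                            meta = TrialMetadata(
                                participant_id=pid, group=group,
                                session=session, task=task, side=side,
                                set_index=set_index)
                            traj, _ = simulate_trial(
                                profile, body,
                                noise_sd=spec.marker_noise_sd_mm,
                                seed=trial_seed,
                                sample_rate=spec.sample_rate,
                                side=side if side != "none" else "right",
                                markers=spec.markers)
                            trials.append((meta, traj))
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def equalized_spec(spec: CohortSpec) -> CohortSpec:
    """Variant of ``spec`` with the control group given the treated
    group's session-to-session mean shifts (no group-specific effect):
    the null hypothesis of the session-by-group interaction holds."""
    rom = {t: {g: dict(v) for g, v in d.items()}
           for t, d in spec.rom_params.items()}
    dur = {t: {g: dict(v) for g, v in d.items()}
           for t, d in spec.duration_params.items()}
    for params in (rom, dur):
        for task in params:
            wg, cg = params[task]["WG"], params[task]["CG"]
            gain = wg["POST"][0] - wg["PRE"][0]
            cg["POST"] = (cg["PRE"][0] + gain, cg["POST"][1])
    return replace(spec, rom_params=rom, duration_params=dur)
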