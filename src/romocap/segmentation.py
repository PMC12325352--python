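"""Repetition detection, per-repetition ROM, duration and pooling.

Repetitions are found on the task's primary angle curve as prominent
extrema: each excursion peak with its flanking returns to the rest
plateau forms one repetition, and its ROM is the max-min excursion in
degrees.  Task duration runs from the start of the first repetition to
the end of the last.  Pooling follows the study protocol: average the
repetitions of each set after dropping the first repetition, average
the two sets per participant, then average sides when a preliminary
side comparison justifies it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import PoolingError, SegmentationError
from .io_formats import TrialMetadata
from .kinematics import AngleSeries

log = logging.getLogger(__name__)

#: Minimum peak prominence as a fraction of the global max-min amplitude.
DEFAULT_PROMINENCE_FRAC = 0.2
#: Repetitions expected per set in the study protocol.
EXPECTED_REPS = 6

POOLING_RULES = ("exclude_first", "all")
EXCLUSION_GRANULARITY = ("per_set", "per_side_first_set_only")


@dataclass(frozen=True)
class Repetition:
    """One movement cycle on the primary angle curve (sample indices)."""

    start_index: int
    peak_index: int
    end_index: int
    max_value: float
    min_value: float

    def __post_init__(self):
        if not self.start_index < self.peak_index < self.end_index:
            raise ValueError("repetition indices must satisfy start < peak < end")
        if self.max_value < self.min_value:
            raise ValueError("max_value < min_value")

    @property
    def rom(self) -> float:
        return self.max_value - self.min_value


@dataclass
class TrialResult:
    """Per-repetition ROMs, pooled ROM and duration for one trial/set/side."""

    metadata: TrialMetadata | None
    repetitions: list
    pooled_rom: float
    duration_s: float
    primary_label: str
    warnings: list = field(default_factory=list)

    @property
    def rep_roms(self) -> np.ndarray:
        return np.array([r.rom for r in self.repetitions])


def _boundary_indices(v: np.ndarray, lo: int, hi: int, peak: int):
    """Start/end of the repetition around ``peak`` within segment [lo, hi].

    The boundary on each side is the tied-minimum sample nearest the
    peak: on a rest plateau every sample attains the segment minimum, so
    this picks the instant motion actually leaves/returns to rest.
    """
    left = v[lo:peak + 1]
    lmin = left.min()
    start = lo + int(np.flatnonzero(left <= lmin + 1e-9)[-1])
    right = v[peak:hi + 1]
    rmin = right.min()
    end = peak + int(np.flatnonzero(right <= rmin + 1e-9)[0])
    return start, end


def detect_repetitions(a: AngleSeries, expected: int = EXPECTED_REPS,
                       min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC):
    """Detect repetitions as prominent extrema of the angle curve.

    The curve's movement direction is inferred from its asymmetry about
    the median (tasks whose primary angle *decreases* from rest, such
    as shoulder-line inclination during bending, produce valleys rather
    than peaks).  Returns ``(repetitions, warnings)``; a repetition
    count different from ``expected`` is a recorded warning, not an
    error.
    """
    if a.n_samples < a.sample_rate:
        raise SegmentationError("angle series shorter than 1 s")
    v = a.values.astype(float).copy()
    if not a.valid.all():
        idx = np.arange(len(v))
        if a.valid.sum() < 2:
            raise SegmentationError("too few valid samples")
        v = np.interp(idx, idx[a.valid], v[a.valid])
    amp = v.max() - v.min()
    if amp < 1e-9:
        raise SegmentationError("flat angle curve; no repetitions")

    med = np.median(v)
    signal = v if (v.max() - med) >= (med - v.min()) else -v
    peaks, _ = find_peaks(signal, prominence=min_prominence_frac * amp)
    if len(peaks) == 0:
        raise SegmentationError("no repetition extremum found")

    reps = []
    bounds = np.concatenate(([0], peaks, [len(v) - 1]))
    for k, pk in enumerate(peaks):
        start, end = _boundary_indices(signal, int(bounds[k]),
                                       int(bounds[k + 2]), int(pk))
        seg = v[start:end + 1]
        reps.append(Repetition(start_index=start, peak_index=int(pk),
                               end_index=end, max_value=float(seg.max()),
                               min_value=float(seg.min())))
    warnings = []
    if expected is not None and len(reps) != expected:
        msg = f"detected {len(reps)} repetitions, expected {expected}"
        warnings.append(msg)
        log.warning("%s (label=%s)", msg, a.label)
    return reps, warnings


def pool_trial(reps, rule: str = "exclude_first") -> float:
    """Average per-repetition ROM within one set.

    The default rule drops the first repetition (settling-in bias)
    before averaging.
    """
    if rule not in POOLING_RULES:
        raise ValueError(f"unknown pooling rule {rule!r}")
    roms = [r.rom for r in reps]
    if rule == "exclude_first":
        if len(roms) < 2:
            raise PoolingError("need >= 2 repetitions to exclude the first")
        roms = roms[1:]
    elif not roms:
        raise PoolingError("no repetitions to pool")
    return float(np.mean(roms))


def participant_rom(set1: float | None, set2: float | None,
                    context: str = "") -> float | None:
    """Average the two set means; a missing set propagates as missing."""
    if set1 is None or set2 is None:
        log.warning("missing set for %s; participant value dropped", context)
        return None
    return (set1 + set2) / 2.0


def pool_sides(left: float | None, right: float | None, justified: bool):
    """Average the sides when the side-comparison test justifies pooling.

    Returns a single float when pooled, else a dict keeping both sides.
    """
    if justified:
        vals = [v for v in (left, right) if v is not None]
        if not vals:
            return None
        return float(np.mean(vals))
    return {"left": left, "right": right}


def task_duration(reps, rate: float) -> float:
    """Seconds from the start of the first repetition to the end of the last."""
    if not reps:
        raise SegmentationError("cannot compute duration of an empty trial")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return (reps[-1].end_index - reps[0].start_index) / rate


def segment_trial(a: AngleSeries, metadata: TrialMetadata | None = None,
                  expected: int = EXPECTED_REPS,
                  min_prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                  pooling_rule: str = "exclude_first") -> TrialResult:
    """Detect repetitions and summarise one trial in a single call."""
    reps, warnings = detect_repetitions(a, expected, min_prominence_frac)
    return TrialResult(
        metadata=metadata,
        repetitions=reps,
        pooled_rom=pool_trial(reps, pooling_rule),
        duration_s=task_duration(reps, a.sample_rate),
        primary_label=a.label,
        warnings=warnings,
    )
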