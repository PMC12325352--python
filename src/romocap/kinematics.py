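"""Pelvis-anchored local frame and the measured shoulder/spine angle set.

Angle conventions
-----------------
* Laboratory frame (X, Y, Z): right-handed, Y vertical up, Z anterior,
  X from the subject's left to right.
* Local frame (x, y, z): per-sample pelvis-anchored basis.  x is the
  inter-ASIS direction (left to right), y the upward normal of the
  pelvic plane, z = x cross y (anterior).  Local-frame angles discount
  pelvic motion; laboratory-frame angles do not.
* Shoulder angles (SF flexion, SA abduction, SE extension) are planar
  projection angles of the upper-arm vector (acromion to elbow) from
  the neutral downward direction (-y): SF in the sagittal (y-z) plane,
  positive anterior; SE the same construction, positive posterior; SA
  in the frontal (x-y) plane, positive away from the midline.  Signed
  in (-180, 180].
* Line-vs-axis angles (SIA/SIL shoulder-line inclination, SRA/SRL
  rotation, and the spinal segment inclinations) are unsigned in
  [0, 180].
* SRL is measured between the projection of the shoulder line onto the
  local *transverse* (x-z) plane and z.  A rotation about the vertical
  axis cannot live in the coronal plane, so the transverse plane is the
  geometrically consistent reading; see docs/methods.md.
* PELVIS / TRUNK / THORAX are signed sagittal-plane projection angles
  (positive = anterior lean); PELVIS uses the local frame, TRUNK the
  laboratory frame, THORAX is the relative angle between the upper
  (L1->T1) and lower (S1->L1) spine projections.

Samples where a projection norm falls below 1% of the vector norm are
flagged invalid rather than producing a wildly unstable angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, SchemaError
from .io_formats import MarkerTrajectorySet

#: Fraction of the vector norm below which a planar projection is
#: considered indeterminate.
PROJECTION_TOL = 0.01

#: Primary angle driving repetition detection for each task.
PRIMARY_ANGLE_BY_TASK = {
    "frontal_rise": "SF",
    "lateral_rise": "SA",
    "backward_push": "SE",
    "lateral_bending": "SIL",
    "twist": "SRL",
    "anterior_flexion": "TRUNK",
}

ANGLE_LABELS = (
    "SF", "SA", "SE",
    "SIA", "SIL", "SRA", "SRL",
    "S1L1", "S1L3", "L1T1", "L1T6", "T6T1",
    "PELVIS", "TRUNK", "THORAX",
)


@dataclass
class AngleSeries:
    """One named angle sampled over a trial, in degrees."""

    label: str
    values: np.ndarray
    sample_rate: float
    frame_used: str = "local"  # "local" or "laboratory"
    side: str = "none"
    valid: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)
        if np.any(np.abs(self.values[self.valid]) > 360):
            raise ValueError("angle values out of range")

    @property
    def n_samples(self) -> int:
        return len(self.values)


@dataclass
class LocalFrame:
    """Per-sample orthonormal pelvis basis expressed in lab coordinates."""

    origin: np.ndarray  # (n, 3) mid-ASIS, mm
    x: np.ndarray       # (n, 3) medial-lateral, left -> right
    y: np.ndarray       # (n, 3) vertical, up
    z: np.ndarray       # (n, 3) anterior-posterior, anterior

    def express(self, v: np.ndarray) -> np.ndarray:
        """Rotate lab-frame direction vectors (n, 3) into local coordinates."""
        return np.stack(
            [np.sum(v * self.x, axis=1),
             np.sum(v * self.y, axis=1),
             np.sum(v * self.z, axis=1)], axis=1
        )


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-9):
        raise DegenerateGeometryError(f"{what}: zero-length vector")
    return v / n


def _require(t: MarkerTrajectorySet, markers) -> None:
    for m in markers:
        if m not in t.positions:
            raise SchemaError(f"marker {m} absent from trial")
        if t.gap_mask[m].any():
            raise SchemaError(f"marker {m} has unfilled gaps")


def build_local_frame(t: MarkerTrajectorySet) -> LocalFrame:
    """Construct the pelvis frame on every sample.

    The pelvic plane passes through RASIS, LASIS and the PSIS point
    (mid-PSIS when both sides are instrumented, the single PSIS
    otherwise).  y is the upward plane normal, x the inter-ASIS
    direction re-orthogonalised against y, z = x cross y.
    """
    _require(t, ("RASIS", "LASIS"))
    psis = [m for m in ("RPSIS", "LPSIS") if m in t.positions]
    if not psis:
        raise SchemaError("at least one PSIS marker is required")
    _require(t, psis)

    rasis = t.positions["RASIS"]
    lasis = t.positions["LASIS"]
    p = np.mean([t.positions[m] for m in psis], axis=0)

    x0 = rasis - lasis
    normal = np.cross(lasis - p, rasis - p)
    nn = np.linalg.norm(normal, axis=1)
    if np.any(nn < 1e-6 * np.maximum(np.linalg.norm(x0, axis=1), 1e-12)):
        raise DegenerateGeometryError("pelvic landmarks are collinear")
    y = normal / nn[:, None]
    # orient the normal upward (upright subject)
    flip = y[:, 1] < 0
    y[flip] *= -1.0
    x = _unit(x0 - np.sum(x0 * y, axis=1, keepdims=True) * y, "inter-ASIS axis")
    z = np.cross(x, y)
    return LocalFrame(origin=(rasis + lasis) / 2.0, x=x, y=y, z=z)


# ---------------------------------------------------------------------------
# angle primitives
# ---------------------------------------------------------------------------

def _line_axis_angle(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Unsigned angle (deg, [0, 180]) between vectors and a fixed axis."""
    vn = _unit(v, "line vector")
    cosang = np.clip(vn @ np.asarray(axis, dtype=float), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def _planar_signed(comp_pos: np.ndarray, comp_ref: np.ndarray,
                   norm3: np.ndarray):
    """Signed planar angle from a reference direction.

    ``comp_ref`` is the component along the zero-angle direction,
    ``comp_pos`` the component along the +90 deg direction.  Returns
    (angle_deg, valid) where valid is False when the in-plane projection
    is below PROJECTION_TOL of the full vector norm.
    """
    proj = np.hypot(comp_pos, comp_ref)
    valid = proj >= PROJECTION_TOL * norm3
    ang = np.degrees(np.arctan2(comp_pos, comp_ref))
    return ang, valid


# ---------------------------------------------------------------------------
# measured angles
# ---------------------------------------------------------------------------

def shoulder_angles(t: MarkerTrajectorySet, frame: LocalFrame, side: str,
                    frame_used: str = "local"):
    """SF / SA / SE projection angles for one arm.

    The arm vector (elbow minus acromion) is expressed in the local
    frame by default (``frame_used='laboratory'`` switches to lab axes).
    The neutral arm hanging along -y gives 0 for all three angles.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    acr, elb = ("RACR", "RELB") if side == "right" else ("LACR", "LELB")
    _require(t, (acr, elb))
    a_lab = t.positions[elb] - t.positions[acr]
    a = frame.express(a_lab) if frame_used == "local" else a_lab
    norm3 = np.linalg.norm(a, axis=1)
    if np.any(norm3 < 1e-9):
        raise DegenerateGeometryError("coincident acromion/elbow markers")

    sf, sf_ok = _planar_signed(a[:, 2], -a[:, 1], norm3)
    se, se_ok = _planar_signed(-a[:, 2], -a[:, 1], norm3)
    lateral = a[:, 0] if side == "right" else -a[:, 0]
    sa, sa_ok = _planar_signed(lateral, -a[:, 1], norm3)

    rate = t.sample_rate
    mk = lambda lbl, v, ok: AngleSeries(lbl, v, rate, frame_used, side, ok)
    return {"SF": mk("SF", sf, sf_ok), "SA": mk("SA", sa, sa_ok),
            "SE": mk("SE", se, se_ok)}


def spine_line_angles(t: MarkerTrajectorySet, frame: LocalFrame):
    """Shoulder-line inclination and rotation angles (SIA, SIL, SRA, SRL).

    s is the left-to-right acromion vector.  Inclination is measured
    against the vertical axis (lab Y for SIA, local y for SIL);
    rotation against the anterior axis (lab Z for SRA); SRL is the
    angle between the projection of s onto the local transverse plane
    and local z.
    """
    _require(t, ("LACR", "RACR"))
    s = t.positions["RACR"] - t.positions["LACR"]
    s_loc = frame.express(s)
    rate = t.sample_rate

    sia = _line_axis_angle(s, [0.0, 1.0, 0.0])
    sil = _line_axis_angle(s_loc, [0.0, 1.0, 0.0])
    sra = _line_axis_angle(s, [0.0, 0.0, 1.0])

    proj = s_loc.copy()
    proj[:, 1] = 0.0
    pn = np.linalg.norm(proj, axis=1)
    valid = pn >= PROJECTION_TOL * np.linalg.norm(s_loc, axis=1)
    safe = np.where(pn < 1e-12, 1.0, pn)
    srl = np.degrees(np.arccos(np.clip(proj[:, 2] / safe, -1.0, 1.0)))

    return {
        "SIA": AngleSeries("SIA", sia, rate, "laboratory"),
        "SIL": AngleSeries("SIL", sil, rate, "local"),
        "SRA": AngleSeries("SRA", sra, rate, "laboratory"),
        "SRL": AngleSeries("SRL", srl, rate, "local", valid=valid),
    }


_SEGMENTS = {
    "S1L1": ("S1", "L1"),
    "S1L3": ("S1", "L3"),
    "L1T1": ("L1", "T1"),
    "L1T6": ("L1", "T6"),
    "T6T1": ("T6", "T1"),
}


def flexion_angles(t: MarkerTrajectorySet, frame: LocalFrame):
    """Spinal segment inclinations plus PELVIS / TRUNK / THORAX.

    Segment angles are unsigned angles of the caudal-to-cranial landmark
    vector against lab Y.  PELVIS projects S1->L1 onto the local
    sagittal plane (signed, anterior positive); TRUNK projects S1->T1
    onto the lab sagittal plane; THORAX is the signed angle between the
    local-sagittal projections of L1->T1 and S1->L1.
    """
    _require(t, ("S1", "L3", "L1", "T6", "T1"))
    rate = t.sample_rate
    out = {}
    for lbl, (lo, hi) in _SEGMENTS.items():
        v = t.positions[hi] - t.positions[lo]
        out[lbl] = AngleSeries(lbl, _line_axis_angle(v, [0.0, 1.0, 0.0]),
                               rate, "laboratory")

    lower = t.positions["L1"] - t.positions["S1"]
    trunk_v = t.positions["T1"] - t.positions["S1"]
    upper = t.positions["T1"] - t.positions["L1"]

    lo_loc = frame.express(lower)
    pelvis, p_ok = _planar_signed(lo_loc[:, 2], lo_loc[:, 1],
                                  np.linalg.norm(lo_loc, axis=1))
    out["PELVIS"] = AngleSeries("PELVIS", pelvis, rate, "local", valid=p_ok)

    trunk, t_ok = _planar_signed(trunk_v[:, 2], trunk_v[:, 1],
                                 np.linalg.norm(trunk_v, axis=1))
    out["TRUNK"] = AngleSeries("TRUNK", trunk, rate, "laboratory", valid=t_ok)

    up_loc = frame.express(upper)
    u2 = up_loc[:, [1, 2]]
    l2 = lo_loc[:, [1, 2]]
    un = np.linalg.norm(u2, axis=1)
    ln = np.linalg.norm(l2, axis=1)
    ok = (un >= PROJECTION_TOL * np.linalg.norm(up_loc, axis=1)) & (
        ln >= PROJECTION_TOL * np.linalg.norm(lo_loc, axis=1))
    cross = l2[:, 0] * u2[:, 1] - l2[:, 1] * u2[:, 0]
    dot = np.sum(l2 * u2, axis=1)
    thorax = np.degrees(np.arctan2(cross, dot))
    out["THORAX"] = AngleSeries("THORAX", thorax, rate, "local", valid=ok)
    return out


def compute_angles(t: MarkerTrajectorySet, labels=None, side: str = "right",
                   shoulder_frame: str = "local"):
    """Compute any subset of the measured angle set for one trial."""
    frame = build_local_frame(t)
    labels = set(ANGLE_LABELS if labels is None else labels)
    out = {}
    if labels & {"SF", "SA", "SE"}:
        out.update({k: v for k, v in
                    shoulder_angles(t, frame, side, shoulder_frame).items()
                    if k in labels})
    if labels & {"SIA", "SIL", "SRA", "SRL"}:
        out.update({k: v for k, v in spine_line_angles(t, frame).items()
                    if k in labels})
    if labels & (set(_SEGMENTS) | {"PELVIS", "TRUNK", "THORAX"}):
        out.update({k: v for k, v in flexion_angles(t, frame).items()
                    if k in labels})
    return out


def primary_angle(t: MarkerTrajectorySet, task: str,
                  side: str = "right") -> AngleSeries:
    """The angle series on which repetitions of ``task`` are segmented."""
    label = PRIMARY_ANGLE_BY_TASK[task]
    use_side = side if side in ("left", "right") else "right"
    return compute_angles(t, labels=[label], side=use_side)[label]
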