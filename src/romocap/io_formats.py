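"""Marker-trajectory and cohort-table I/O.

Laboratory frame convention: right-handed, Y vertical (up), Z anterior,
X from the subject's left to right.  All coordinates are millimetres;
all angles downstream are degrees.

Supported trajectory formats:

* **C3D** — 3D point data only, Intel (little-endian) processor type,
  integer or floating-point storage.  The reader/writer here implements
  the common subset of the public C3D specification needed for marker
  trajectories (POINT group with LABELS/RATE/SCALE/UNITS); analog
  channels, force plates and event data are ignored.
* **TRC** — the Motion Analysis tab-separated dialect used by most
  mocap toolchains (two header lines of metadata, marker-name row,
  X/Y/Z column row, blank line, then ``Frame# Time X1 Y1 Z1 ...``).
* **Wide CSV** — one row per sample, a ``time`` column in seconds plus
  ``<MARKER>_X/_Y/_Z`` columns in mm.  Empty cells are gaps.

Cohort result tables are long-format UTF-8 CSV with "." decimal
separator and columns (participant, group, session, task, parameter,
value) plus optional key columns (side, set, repetition).
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, SchemaError

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

GROUPS = ("WG", "CG")
SESSIONS = ("PRE", "ACUTE", "POST")
#: Sessions recorded per group: the treated group has an extra time point
#: immediately after the first treatment session.
SESSIONS_BY_GROUP = {"WG": ("PRE", "ACUTE", "POST"), "CG": ("PRE", "POST")}

TASKS = (
    "anterior_flexion",
    "lateral_bending",
    "twist",
    "frontal_rise",
    "lateral_rise",
    "backward_push",
)
#: Tasks executed once (no left/right side).
UNILATERAL_TASKS = ("anterior_flexion",)
SIDES = ("left", "right", "none")

#: Canonical marker labels: acromia, elbows, pelvis landmarks and the
#: spinous-process chain from sacrum to upper thorax.
CANONICAL_MARKERS = (
    "RACR", "LACR", "RELB", "LELB",
    "RASIS", "LASIS", "RPSIS", "LPSIS",
    "S1", "L3", "L1", "T6", "T1",
)

#: Markers each task's angle set cannot be computed without.  The pelvis
#: cluster is always needed for the local frame (one PSIS suffices, see
#: MarkerSchema.required_markers).
_PELVIS = ("RASIS", "LASIS")
_SPINE = ("S1", "L3", "L1", "T6", "T1")
REQUIRED_BY_TASK = {
    "anterior_flexion": _PELVIS + _SPINE,
    "lateral_bending": _PELVIS + ("LACR", "RACR"),
    "twist": _PELVIS + ("LACR", "RACR"),
    "frontal_rise": _PELVIS + ("RACR", "RELB", "LACR", "LELB"),
    "lateral_rise": _PELVIS + ("RACR", "RELB", "LACR", "LELB"),
    "backward_push": _PELVIS + ("RACR", "RELB", "LACR", "LELB"),
}


@dataclass(frozen=True)
class MarkerSchema:
    """Canonical marker vocabulary plus vendor-label aliases.

    ``aliases`` maps vendor labels (e.g. ``"R.Acromion"``) onto canonical
    labels; the map must be injective (two vendor labels may not claim the
    same canonical marker).  Markers outside the canonical set are read
    but ignored downstream.
    """

    names: tuple[str, ...] = CANONICAL_MARKERS
    required_by_task: dict = field(default_factory=lambda: dict(REQUIRED_BY_TASK))
    aliases: dict = field(default_factory=dict)

    def __post_init__(self):
        targets = list(self.aliases.values())
        if len(targets) != len(set(targets)):
            raise SchemaError("alias map is not injective onto canonical labels")
        for tgt in targets:
            if tgt not in self.names:
                raise SchemaError(f"alias target {tgt!r} is not a canonical label")

    def canonicalize(self, label: str) -> str:
        return self.aliases.get(label, label)

    def required_markers(self, task: str) -> tuple[str, ...]:
        """Markers without which ``task`` cannot be analysed.

        Either PSIS marker satisfies the pelvic-plane requirement, so
        PSIS presence is checked separately by the kinematics layer.
        """
        if task not in self.required_by_task:
            raise SchemaError(f"unknown task {task!r}")
        return tuple(self.required_by_task[task])

    def check_required(self, present: set, task: str) -> None:
        missing = [m for m in self.required_markers(task) if m not in present]
        if not any(p in present for p in ("RPSIS", "LPSIS")):
            missing.append("RPSIS|LPSIS")
        if missing:
            raise SchemaError(
                f"task {task!r} requires missing marker(s): {', '.join(missing)}"
            )


@dataclass
class MarkerTrajectorySet:
    """Time-indexed 3D marker positions (mm, laboratory frame) for one trial.

    ``positions[label]`` is an ``(n_samples, 3)`` float array;
    ``gap_mask[label]`` is an ``(n_samples,)`` boolean array, True where
    the marker was not reconstructed (coordinates there are meaningless).
    """

    positions: dict
    sample_rate: float
    gap_mask: dict = None
    #: skip invariants for internally constructed, already-checked data
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.gap_mask is None:
            self.gap_mask = {
                m: np.zeros(len(p), dtype=bool) for m, p in self.positions.items()
            }
        if not self.validate:
            return
        n = {len(p) for p in self.positions.values()}
        n |= {len(g) for g in self.gap_mask.values()}
        if len(n) > 1:
            raise ValueError("all markers must share n_samples")
        for m, p in self.positions.items():
            valid = ~self.gap_mask[m]
            if not np.all(np.isfinite(np.asarray(p)[valid])):
                raise ValueError(f"non-finite coordinates outside gaps for {m!r}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.positions.values())))

    @property
    def markers(self) -> tuple:
        return tuple(self.positions)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            positions={m: p.copy() for m, p in self.positions.items()},
            sample_rate=self.sample_rate,
            gap_mask={m: g.copy() for m, g in self.gap_mask.items()},
            validate=False,
        )

    def has_gaps(self, markers=None) -> bool:
        markers = self.markers if markers is None else markers
        return any(self.gap_mask[m].any() for m in markers)


@dataclass(frozen=True)
class TrialMetadata:
    """Identity of one recorded set: who, when, which task, which side."""

    participant_id: str
    group: str
    session: str
    task: str
    side: str = "none"
    set_index: int = 1

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.session not in SESSIONS_BY_GROUP[self.group]:
            raise ValueError(
                f"session {self.session!r} not recorded for group {self.group}"
            )
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.task in UNILATERAL_TASKS:
            if self.side != "none":
                raise ValueError(f"{self.task} is unilateral; side must be 'none'")
        elif self.side not in ("left", "right"):
            raise ValueError(f"{self.task} is bilateral; side must be left/right")
        if self.set_index not in (1, 2):
            raise ValueError("set_index must be 1 or 2")


# ---------------------------------------------------------------------------
# TRC (Motion Analysis dialect)
# ---------------------------------------------------------------------------

def write_trc(t: MarkerTrajectorySet, path) -> None:
    """Write the trial as a Motion Analysis TRC file (mm, tab-separated)."""
    markers = t.markers
    n = t.n_samples
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(
            f"{t.sample_rate:g}\t{t.sample_rate:g}\t{n}\t{len(markers)}\tmm\t"
            f"{t.sample_rate:g}\t1\t{n}\n"
        )
        fh.write("Frame#\tTime\t" + "\t\t\t".join(markers) + "\t\t\n")
        cols = [f"{ax}{i}" for i in range(1, len(markers) + 1) for ax in "XYZ"]
        fh.write("\t\t" + "\t".join(cols) + "\n\n")
        for i in range(n):
            row = [str(i + 1), f"{i / t.sample_rate:.5f}"]
            for m in markers:
                if t.gap_mask[m][i]:
                    row += ["", "", ""]
                else:
                    row += [f"{v:.6f}" for v in t.positions[m][i]]
            fh.write("\t".join(row) + "\n")


def read_trc(path, schema: MarkerSchema | None = None,
             task: str | None = None) -> MarkerTrajectorySet:
    """Read a TRC file; empty coordinate cells become gaps."""
    schema = schema or MarkerSchema()
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{path}: not a TRC file")
    meta = lines[2].split("\t")
    try:
        rate = float(meta[0])
        n_markers = int(meta[3])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed TRC metadata line") from exc
    raw_labels = [x for x in lines[3].split("\t")[2:] if x]
    if len(raw_labels) != n_markers:
        raise FormatError(f"{path}: marker count mismatch in header")
    labels = [schema.canonicalize(x) for x in raw_labels]
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    n = len(data_lines)
    pos = {m: np.full((n, 3), np.nan) for m in labels}
    mask = {m: np.zeros(n, dtype=bool) for m in labels}
    for i, ln in enumerate(data_lines):
        cells = ln.split("\t")
        for j, m in enumerate(labels):
            triple = cells[2 + 3 * j: 5 + 3 * j]
            if len(triple) < 3 or any(c.strip() == "" for c in triple):
                mask[m][i] = True
            else:
                pos[m][i] = [float(c) for c in triple]
    for m in labels:
        pos[m][mask[m]] = 0.0
    out = MarkerTrajectorySet(positions=pos, sample_rate=rate, gap_mask=mask)
    if task is not None:
        schema.check_required(set(out.markers), task)
    return out


# ---------------------------------------------------------------------------
# Wide CSV dialect
# ---------------------------------------------------------------------------

def write_csv(t: MarkerTrajectorySet, path) -> None:
    """Write the trial as wide CSV: time + <MARKER>_X/_Y/_Z columns (mm)."""
    n = t.n_samples
    data = {"time": np.arange(n) / t.sample_rate}
    for m in t.markers:
        for k, ax in enumerate("XYZ"):
            col = t.positions[m][:, k].astype(float).copy()
            col[t.gap_mask[m]] = np.nan
            data[f"{m}_{ax}"] = col
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_csv(path, schema: MarkerSchema | None = None,
             task: str | None = None) -> MarkerTrajectorySet:
    """Read the wide-CSV dialect; empty cells become gaps.

    The sample rate is derived from the ``time`` column, which must be
    strictly increasing and regular to within 1e-6 s.
    """
    schema = schema or MarkerSchema()
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unreadable CSV") from exc
    if "time" not in df.columns:
        raise FormatError(f"{path}: missing 'time' column")
    tcol = df["time"].to_numpy(dtype=float)
    dt = np.diff(tcol)
    if len(dt) == 0 or np.any(dt <= 0):
        raise FormatError(f"{path}: time column not strictly increasing")
    if np.max(np.abs(dt - dt[0])) > 1e-6:
        raise FormatError(f"{path}: irregular sampling in time column")
    rate = 1.0 / dt[0]

    triplets: dict[str, list] = {}
    for col in df.columns:
        if col == "time":
            continue
        if not (len(col) > 2 and col[-2] == "_" and col[-1] in "XYZ"):
            raise FormatError(f"{path}: unexpected column {col!r}")
        triplets.setdefault(col[:-2], []).append(col)
    n = len(df)
    pos, mask = {}, {}
    for raw, cols in triplets.items():
        if len(cols) != 3:
            raise FormatError(f"{path}: marker {raw!r} lacks X/Y/Z triplet")
        m = schema.canonicalize(raw)
        arr = df[[f"{raw}_{ax}" for ax in "XYZ"]].to_numpy(dtype=float)
        g = np.isnan(arr).any(axis=1)
        arr[g] = 0.0
        pos[m], mask[m] = arr, g
    out = MarkerTrajectorySet(positions=pos, sample_rate=rate, gap_mask=mask)
    if task is not None:
        schema.check_required(set(out.markers), task)
    return out


# ---------------------------------------------------------------------------
# C3D (minimal Intel subset)
# ---------------------------------------------------------------------------

_INTEL = 84  # C3D processor-type code for IEEE little-endian


def _param_bytes(name: str, group_id: int, dtype: int, dims: list,
                 payload: bytes) -> bytes:
    """Serialize one parameter record (unlocked, empty description)."""
    buf = struct.pack("bb", len(name), group_id) + name.encode("ascii")
    body = struct.pack("b", dtype) + struct.pack("B", len(dims))
    body += bytes(dims) + payload + b"\x00"  # desc length 0
    buf += struct.pack("<h", 2 + len(body)) + body
    return buf


def write_c3d(t: MarkerTrajectorySet, path) -> None:
    """Write 3D point data as a little-endian floating-point C3D file.

    Residuals are 0.0 for valid samples and -1.0 under gaps (the C3D
    convention for invalid points).
    """
    markers = t.markers
    npts, n = len(markers), t.n_samples
    if n > 65535:
        raise FormatError("C3D writer supports at most 65535 frames")

    # --- parameter section (group POINT) ---
    p = io.BytesIO()
    p.write(struct.pack("bb", 5, -1) + b"POINT" + struct.pack("<h", 3) + b"\x00")
    p.write(_param_bytes("USED", 1, 2, [], struct.pack("<h", npts)))
    p.write(_param_bytes("FRAMES", 1, 2, [], struct.pack("<H", n)))
    p.write(_param_bytes("RATE", 1, 4, [], struct.pack("<f", t.sample_rate)))
    p.write(_param_bytes("SCALE", 1, 4, [], struct.pack("<f", -1.0)))
    p.write(_param_bytes("UNITS", 1, -1, [2], b"mm"))
    width = max(len(m) for m in markers)
    lab = b"".join(m.ljust(width).encode("ascii") for m in markers)
    p.write(_param_bytes("LABELS", 1, -1, [width, npts], lab))
    p.write(b"\x00\x00")  # terminating record: name length 0, offset 0
    pbytes = p.getvalue()
    n_param_blocks = -(-len(pbytes) // 512)
    data_start = 2 + n_param_blocks  # 1-based block index

    header = bytearray(512)
    struct.pack_into("<BB", header, 0, 2, 0x50)
    struct.pack_into("<HHHHH", header, 2, npts, 0, 1, n, 0)
    struct.pack_into("<f", header, 12, -1.0)
    struct.pack_into("<HH", header, 16, data_start, 0)
    struct.pack_into("<f", header, 20, t.sample_rate)

    pblock = bytearray(512 * n_param_blocks)
    struct.pack_into("<BBBB", pblock, 0, 1, 0x50, n_param_blocks, _INTEL)
    pblock[4:4 + len(pbytes)] = pbytes

    frames = np.zeros((n, npts, 4), dtype="<f4")
    for j, m in enumerate(markers):
        frames[:, j, :3] = t.positions[m]
        frames[t.gap_mask[m], j, :3] = 0.0
        frames[:, j, 3] = np.where(t.gap_mask[m], -1.0, 0.0)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(bytes(pblock))
        fh.write(frames.tobytes())


def _parse_c3d_params(raw: bytes):
    """Walk the parameter section, returning {(group, param): value}."""
    if len(raw) < 4:
        raise FormatError("C3D parameter section truncated")
    if raw[3] != _INTEL:
        raise FormatError(
            f"unsupported C3D processor type {raw[3]} (only Intel/84)"
        )
    groups: dict[int, str] = {}
    params: dict[tuple, object] = {}
    pos = 4
    while pos + 2 <= len(raw):
        nname = struct.unpack_from("b", raw, pos)[0]
        gid = struct.unpack_from("b", raw, pos + 1)[0]
        if nname == 0:
            break
        nchar = abs(nname)
        name = raw[pos + 2: pos + 2 + nchar].decode("ascii", "replace")
        opos = pos + 2 + nchar
        offset = struct.unpack_from("<h", raw, opos)[0]
        nxt = opos + offset if offset != 0 else len(raw)
        if gid < 0:
            groups[-gid] = name
        else:
            dpos = opos + 2
            dtype = struct.unpack_from("b", raw, dpos)[0]
            ndims = raw[dpos + 1]
            dims = list(raw[dpos + 2: dpos + 2 + ndims])
            dpos += 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            size = {-1: 1, 1: 1, 2: 2, 4: 4}.get(dtype)
            if size is None:
                raise FormatError(f"bad C3D parameter type {dtype}")
            blob = raw[dpos: dpos + count * size]
            if dtype == -1:
                val = (blob, dims)
            elif dtype == 1:
                val = np.frombuffer(blob, dtype=np.int8)
            elif dtype == 2:
                val = np.frombuffer(blob, dtype="<i2")
            else:
                val = np.frombuffer(blob, dtype="<f4")
            params[(gid, name.upper())] = val
        if nxt <= pos:
            break
        pos = nxt
    named = {}
    for (gid, name), val in params.items():
        named[(groups.get(gid, str(gid)).upper(), name)] = val
    return named


def read_c3d(path, schema: MarkerSchema | None = None,
             task: str | None = None) -> MarkerTrajectorySet:
    """Read 3D point trajectories from a C3D file (Intel subset).

    Gap mask is True where the stored residual is negative.  Integer
    storage is de-scaled by POINT:SCALE; units other than mm are
    converted to mm when POINT:UNITS declares m or cm.
    """
    schema = schema or MarkerSchema()
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 512 or blob[1] != 0x50:
        raise FormatError(f"{path}: not a C3D file")
    param_block = blob[0]
    npts, nanalog, first, last = struct.unpack_from("<HHHH", blob, 2)
    scale = struct.unpack_from("<f", blob, 12)[0]
    data_start, analog_per = struct.unpack_from("<HH", blob, 16)
    rate = struct.unpack_from("<f", blob, 20)[0]
    n = last - first + 1

    params = _parse_c3d_params(blob[(param_block - 1) * 512:])
    prate = params.get(("POINT", "RATE"))
    if prate is not None and len(prate):
        rate = float(prate[0])
    pscale = params.get(("POINT", "SCALE"))
    if pscale is not None and len(pscale):
        scale = float(pscale[0])
    unit_scale = 1.0
    units = params.get(("POINT", "UNITS"))
    if units is not None:
        ustr = units[0].decode("ascii", "replace").strip().lower()
        unit_scale = {"m": 1000.0, "cm": 10.0}.get(ustr, 1.0)
    labels_raw = params.get(("POINT", "LABELS"))
    if labels_raw is None:
        raise FormatError(f"{path}: POINT:LABELS missing")
    lblob, dims = labels_raw
    width = dims[0] if dims else len(lblob)
    raw_labels = [
        lblob[i * width:(i + 1) * width].decode("ascii", "replace").strip()
        for i in range(npts)
    ]
    labels = [schema.canonicalize(x) for x in raw_labels]

    off = (data_start - 1) * 512
    if scale < 0:
        frame_words = npts * 4 + nanalog
        need = off + n * frame_words * 4
        if len(blob) < need:
            raise FormatError(f"{path}: truncated point data")
        arr = np.frombuffer(blob, dtype="<f4", count=n * frame_words, offset=off)
        arr = arr.reshape(n, frame_words)[:, : npts * 4].reshape(n, npts, 4)
        xyz = arr[:, :, :3].astype(float)
        resid = arr[:, :, 3].astype(float)
    else:
        frame_words = npts * 4 + nanalog
        need = off + n * frame_words * 2
        if len(blob) < need:
            raise FormatError(f"{path}: truncated point data")
        arr = np.frombuffer(blob, dtype="<i2", count=n * frame_words, offset=off)
        arr = arr.reshape(n, frame_words)[:, : npts * 4].reshape(n, npts, 4)
        xyz = arr[:, :, :3].astype(float) * scale
        resid = arr[:, :, 3].astype(float)

    pos, mask = {}, {}
    for j, m in enumerate(labels):
        g = resid[:, j] < 0
        coords = xyz[:, j, :] * unit_scale
        coords[g] = 0.0
        pos[m], mask[m] = coords, g
    out = MarkerTrajectorySet(positions=pos, sample_rate=float(rate), gap_mask=mask)
    if task is not None:
        schema.check_required(set(out.markers), task)
    return out


def read_trajectories(path, schema: MarkerSchema | None = None,
                      task: str | None = None) -> MarkerTrajectorySet:
    """Dispatch on file extension: .c3d, .trc or .csv."""
    p = str(path).lower()
    if p.endswith(".c3d"):
        return read_c3d(path, schema, task)
    if p.endswith(".trc"):
        return read_trc(path, schema, task)
    if p.endswith(".csv"):
        return read_csv(path, schema, task)
    raise FormatError(f"unrecognised trajectory format: {path}")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ("participant", "group", "session", "task", "parameter", "value")
_OPTIONAL_KEYS = ("side", "set", "repetition")


def _key_columns(df: pd.DataFrame):
    return [c for c in df.columns if c != "value"]


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check column contract and key uniqueness of a long-format table."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"cohort table missing column(s): {missing}")
    extra = [c for c in df.columns
             if c not in COHORT_COLUMNS and c not in _OPTIONAL_KEYS]
    if extra:
        raise IntegrityError(f"cohort table has unknown column(s): {extra}")
    dup = df.duplicated(subset=_key_columns(df))
    if dup.any():
        rows = df.loc[dup, _key_columns(df)].iloc[0].to_dict()
        raise IntegrityError(f"duplicate cohort rows, e.g. {rows}")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    if len(df) == 0:
        raise IntegrityError("refusing to write an empty cohort table")
    validate_cohort_table(df)
    df.to_csv(path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str})
    return validate_cohort_table(df)
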