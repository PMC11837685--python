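"""Raw-device representations to COP / COM sway trajectories.

The center of pressure (COP) comes from a four-sensor balance board by
moment balance over the corner loads; the whole-body center of mass (COM)
comes from 25-joint skeleton tracking via an anthropometric segment table
(mass fractions and segment-center positions).  Both yield
:class:`SwayTrial` objects with explicit anterior-posterior (a-p) and
medio-lateral (m-l) displacement channels.

Axis conventions (fixed here; devices do not state them): m-l positive to
the subject's right, a-p positive forward.  Skeleton axes are
(m-l, vertical, a-p).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "KINECT_JOINTS",
    "ForcePlateRecord",
    "SkeletonSequence",
    "Segment",
    "SegmentModel",
    "SwayTrial",
    "compute_cop",
    "compute_com",
    "discard_invalid_trials",
    "read_board_csv",
    "read_skeleton_csv",
]

#: The 25 joints tracked by the Kinect v2 skeleton algorithm.
KINECT_JOINTS = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)


def _check_monotone(t):
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("time axis must be a nonempty 1-D array")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    return t


@dataclass
class ForcePlateRecord:
    """Four corner loads (N) over time, ordered top-left, top-right,
    bottom-left, bottom-right, plus the sensor rectangle (m)."""

    t: np.ndarray
    loads: np.ndarray
    board_width: float
    board_depth: float

    def __post_init__(self):
        self.t = _check_monotone(self.t)
        self.loads = np.asarray(self.loads, dtype=float)
        if self.loads.shape != (len(self.t), 4):
            raise ValueError("loads must have shape (n_samples, 4)")
        if np.any(self.loads < 0):
            raise ValueError("corner loads must be nonnegative")


@dataclass
class SkeletonSequence:
    """25 named 3-D joint positions per frame, axes (m-l, vertical, a-p)."""

    t: np.ndarray
    joints: np.ndarray
    joint_names: tuple = KINECT_JOINTS

    def __post_init__(self):
        self.t = _check_monotone(self.t)
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.shape != (len(self.t), len(self.joint_names), 3):
            raise ValueError(
                f"joints must have shape (n_frames, {len(self.joint_names)}, 3)"
            )


@dataclass(frozen=True)
class Segment:
    name: str
    proximal: str
    distal: str
    mass_fraction: float
    com_fraction: float


@dataclass(frozen=True)
class SegmentModel:
    """Anthropometric table: per body segment, its delimiting joints, mass
    fraction and center position along the proximal->distal axis."""

    segments: tuple

    def __post_init__(self):
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment mass fractions sum to {total}, not 1")
        for s in self.segments:
            if not 0.0 <= s.com_fraction <= 1.0:
                raise ValueError(f"com_fraction of {s.name} outside [0, 1]")

    @classmethod
    def from_mapping(cls, mapping) -> "SegmentModel":
        return cls(tuple(Segment(**row) for row in mapping["segments"]))

    @classmethod
    def from_yaml(cls, path) -> "SegmentModel":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "SegmentModel":
        """The bundled Winter-style 11-segment table."""
        ref = importlib.resources.files("swayclass.data") / "segment_model.yaml"
        return cls.from_mapping(yaml.safe_load(ref.read_text()))


@dataclass
class SwayTrial:
    """One trial of one postural parameter (COP or COM) for one subject."""

    subject_id: str
    group_label: str
    trial_index: int
    parameter: str
    t: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.t = _check_monotone(self.t)
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        if not len(self.t) == len(self.ap) == len(self.ml):
            raise ValueError("t, ap, ml must have equal length")
        if self.parameter not in ("COP", "COM"):
            raise ValueError("parameter must be 'COP' or 'COM'")
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def channel(self, direction: str) -> np.ndarray:
        if direction not in ("ap", "ml"):
            raise ValueError("direction must be 'ap' or 'ml'")
        return getattr(self, direction)

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean())


def compute_cop(record: ForcePlateRecord, subject_id="", group_label="",
                trial_index=0) -> SwayTrial:
    """COP trajectory by moment balance over the four corner loads.

    ml = (W/2) * [(F_TR + F_BR) - (F_TL + F_BL)] / sum(F)
    ap = (D/2) * [(F_TL + F_TR) - (F_BL + F_BR)] / sum(F)
    """
    f = record.loads
    total = f.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("no contact: zero total load at some sample")
    ml = (record.board_width / 2.0) * ((f[:, 1] + f[:, 3]) - (f[:, 0] + f[:, 2])) / total
    ap = (record.board_depth / 2.0) * ((f[:, 0] + f[:, 1]) - (f[:, 2] + f[:, 3])) / total
    return SwayTrial(subject_id=subject_id, group_label=group_label,
                     trial_index=trial_index, parameter="COP",
                     t=record.t, ap=ap, ml=ml)


def _interp_short_gaps(t, x, max_gap):
    """Linearly fill NaN runs no longer than ``max_gap`` seconds; longer
    runs (and unbounded edge runs) stay NaN.  Returns (filled, was_filled)."""
    x = x.copy()
    isnan = ~np.isfinite(x)
    if not isnan.any():
        return x, np.zeros_like(isnan)
    filled = np.zeros_like(isnan)
    n = len(x)
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        interior = i > 0 and j < n
        if interior and (t[j] - t[i - 1]) <= max_gap:
            x[i:j] = np.interp(t[i:j], [t[i - 1], t[j]], [x[i - 1], x[j]])
            filled[i:j] = True
        i = j
    return x, filled


def compute_com(seq: SkeletonSequence, model: SegmentModel = None,
                max_gap: float = 0.5, subject_id="", group_label="",
                trial_index=0) -> SwayTrial:
    """Whole-body COM from segment centers and anthropometric mass fractions.

    Per frame each segment's center is interpolated between its proximal
    and distal joints; the COM is the mass-fraction-weighted sum.  Tracking
    gaps shorter than ``max_gap`` seconds are linearly interpolated per
    joint coordinate; frames still containing non-finite joints used by the
    model are flagged invalid (``valid``) for the trial-discard logic.
    """
    model = model or SegmentModel.default()
    index = {name: i for i, name in enumerate(seq.joint_names)}
    used = set()
    for seg in model.segments:
        for joint in (seg.proximal, seg.distal):
            if joint not in index:
                raise ValueError(f"missing joint '{joint}' in skeleton sequence")
            used.add(joint)
    joints = seq.joints.copy()
    for joint in used:
        j = index[joint]
        for axis in range(3):
            joints[:, j, axis], _ = _interp_short_gaps(
                seq.t, joints[:, j, axis], max_gap
            )
    com = np.zeros((len(seq.t), 3))
    for seg in model.segments:
        prox = joints[:, index[seg.proximal], :]
        dist = joints[:, index[seg.distal], :]
        com += seg.mass_fraction * (prox + seg.com_fraction * (dist - prox))
    valid = np.isfinite(com).all(axis=1)
    return SwayTrial(subject_id=subject_id, group_label=group_label,
                     trial_index=trial_index, parameter="COM",
                     t=seq.t, ap=com[:, 2], ml=com[:, 0], valid=valid)


def discard_invalid_trials(trials, min_valid_fraction=0.9):
    """Drop trials whose fraction of valid frames falls below the threshold.

    Returns (surviving trials, discard log); the log records subject,
    trial, parameter and the offending valid fraction.
    """
    kept, log = [], []
    for trial in trials:
        frac = trial.valid_fraction
        if frac < min_valid_fraction:
            log.append({
                "subject_id": trial.subject_id,
                "trial_index": trial.trial_index,
                "parameter": trial.parameter,
                "valid_fraction": frac,
                "reason": f"valid fraction {frac:.3f} < {min_valid_fraction}",
            })
        else:
            kept.append(trial)
    return kept, log


def read_board_csv(path, board_width=0.433, board_depth=0.238) -> ForcePlateRecord:
    """Board-load CSV with columns t, f_tl, f_tr, f_bl, f_br (N)."""
    df = pd.read_csv(path)
    cols = ["f_tl", "f_tr", "f_bl", "f_br"]
    missing = [c for c in ["t"] + cols if c not in df.columns]
    if missing:
        raise ValueError(f"board CSV missing columns: {missing}")
    return ForcePlateRecord(
        t=df["t"].to_numpy(), loads=df[cols].to_numpy(),
        board_width=board_width, board_depth=board_depth,
    )


def read_skeleton_csv(path) -> SkeletonSequence:
    """Skeleton CSV with columns t plus ``<Joint>_<x|y|z>`` for each of the
    25 joints, axes (x=m-l, y=vertical, z=a-p), metres."""
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValueError("skeleton CSV missing column 't'")
    n = len(df)
    joints = np.empty((n, len(KINECT_JOINTS), 3))
    for j, name in enumerate(KINECT_JOINTS):
        for a, axis in enumerate("xyz"):
            col = f"{name}_{axis}"
            if col not in df.columns:
                raise ValueError(f"skeleton CSV missing column '{col}'")
            joints[:, j, a] = df[col].to_numpy()
    return SkeletonSequence(t=df["t"].to_numpy(), joints=joints)
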