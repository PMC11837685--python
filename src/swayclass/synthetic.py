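"""Synthetic two-group quiet-stance sway cohorts.

Generates cohorts with the statistical structure the classification
analysis assumes: a 1/f^alpha colored-noise sway baseline, a
class-discriminative excess of band power above ~1 Hz in the PD-like
group, per-subject random effects, stochastic trial dropout, and both
raw-device representations (four-corner balance-board loads, 25-joint
skeleton trajectories) that invert exactly under the forward kinematics
in :mod:`swayclass.kinematics`.

The generator is the package's study-condition stand-in for recorded
cohorts: two groups, 10 trials x 30 s per subject, and dropout rates of
10 % (PD-like) and 3 % (HC-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import (
    KINECT_JOINTS,
    ForcePlateRecord,
    SegmentModel,
    SkeletonSequence,
    SwayTrial,
)

__all__ = [
    "ClassSpec",
    "CohortSpec",
    "BoardGeometry",
    "TrialData",
    "SubjectData",
    "Cohort",
    "gen_sway_trajectory",
    "gen_board_loads",
    "gen_skeleton",
    "gen_cohort",
    "canonical_pose",
]


@dataclass(frozen=True)
class ClassSpec:
    """Spectral description of one group's sway.

    The baseline is colored noise with power spectral density proportional
    to ``1/f**baseline_slope``; inside ``[band_lo, band_hi]`` Hz the PSD is
    multiplied by ``band_gain``.  ``rms_amplitude`` is the per-channel RMS
    displacement (m) of the gain-free baseline.
    """

    group_label: str
    baseline_slope: float = 1.5
    band_lo: float = 1.0
    band_hi: float = 10.0
    band_gain: float = 1.0
    trial_dropout_prob: float = 0.0
    rms_amplitude: float = 0.005
    subject_gain_sigma: float = 0.15

    def __post_init__(self):
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("require 0 < band_lo < band_hi")
        if self.band_gain < 0:
            raise ValueError("band_gain must be >= 0")
        if not 0 <= self.trial_dropout_prob < 1:
            raise ValueError("trial_dropout_prob must be in [0, 1)")

    @classmethod
    def pd_default(cls, band_gain: float = 4.0) -> "ClassSpec":
        return cls("PD", band_gain=band_gain, trial_dropout_prob=0.10)

    @classmethod
    def hc_default(cls) -> "ClassSpec":
        return cls("HC", band_gain=1.0, trial_dropout_prob=0.03)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: group sizes, trials per subject, device rates."""

    n_pd: int = 18
    n_hc: int = 15
    trials_per_subject: int = 10
    trial_duration: float = 30.0
    native_rate_board: float = 100.0
    native_rate_skeleton: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pd, self.n_hc, self.trials_per_subject) < 1:
            raise ValueError("counts must be >= 1")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be > 0")


@dataclass(frozen=True)
class BoardGeometry:
    """Sensor rectangle of the balance board (m); defaults follow the
    footprint of the consumer board used for COP posturography."""

    width: float = 0.433
    depth: float = 0.238


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_sway_trajectory(class_spec, duration, rate, seed, subject_gain=1.0):
    """Two-channel (a-p, m-l) colored-noise sway trajectory.

    Synthesised in the frequency domain: independent complex-Gaussian
    Fourier coefficients shaped to a ``1/f**alpha`` PSD, multiplied by
    ``sqrt(band_gain * subject_gain)`` inside the class band, and inverse
    transformed.  The amplitude scale is fixed by the gain-free baseline,
    so the expected in-band PSD ratio between two specs equals the ratio
    of their effective band gains.

    Returns an ``(n, 2)`` array with columns (a-p, m-l) in metres.
    """
    if rate <= 2 * class_spec.band_hi:
        raise ValueError(
            f"sampling rate {rate} Hz violates the Nyquist bound for "
            f"band_hi={class_spec.band_hi} Hz (need rate > {2 * class_spec.band_hi} Hz)"
        )
    rng = _as_rng(seed)
    n = int(round(duration * rate))
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-class_spec.baseline_slope / 2.0)
    if n % 2 == 0:
        shape[-1] = 0.0  # drop the Nyquist bin; keeps the synthesis exact
    # scale so the gain-free baseline has per-sample variance rms^2
    base_var = 2.0 * np.sum(shape**2) / n**2
    amp = class_spec.rms_amplitude / np.sqrt(base_var)
    gain = np.ones_like(freqs)
    in_band = (freqs >= class_spec.band_lo) & (freqs <= class_spec.band_hi)
    gain[in_band] = np.sqrt(class_spec.band_gain * subject_gain)
    out = np.empty((n, 2))
    for ch in range(2):
        z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
        out[:, ch] = np.fft.irfft(amp * shape * gain * z / np.sqrt(2.0), n=n)
    return out


def gen_board_loads(trajectory, geometry=None, total_weight=700.0, seed=None,
                    rate=100.0, twist_noise=1.0):
    """Four corner-load time series whose COP equals ``trajectory``.

    The total weight is distributed bilinearly over the corners (ordered
    top-left, top-right, bottom-left, bottom-right); a seeded "twist"
    perturbation — the one load pattern with zero net force and zero
    moments — adds sensor-like noise without moving the COP.
    """
    geometry = geometry or BoardGeometry()
    ap = np.asarray(trajectory)[:, 0]
    ml = np.asarray(trajectory)[:, 1]
    u = ml / (geometry.width / 2.0)
    v = ap / (geometry.depth / 2.0)
    if np.max(np.abs(u)) >= 1.0 or np.max(np.abs(v)) >= 1.0:
        raise ValueError(
            "COP outside the sensor rectangle: no nonnegative corner loads "
            "can realize it"
        )
    q = total_weight / 4.0
    loads = np.stack(
        [
            q * (1 - u) * (1 + v),  # top-left
            q * (1 + u) * (1 + v),  # top-right
            q * (1 - u) * (1 - v),  # bottom-left
            q * (1 + u) * (1 - v),  # bottom-right
        ],
        axis=1,
    )
    if twist_noise > 0 and seed is not None:
        rng = _as_rng(seed)
        eta = rng.normal(0.0, twist_noise, size=len(ap))
        # pattern (+1, -1, -1, +1): clip so all loads stay nonnegative
        eta = np.clip(eta, -np.minimum(loads[:, 0], loads[:, 3]),
                      np.minimum(loads[:, 1], loads[:, 2]))
        loads += eta[:, None] * np.array([1.0, -1.0, -1.0, 1.0])
    t = np.arange(len(ap)) / rate
    return ForcePlateRecord(
        t=t, loads=loads, board_width=geometry.width, board_depth=geometry.depth
    )


def canonical_pose() -> np.ndarray:
    """Canonical upright 25-joint pose, axes (m-l, vertical, a-p), metres.

    A schematic 1.75 m standing adult; only the vertical ordering and
    rough segment proportions matter for the synthetic inverse map.
    """
    y = {
        "SpineBase": 1.00, "SpineMid": 1.20, "Neck": 1.50, "Head": 1.65,
        "ShoulderLeft": 1.45, "ElbowLeft": 1.15, "WristLeft": 0.92,
        "HandLeft": 0.87, "ShoulderRight": 1.45, "ElbowRight": 1.15,
        "WristRight": 0.92, "HandRight": 0.87, "HipLeft": 0.95,
        "KneeLeft": 0.50, "AnkleLeft": 0.08, "FootLeft": 0.03,
        "HipRight": 0.95, "KneeRight": 0.50, "AnkleRight": 0.08,
        "FootRight": 0.03, "SpineShoulder": 1.42, "HandTipLeft": 0.80,
        "ThumbLeft": 0.84, "HandTipRight": 0.80, "ThumbRight": 0.84,
    }
    x = {
        "ShoulderLeft": -0.19, "ElbowLeft": -0.22, "WristLeft": -0.23,
        "HandLeft": -0.23, "HandTipLeft": -0.23, "ThumbLeft": -0.21,
        "ShoulderRight": 0.19, "ElbowRight": 0.22, "WristRight": 0.23,
        "HandRight": 0.23, "HandTipRight": 0.23, "ThumbRight": 0.21,
        "HipLeft": -0.09, "KneeLeft": -0.10, "AnkleLeft": -0.10,
        "FootLeft": -0.10, "HipRight": 0.09, "KneeRight": 0.10,
        "AnkleRight": 0.10, "FootRight": 0.10,
    }
    z = {"FootLeft": 0.12, "FootRight": 0.12}
    pose = np.zeros((len(KINECT_JOINTS), 3))
    for i, name in enumerate(KINECT_JOINTS):
        pose[i] = (x.get(name, 0.0), y[name], z.get(name, 0.0))
    return pose


def _com_height_scale(model: SegmentModel, pose: np.ndarray) -> float:
    """Mass-weighted mean height of the segment centers in the pose."""
    index = {name: i for i, name in enumerate(KINECT_JOINTS)}
    h = 0.0
    for seg in model.segments:
        yp = pose[index[seg.proximal], 1]
        yd = pose[index[seg.distal], 1]
        h += seg.mass_fraction * (yp + seg.com_fraction * (yd - yp))
    return h


def gen_skeleton(trajectory, segment_model=None, seed=None, rate=30.0,
                 jitter_std=0.001):
    """25-joint skeleton whose whole-body COM sways along ``trajectory``.

    Joints sway like an inverted pendulum pivoting at the floor — each
    joint's horizontal displacement is proportional to its height — with
    the proportionality normalised so the model-weighted COM reproduces
    the input trajectory exactly; small independent Gaussian jitter
    (``jitter_std`` m, default 1 mm) emulates marker noise.
    """
    segment_model = segment_model or SegmentModel.default()
    pose = canonical_pose()
    traj = np.asarray(trajectory)
    n = len(traj)
    h_com = _com_height_scale(segment_model, pose)
    factors = pose[:, 1] / h_com  # per-joint pendulum gain
    joints = np.broadcast_to(pose, (n, *pose.shape)).copy()
    joints[:, :, 0] += traj[:, 1][:, None] * factors  # m-l
    joints[:, :, 2] += traj[:, 0][:, None] * factors  # a-p
    if jitter_std > 0 and seed is not None:
        rng = _as_rng(seed)
        joints += rng.normal(0.0, jitter_std, size=joints.shape)
    t = np.arange(n) / rate
    return SkeletonSequence(t=t, joints=joints)


@dataclass
class TrialData:
    """One surviving trial of one subject: COP and COM sway trials plus the
    seed from which its raw representations regenerate deterministically."""

    trial_index: int
    cop: SwayTrial
    com: SwayTrial
    raw_seed: int


@dataclass
class SubjectData:
    subject_id: str
    group_label: str
    band_gain_multiplier: float
    trials: list = field(default_factory=list)


@dataclass
class Cohort:
    spec: CohortSpec
    pd_spec: ClassSpec
    hc_spec: ClassSpec
    subjects: list = field(default_factory=list)
    dropout_log: list = field(default_factory=list)

    def group(self, label):
        return [s for s in self.subjects if s.group_label == label]

    def trials(self, parameter="COP"):
        attr = parameter.lower()
        for subj in self.subjects:
            for trial in subj.trials:
                yield getattr(trial, attr)

    def raw_trial(self, subject_id, trial_index, segment_model=None):
        """Regenerate the raw board-load and skeleton representations of a
        stored trial (deterministic in the trial's seed)."""
        subj = next(s for s in self.subjects if s.subject_id == subject_id)
        trial = next(t for t in subj.trials if t.trial_index == trial_index)
        traj_cop = np.stack([trial.cop.ap, trial.cop.ml], axis=1)
        traj_com = np.stack([trial.com.ap, trial.com.ml], axis=1)
        board = gen_board_loads(
            traj_cop, seed=trial.raw_seed, rate=self.spec.native_rate_board
        )
        skeleton = gen_skeleton(
            traj_com, segment_model=segment_model, seed=trial.raw_seed + 1,
            rate=self.spec.native_rate_skeleton,
        )
        return board, skeleton


def _make_trial(subj_id, group, idx, class_spec, cohort_spec, gain_mult, rng):
    kw = dict(subject_id=subj_id, group_label=group, trial_index=idx)
    traj_cop = gen_sway_trajectory(
        class_spec, cohort_spec.trial_duration, cohort_spec.native_rate_board,
        rng, subject_gain=gain_mult,
    )
    traj_com = gen_sway_trajectory(
        class_spec, cohort_spec.trial_duration, cohort_spec.native_rate_skeleton,
        rng, subject_gain=gain_mult,
    )
    t_cop = np.arange(len(traj_cop)) / cohort_spec.native_rate_board
    t_com = np.arange(len(traj_com)) / cohort_spec.native_rate_skeleton
    raw_seed = int(rng.integers(0, 2**31 - 2))
    return TrialData(
        trial_index=idx,
        cop=SwayTrial(parameter="COP", t=t_cop, ap=traj_cop[:, 0],
                      ml=traj_cop[:, 1], **kw),
        com=SwayTrial(parameter="COM", t=t_com, ap=traj_com[:, 0],
                      ml=traj_com[:, 1], **kw),
        raw_seed=raw_seed,
    )


def gen_cohort(cohort_spec, pd_class_spec=None, hc_class_spec=None):
    """Generate a labeled two-group cohort with trial dropout applied.

    Per-subject random effects: the class band gain is multiplied by a
    log-normal factor ``exp(sigma * Z)`` so subjects differ systematically
    and subject-wise splits are harder than sample-wise ones.  Fully
    reproducible from ``cohort_spec.seed``.
    """
    pd_class_spec = pd_class_spec or ClassSpec.pd_default()
    hc_class_spec = hc_class_spec or ClassSpec.hc_default()
    root = np.random.SeedSequence(cohort_spec.seed)
    cohort = Cohort(spec=cohort_spec, pd_spec=pd_class_spec, hc_spec=hc_class_spec)
    groups = [("PD", cohort_spec.n_pd, pd_class_spec),
              ("HC", cohort_spec.n_hc, hc_class_spec)]
    children = root.spawn(cohort_spec.n_pd + cohort_spec.n_hc)
    k = 0
    for label, count, cspec in groups:
        for i in range(count):
            rng = np.random.default_rng(children[k])
            k += 1
            subj_id = f"{label}{i + 1:02d}"
            gain_mult = float(np.exp(rng.normal(0.0, cspec.subject_gain_sigma)))
            subj = SubjectData(subj_id, label, gain_mult)
            for idx in range(cohort_spec.trials_per_subject):
                if rng.random() < cspec.trial_dropout_prob:
                    cohort.dropout_log.append(
                        {"subject_id": subj_id, "trial_index": idx,
                         "reason": "simulated tracking loss"}
                    )
                    continue
                subj.trials.append(
                    _make_trial(subj_id, label, idx, cspec, cohort_spec,
                                gain_mult, rng)
                )
            cohort.subjects.append(subj)
    return cohort
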