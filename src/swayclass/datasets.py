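"""Labeled spectrogram-sample datasets with subject-wise splits.

Assembles per-(parameter, direction) image datasets from a cohort,
balances group sizes by randomly retaining a subset of the larger group,
splits train/validation on a per-subject basis (all of a subject's
samples land on one side), and normalizes pixels with one global
mean/standard-deviation pair computed on the training set only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timefreq import detrend, gaussian_resample, morse_cwt, segment_spectrogram

__all__ = [
    "CohortDataset",
    "SplitPlan",
    "NormalizationCoefficients",
    "SplitTensors",
    "trial_to_samples",
    "make_split",
    "normalize",
    "shuffle_labels",
    "audit_no_leakage",
]

LABELS = {"HC": 0, "PD": 1}  # PD is the positive class throughout


def trial_to_samples(trial, direction, n_segments=6, **cwt_kwargs):
    """One SwayTrial channel -> detrend -> 50 Hz resample -> Morse CWT ->
    list of spectrogram image samples."""
    x = detrend(trial.channel(direction))
    rs = gaussian_resample(x, trial.t)
    rs.values = detrend(rs.values)
    meta = {
        "subject_id": trial.subject_id,
        "group_label": trial.group_label,
        "trial_index": trial.trial_index,
        "parameter": trial.parameter,
        "direction": direction,
    }
    spec = morse_cwt(rs, meta=meta, **cwt_kwargs)
    return segment_spectrogram(spec, n_segments=n_segments)


@dataclass
class CohortDataset:
    """Stacked spectrogram samples for one parameter and direction.

    ``x`` is (n_samples, n_freq, n_time) float32, ``y`` the binary labels
    (PD = 1, HC = 0), ``subjects`` the per-sample subject ids, and
    ``manifest`` a DataFrame with one row per sample.
    """

    x: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    freqs: np.ndarray
    parameter: str
    direction: str
    manifest: pd.DataFrame = None
    label_shuffled: bool = False
    subject_groups: dict = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.subjects = np.asarray(self.subjects)
        if not len(self.x) == len(self.y) == len(self.subjects):
            raise ValueError("x, y, subjects must have equal length")
        if self.manifest is None:
            self.manifest = pd.DataFrame({
                "subject_id": self.subjects,
                "label": self.y,
            })
        if self.subject_groups is None:
            if self.label_shuffled:
                raise ValueError(
                    "a label-shuffled dataset needs the true subject_groups "
                    "for subject-wise splitting"
                )
            # labels must be constant within subject
            lab = pd.Series(self.y).groupby(pd.Series(self.subjects)).nunique()
            if (lab > 1).any():
                raise ValueError("labels vary within a subject")
            inv = {v: k for k, v in LABELS.items()}
            self.subject_groups = {
                str(s): inv[int(self.y[self.subjects == s][0])]
                for s in np.unique(self.subjects)
            }

    def __len__(self):
        return len(self.x)

    def subjects_by_group(self):
        """Sorted unique subject ids per (true) group label.

        Splitting stays subject-wise by the subjects' true groups even in
        the shuffled-label arm, mirroring the protocol in which only the
        training labels — not the participants — are permuted.
        """
        out = {g: [] for g in LABELS}
        for subj, group in self.subject_groups.items():
            out[group].append(subj)
        return {g: sorted(v) for g, v in out.items()}

    @classmethod
    def from_cohort(cls, cohort, parameter, direction, n_segments=6,
                    max_samples_per_subject=60, **cwt_kwargs):
        """Run the spectrogram pipeline over every surviving trial."""
        xs, ys, subj, rows = [], [], [], []
        for trial in cohort.trials(parameter):
            for sample in trial_to_samples(trial, direction,
                                           n_segments=n_segments, **cwt_kwargs):
                xs.append(sample.pixels.astype(np.float32))
                ys.append(LABELS[trial.group_label])
                subj.append(trial.subject_id)
                rows.append({**sample.meta, "label": LABELS[trial.group_label]})
                freqs = sample.freqs
        counts = pd.Series(subj).value_counts()
        if (counts > max_samples_per_subject).any():
            raise ValueError("a subject contributed more samples than "
                             f"{max_samples_per_subject}")
        return cls(
            x=np.stack(xs), y=np.array(ys), subjects=np.array(subj),
            freqs=freqs, parameter=parameter, direction=direction,
            manifest=pd.DataFrame(rows),
        )


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level train/validation assignment for one replicate."""

    train_subjects: tuple
    val_subjects: tuple
    retained: tuple
    seed: int

    def __post_init__(self):
        if set(self.train_subjects) & set(self.val_subjects):
            raise ValueError("train and validation subjects overlap")

    def to_dict(self):
        return {
            "train_subjects": list(self.train_subjects),
            "val_subjects": list(self.val_subjects),
            "retained": list(self.retained),
            "seed": self.seed,
        }


def make_split(dataset, seed, retain_per_group=15, train_per_group=11,
               val_per_group=4) -> SplitPlan:
    """Balance groups and split subjects uniformly at random.

    From each group ``retain_per_group`` subjects are retained (a fresh
    random subsample of the larger group per call, mirroring the
    15-of-18 balancing of the source protocol), then assigned
    ``train_per_group`` / ``val_per_group`` to train / validation.
    """
    if train_per_group + val_per_group != retain_per_group:
        raise ValueError("train + validation must equal retained subjects")
    rng = np.random.default_rng(seed)
    train, val, retained = [], [], []
    for group, subjects in sorted(dataset.subjects_by_group().items()):
        if len(subjects) < retain_per_group:
            raise ValueError(
                f"group {group} has {len(subjects)} subjects, "
                f"need >= {retain_per_group}"
            )
        chosen = rng.permutation(np.array(subjects))[:retain_per_group]
        retained.extend(chosen)
        train.extend(chosen[:train_per_group])
        val.extend(chosen[train_per_group:])
    return SplitPlan(
        train_subjects=tuple(sorted(train)), val_subjects=tuple(sorted(val)),
        retained=tuple(sorted(retained)), seed=int(seed),
    )


@dataclass(frozen=True)
class NormalizationCoefficients:
    """Global pixel mean / standard deviation, training set only."""

    mean: float
    sd: float

    def apply(self, x):
        return ((np.asarray(x, dtype=np.float32) - np.float32(self.mean))
                / np.float32(self.sd))


@dataclass
class SplitTensors:
    x_train: np.ndarray
    y_train: np.ndarray
    train_subjects_per_sample: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    val_subjects_per_sample: np.ndarray
    coeffs: NormalizationCoefficients
    plan: SplitPlan


def normalize(dataset, plan) -> SplitTensors:
    """Materialize normalized train/validation tensors for a split plan.

    The coefficients are computed over all training pixels jointly and
    applied unchanged to the validation set (whose mean/sd need not be
    0/1 afterwards).
    """
    tr = np.isin(dataset.subjects, plan.train_subjects)
    va = np.isin(dataset.subjects, plan.val_subjects)
    x_tr = dataset.x[tr]
    if x_tr.size == 0:
        raise ValueError("empty training set for this plan")
    mean = float(x_tr.mean(dtype=np.float64))
    sd = float(x_tr.std(dtype=np.float64))
    if sd == 0:
        raise ValueError("degenerate training pixels: zero variance")
    coeffs = NormalizationCoefficients(mean=mean, sd=sd)
    return SplitTensors(
        x_train=coeffs.apply(x_tr),
        y_train=dataset.y[tr],
        train_subjects_per_sample=dataset.subjects[tr],
        x_val=coeffs.apply(dataset.x[va]),
        y_val=dataset.y[va],
        val_subjects_per_sample=dataset.subjects[va],
        coeffs=coeffs,
        plan=plan,
    )


def shuffle_labels(dataset, seed) -> CohortDataset:
    """Per-sample label permutation (the shuffled-label null).

    The label multiset is preserved; subjects keep their samples, so the
    permutation deliberately breaks the label/subject association.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    return CohortDataset(
        x=dataset.x, y=dataset.y[perm], subjects=dataset.subjects,
        freqs=dataset.freqs, parameter=dataset.parameter,
        direction=dataset.direction, manifest=dataset.manifest,
        label_shuffled=True, subject_groups=dict(dataset.subject_groups),
    )


def audit_no_leakage(tensors: SplitTensors):
    """Assert no subject contributes samples to both sides of the split."""
    tr = set(tensors.train_subjects_per_sample.tolist())
    va = set(tensors.val_subjects_per_sample.tolist())
    overlap = tr & va
    if overlap:
        raise AssertionError(f"subject leakage across split: {sorted(overlap)}")
    return True
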