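"""Scoring, the replicate validation protocol, and the shuffled baseline.

One *replicate* = draw a fresh subject-wise split (including a fresh
balancing subsample of the larger group), train a fresh model, score it
on its validation subjects.  The protocol repeats this ``n_replicates``
times (250 in the full study design; 10 in the reduced preset) and
aggregates mean +- sd per metric.  The shuffled-label baseline runs the
identical protocol after a per-sample label permutation; the two arms
are compared with Welch's t-test on final validation accuracy.

PD is the positive class for sensitivity/precision throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .datasets import audit_no_leakage, make_split, normalize, shuffle_labels
from .model import ModelConfig, TrainedModel, build_model, train

__all__ = [
    "MetricSet",
    "ProtocolConfig",
    "ReplicateReport",
    "ComparisonResult",
    "score",
    "run_replicates",
    "baseline_comparison",
    "ReplicateExperiment",
    "ReplicateResults",
]

METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1",
           "roc_auc", "pr_auc")


@dataclass(frozen=True)
class MetricSet:
    """Validation metrics of one model; undefined entries are NaN.

    Precision is undefined when the model makes no positive call; ROC and
    PR AUC are undefined on a single-class validation set.  Undefined
    values are reported as NaN (never silently 0) and excluded from
    aggregation, with counts logged in the report.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    roc_auc: float
    pr_auc: float

    def as_dict(self):
        return {m: getattr(self, m) for m in METRICS}


def score(model, x_val, y_val) -> MetricSet:
    """Confusion-matrix metrics at the argmax decision plus threshold-swept
    ROC / PR areas over the positive-class probability."""
    y_val = np.asarray(y_val, dtype=np.int64)
    if len(y_val) == 0:
        raise ValueError("empty validation set")
    proba = model.predict_proba(x_val)[:, 1]
    yhat = (proba >= 0.5).astype(np.int64)
    tp = int(np.sum((yhat == 1) & (y_val == 1)))
    tn = int(np.sum((yhat == 0) & (y_val == 0)))
    fp = int(np.sum((yhat == 1) & (y_val == 0)))
    fn = int(np.sum((yhat == 0) & (y_val == 1)))
    n = len(y_val)
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else np.nan
    specificity = tn / (tn + fp) if tn + fp else np.nan
    precision = tp / (tp + fp) if tp + fp else np.nan
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = np.nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    if len(np.unique(y_val)) < 2:
        roc_auc = pr_auc = np.nan  # undefined on a single-class set
    else:
        roc_auc = float(roc_auc_score(y_val, proba))
        pr_auc = float(average_precision_score(y_val, proba))
    return MetricSet(accuracy=accuracy, sensitivity=sensitivity,
                     specificity=specificity, precision=precision, f1=f1,
                     roc_auc=roc_auc, pr_auc=pr_auc)


@dataclass(frozen=True)
class ProtocolConfig:
    """Replicate-protocol parameters.

    Defaults follow the full study design (250 replicates, 15 subjects
    per group split 11/4); :meth:`reduced` is the desk-scale preset
    (10 replicates, 8 subjects per group split 6/2, 200-epoch model).
    """

    n_replicates: int = 250
    retain_per_group: int = 15
    train_per_group: int = 11
    val_per_group: int = 4
    model: ModelConfig = field(default_factory=ModelConfig)
    keep_model_from: int = 0  # replicate whose trained model is retained

    @classmethod
    def reduced(cls, n_replicates=10) -> "ProtocolConfig":
        return cls(n_replicates=n_replicates, retain_per_group=8,
                   train_per_group=6, val_per_group=2,
                   model=ModelConfig.reduced_benchmark())


@dataclass
class ReplicateReport:
    """Per-replicate metrics and their aggregation for one analysis arm."""

    parameter: str
    direction: str
    n_replicates: int
    metrics: list
    seeds: list
    plans: list
    failures: list = field(default_factory=list)
    representative: TrainedModel = None
    representative_tensors: object = None

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame([m.as_dict() for m in self.metrics])
        df.insert(0, "replicate", np.arange(len(df)))
        return df

    def mean(self) -> dict:
        df = self.frame()[list(METRICS)]
        return df.mean(skipna=True).to_dict()

    def sd(self) -> dict:
        df = self.frame()[list(METRICS)]
        return df.std(ddof=1, skipna=True).to_dict()

    def undefined_counts(self) -> dict:
        df = self.frame()[list(METRICS)]
        return df.isna().sum().to_dict()

    def final_val_accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.metrics])


def _replicate_seeds(base_seed, n):
    """Independent (split_seed, model_seed, shuffle_seed) triples."""
    ss = np.random.SeedSequence(base_seed)
    out = []
    for child in ss.spawn(n):
        s = child.generate_state(3) % (2**31 - 1)
        out.append(tuple(int(v) for v in s))
    return out


def run_replicates(dataset, protocol: ProtocolConfig, base_seed=0,
                   shuffle=False) -> ReplicateReport:
    """Run the full replicate protocol on one parameter/direction dataset.

    Each replicate draws a fresh balancing subsample and subject split,
    verifies subject-level disjointness, trains a fresh model and scores
    it.  With ``shuffle=True`` the labels are re-permuted per replicate
    before splitting (the baseline arm).  Failures are recorded in the
    report, never silently swallowed.
    """
    report = ReplicateReport(parameter=dataset.parameter,
                             direction=dataset.direction,
                             n_replicates=protocol.n_replicates,
                             metrics=[], seeds=[], plans=[])
    for i, (split_seed, model_seed, shuffle_seed) in enumerate(
            _replicate_seeds(base_seed, protocol.n_replicates)):
        try:
            ds = shuffle_labels(dataset, shuffle_seed) if shuffle else dataset
            plan = make_split(
                ds, split_seed,
                retain_per_group=protocol.retain_per_group,
                train_per_group=protocol.train_per_group,
                val_per_group=protocol.val_per_group,
            )
            tensors = normalize(ds, plan)
            audit_no_leakage(tensors)
            model = build_model(protocol.model.with_seed(model_seed))
            trained = train(model, tensors.x_train, tensors.y_train,
                            tensors.x_val, tensors.y_val)
            report.metrics.append(score(model, tensors.x_val, tensors.y_val))
            report.seeds.append((split_seed, model_seed, shuffle_seed))
            report.plans.append(plan)
            if i == protocol.keep_model_from:
                report.representative = trained
                report.representative_tensors = tensors
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            report.failures.append({"replicate": i, "error": repr(exc)})
    return report


@dataclass(frozen=True)
class ComparisonResult:
    """Welch two-sample t-test between two replicate arms."""

    t: float
    df: float
    p: float
    significant: bool
    alpha: float
    mean_actual: float
    mean_baseline: float


def baseline_comparison(actual: ReplicateReport, shuffled: ReplicateReport,
                        alpha=0.05) -> ComparisonResult:
    """Welch's (unequal-variance) t-test on final validation accuracies."""
    a = actual.final_val_accuracies()
    b = shuffled.final_val_accuracies()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates in each arm for a t-test")
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        significant=bool(res.pvalue < alpha), alpha=alpha,
        mean_actual=float(a.mean()), mean_baseline=float(b.mean()),
    )


class ReplicateExperiment:
    """Model-object interface over the replicate protocol.

    Built from a :class:`~swayclass.datasets.CohortDataset` and a
    :class:`ProtocolConfig`; :meth:`fit` runs the protocol and returns a
    :class:`ReplicateResults` carrying estimates and diagnostics.
    """

    def __init__(self, dataset, protocol: ProtocolConfig = None,
                 shuffle_labels: bool = False):
        self.dataset = dataset
        self.protocol = protocol or ProtocolConfig()
        self.shuffle = shuffle_labels

    def fit(self, seed=0) -> "ReplicateResults":
        report = run_replicates(self.dataset, self.protocol, base_seed=seed,
                                shuffle=self.shuffle)
        return ReplicateResults(self, report)


class ReplicateResults:
    """Aggregated replicate metrics with a summary table."""

    def __init__(self, experiment: ReplicateExperiment,
                 report: ReplicateReport):
        self.experiment = experiment
        self.report = report

    @property
    def metrics(self) -> pd.DataFrame:
        return self.report.frame()

    @property
    def mean(self) -> dict:
        return self.report.mean()

    @property
    def sd(self) -> dict:
        return self.report.sd()

    def compare(self, baseline: "ReplicateResults",
                alpha=0.05) -> ComparisonResult:
        return baseline_comparison(self.report, baseline.report, alpha=alpha)

    def summary(self) -> str:
        rep = self.report
        lines = [
            "Replicate validation summary",
            "=" * 60,
            f"parameter: {rep.parameter}   direction: {rep.direction}",
            f"replicates: {len(rep.metrics)} of {rep.n_replicates}"
            + (f"   FAILURES: {len(rep.failures)}" if rep.failures else ""),
            f"label-shuffled baseline arm: {self.experiment.shuffle}",
            "-" * 60,
            f"{'metric':<14}{'mean':>10}{'sd':>10}{'undefined':>12}",
        ]
        mean, sd, und = rep.mean(), rep.sd(), rep.undefined_counts()
        for m in mean:
            lines.append(
                f"{m:<14}{mean[m] * 100:>9.2f}%{sd[m] * 100:>9.2f}%"
                f"{und[m]:>12d}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)
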