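"""Metric arithmetic against hand-computed confusion matrices, the
replicate protocol, and the Welch baseline comparison."""

import numpy as np
import pytest

from swayclass.evaluation import (MetricSet, ProtocolConfig, ReplicateReport,
                                  ReplicateExperiment, baseline_comparison,
                                  run_replicates, score)
from swayclass.model import ModelConfig

from conftest import make_fake_dataset


class FixedModel:
    """Stub classifier emitting predetermined positive-class scores."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, x):
        return np.stack([1 - self.scores, self.scores], axis=1)


class TestScore:
    def test_hand_computed_confusion_arithmetic(self):
        # TP=3, FP=1, FN=2, TN=4
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        s = np.array([.9, .8, .7, .2, .1, .6, .3, .2, .1, .05])
        m = score(FixedModel(s), np.zeros((10, 1)), y)
        assert m.accuracy == pytest.approx(0.7)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.f1 == pytest.approx(2 / 3, abs=1e-4)

    def test_perfect_predictor_scores_one_everywhere(self):
        y = np.array([1, 1, 0, 0])
        m = score(FixedModel([.9, .8, .1, .2]), np.zeros((4, 1)), y)
        assert all(getattr(m, k) == 1.0 for k in
                   ("accuracy", "sensitivity", "specificity", "precision",
                    "f1", "roc_auc", "pr_auc"))

    def test_coin_flip_scores_give_chance_auc(self):
        """Permutation oracle: random scores on balanced labels average to
        ROC AUC ~ 0.5."""
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 50)
        aucs = [score(FixedModel(rng.random(100)), np.zeros((100, 1)), y).roc_auc
                for _ in range(300)]
        assert 0.47 < np.mean(aucs) < 0.53

    def test_single_class_validation_reports_undefined_auc(self):
        y = np.ones(5, dtype=int)
        m = score(FixedModel([.9, .8, .7, .6, .9]), np.zeros((5, 1)), y)
        assert np.isnan(m.roc_auc) and np.isnan(m.pr_auc)
        assert np.isnan(m.specificity)  # no negatives either

    def test_no_positive_calls_give_undefined_precision(self):
        y = np.array([1, 0, 1, 0])
        m = score(FixedModel([.1, .2, .3, .4]), np.zeros((4, 1)), y)
        assert np.isnan(m.precision) and np.isnan(m.f1)


def _report(accs, parameter="COP", direction="ml"):
    metrics = [MetricSet(a, a, a, a, a, a, a) for a in accs]
    return ReplicateReport(parameter=parameter, direction=direction,
                           n_replicates=len(accs), metrics=metrics,
                           seeds=[(i, i, i) for i in range(len(accs))],
                           plans=[])


class TestAggregationAndComparison:
    def test_single_replicate_report_equals_its_metricset(self):
        rep = _report([0.8])
        assert rep.mean()["accuracy"] == pytest.approx(0.8)
        assert np.isnan(rep.sd()["accuracy"])  # sd undefined for n=1

    def test_mean_sd_recomputable_from_stored_metrics(self):
        rep = _report([0.7, 0.8, 0.9])
        accs = [m.accuracy for m in rep.metrics]
        assert rep.mean()["accuracy"] == pytest.approx(np.mean(accs))
        assert rep.sd()["accuracy"] == pytest.approx(np.std(accs, ddof=1))

    def test_identical_arms_not_significant(self):
        a, b = _report([0.6, 0.7, 0.8]), _report([0.6, 0.7, 0.8])
        cmp = baseline_comparison(a, b)
        assert cmp.t == pytest.approx(0.0)
        assert cmp.p == pytest.approx(1.0)
        assert not cmp.significant

    def test_separated_arms_significant_with_closed_form_welch_t(self):
        a = _report([0.95, 0.92, 0.98, 0.94])
        b = _report([0.50, 0.45, 0.55, 0.52])
        cmp = baseline_comparison(a, b)
        x, y = np.array([0.95, 0.92, 0.98, 0.94]), np.array([0.50, 0.45, 0.55, 0.52])
        t_hand = (x.mean() - y.mean()) / np.sqrt(
            x.var(ddof=1) / 4 + y.var(ddof=1) / 4
        )
        assert cmp.t == pytest.approx(t_hand)
        assert cmp.significant and cmp.p < 0.05

    def test_tiny_arms_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            baseline_comparison(_report([0.9]), _report([0.5, 0.6]))


def _tiny_protocol(n_replicates=2, epochs=60):
    model = ModelConfig(conv_channels=(4, 4, 4), kernel_size=(3, 3, 3),
                        conv_strides=(1, 1, 1), pool_sizes=(2, 2, 2),
                        dense_widths=(8, 4, 2), learning_rate=3e-3,
                        weight_decay=0.0, epochs=epochs, input_shape=(12, 12))
    return ProtocolConfig(n_replicates=n_replicates, retain_per_group=4,
                          train_per_group=3, val_per_group=1, model=model)


class TestRunReplicates:
    def test_separable_fake_cohort_classified_accurately(self):
        ds = make_fake_dataset(separation=2.0, noise=0.3, seed=3)
        rep = run_replicates(ds, _tiny_protocol(n_replicates=3), base_seed=0)
        assert rep.failures == []
        assert np.mean([m.accuracy for m in rep.metrics]) > 0.9

    def test_replicate_seeds_distinct_and_logged(self):
        ds = make_fake_dataset(separation=2.0, seed=4)
        rep = run_replicates(ds, _tiny_protocol(n_replicates=3), base_seed=1)
        assert len(rep.seeds) == 3
        assert len({s for trip in rep.seeds for s in trip}) == 9

    def test_every_replicate_plan_is_subject_disjoint(self):
        ds = make_fake_dataset(separation=1.0, seed=5)
        rep = run_replicates(ds, _tiny_protocol(n_replicates=4), base_seed=2)
        for plan in rep.plans:
            assert not set(plan.train_subjects) & set(plan.val_subjects)

    def test_experiment_results_interface(self):
        ds = make_fake_dataset(separation=2.0, seed=6)
        res = ReplicateExperiment(ds, _tiny_protocol()).fit(seed=0)
        base = ReplicateExperiment(ds, _tiny_protocol(),
                                   shuffle_labels=True).fit(seed=1)
        text = res.summary()
        assert "accuracy" in text and "replicates: 2 of 2" in text
        cmp = res.compare(base)
        assert cmp.mean_actual >= cmp.mean_baseline - 0.25
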