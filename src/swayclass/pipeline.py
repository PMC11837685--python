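"""End-to-end orchestration: simulate -> spectrograms -> replicate
evaluation -> shuffled baseline -> Grad-CAM attribution.

Every random draw flows from one global seed through named per-stage
substreams (stage-name-hashed, so adding a stage never perturbs earlier
draws).  Stages write their artifacts into a run directory and are
skipped on resume when their outputs already exist.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .datasets import CohortDataset
from .evaluation import (ProtocolConfig, baseline_comparison, run_replicates)
from .explain import band_attribution, class_average
from .model import ModelConfig
from .synthetic import ClassSpec, CohortSpec, gen_cohort

__all__ = ["RunConfig", "stage_seed", "run_all"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (global seed + name hash)."""
    h = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([global_seed, h]).generate_state(1)[0]
               % (2**31 - 1))


@dataclass
class RunConfig:
    """Fully serializable end-to-end run description."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    pd_class: ClassSpec = field(default_factory=ClassSpec.pd_default)
    hc_class: ClassSpec = field(default_factory=ClassSpec.hc_default)
    parameter: str = "COP"
    direction: str = "ml"
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig.reduced)
    run_shuffled_baseline: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "cohort" in raw:
            kw["cohort"] = CohortSpec(**raw["cohort"])
        if "pd_class" in raw:
            kw["pd_class"] = ClassSpec(**{"group_label": "PD", **raw["pd_class"]})
        if "hc_class" in raw:
            kw["hc_class"] = ClassSpec(**{"group_label": "HC", **raw["hc_class"]})
        proto = raw.get("protocol", {})
        if proto or "model" in raw:
            model_kw = raw.get("model", {})
            preset = model_kw.pop("preset", "reduced")
            base = (ModelConfig.reduced_benchmark() if preset == "reduced"
                    else ModelConfig())
            if model_kw:
                from dataclasses import replace
                base = replace(base, **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in model_kw.items()
                })
            kw["protocol"] = ProtocolConfig(
                **{**dict(ProtocolConfig.reduced().__dict__, model=base),
                   **proto}
            )
        for key in ("parameter", "direction", "seed", "run_shuffled_baseline"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)

    def to_dict(self):
        return {
            "cohort": self.cohort.__dict__,
            "pd_class": self.pd_class.__dict__,
            "hc_class": self.hc_class.__dict__,
            "parameter": self.parameter,
            "direction": self.direction,
            "protocol": {
                **{k: v for k, v in self.protocol.__dict__.items()
                   if k != "model"},
                "model": self.protocol.model.to_dict(),
            },
            "run_shuffled_baseline": self.run_shuffled_baseline,
            "seed": self.seed,
        }


def _log(messages, out_dir, level, msg):
    line = f"[{level}] {msg}"
    messages.append(line)
    print(line, flush=True)
    with open(Path(out_dir) / "run.log", "a") as fh:
        fh.write(line + "\n")


def run_all(config: RunConfig, out_dir, resume=True) -> dict:
    """Execute all stages, logging seeds and counts; returns the summary.

    Artifacts: ``cohort.h5``, ``samples.h5``, per-arm ``report.csv/json``,
    Grad-CAM attribution CSV and PNG panels, ``summary.json`` and a
    ``manifest.json`` listing the per-stage substream seeds.
    """
    out = Path(out_dir)
    arm = out / f"{config.parameter}_{config.direction}"
    arm.mkdir(parents=True, exist_ok=True)
    log = []
    seeds = {name: stage_seed(config.seed, name)
             for name in ("simulate", "evaluate", "baseline")}
    (arm / "manifest.json").write_text(json.dumps(
        {"stage_seeds": seeds, "config": config.to_dict()}, indent=2))

    cohort_path = arm / "cohort.h5"
    if resume and cohort_path.exists():
        _log(log, arm, "INFO", f"resume: cohort exists at {cohort_path}")
        cohort = sio.load_cohort_hdf5(cohort_path)
    else:
        spec = CohortSpec(**{**config.cohort.__dict__,
                             "seed": seeds["simulate"]})
        cohort = gen_cohort(spec, config.pd_class, config.hc_class)
        sio.save_cohort_hdf5(cohort, cohort_path)
        _log(log, arm, "INFO",
             f"simulate: {spec.n_pd} PD + {spec.n_hc} HC subjects, "
             f"{sum(len(s.trials) for s in cohort.subjects)} trials kept, "
             f"{len(cohort.dropout_log)} dropped (seed {seeds['simulate']})")

    samples_path = arm / "samples.h5"
    if resume and samples_path.exists():
        _log(log, arm, "INFO", "resume: samples exist")
        dataset = sio.load_samples_hdf5(samples_path)
    else:
        dataset = CohortDataset.from_cohort(
            cohort, config.parameter, config.direction
        )
        sio.save_samples_hdf5(dataset, samples_path)
        _log(log, arm, "INFO",
             f"spectrogram: {len(dataset)} samples of shape "
             f"{dataset.x.shape[1:]} ({config.parameter} {config.direction})")

    report_json = arm / "actual" / "report.json"
    report_csv = arm / "actual" / "report.csv"
    if resume and report_json.exists():
        _log(log, arm, "INFO", "resume: actual-arm report exists")
        actual_summary = json.loads(report_json.read_text())
        actual = None
    elif resume and report_csv.exists():
        # report deleted but per-replicate metrics persist: rebuild the
        # summary from stored artifacts without retraining
        import pandas as pd
        df = pd.read_csv(report_csv)
        cols = [c for c in df.columns if c != "replicate"]
        actual_summary = {
            "n_replicates": len(df),
            "mean": df[cols].mean(skipna=True).to_dict(),
            "sd": df[cols].std(ddof=1, skipna=True).to_dict(),
        }
        report_json.write_text(json.dumps(actual_summary, indent=2))
        _log(log, arm, "INFO", "resume: rebuilt actual-arm report from CSV")
        actual = None
    else:
        actual = run_replicates(dataset, config.protocol,
                                base_seed=seeds["evaluate"])
        if actual.failures:
            raise RuntimeError(f"evaluate stage failures: {actual.failures}")
        actual_summary = sio.save_report(actual, arm / "actual")
        if actual.representative is not None:
            sio.save_trained_model(actual.representative,
                                   arm / "actual" / "model")
        _log(log, arm, "INFO",
             f"evaluate: {len(actual.metrics)} replicates, mean accuracy "
             f"{actual_summary['mean']['accuracy']:.3f}")

    shuffled_summary = None
    comparison = None
    if config.run_shuffled_baseline:
        shuf_json = arm / "shuffled" / "report.json"
        if resume and shuf_json.exists() and actual is None:
            _log(log, arm, "INFO", "resume: shuffled-arm report exists")
            shuffled_summary = json.loads(shuf_json.read_text())
        else:
            shuffled = run_replicates(dataset, config.protocol,
                                      base_seed=seeds["baseline"],
                                      shuffle=True)
            if shuffled.failures:
                raise RuntimeError(
                    f"baseline stage failures: {shuffled.failures}")
            shuffled_summary = sio.save_report(shuffled, arm / "shuffled")
            _log(log, arm, "INFO",
                 f"baseline: mean shuffled accuracy "
                 f"{shuffled_summary['mean']['accuracy']:.3f}")
            if actual is not None:
                comparison = baseline_comparison(actual, shuffled)
                _log(log, arm, "INFO",
                     f"welch t-test actual vs shuffled: t={comparison.t:.2f} "
                     f"p={comparison.p:.2e}")

    attribution = None
    if actual is not None and actual.representative is not None:
        tens = actual.representative_tensors
        maps = class_average(actual.representative.model, tens.x_val,
                             freqs=dataset.freqs)
        attribution = {}
        for cls, hm in maps.items():
            ba = band_attribution(hm)
            attribution[cls] = {
                "n_averaged": hm.n_averaged,
                "fraction_above_1hz": None if not ba.defined
                else ba.fraction_above,
            }
            if not hm.empty:
                sio.export_heatmap_png(
                    hm, arm / f"gradcam_{cls}.png",
                    title=f"{cls} (n={hm.n_averaged})",
                )
        with open(arm / "attribution.csv", "w") as fh:
            fh.write("parameter,direction,decoded_class,n_averaged,"
                     "fraction_above_1hz\n")
            for cls, row in attribution.items():
                fh.write(f"{config.parameter},{config.direction},{cls},"
                         f"{row['n_averaged']},{row['fraction_above_1hz']}\n")
        _log(log, arm, "INFO", f"explain: {attribution}")

    summary = {
        "parameter": config.parameter,
        "direction": config.direction,
        "stage_seeds": seeds,
        "actual": {k: actual_summary[k] for k in
                   ("n_replicates", "mean", "sd")},
        "shuffled": None if shuffled_summary is None else
        {k: shuffled_summary[k] for k in ("n_replicates", "mean", "sd")},
        "comparison": None if comparison is None else comparison.__dict__,
        "attribution": attribution,
    }
    (arm / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
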