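"""HDF5 / CSV / JSON persistence for pipeline artifacts."""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datasets import CohortDataset, SplitPlan
from .kinematics import SwayTrial
from .model import ModelConfig, SwayCNN, TrainedModel
from .synthetic import ClassSpec, Cohort, CohortSpec, SubjectData, TrialData

__all__ = [
    "save_cohort_hdf5", "load_cohort_hdf5", "export_trial_csv",
    "save_samples_hdf5", "load_samples_hdf5",
    "save_plan_json", "load_plan_json",
    "save_trained_model", "load_trained_model",
    "save_report", "export_heatmap_png", "export_sample_png",
]


def save_cohort_hdf5(cohort: Cohort, path):
    """One group per subject; per trial, COP and COM (n, 2) arrays with
    time axes as attributes."""
    with h5py.File(path, "w") as fh:
        fh.attrs["spec"] = json.dumps(cohort.spec.__dict__)
        fh.attrs["pd_spec"] = json.dumps(cohort.pd_spec.__dict__)
        fh.attrs["hc_spec"] = json.dumps(cohort.hc_spec.__dict__)
        fh.attrs["dropout_log"] = json.dumps(cohort.dropout_log)
        for subj in cohort.subjects:
            g = fh.create_group(f"subjects/{subj.subject_id}")
            g.attrs["group_label"] = subj.group_label
            g.attrs["band_gain_multiplier"] = subj.band_gain_multiplier
            for trial in subj.trials:
                tg = g.create_group(f"trials/{trial.trial_index:03d}")
                tg.attrs["raw_seed"] = trial.raw_seed
                for param in ("cop", "com"):
                    st = getattr(trial, param)
                    d = tg.create_dataset(
                        param, data=np.stack([st.ap, st.ml], axis=1)
                    )
                    d.attrs["rate"] = 1.0 / np.median(np.diff(st.t))


def load_cohort_hdf5(path) -> Cohort:
    with h5py.File(path, "r") as fh:
        spec = CohortSpec(**json.loads(fh.attrs["spec"]))
        cohort = Cohort(
            spec=spec,
            pd_spec=ClassSpec(**json.loads(fh.attrs["pd_spec"])),
            hc_spec=ClassSpec(**json.loads(fh.attrs["hc_spec"])),
            dropout_log=json.loads(fh.attrs["dropout_log"]),
        )
        for sid in sorted(fh["subjects"]):
            g = fh[f"subjects/{sid}"]
            subj = SubjectData(sid, g.attrs["group_label"],
                               float(g.attrs["band_gain_multiplier"]))
            for tidx in sorted(g.get("trials", {})):
                tg = g[f"trials/{tidx}"]
                trials = {}
                for param in ("cop", "com"):
                    arr = tg[param][...]
                    rate = float(tg[param].attrs["rate"])
                    trials[param] = SwayTrial(
                        subject_id=sid, group_label=subj.group_label,
                        trial_index=int(tidx), parameter=param.upper(),
                        t=np.arange(len(arr)) / rate,
                        ap=arr[:, 0], ml=arr[:, 1],
                    )
                subj.trials.append(TrialData(
                    trial_index=int(tidx), cop=trials["cop"],
                    com=trials["com"], raw_seed=int(tg.attrs["raw_seed"]),
                ))
            cohort.subjects.append(subj)
    return cohort


def export_trial_csv(trial: SwayTrial, path):
    pd.DataFrame({"t": trial.t, "ap": trial.ap, "ml": trial.ml}).to_csv(
        path, index=False
    )


def save_samples_hdf5(dataset: CohortDataset, path):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("x", data=dataset.x, compression="gzip",
                          compression_opts=1)
        fh.create_dataset("y", data=dataset.y)
        fh.create_dataset(
            "subjects", data=np.array(dataset.subjects, dtype="S")
        )
        fh.create_dataset("freqs", data=dataset.freqs)
        fh.attrs["parameter"] = dataset.parameter
        fh.attrs["direction"] = dataset.direction
        fh.attrs["label_shuffled"] = dataset.label_shuffled
        fh.attrs["manifest_csv"] = dataset.manifest.to_csv(index=False)
        fh.attrs["subject_groups"] = json.dumps(dataset.subject_groups)


def load_samples_hdf5(path) -> CohortDataset:
    with h5py.File(path, "r") as fh:
        return CohortDataset(
            x=fh["x"][...],
            y=fh["y"][...],
            subjects=fh["subjects"][...].astype(str),
            freqs=fh["freqs"][...],
            parameter=fh.attrs["parameter"],
            direction=fh.attrs["direction"],
            manifest=pd.read_csv(_io.StringIO(fh.attrs["manifest_csv"])),
            label_shuffled=bool(fh.attrs["label_shuffled"]),
            subject_groups=json.loads(fh.attrs["subject_groups"]),
        )


def save_plan_json(plan: SplitPlan, path):
    Path(path).write_text(json.dumps(plan.to_dict(), indent=2))


def load_plan_json(path) -> SplitPlan:
    d = json.loads(Path(path).read_text())
    return SplitPlan(
        train_subjects=tuple(d["train_subjects"]),
        val_subjects=tuple(d["val_subjects"]),
        retained=tuple(d["retained"]), seed=d["seed"],
    )


def save_trained_model(trained: TrainedModel, out_dir):
    """Checkpoint = parameter npz + JSON config sidecar + curve CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez(out_dir / "params.npz", **trained.model.core.params)
    (out_dir / "config.json").write_text(
        json.dumps(trained.config.to_dict(), indent=2)
    )
    trained.curve.to_csv(out_dir / "curve.csv", index=False)


def load_trained_model(out_dir) -> TrainedModel:
    out_dir = Path(out_dir)
    config = ModelConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in json.loads((out_dir / "config.json").read_text()).items()
    })
    model = SwayCNN(config)
    with np.load(out_dir / "params.npz") as npz:
        for k in model.core.params:
            model.core.params[k] = npz[k]
    curve = pd.read_csv(out_dir / "curve.csv")
    return TrainedModel(model=model, config=config, curve=curve)


def save_report(report, out_dir, name="report"):
    """Per-replicate CSV plus a JSON summary (mean ± sd per metric)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.frame().to_csv(out_dir / f"{name}.csv", index=False)
    summary = {
        "parameter": report.parameter,
        "direction": report.direction,
        "n_replicates": len(report.metrics),
        "n_failures": len(report.failures),
        "mean": report.mean(),
        "sd": report.sd(),
        "undefined_counts": report.undefined_counts(),
        "seeds": report.seeds,
        "plans": [p.to_dict() for p in report.plans],
    }
    (out_dir / f"{name}.json").write_text(json.dumps(summary, indent=2))
    return summary


def export_sample_png(sample, path):
    """8-bit grayscale PNG of a spectrogram sample (inspection only; the
    model always consumes full-precision floats)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3), dpi=100)
    px = sample.pixels if hasattr(sample, "pixels") else np.asarray(sample)
    ax.imshow(np.log10(px + 1e-12), aspect="auto", cmap="gray")
    ax.set_xlabel("time (samples)")
    ax.set_ylabel("frequency band (descending)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def export_heatmap_png(heatmap, path, title=""):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    weights = heatmap.weights if hasattr(heatmap, "weights") else heatmap
    mx = weights.max()
    fig, ax = plt.subplots(figsize=(3.2, 3), dpi=100)
    im = ax.imshow(weights / mx if mx > 0 else weights, aspect="auto",
                   cmap="inferno")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    ax.set_xlabel("time (px)")
    ax.set_ylabel("frequency band (descending)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
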