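"""Dataset directory serialization.

Layout::

    <dir>/
      manifest.json   design, trust spec/truth summary, master seed
      index.csv       one row per epoch: keys, trust, condition, missing flags
      background.csv  one row per participant: 25 background values
      embedded.csv    one row per epoch: raw interaction record
      signals/        optional NPZ per epoch (materialized waveforms)

Because epoch records carry generator parameters and seeds, the manifest and
index are sufficient to regenerate every waveform bit-identically; the
signals/ directory is an optional cache for consumers that want raw arrays
on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from physiotrust.design import StudyDesign
from physiotrust.synth.study import STREAMS, StudyDataset, TrustSpec, generate_study

__all__ = ["save_dataset", "load_dataset", "dataset_index_frame"]


def dataset_index_frame(dataset: StudyDataset) -> pd.DataFrame:
    rows = []
    for r in dataset.records:
        row = {
            "participant": r.participant,
            "session": r.session,
            "trial": r.trial,
            "epoch": r.epoch,
            "trust": r.y,
            "reliability": r.condition["reliability"],
            "explainability": r.condition["explainability"],
        }
        row.update({f"missing_{s}": int(r.missing[s]) for s in STREAMS})
        rows.append(row)
    return pd.DataFrame(rows)


def save_dataset(
    dataset: StudyDataset,
    path,
    materialize_signals: bool = False,
    overwrite: bool = False,
) -> Path:
    """Write the dataset directory; refuses to overwrite unless asked."""
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not overwrite:
        raise FileExistsError(f"{path} exists and is non-empty; pass overwrite=True")
    path.mkdir(parents=True, exist_ok=True)

    spec_like = {
        "planted": [
            {"name": p.name, "stream": p.stream, "sign": p.sign, "aliases": list(p.aliases)}
            for p in dataset.truth.planted
        ],
        "betas": dataset.truth.betas.tolist(),
        "intercept": dataset.truth.intercept,
        "noise_sd": dataset.truth.noise_sd,
    }
    spec = dataset.trust_spec
    if spec is not None:
        spec_like["spec_params"] = {
            "intercept": spec.intercept,
            "noise_sd": spec.noise_sd,
            "signal_r2": spec.signal_r2,
            "participant_sd": spec.participant_sd,
            "reliability_effect": spec.reliability_effect,
            "explainability_effect": spec.explainability_effect,
            "embedded_noise_sd": spec.embedded_noise_sd,
        }
    manifest = {
        "format_version": 1,
        "seed": dataset.seed,
        "design": {
            "n_participants": dataset.design.n_participants,
            "n_sessions": dataset.design.n_sessions,
            "n_trials": dataset.design.n_trials,
            "n_epochs": dataset.design.n_epochs,
            "epoch_s": dataset.design.epoch_s,
            "pretrial_baseline_s": dataset.design.pretrial_baseline_s,
            "preexp_baseline_s": dataset.design.preexp_baseline_s,
            "sampling_rates": dataset.design.sampling_rates,
        },
        "truth": spec_like,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    dataset_index_frame(dataset).to_csv(path / "index.csv", index=False)
    pd.DataFrame.from_dict(dataset.background, orient="index").rename_axis(
        "participant"
    ).to_csv(path / "background.csv")
    pd.DataFrame([
        {"participant": r.participant, **{k: v for k, v in r.embedded.items()}}
        for r in dataset.records
    ]).to_csv(path / "embedded.csv", index=False)

    if materialize_signals:
        sigdir = path / "signals"
        sigdir.mkdir(exist_ok=True)
        for r in dataset.records:
            arrays = {}
            for s in STREAMS:
                data, _ = r.signals(s)
                if s == "fnirs":
                    arrays["fnirs_hbo"], arrays["fnirs_hbr"] = data
                elif s == "eye":
                    arrays["eye_pupil"] = data["pupil"]
                else:
                    arrays[s] = data
            p, se, t, e = r.key
            np.savez_compressed(sigdir / f"p{p:02d}_s{se}_t{t}_e{e}.npz", **arrays)
    return path


def load_dataset(path) -> StudyDataset:
    """Rebuild a dataset from its manifest (signals regenerate lazily)."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("format_version") != 1:
        raise ValueError("unrecognized dataset format version")
    d = manifest["design"]
    design = StudyDesign(
        n_participants=d["n_participants"],
        n_sessions=d["n_sessions"],
        n_trials=d["n_trials"],
        n_epochs=d["n_epochs"],
        epoch_s=d["epoch_s"],
        pretrial_baseline_s=d["pretrial_baseline_s"],
        preexp_baseline_s=d["preexp_baseline_s"],
        sampling_rates=d["sampling_rates"],
    )
    tr = manifest["truth"]
    from physiotrust.synth.study import DEFAULT_PLANTED

    by_name = {p.name: p for p in DEFAULT_PLANTED}
    planted = tuple(by_name[p["name"]] for p in tr["planted"])
    params = tr.get("spec_params") or {
        "intercept": tr["intercept"], "noise_sd": tr["noise_sd"]
    }
    spec = TrustSpec(planted=planted, **params)
    ds = generate_study(design, spec, seed=manifest["seed"])

    # restore missingness flags from the index
    idx = pd.read_csv(path / "index.csv")
    for _, row in idx.iterrows():
        rec = ds.record(
            (int(row["participant"]), int(row["session"]), int(row["trial"]), int(row["epoch"]))
        )
        for s in STREAMS:
            rec.missing[s] = bool(row[f"missing_{s}"])
    return ds
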