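"""HDF5 session containers and cohort manifests.

One HDF5 file per trial:

* ``/lfp/<region>`` — (channels x samples) float32 dataset, attr ``fs``;
* ``/tracking/xy`` — (2 x frames) dataset, attr ``fs`` = 30;
* root attrs ``subject_id``, ``sex``, ``estrous``, ``px_per_cm``, ``t0``.

A cohort is a directory of such files plus a ``manifest.csv`` with columns
(trial_id, subject_id, sex, estrous, path). Preprocessed trials use the same
layout with ``/lfp_regional/<region>``, ``/velocity`` and a JSON QC attr.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import ANALYSIS_FS, ChannelQCReport, RegionalLFPSet
from .synthetic import TRACK_FS, TrialRecording

__all__ = [
    "save_trial",
    "load_trial",
    "save_regional",
    "load_regional",
    "write_manifest",
    "read_manifest",
]


def save_trial(trial: TrialRecording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp")
        for region, chans in trial.lfp.items():
            d = g.create_dataset(region, data=np.asarray(chans, dtype=np.float32))
            d.attrs["fs"] = trial.fs
        tr = f.create_group("tracking")
        d = tr.create_dataset("xy", data=trial.tracking_xy)
        d.attrs["fs"] = TRACK_FS
        f.attrs.update({"subject_id": trial.subject_id, "sex": trial.sex,
                        "estrous": trial.estrous, "px_per_cm": trial.px_per_cm,
                        "t0": trial.t0, "trial_id": trial.trial_id})
    return path


def load_trial(path: str | Path) -> TrialRecording:
    with h5py.File(path, "r") as f:
        lfp = {r: f["lfp"][r][()] for r in f["lfp"]}
        fs = float(next(iter(f["lfp"].values())).attrs["fs"])
        return TrialRecording(
            subject_id=str(f.attrs["subject_id"]), sex=str(f.attrs["sex"]),
            estrous=str(f.attrs["estrous"]), fs=fs, lfp=lfp,
            tracking_xy=f["tracking"]["xy"][()],
            px_per_cm=float(f.attrs["px_per_cm"]), t0=float(f.attrs["t0"]),
            trial_id=str(f.attrs["trial_id"]),
        )


def save_regional(rset: RegionalLFPSet, path: str | Path) -> Path:
    path = Path(path)
    qc_json = json.dumps({
        r: {"kept_mask": rep.kept_mask.tolist(), "threshold": rep.threshold,
            "plv_matrix": np.round(rep.plv_matrix, 6).tolist()}
        for r, rep in rset.qc.items()
    })
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp_regional")
        for region, trace in rset.traces.items():
            d = g.create_dataset(region, data=trace.astype(np.float32))
            d.attrs["fs"] = rset.fs
        f.create_dataset("velocity", data=rset.velocity.astype(np.float32))
        f.attrs.update({"subject_id": rset.subject_id, "sex": rset.sex,
                        "estrous": rset.estrous, "trial_id": rset.trial_id,
                        "fs": rset.fs, "qc": qc_json})
    return path


def load_regional(path: str | Path) -> RegionalLFPSet:
    with h5py.File(path, "r") as f:
        traces = {r: f["lfp_regional"][r][()].astype(np.float64)
                  for r in f["lfp_regional"]}
        qc = {}
        for r, d in json.loads(f.attrs.get("qc", "{}")).items():
            qc[r] = ChannelQCReport(region=r,
                                    plv_matrix=np.asarray(d["plv_matrix"]),
                                    kept_mask=np.asarray(d["kept_mask"], dtype=bool),
                                    threshold=d["threshold"])
        return RegionalLFPSet(
            fs=float(f.attrs.get("fs", ANALYSIS_FS)), traces=traces,
            velocity=f["velocity"][()].astype(np.float64),
            subject_id=str(f.attrs["subject_id"]), sex=str(f.attrs["sex"]),
            estrous=str(f.attrs["estrous"]), trial_id=str(f.attrs["trial_id"]),
            qc=qc,
        )


def write_manifest(rows: list[dict], out_dir: str | Path) -> Path:
    out = Path(out_dir) / "manifest.csv"
    pd.DataFrame(rows, columns=["trial_id", "subject_id", "sex", "estrous",
                                "path"]).to_csv(out, index=False)
    return out


def read_manifest(cohort_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(cohort_dir) / "manifest.csv")
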