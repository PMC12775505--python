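"""On-disk schemas: CSV time series, JSON annotations, NPZ window stores.

Per-recording layout inside a subject directory:

    imu_0.csv .. imu_3.csv   columns t_s, ax, ay, az, gx, gy, gz
    pose.csv                 columns t_s, kp00_x .. kp32_z
    annotations.json         {"subject_id", "duration_s", "intervals": [...]}

A cohort directory holds one subject directory per recording plus
``manifest.json``. Window datasets and feature matrices are stored as a
binary array container (.npz) with a JSON sidecar carrying labels and
provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .hcf import FeatureMatrix
from .preprocessing import WindowDataset
from .synthetic import (N_KEYPOINTS, N_SENSORS, AnnotationInterval, Recording)

IMU_COLUMNS = ["t_s", "ax", "ay", "az", "gx", "gy", "gz"]
POSE_COLUMNS = ["t_s"] + [f"kp{k:02d}_{c}" for k in range(N_KEYPOINTS)
                          for c in "xyz"]
_FLOAT_FMT = "%.6f"


class SchemaError(ValueError):
    pass


def write_recording(recording: Recording, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rec = recording.validate()
    for s in range(N_SENSORS):
        arr = np.column_stack([rec.imu_t[s], rec.imu[s]])
        pd.DataFrame(arr, columns=IMU_COLUMNS).to_csv(
            d / f"imu_{s}.csv", index=False, float_format=_FLOAT_FMT)
    pose = np.column_stack([rec.pose_t, rec.pose])
    pd.DataFrame(pose, columns=POSE_COLUMNS).to_csv(
        d / "pose.csv", index=False, float_format=_FLOAT_FMT)
    ann = {
        "subject_id": rec.subject_id,
        "duration_s": round(float(rec.duration_s), 6),
        "intervals": [
            {"start_s": round(iv.start_s, 6), "end_s": round(iv.end_s, 6),
             "label": iv.label, "regions": list(iv.regions)}
            for iv in rec.annotations],
    }
    (d / "annotations.json").write_text(json.dumps(ann, indent=2,
                                                   sort_keys=True))
    return d


def _read_csv(path: Path, columns: List[str]) -> np.ndarray:
    if not path.exists():
        raise SchemaError(f"{path}: missing file")
    df = pd.read_csv(path)
    if list(df.columns) != columns:
        raise SchemaError(
            f"{path}: expected columns {columns[:3]}..., got "
            f"{list(df.columns)[:3]}...")
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise SchemaError(f"{path}: non-finite values")
    return vals


def read_recording(directory) -> Recording:
    d = Path(directory)
    ann_path = d / "annotations.json"
    if not ann_path.exists():
        raise SchemaError(f"{ann_path}: missing file")
    ann = json.loads(ann_path.read_text())
    for key in ("subject_id", "duration_s", "intervals"):
        if key not in ann:
            raise SchemaError(f"{ann_path}: missing field {key!r}")
    intervals = []
    for i, iv in enumerate(ann["intervals"]):
        try:
            intervals.append(AnnotationInterval(
                float(iv["start_s"]), float(iv["end_s"]), iv["label"],
                list(iv.get("regions", []))).validate(ann["duration_s"]))
        except (KeyError, ValueError) as exc:
            raise SchemaError(
                f"{ann_path}: intervals[{i}]: {exc}") from exc
    imu_t, imu = [], []
    for s in range(N_SENSORS):
        vals = _read_csv(d / f"imu_{s}.csv", IMU_COLUMNS)
        imu_t.append(vals[:, 0])
        imu.append(vals[:, 1:])
    pose_vals = _read_csv(d / "pose.csv", POSE_COLUMNS)
    return Recording(subject_id=ann["subject_id"], imu_t=imu_t, imu=imu,
                     pose_t=pose_vals[:, 0], pose=pose_vals[:, 1:],
                     annotations=intervals,
                     duration_s=float(ann["duration_s"])).validate()


def write_cohort(recordings: Sequence[Recording], manifest: dict,
                 directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = json.loads(json.dumps(manifest))  # deep copy
    for rec, entry in zip(recordings, manifest["subjects"]):
        sub = write_recording(rec, d / rec.subject_id)
        entry["files"] = sorted(p.name for p in sub.iterdir())
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                sort_keys=True))
    return d


def read_cohort(directory) -> Tuple[List[Recording], dict]:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    recordings = [read_recording(d / e["subject_id"])
                  for e in manifest["subjects"]]
    return recordings, manifest


# -- window datasets and feature matrices -----------------------------------

def save_windows(windows: WindowDataset, path) -> Path:
    path = Path(path)
    np.savez_compressed(path, imu=windows.imu, pose=windows.pose,
                        labels=windows.labels,
                        window_start_s=windows.window_start_s,
                        majority_fraction=windows.majority_fraction)
    sidecar = {
        "subject_ids": [str(s) for s in windows.subject_ids],
        "n_excluded": windows.n_excluded,
        "n_invalid_discarded": windows.n_invalid_discarded,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def load_windows(path) -> WindowDataset:
    path = Path(path)
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path
                 ) as z:
        data = {k: z[k] for k in z.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return WindowDataset(
        imu=data["imu"], pose=data["pose"], labels=data["labels"],
        subject_ids=np.array(sidecar["subject_ids"], dtype=object),
        window_start_s=data["window_start_s"],
        majority_fraction=data["majority_fraction"],
        n_excluded=int(sidecar["n_excluded"]),
        n_invalid_discarded=int(sidecar["n_invalid_discarded"]))


def save_features(features: FeatureMatrix, path) -> Path:
    path = Path(path)
    np.savez_compressed(path, values=features.values, labels=features.labels)
    sidecar = {"feature_names": features.feature_names,
               "subject_ids": [str(s) for s in features.subject_ids]}
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def load_features(path) -> FeatureMatrix:
    path = Path(path)
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path
                 ) as z:
        values, labels = z["values"], z["labels"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return FeatureMatrix(values=values,
                         feature_names=sidecar["feature_names"],
                         labels=labels,
                         subject_ids=np.array(sidecar["subject_ids"],
                                              dtype=object))
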