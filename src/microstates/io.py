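"""On-disk formats: trial matrices with JSON sidecars, manifests, templates.

A trial is stored as a comma-separated channels x samples matrix with no
header row; its metadata (sampling rate, ordered channel names, identifiers,
ratings) lives in a JSON sidecar at `<path>.json`. The dataset manifest is a
CSV with one row per trial. Templates are written as a channels x K
delimited matrix plus a JSON metadata file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import MicrostateSet
from .core import Recording
from .exceptions import FormatError, InvalidInputError
from .simulate import SimulatedDataset
from .strategies import Dataset

__all__ = [
    "write_recording",
    "read_recording",
    "load_manifest",
    "write_dataset",
    "load_dataset",
    "write_templates",
    "read_templates",
]

MANIFEST_COLUMNS = ["subject_id", "trial_id", "video_id", "valence", "arousal", "path"]


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a trial matrix and its JSON sidecar; returns the matrix path."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter=",")
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "video_id": rec.video_id,
        "valence": rec.valence,
        "arousal": rec.arousal,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> Recording:
    """Read a delimited trial matrix with its JSON sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else Path(str(path) + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta or meta["fs"] is None:
        raise FormatError(f"sidecar {sidecar} lacks the sampling rate 'fs'")
    data = np.atleast_2d(np.loadtxt(path, delimiter=","))
    if np.isnan(data).any():
        raise FormatError(f"{path} contains NaN values")
    names = meta.get("channel_names") or []
    if names and len(names) != data.shape[0]:
        raise FormatError(
            f"{path}: {data.shape[0]} channels in file vs {len(names)} in sidecar"
        )
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channel_names=list(names),
        subject_id=meta.get("subject_id"),
        trial_id=meta.get("trial_id"),
        video_id=meta.get("video_id"),
        valence=meta.get("valence"),
        arousal=meta.get("arousal"),
    )


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a dataset manifest CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "path"]
    if missing:
        raise FormatError(f"manifest missing required columns: {missing}")
    dup = df.duplicated(subset=["subject_id", "trial_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"duplicate (subject, trial) in manifest: ({row['subject_id']}, {row['trial_id']})"
        )
    for col in ("valence", "arousal"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ((vals < 1) | (vals > 9))
        if bad.any():
            raise FormatError(f"{col} ratings outside [1, 9] in manifest")
    return df


def write_dataset(sim: SimulatedDataset, outdir: str | Path) -> Path:
    """Write a simulated dataset: one file per trial, manifest, ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = sim.manifest.copy()
    paths = []
    for rec in sim.recordings:
        fname = f"{rec.subject_id}_{rec.trial_id}.csv"
        write_recording(rec, outdir / fname)
        paths.append(fname)
    manifest["path"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    truth = sim.truth
    truth_json = {
        "templates": truth.templates.tolist(),
        "occurrence_modulation": truth.occurrence_modulation.tolist(),
        "designated_state": truth.designated_state,
        "seed": truth.seed,
        "condition": {f"{s}/{t}": c for (s, t), c in truth.condition.items()},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
    return outdir


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load a full dataset from its manifest (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    df = load_manifest(manifest_path)
    if "path" not in df.columns:
        raise FormatError("manifest lacks a 'path' column; cannot load recordings")
    root = manifest_path.parent
    recordings = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        rec = read_recording(p if p.is_absolute() else root / p)
        if (rec.subject_id, rec.trial_id) != (row["subject_id"], row["trial_id"]):
            raise InvalidInputError(
                f"sidecar identity mismatch for manifest row {row['subject_id']}/{row['trial_id']}"
            )
        recordings.append(rec)
    return Dataset(recordings=recordings, manifest=df.drop(columns=["path"]))


def write_templates(ms: MicrostateSet, path: str | Path) -> Path:
    """Write templates as a channels x K delimited matrix plus JSON metadata."""
    path = Path(path)
    np.savetxt(path, ms.templates.T, delimiter=",")
    meta = {
        "K": ms.K,
        "channel_names": list(ms.channel_names),
        "criterion_value": ms.criterion_value,
        "explained": ms.explained,
        "provenance": _jsonable(ms.provenance),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_templates(path: str | Path) -> MicrostateSet:
    path = Path(path)
    mat = np.atleast_2d(np.loadtxt(path, delimiter=","))
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return MicrostateSet(
        templates=mat.T,
        channel_names=meta.get("channel_names") or [],
        criterion_value=meta.get("criterion_value"),
        explained=meta.get("explained"),
        provenance=meta.get("provenance", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
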