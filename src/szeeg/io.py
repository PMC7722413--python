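"""Reading and writing recordings, cohorts and feature matrices.

Recordings are stored as plain CSV matrices (samples x channels, header
row of channel names) next to a JSON cohort manifest (subject_id, class,
file path, fs).  EDF reading is available when ``mne`` is installed.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .features import FeatureMatrix
from .synthetic import EEGRecording

__all__ = [
    "save_recording_csv",
    "load_recording_csv",
    "read_recording_edf",
    "save_cohort",
    "load_cohort",
    "save_feature_matrix",
    "load_feature_matrix",
]

MANIFEST_NAME = "cohort_manifest.json"


def save_recording_csv(recording: EEGRecording, path: str) -> None:
    """Write one recording as a samples x channels CSV with channel headers."""
    df = pd.DataFrame(recording.data.T, columns=list(recording.channel_names))
    df.to_csv(path, index=False)


def load_recording_csv(path: str, fs: float, class_label: str,
                       subject_id: str | None = None) -> EEGRecording:
    df = pd.read_csv(path)
    return EEGRecording(
        subject_id=subject_id or os.path.splitext(os.path.basename(path))[0],
        class_label=class_label,
        data=df.to_numpy().T,
        fs=fs,
        channel_names=list(df.columns),
    )


def read_recording_edf(path: str, class_label: str,
                       subject_id: str | None = None) -> EEGRecording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ParameterError(
            "reading EDF requires the optional 'mne' dependency; "
            "install szeeg[edf] or convert the file to CSV"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(
        subject_id=subject_id or os.path.splitext(os.path.basename(path))[0],
        class_label=class_label,
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def save_cohort(recordings: Sequence[EEGRecording], out_dir: str) -> str:
    """Write per-subject CSVs plus a JSON manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        save_recording_csv(rec, os.path.join(out_dir, fname))
        entries.append(
            {
                "subject_id": rec.subject_id,
                "class": rec.class_label,
                "path": fname,
                "fs": rec.fs,
            }
        )
    manifest_path = os.path.join(out_dir, MANIFEST_NAME)
    with open(manifest_path, "w") as fh:
        json.dump({"recordings": entries}, fh, indent=2)
    return manifest_path


def load_cohort(cohort_dir: str) -> list[EEGRecording]:
    manifest_path = os.path.join(cohort_dir, MANIFEST_NAME)
    if not os.path.exists(manifest_path):
        raise ParameterError(f"no {MANIFEST_NAME} in {cohort_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    recs = []
    for entry in manifest["recordings"]:
        recs.append(
            load_recording_csv(
                os.path.join(cohort_dir, entry["path"]),
                fs=entry["fs"],
                class_label=entry["class"],
                subject_id=entry["subject_id"],
            )
        )
    return recs


def save_feature_matrix(fm: FeatureMatrix, path_prefix: str) -> None:
    """Write values as CSV (variant-descriptor header) plus a JSON sidecar."""
    cols = [json.dumps(v, sort_keys=True) for v in fm.variants]
    df = pd.DataFrame(fm.values, columns=cols)
    df.insert(0, "segment_index", fm.segment_index)
    df.to_csv(path_prefix + ".csv", index=False)
    with open(path_prefix + ".json", "w") as fh:
        json.dump(
            {
                "method": fm.method,
                "channel": fm.channel,
                "mode": fm.mode,
                "n_imputed": fm.n_imputed,
                "variants": fm.variants,
            },
            fh,
            indent=2,
        )


def load_feature_matrix(path_prefix: str) -> FeatureMatrix:
    with open(path_prefix + ".json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(path_prefix + ".csv")
    seg = df.pop("segment_index").to_numpy(dtype=int)
    return FeatureMatrix(
        method=meta["method"],
        channel=meta["channel"],
        values=df.to_numpy(dtype=float),
        variants=meta["variants"],
        segment_index=seg,
        n_imputed=meta["n_imputed"],
        mode=meta["mode"],
    )
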