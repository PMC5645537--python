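"""Dataset container: per-trial array payloads plus sidecar metadata.

A dataset directory holds

* ``trials.npz`` — one float32 array per trial (``trial_0000`` ...),
* ``metadata.csv`` — one row per trial (subject, condition, trial index,
  onset sample, sampling rate),
* ``dataset.json`` — schema version, montage, timing and generator config.

Round-trips are sample-exact (payloads are stored at the trials' own
float32 precision).  EDF import is available when ``mne`` is installed;
there is no EDF export.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    CohortConfig,
    CohortDataset,
    Montage,
    StimulusTiming,
    TrialRecording,
)

__all__ = ["SchemaError", "write_dataset", "read_dataset", "trial_from_edf"]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """The on-disk layout does not match the supported schema."""


def write_dataset(dataset: CohortDataset, path: str | Path) -> Path:
    """Write the dataset container to ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    payload = {
        f"trial_{i:04d}": tr.data.astype(np.float32)
        for i, tr in enumerate(dataset.trials)
    }
    np.savez(path / "trials.npz", **payload)

    meta = pd.DataFrame(
        {
            "trial": [f"trial_{i:04d}" for i in range(len(dataset.trials))],
            "subject_id": [tr.subject_id for tr in dataset.trials],
            "condition": [tr.condition for tr in dataset.trials],
            "trial_index": [tr.trial_index for tr in dataset.trials],
            "onset_index": [tr.onset_index for tr in dataset.trials],
            "sampling_rate": [tr.sampling_rate for tr in dataset.trials],
        }
    )
    meta.to_csv(path / "metadata.csv", index=False)

    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "montage": {
            "channel_names": list(dataset.montage.channel_names),
            "occipital": list(dataset.montage.occipital),
            "frontal_pair": list(dataset.montage.frontal_pair),
        },
        "timing": dataclasses.asdict(dataset.timing),
        "config": dataclasses.asdict(dataset.config),
        "subject_gains": {str(k): v for k, v in dataset.subject_gains.items()},
    }
    (path / "dataset.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_dataset(path: str | Path) -> CohortDataset:
    """Read a dataset container; raises :class:`SchemaError` on mismatch."""
    path = Path(path)
    sidecar_path = path / "dataset.json"
    if not sidecar_path.exists():
        raise SchemaError(f"no dataset.json in {path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"corrupted sidecar: {exc}") from exc
    version = sidecar.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {version!r} (supported: {SCHEMA_VERSION})"
        )
    for key in ("montage", "timing", "config"):
        if key not in sidecar:
            raise SchemaError(f"sidecar missing required key {key!r}")

    montage = Montage(
        channel_names=tuple(sidecar["montage"]["channel_names"]),
        occipital=tuple(sidecar["montage"]["occipital"]),
        frontal_pair=tuple(sidecar["montage"]["frontal_pair"]),
    )
    timing = StimulusTiming(**sidecar["timing"])
    config = CohortConfig(**sidecar["config"])
    gains = {int(k): float(v) for k, v in sidecar.get("subject_gains", {}).items()}

    meta = pd.read_csv(path / "metadata.csv")
    with np.load(path / "trials.npz") as payload:
        trials = [
            TrialRecording(
                subject_id=int(row.subject_id),
                condition=str(row.condition),
                data=payload[row.trial],
                sampling_rate=float(row.sampling_rate),
                onset_index=int(row.onset_index),
                trial_index=int(row.trial_index),
            )
            for row in meta.itertuples(index=False)
        ]
    return CohortDataset(
        trials=trials, montage=montage, timing=timing, config=config,
        subject_gains=gains,
    )


def trial_from_edf(
    path: str | Path,
    subject_id: int = 0,
    condition: str = "marker_viewing",
    onset_index: int = 0,
) -> TrialRecording:
    """Import one trial from an EDF recording (requires the ``edf`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "EDF import requires mne; install the 'edf' extra"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_volts = raw.get_data()
    return TrialRecording(
        subject_id=subject_id,
        condition=condition,
        data=(data_volts * 1e6).astype(np.float32),  # volts -> µV
        sampling_rate=float(raw.info["sfreq"]),
        onset_index=onset_index,
    )
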