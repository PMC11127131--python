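"""Cohort container I/O and YAML configuration.

One HDF5 file per participant holds the recording: datasets ``signals``
(n_modalities x n_samples) and ``labels`` (n_samples), with attributes
``participant_id`` and ``fs``. The same reader accepts user-converted real
recordings laid out this way, so synthetic and real cohorts flow through an
identical pipeline. This container layout is this package's own
convention.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .model import ModelConfig
from .synth import Cohort, CohortConfig, Recording
from .train import TrainConfig


def save_recording(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=recording.signals)
        f.create_dataset("labels", data=recording.labels)
        f.attrs["participant_id"] = recording.participant_id
        f.attrs["fs"] = recording.sampling_rate


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            participant_id=str(f.attrs["participant_id"]),
            signals=f["signals"][:],
            labels=f["labels"][:].astype(np.int64),
            sampling_rate=float(f.attrs["fs"]),
        )


def save_cohort(cohort: Cohort, directory) -> list[Path]:
    """One file per participant: <directory>/<participant_id>.h5."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in cohort.recordings:
        p = d / f"{rec.participant_id}.h5"
        save_recording(rec, p)
        paths.append(p)
    return paths


def load_cohort(directory, config: CohortConfig | None = None) -> Cohort:
    """Read every *.h5 participant file in the directory (sorted by name)."""
    d = Path(directory)
    paths = sorted(d.glob("*.h5"))
    if not paths:
        raise FileNotFoundError(f"no participant files (*.h5) in {d}")
    recordings = [load_recording(p) for p in paths]
    if config is None:
        fs = recordings[0].sampling_rate
        n0 = recordings[0].n_samples
        config = CohortConfig(
            n_participants=len(recordings),
            sampling_rate=fs,
            duration=n0 / fs,
            n_modalities=recordings[0].n_modalities,
        )
    return Cohort(recordings=recordings, config=config)


def load_configs(path) -> tuple[CohortConfig, ModelConfig, TrainConfig]:
    """YAML with optional sections ``cohort``, ``model``, ``train``."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cohort_kwargs = raw.get("cohort", {})
    if "class_fractions" in cohort_kwargs:
        cohort_kwargs["class_fractions"] = tuple(cohort_kwargs["class_fractions"])
    return (
        CohortConfig(**cohort_kwargs),
        ModelConfig(**raw.get("model", {})),
        TrainConfig(**raw.get("train", {})),
    )


def save_configs(path, cohort: CohortConfig, model: ModelConfig,
                 train: TrainConfig) -> None:
    from dataclasses import asdict

    doc = {"cohort": asdict(cohort), "model": asdict(model), "train": asdict(train)}
    doc["cohort"]["class_fractions"] = list(doc["cohort"]["class_fractions"])
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)
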