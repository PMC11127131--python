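"""Normalization and sliding-window segmentation.

Each modality is z-scored to mean 0, SD 1 (population convention), then the
recording is cut into 64-sample intervals with 50% overlap between
consecutive intervals. A candidate interval is kept only if all 64
underlying samples share one annotation, so every interval carries a single
affective state; candidates straddling a state change are discarded, never
truncated.

Normalization scope defaults to the participant's full recording, computed
before any train/val/test split and held identical across all three
evaluation protocols so the personalized-vs-generalized comparison is not
confounded by differing statistics. A sample-range scope is available for
leakage-sensitive use (compute statistics on the training portion only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .synth import Cohort, Recording

WINDOW = 64
DEFAULT_OVERLAP = 0.5


class DegenerateModalityError(ValueError):
    """A modality has zero variance over the normalization scope."""


@dataclass(frozen=True)
class NormStats:
    """Per-modality mean/SD used for normalization, kept for reuse."""

    mean: np.ndarray  # [n_modalities]
    sd: np.ndarray  # [n_modalities]
    scope: str


def zscore_normalize(
    recording: Recording, stats_scope: str | slice = "recording"
) -> tuple[Recording, NormStats]:
    """Z-score each modality; returns the normalized recording and its stats.

    ``stats_scope`` is ``"recording"`` (statistics over the full recording,
    the default) or a slice of sample indices to compute statistics from
    (e.g. the training portion); the transform is always applied to the
    whole recording. SD uses the population convention (divide by n).
    """
    if isinstance(stats_scope, slice):
        ref = recording.signals[:, stats_scope]
        scope_name = f"samples[{stats_scope.start}:{stats_scope.stop}]"
    elif stats_scope == "recording":
        ref = recording.signals
        scope_name = "recording"
    else:
        raise ValueError(f"unknown stats_scope: {stats_scope!r}")

    mean = ref.mean(axis=1)
    sd = ref.std(axis=1)  # population SD
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateModalityError(
            f"modality index {bad[0]} is constant over scope '{scope_name}' "
            "(SD = 0); cannot z-score"
        )
    normalized = (recording.signals - mean[:, None]) / sd[:, None]
    out = Recording(
        participant_id=recording.participant_id,
        signals=normalized,
        labels=recording.labels,
        sampling_rate=recording.sampling_rate,
    )
    return out, NormStats(mean=mean, sd=sd, scope=scope_name)


def apply_stats(recording: Recording, stats: NormStats) -> Recording:
    """Apply previously computed normalization statistics to a recording."""
    normalized = (recording.signals - stats.mean[:, None]) / stats.sd[:, None]
    return Recording(
        participant_id=recording.participant_id,
        signals=normalized,
        labels=recording.labels,
        sampling_rate=recording.sampling_rate,
    )


def window_count(segment_length: int, window: int = WINDOW, stride: int = 32) -> int:
    """Number of stride-spaced windows fully inside a uniform segment.

    Closed form: floor((segment_length - window)/stride) + 1 for
    segment_length >= window, else 0.
    """
    if segment_length < 0:
        raise ValueError("segment_length must be >= 0")
    if segment_length < window:
        return 0
    return (segment_length - window) // stride + 1


@dataclass(frozen=True)
class Interval:
    """A fixed-length uniformly-labeled slice of one recording."""

    data: np.ndarray  # [n_modalities, window]
    label: int
    participant_id: str
    start_index: int


@dataclass
class WindowedDataset:
    """Uniformly-labeled intervals from one or more recordings.

    Array-of-structs layout: ``X`` [N, n_modalities, window], ``y`` [N],
    ``participant`` [N] (string labels), ``start`` [N] (0-based sample
    offsets). Within one participant intervals are in nondecreasing
    ``start`` order. ``provenance`` maps participant_id -> NormStats.
    """

    X: np.ndarray
    y: np.ndarray
    participant: np.ndarray
    start: np.ndarray
    window: int = WINDOW
    provenance: dict[str, NormStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.X) == len(self.participant) == len(self.start) == n):
            raise ValueError("X, y, participant, start must share length")

    def __len__(self) -> int:
        return len(self.y)

    def __getitem__(self, i: int) -> Interval:
        return Interval(
            data=self.X[i],
            label=int(self.y[i]),
            participant_id=str(self.participant[i]),
            start_index=int(self.start[i]),
        )

    @property
    def participant_ids(self) -> list[str]:
        """Unique participants in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.participant:
            seen.setdefault(str(p), None)
        return list(seen)

    def indices_of(self, participant_id: str) -> np.ndarray:
        return np.flatnonzero(self.participant == participant_id)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X)
            f.create_dataset("y", data=self.y)
            f.create_dataset(
                "participant", data=np.asarray(self.participant, dtype="S")
            )
            f.create_dataset("start", data=self.start)
            f.attrs["window"] = self.window

    @classmethod
    def load(cls, path) -> "WindowedDataset":
        with h5py.File(path, "r") as f:
            return cls(
                X=f["X"][:],
                y=f["y"][:],
                participant=f["participant"][:].astype("U"),
                start=f["start"][:],
                window=int(f.attrs["window"]),
            )


def slide_windows(
    recording: Recording,
    window: int = WINDOW,
    overlap: float = DEFAULT_OVERLAP,
) -> WindowedDataset:
    """Segment one recording into uniformly-annotated overlapping intervals.

    Candidate windows start at 0, stride, 2*stride, ... with
    stride = window * (1 - overlap); a candidate is kept iff all ``window``
    samples share one annotation, and then carries that annotation. A
    recording shorter than one window yields an empty dataset with a
    warning.
    """
    if window % 2 != 0:
        raise ValueError("window must be even")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    stride_f = window * (1.0 - overlap)
    if abs(stride_f - round(stride_f)) > 1e-9:
        raise ValueError(
            f"window * (1 - overlap) = {stride_f} is not an integer stride"
        )
    stride = int(round(stride_f))

    n = recording.n_samples
    if n < window:
        warnings.warn(
            f"recording {recording.participant_id} has {n} < {window} samples; "
            "empty dataset",
            stacklevel=2,
        )
        empty = np.empty((0, recording.n_modalities, window))
        return WindowedDataset(
            X=empty,
            y=np.empty(0, dtype=np.int64),
            participant=np.empty(0, dtype="U8"),
            start=np.empty(0, dtype=np.int64),
            window=window,
        )

    starts = np.arange(0, n - window + 1, stride)
    labels = recording.labels
    keep, kept_labels = [], []
    for s in starts:
        seg = labels[s : s + window]
        if (seg == seg[0]).all():
            keep.append(s)
            kept_labels.append(seg[0])
    keep_arr = np.asarray(keep, dtype=np.int64)
    X = np.stack([recording.signals[:, s : s + window] for s in keep_arr]) if keep else (
        np.empty((0, recording.n_modalities, window))
    )
    return WindowedDataset(
        X=X,
        y=np.asarray(kept_labels, dtype=np.int64),
        participant=np.full(len(keep_arr), recording.participant_id),
        start=keep_arr,
        window=window,
    )


def prepare_cohort(
    cohort: Cohort,
    window: int = WINDOW,
    overlap: float = DEFAULT_OVERLAP,
    stats_scope: str | slice = "recording",
) -> WindowedDataset:
    """Normalize every recording, window it, and concatenate the results."""
    parts, stats_by_pid = [], {}
    for rec in cohort.recordings:
        norm, stats = zscore_normalize(rec, stats_scope)
        stats_by_pid[rec.participant_id] = stats
        parts.append(slide_windows(norm, window=window, overlap=overlap))
    nonempty = [p for p in parts if len(p)]
    if not nonempty:
        raise ValueError("no recording produced any interval")
    ws = WindowedDataset(
        X=np.concatenate([p.X for p in nonempty]),
        y=np.concatenate([p.y for p in nonempty]),
        participant=np.concatenate([p.participant for p in nonempty]),
        start=np.concatenate([p.start for p in nonempty]),
        window=window,
        provenance=stats_by_pid,
    )
    return ws
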