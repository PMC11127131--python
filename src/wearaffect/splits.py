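"""Train/validation/test protocols for comparing personalization regimes.

Three protocols over a WindowedDataset, all sharing one per-participant
test set so their metrics are directly comparable:

* **personalized** — train, validation and test all come from the test
  participant's own recording.
* **participant_inclusive** — train/validation pool every participant's
  early intervals (the test participant overlaps with training).
* **participant_exclusive** — train/validation pool every participant
  *except* the test participant.

Within each (participant, class) the split is sequential in time, never
random: the initial 70% of that class's intervals go to training, the next
15% to validation, and the final 15% to test. Sequential allocation keeps
adjacent (hence feature-correlated) intervals inside one set, and per-class
allocation keeps the relative class frequencies consistent across the three
sets. Counts use floor for train and validation with the remainder to test,
applied identically everywhere.

Consecutive intervals overlap by half a window, so the last training
interval and the first validation interval of a class share samples; this
is inherent to splitting intervals rather than samples and is accepted by
default. ``boundary_gap=True`` drops one interval at each set boundary for
users who want sample-disjoint sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .preprocess import WindowedDataset
from .synth import N_STATES

PROTOCOLS = ("personalized", "participant_inclusive", "participant_exclusive")
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


class ProtocolError(ValueError):
    """Split request cannot be satisfied by the dataset."""


@dataclass
class DataSplit:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    protocol: str
    test_participant: str
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS

    def __post_init__(self) -> None:
        tr, va, te = map(set, (self.train, self.val, self.test))
        if tr & va or va & te or tr & te:
            raise ProtocolError("train/val/test index sets must be disjoint")

    def to_manifest(self) -> dict:
        return {
            "protocol": self.protocol,
            "test_participant": self.test_participant,
            "fractions": list(self.fractions),
            "train": [int(i) for i in self.train],
            "val": [int(i) for i in self.val],
            "test": [int(i) for i in self.test],
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_manifest(), f)

    @classmethod
    def from_manifest(cls, path) -> "DataSplit":
        with open(path) as f:
            d = json.load(f)
        return cls(
            train=np.asarray(d["train"], dtype=np.int64),
            val=np.asarray(d["val"], dtype=np.int64),
            test=np.asarray(d["test"], dtype=np.int64),
            protocol=d["protocol"],
            test_participant=d["test_participant"],
            fractions=tuple(d["fractions"]),
        )


def stratified_sequential_split(
    indices_by_class: dict[int, np.ndarray],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    boundary_gap: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per class: first floor(f_train*n) indices, next floor(f_val*n), rest.

    ``indices_by_class`` maps class -> time-ordered index array. Every class
    must contribute at least 3 intervals (one per set). With
    ``boundary_gap`` the last train and last val interval of each class are
    dropped so half-overlapping neighbours never span a set boundary.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    first, middle, last = [], [], []
    for cls in sorted(indices_by_class):
        idx = np.asarray(indices_by_class[cls])
        n = len(idx)
        if n < 3:
            raise ProtocolError(
                f"class {cls} has only {n} interval(s); need >= 3 to split"
            )
        # epsilon guards the exact-decimal floor against float error
        # (0.70 * 530 = 370.999...94 must still floor to 371)
        n_train = int(np.floor(fractions[0] * n + 1e-9))
        n_val = int(np.floor(fractions[1] * n + 1e-9))
        tr = idx[:n_train]
        va = idx[n_train : n_train + n_val]
        if boundary_gap:
            tr, va = tr[:-1], va[:-1]
        first.append(tr)
        middle.append(va)
        last.append(idx[n_train + n_val :])
    return (
        np.concatenate(first),
        np.concatenate(middle),
        np.concatenate(last),
    )


def _indices_by_class(ws: WindowedDataset, idx: np.ndarray) -> dict[int, np.ndarray]:
    """Class -> indices (subset of idx) in time order; requires idx time-ordered."""
    return {
        c: idx[ws.y[idx] == c]
        for c in range(N_STATES)
        if (ws.y[idx] == c).any()
    }


def _participant_split(
    ws: WindowedDataset,
    participant: str,
    fractions: tuple[float, float, float],
    boundary_gap: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = ws.indices_of(participant)
    if idx.size == 0:
        raise ProtocolError(f"unknown participant: {participant!r}")
    order = np.argsort(ws.start[idx], kind="stable")
    return stratified_sequential_split(
        _indices_by_class(ws, idx[order]), fractions, boundary_gap
    )


def split_personalized(
    ws: WindowedDataset,
    participant: str,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    boundary_gap: bool = False,
) -> DataSplit:
    """All three sets from the test participant's own intervals."""
    tr, va, te = _participant_split(ws, participant, fractions, boundary_gap)
    return DataSplit(tr, va, te, "personalized", participant, fractions)


def split_participant_inclusive(
    ws: WindowedDataset,
    test_participant: str,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    boundary_gap: bool = False,
) -> DataSplit:
    """Train/val from every participant's early intervals; test from one.

    The test participant's early intervals are in training, so the
    participant sets of train and test overlap by exactly that participant.
    """
    pids = ws.participant_ids
    if len(pids) < 2:
        raise ProtocolError("participant_inclusive requires >= 2 participants")
    if test_participant not in pids:
        raise ProtocolError(f"unknown participant: {test_participant!r}")
    trains, vals = [], []
    test = None
    for pid in pids:
        tr, va, te = _participant_split(ws, pid, fractions, boundary_gap)
        trains.append(tr)
        vals.append(va)
        if pid == test_participant:
            test = te
    return DataSplit(
        np.concatenate(trains),
        np.concatenate(vals),
        test,
        "participant_inclusive",
        test_participant,
        fractions,
    )


def split_participant_exclusive(
    ws: WindowedDataset,
    test_participant: str,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    boundary_gap: bool = False,
) -> DataSplit:
    """Train/val from all other participants; test from the held-out one.

    Train/test participant sets are mutually exclusive — the defining
    property of the protocol.
    """
    pids = ws.participant_ids
    if len(pids) < 2:
        raise ProtocolError("participant_exclusive requires >= 2 participants")
    if test_participant not in pids:
        raise ProtocolError(f"unknown participant: {test_participant!r}")
    trains, vals = [], []
    test = None
    for pid in pids:
        tr, va, te = _participant_split(ws, pid, fractions, boundary_gap)
        if pid == test_participant:
            test = te
        else:
            trains.append(tr)
            vals.append(va)
    return DataSplit(
        np.concatenate(trains),
        np.concatenate(vals),
        test,
        "participant_exclusive",
        test_participant,
        fractions,
    )


def make_split(
    ws: WindowedDataset,
    protocol: str,
    test_participant: str,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
) -> DataSplit:
    if protocol == "personalized":
        return split_personalized(ws, test_participant, fractions)
    if protocol == "participant_inclusive":
        return split_participant_inclusive(ws, test_participant, fractions)
    if protocol == "participant_exclusive":
        return split_participant_exclusive(ws, test_participant, fractions)
    raise ValueError(f"unknown protocol: {protocol!r}; expected one of {PROTOCOLS}")
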