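"""Training and the three-protocol experiment runner.

Every model — personalized, participant-inclusive generalized,
participant-exclusive generalized — is trained with cross-entropy loss and
AdamW under one shared set of hyperparameters and one shared initialization
seed, so that the only variable separating the protocols is which data each
model sees. After every epoch the validation loss is evaluated in eval
mode; the parameter state with the lowest validation loss is the checkpoint
used for testing (ties break to the earliest epoch).

An n-participant comparison runs n personalized models, n
participant-exclusive models (one per held-out participant), and a single
participant-inclusive model evaluated against every participant's test set:
n + n + 1 training runs in total.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .model import Classifier, ModelConfig, build_model, cross_entropy
from .preprocess import WindowedDataset
from .splits import PROTOCOLS, DataSplit, make_split


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


class TrainingProtocolError(ValueError):
    """Split/dataset unusable for training."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters, shared across protocols.

    ``max_epochs`` may go up to 1000 for full-scale runs; the default is a
    desk-scale profile. Learning rate, weight decay and batch size are
    conventional AdamW settings exposed here so they can be held constant
    across protocols.
    """

    max_epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.max_epochs <= 1000:
            raise ValueError("max_epochs must lie in [1, 1000]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class AdamW:
    """AdamW with decoupled weight decay over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], tc: TrainConfig):
        self.tc = tc
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        tc = self.tc
        self.t += 1
        bc1 = 1.0 - tc.beta1**self.t
        bc2 = 1.0 - tc.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= tc.beta1
            m += (1.0 - tc.beta1) * g
            v *= tc.beta2
            v += (1.0 - tc.beta2) * g * g
            p -= tc.learning_rate * tc.weight_decay * p  # decoupled decay
            p -= tc.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + tc.eps)


@dataclass
class TrainedRun:
    """Outcome of one training run: best checkpoint plus its history."""

    model: Classifier
    history: list[dict]  # per-epoch {"epoch", "train_loss", "val_loss"}
    best_epoch: int
    best_val_loss: float
    protocol: str
    test_participant: str

    def manifest(self, model_config: ModelConfig, train_config: TrainConfig) -> dict:
        return {
            "protocol": self.protocol,
            "test_participant": self.test_participant,
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
            "model_config": asdict(model_config),
            "train_config": asdict(train_config),
        }


def _eval_loss(model: Classifier, X: np.ndarray, y: np.ndarray,
               batch_size: int = 512) -> float:
    total = 0.0
    for i in range(0, len(y), batch_size):
        logits = model.forward(X[i : i + batch_size])
        loss, _ = cross_entropy(logits, y[i : i + batch_size])
        total += loss * len(y[i : i + batch_size])
    return total / len(y)


def train(
    model: Classifier,
    split: DataSplit,
    ws: WindowedDataset,
    tc: TrainConfig,
) -> TrainedRun:
    """Optimize the model on the split's training set, checkpoint on val loss.

    Fully deterministic given ``tc.seed`` on a fixed device: the seed drives
    minibatch shuffling and dropout. The returned model carries the
    parameters of the epoch with minimum validation loss (earliest on ties).
    """
    if len(split.train) == 0 or len(split.val) == 0:
        raise TrainingProtocolError("train and val sets must be nonempty")
    Xtr, ytr = ws.X[split.train], ws.y[split.train]
    Xva, yva = ws.X[split.val], ws.y[split.val]

    rng = np.random.default_rng(tc.seed)
    opt = AdamW(model.parameters(), tc)
    history: list[dict] = []
    best_state = model.get_state()
    best_val = np.inf
    best_epoch = 0
    since_best = 0

    for epoch in range(1, tc.max_epochs + 1):
        perm = rng.permutation(len(ytr))
        running = 0.0
        for i in range(0, len(perm), tc.batch_size):
            batch = perm[i : i + tc.batch_size]
            logits = model.forward(Xtr[batch], train=True, rng=rng)
            loss, dlogits = cross_entropy(logits, ytr[batch])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(learning_rate={tc.learning_rate})"
                )
            model.backward(dlogits)
            opt.step(model.parameters(), model.gradients())
            running += loss * len(batch)
        val_loss = _eval_loss(model, Xva, yva)
        if not np.isfinite(val_loss):
            raise DivergenceError(
                f"non-finite validation loss at epoch {epoch} "
                f"(learning_rate={tc.learning_rate})"
            )
        history.append(
            {"epoch": epoch, "train_loss": running / len(ytr), "val_loss": val_loss}
        )
        if val_loss < best_val:  # strict: earliest epoch wins ties
            best_val = val_loss
            best_state = model.get_state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if tc.early_stop_patience is not None and since_best >= tc.early_stop_patience:
                break

    model.set_state(best_state)
    return TrainedRun(
        model=model,
        history=history,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        protocol=split.protocol,
        test_participant=split.test_participant,
    )


def default_trainer(
    split: DataSplit, ws: WindowedDataset, mc: ModelConfig, tc: TrainConfig
) -> TrainedRun:
    """Build a freshly initialized model (seed = tc.seed) and train it."""
    return train(build_model(mc, seed=tc.seed), split, ws, tc)


@dataclass
class EvaluatedRun:
    """One (protocol, test participant) cell: predictions on the shared test set."""

    protocol: str
    test_participant: str
    test_indices: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    best_epoch: int
    best_val_loss: float


def run_protocol(
    ws: WindowedDataset,
    protocol: str,
    model_config: ModelConfig,
    train_config: TrainConfig,
    trainer=default_trainer,
) -> list[EvaluatedRun]:
    """Run one protocol over every participant of the dataset.

    personalized / participant_exclusive: one training run per participant.
    participant_inclusive: a single training run whose checkpoint is
    evaluated against every participant's test set. All runs share
    ``model_config`` and ``train_config`` (including the init seed).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol: {protocol!r}")
    pids = ws.participant_ids
    if protocol != "personalized" and len(pids) < 2:
        raise TrainingProtocolError(f"{protocol} requires >= 2 participants")

    results: list[EvaluatedRun] = []
    if protocol == "participant_inclusive":
        split = make_split(ws, protocol, pids[0])
        run = trainer(split, ws, model_config, train_config)
        for pid in pids:
            test_idx = make_split(ws, protocol, pid).test
            y_pred = run.model.predict(ws.X[test_idx])
            results.append(
                EvaluatedRun(protocol, pid, test_idx, ws.y[test_idx], y_pred,
                             run.best_epoch, run.best_val_loss)
            )
    else:
        for pid in pids:
            split = make_split(ws, protocol, pid)
            run = trainer(split, ws, model_config, train_config)
            y_pred = run.model.predict(ws.X[split.test])
            results.append(
                EvaluatedRun(protocol, pid, split.test, ws.y[split.test], y_pred,
                             run.best_epoch, run.best_val_loss)
            )
    return results


def run_comparison(
    ws: WindowedDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    protocols: tuple[str, ...] = PROTOCOLS,
    trainer=default_trainer,
) -> dict[str, list[EvaluatedRun]]:
    """All protocols under identical hyperparameters and init seed."""
    return {
        proto: run_protocol(ws, proto, model_config, train_config, trainer)
        for proto in protocols
    }
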