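"""Metrics, summary statistics, significance tests and diagnostics.

Accuracy and macro-averaged F1 are computed from a 3x3 confusion matrix
(rows = true class, columns = predicted class) and reported in percent.
Macro F1 — the unweighted mean over classes of the per-class harmonic mean
of precision and recall — is the imbalance-sensitive convention for a
3-class task with skewed class frequencies; a weighted variant is available
by flag. Per-class F1 is 0 when precision + recall = 0 (the degenerate
class is logged).

Protocol comparisons use two-tailed t tests on participant-aligned metric
vectors: paired by default (the design is within-participant), with the
unpaired two-sample variant available. No multiple-testing correction is
applied by default; a Bonferroni factor is available by flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import WindowedDataset
from .synth import MODALITY_NAMES, N_STATES, STATE_NAMES, Cohort

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion matrix, accuracy, F1


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = N_STATES) -> np.ndarray:
    """Counts[i, j] = #(true class i predicted as class j)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Percent of test intervals on the diagonal: 100 * trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm)) / float(total)


def f1_score(cm: np.ndarray, averaging: str = "macro") -> float:
    """Percent F1 from a confusion matrix; macro (default) or weighted.

    Per class c: precision = cm[c,c]/column_sum, recall = cm[c,c]/row_sum,
    F1_c = 2PR/(P+R), with the 0-convention when P+R = 0 (flagged in the
    log, since it means the class was never predicted and never recalled).
    """
    cm = np.asarray(cm, dtype=float)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm)
    pred_tot = cm.sum(axis=0)
    true_tot = cm.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)
    degenerate = np.flatnonzero(pr == 0)
    for c in degenerate:
        logger.warning(
            "class %d has precision + recall = 0; its F1 set to 0 by convention", c
        )
    if averaging == "macro":
        return 100.0 * float(f1.mean())
    if averaging == "weighted":
        w = true_tot / true_tot.sum()
        return 100.0 * float((f1 * w).sum())
    raise ValueError(f"unknown averaging: {averaging!r}")


def summarize(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator) of a metric vector."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values for a sample SD")
    return float(v.mean()), float(v.std(ddof=1))


# ---------------------------------------------------------------------------
# significance tests


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    paired: bool
    defined: bool = True
    note: str = ""


def t_test(a, b, paired: bool = True) -> TTestResult:
    """Two-tailed t test between two participant-aligned metric vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test needs equal-length aligned vectors")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            return TTestResult(
                t=np.nan, df=len(d) - 1, p=np.nan, paired=True, defined=False,
                note="zero-variance difference vector; paired p undefined",
            )
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), True)
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        return TTestResult(
            t=np.nan, df=len(a) + len(b) - 2, p=np.nan, paired=False, defined=False,
            note="both samples have zero variance; p undefined",
        )
    res = stats.ttest_ind(a, b)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), False)


def pairwise_t_tests(
    metric_by_protocol: dict[str, np.ndarray],
    paired: bool = True,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Two-tailed t tests for every protocol pair on aligned metric vectors."""
    names = list(metric_by_protocol)
    lengths = {len(np.asarray(metric_by_protocol[n])) for n in names}
    if len(lengths) > 1:
        raise ValueError("metric vectors must be participant-aligned (equal length)")
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        r = t_test(metric_by_protocol[a], metric_by_protocol[b], paired=paired)
        p = r.p * n_pairs if (bonferroni and r.defined) else r.p
        rows.append(
            {
                "protocol_a": a,
                "protocol_b": b,
                "t": r.t,
                "df": r.df,
                "p": min(p, 1.0) if r.defined else np.nan,
                "paired": r.paired,
                "defined": r.defined,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diagnostics


def modality_profiles(
    data: Cohort | WindowedDataset, k: float = 2.0
) -> pd.DataFrame:
    """State-conditional mean/SD per (participant, class, modality) + flags.

    A cell is flagged when its mean deviates from the leave-one-out
    cross-participant mean of that (class, modality) by more than ``k``
    leave-one-out SDs — the diagnostic used to explain participants whose
    personalized models underperform. Leave-one-out reference statistics
    keep a genuine outlier from inflating its own yardstick (with few
    participants a pooled SD can never exceed ~sqrt(n) no matter how far
    the outlier sits). With fewer than 3 participants no reference SD
    exists; flags are absent and a warning is emitted.
    """
    rows = []
    if isinstance(data, Cohort):
        for rec in data.recordings:
            for s in range(N_STATES):
                mask = rec.labels == s
                for m in range(rec.n_modalities):
                    name = MODALITY_NAMES[m] if m < len(MODALITY_NAMES) else f"ch{m}"
                    if mask.any():
                        vals = rec.signals[m, mask]
                        rows.append((rec.participant_id, STATE_NAMES[s], name,
                                     vals.mean(), vals.std(), True))
                    else:
                        rows.append((rec.participant_id, STATE_NAMES[s], name,
                                     np.nan, np.nan, False))
    else:
        ws = data
        for pid in ws.participant_ids:
            idx = ws.indices_of(pid)
            for s in range(N_STATES):
                sel = idx[ws.y[idx] == s]
                for m in range(ws.X.shape[1]):
                    name = MODALITY_NAMES[m] if m < len(MODALITY_NAMES) else f"ch{m}"
                    if sel.size:
                        vals = ws.X[sel, m, :]
                        rows.append((pid, STATE_NAMES[s], name,
                                     vals.mean(), vals.std(), True))
                    else:
                        rows.append((pid, STATE_NAMES[s], name, np.nan, np.nan, False))
    df = pd.DataFrame(
        rows, columns=["participant", "state", "modality", "mean", "sd", "present"]
    )

    n_participants = df["participant"].nunique()
    if n_participants < 3:
        warnings.warn(
            "fewer than 3 participants (single participant gives no "
            "cross-participant SD at all); deviation flags absent",
            stacklevel=2,
        )
        df["deviation_z"] = np.nan
        df["flagged"] = pd.array([pd.NA] * len(df), dtype="boolean")
        return df

    def _loo_z(group: pd.Series) -> pd.Series:
        x = group.to_numpy(dtype=float)
        n = len(x)
        z = np.full(n, np.nan)
        for i in range(n):
            rest = np.delete(x, i)
            sd = rest.std(ddof=1)
            if sd > 0:
                z[i] = (x[i] - rest.mean()) / sd
        return pd.Series(z, index=group.index)

    df["deviation_z"] = np.nan
    present = df["present"]
    z = (
        df[present]
        .groupby(["state", "modality"], group_keys=False)["mean"]
        .apply(_loo_z)
    )
    df.loc[present, "deviation_z"] = z
    flagged = pd.array(df["deviation_z"].abs() > k, dtype="boolean")
    flagged[~present.to_numpy() | df["deviation_z"].isna().to_numpy()] = pd.NA
    df["flagged"] = flagged
    return df


def class_balance_report(ws: WindowedDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant class percentages plus cross-participant min-max ranges."""
    if len(ws) == 0:
        raise ValueError("empty dataset")
    rows = []
    for pid in ws.participant_ids:
        idx = ws.indices_of(pid)
        frac = [100.0 * np.mean(ws.y[idx] == c) for c in range(N_STATES)]
        rows.append({"participant": pid, **dict(zip(STATE_NAMES, frac))})
    per = pd.DataFrame(rows)
    if any((per[s] == 0).all() or (per[s] == 100).all() for s in STATE_NAMES):
        warnings.warn("degenerate class distribution (a class is absent or total)",
                      stacklevel=2)
    ranges = pd.DataFrame(
        {
            "state": STATE_NAMES,
            "min_pct": [per[s].min() for s in STATE_NAMES],
            "max_pct": [per[s].max() for s in STATE_NAMES],
        }
    )
    return per, ranges
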