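"""Assemble experiment results into metric tables and serialized reports.

Mirrors the layout of the study's result tables: a per-participant
accuracy table and F1 table (one column per protocol), a summary table of
mean (SD) per protocol, a p-value table of pairwise protocol comparisons,
and a per-participant class-balance table with cross-participant ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import (
    accuracy,
    class_balance_report,
    confusion_matrix,
    f1_score,
    pairwise_t_tests,
    summarize,
)
from .preprocess import WindowedDataset
from .train import EvaluatedRun


@dataclass
class MetricsTable:
    """Per-participant metrics, per-protocol summaries and p-values."""

    per_participant: pd.DataFrame  # protocol, participant, accuracy, f1
    summary: pd.DataFrame  # protocol, accuracy_mean, accuracy_sd, f1_mean, f1_sd
    p_values: pd.DataFrame  # pairwise tests for both metrics

    def metric_vector(self, protocol: str, metric: str) -> np.ndarray:
        df = self.per_participant
        sel = df[df["protocol"] == protocol].sort_values("participant")
        return sel[metric].to_numpy()


def build_metrics_table(
    results: dict[str, list[EvaluatedRun]], paired: bool = True
) -> MetricsTable:
    """Score every (protocol, participant) run and attach summaries/tests."""
    rows = []
    for proto, runs in results.items():
        for r in runs:
            cm = confusion_matrix(r.y_true, r.y_pred)
            rows.append(
                {
                    "protocol": proto,
                    "participant": r.test_participant,
                    "accuracy": accuracy(cm),
                    "f1": f1_score(cm),
                    "n_test": int(cm.sum()),
                    "best_epoch": r.best_epoch,
                }
            )
    per = pd.DataFrame(rows)

    summary_rows = []
    for proto in results:
        sub = per[per["protocol"] == proto]
        acc_m, acc_sd = summarize(sub["accuracy"])
        f1_m, f1_sd = summarize(sub["f1"])
        summary_rows.append(
            {
                "protocol": proto,
                "accuracy_mean": acc_m,
                "accuracy_sd": acc_sd,
                "f1_mean": f1_m,
                "f1_sd": f1_sd,
            }
        )
    summary = pd.DataFrame(summary_rows)

    pv_frames = []
    for metric in ("accuracy", "f1"):
        vectors = {
            proto: per[per["protocol"] == proto]
            .sort_values("participant")[metric]
            .to_numpy()
            for proto in results
        }
        pv = pairwise_t_tests(vectors, paired=paired)
        pv.insert(0, "metric", metric)
        pv_frames.append(pv)
    p_values = pd.concat(pv_frames, ignore_index=True)
    return MetricsTable(per_participant=per, summary=summary, p_values=p_values)


def write_report(
    table: MetricsTable,
    out_dir,
    ws: WindowedDataset | None = None,
    float_format: str = "%.6f",
) -> dict:
    """Write CSV tables + a JSON bundle; returns the bundle as a dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    acc = table.per_participant.pivot(
        index="participant", columns="protocol", values="accuracy"
    ).sort_index()
    f1 = table.per_participant.pivot(
        index="participant", columns="protocol", values="f1"
    ).sort_index()
    acc.to_csv(out / "table_accuracy.csv", float_format=float_format)
    f1.to_csv(out / "table_f1.csv", float_format=float_format)
    table.summary.to_csv(out / "table_summary.csv", index=False,
                         float_format=float_format)
    table.p_values.to_csv(out / "table_p_values.csv", index=False,
                          float_format=float_format)
    if ws is not None:
        per, ranges = class_balance_report(ws)
        per.to_csv(out / "class_balance_per_participant.csv", index=False,
                   float_format=float_format)
        ranges.to_csv(out / "class_balance_ranges.csv", index=False,
                      float_format=float_format)

    bundle = {
        "per_participant": table.per_participant.to_dict(orient="records"),
        "summary": table.summary.to_dict(orient="records"),
        "p_values": table.p_values.replace({np.nan: None}).to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as f:
        json.dump(bundle, f, indent=2)
    return bundle
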