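"""Train and evaluate the three protocols on a windowed dataset.

Runs n personalized models, n participant-exclusive generalized models and
one participant-inclusive generalized model (n + n + 1 training runs),
every model sharing the same architecture, hyperparameters and
initialization seed, and every protocol tested on the same per-participant
test sets. Writes the per-participant accuracy/F1 tables, the per-protocol
summary, and the paired-t-test table under --out.

Usage:
    python analysis/03_train_protocols.py [--windows scratch/windows.h5]
        [--out results/tables] [--seed 0] [--epochs 80] [--patience 15]
"""

import argparse
import time
from pathlib import Path

from wearaffect import ModelConfig, TrainConfig, WindowedDataset, run_comparison
from wearaffect.report import build_metrics_table, write_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--windows", default="scratch/windows.h5", type=Path)
    ap.add_argument("--out", default="results/tables", type=Path)
    ap.add_argument("--seed", default=0, type=int)
    ap.add_argument("--epochs", default=80, type=int)
    ap.add_argument("--patience", default=15, type=int)
    ap.add_argument("--base-channels", default=8, type=int)
    ap.add_argument("--fc-hidden", default=32, type=int)
    args = ap.parse_args()

    ws = WindowedDataset.load(args.windows)
    mc = ModelConfig(base_channels=args.base_channels, fc_hidden=args.fc_hidden)
    tc = TrainConfig(max_epochs=args.epochs, seed=args.seed,
                     learning_rate=3e-3, batch_size=32,
                     early_stop_patience=args.patience)

    n = len(ws.participant_ids)
    print(f"{n} participants -> {n} personalized + {n} participant-exclusive "
          f"+ 1 participant-inclusive = {2 * n + 1} training runs")
    t0 = time.time()
    results = run_comparison(ws, mc, tc)
    table = build_metrics_table(results)
    write_report(table, args.out, ws=ws)
    print(f"done in {time.time() - t0:.0f} s; tables written to {args.out}/")

    print("\nper-protocol summary, mean (SD) over participants:")
    for _, row in table.summary.iterrows():
        print(f"  {row.protocol:>24}: accuracy {row.accuracy_mean:6.2f} "
              f"({row.accuracy_sd:5.2f})   F1 {row.f1_mean:6.2f} ({row.f1_sd:5.2f})")
    print("\npaired two-tailed t tests:")
    for _, row in table.p_values.iterrows():
        p = "undefined" if not row.defined else f"{row.p:.4g}"
        print(f"  {row.metric:>8}: {row.protocol_a} vs {row.protocol_b}: p = {p}")


if __name__ == "__main__":
    main()
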