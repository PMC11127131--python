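"""Normalize each recording and segment it into labeled 64-sample intervals.

Each modality is z-scored over the participant's full recording, then cut
into 64-point windows with 50% overlap; windows straddling a state change
are dropped so every interval carries a single annotation. Writes the
windowed dataset as one HDF5 file and prints per-participant interval
counts and the window-level class balance.

Usage:
    python analysis/02_make_windows.py [--cohort scratch/cohort]
        [--out scratch/windows.h5]
"""

import argparse
from pathlib import Path

from wearaffect import prepare_cohort
from wearaffect.io import load_cohort
from wearaffect.metrics import class_balance_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--cohort", default="scratch/cohort", type=Path)
    ap.add_argument("--out", default="scratch/windows.h5", type=Path)
    args = ap.parse_args()

    cohort = load_cohort(args.cohort)
    ws = prepare_cohort(cohort)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    ws.save(args.out)

    print(f"{len(ws)} uniformly-annotated intervals from "
          f"{len(ws.participant_ids)} participants -> {args.out}")
    per, ranges = class_balance_report(ws)
    print("\nwindow-level class balance (%):")
    print(per.to_string(index=False, float_format="%.1f"))
    print("\ncross-participant ranges (%):")
    print(ranges.to_string(index=False, float_format="%.1f"))


if __name__ == "__main__":
    main()
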