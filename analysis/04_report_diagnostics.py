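"""Modality-deviation diagnostics and class-balance report for a cohort.

For every (participant, state, modality) cell, computes the
state-conditional mean and SD and flags cells whose mean deviates from the
cross-participant mean by more than k cross-participant SDs — the
diagnostic used to investigate participants whose personalized models
underperform. Writes the profile table and the flagged cells as CSV.

Usage:
    python analysis/04_report_diagnostics.py [--cohort scratch/cohort]
        [--out results/diagnostics] [--k 2.0]
"""

import argparse
from pathlib import Path

from wearaffect.io import load_cohort
from wearaffect.metrics import modality_profiles


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--cohort", default="scratch/cohort", type=Path)
    ap.add_argument("--out", default="results/diagnostics", type=Path)
    ap.add_argument("--k", default=2.0, type=float,
                    help="flag threshold in cross-participant SDs")
    args = ap.parse_args()

    cohort = load_cohort(args.cohort)
    df = modality_profiles(cohort, k=args.k)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "modality_profiles.csv", index=False,
              float_format="%.6f")
    flagged = df[df.flagged.fillna(False)]
    flagged.to_csv(args.out / "flagged_cells.csv", index=False,
                   float_format="%.6f")

    print(f"profiles for {df.participant.nunique()} participants -> {args.out}/")
    if len(flagged):
        print(f"\n{len(flagged)} cells deviate by more than {args.k} "
              "cross-participant SDs:")
        print(flagged[["participant", "state", "modality", "deviation_z"]]
              .to_string(index=False, float_format="%.2f"))
    else:
        print(f"\nno cell deviates by more than {args.k} cross-participant SDs")


if __name__ == "__main__":
    main()
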