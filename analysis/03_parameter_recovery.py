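#!/usr/bin/env python
"""Parameter-recovery study: can the pipeline see the temporal dissociation?

Simulates repeated cohorts (default 60 per arm, n = 40 participants) under
(i) the recovery scenario — early pulses suppress sensitivity, late pulses
relax criteria — and (ii) a null scenario with inert TMS, then runs each
cohort through the analysis pipeline and tallies how often each early-vs-
late contrast recovers the generating sign, and how often null cohorts
produce spurious significance.
"""

import argparse
from pathlib import Path

import pandas as pd

from unseen.observer import (
    null_cohort_spec,
    recovery_cohort_spec,
    recovery_experiment,
    summarize_recovery,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohorts", type=int, default=60)
    ap.add_argument("--n", type=int, default=40)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    effect = recovery_experiment(recovery_cohort_spec(), n_cohorts=args.cohorts,
                                 n_participants=args.n, seed=args.seed)
    null = recovery_experiment(null_cohort_spec(), n_cohorts=args.cohorts,
                               n_participants=args.n, seed=args.seed + 1)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    se = summarize_recovery(effect).assign(arm="effect")
    sn = summarize_recovery(null).assign(arm="null")
    summary = pd.concat([se, sn], ignore_index=True)
    summary.to_csv(out / "recovery_summary.csv", index=False)
    effect.assign(arm="effect").to_csv(out / "recovery_cohorts.csv", index=False)

    print(f"{args.cohorts} cohorts per arm, n = {args.n} participants each")
    for _, row in summary.iterrows():
        print(f"  [{row['arm']:6s}] {row['measure']:4s} "
              f"sign-negative in {row['frac_negative']:.0%} of cohorts, "
              f"significant in {row['frac_significant']:.0%}")
    fpr = sn["frac_significant"].mean()
    print(f"null arm false-positive rate ~{fpr:.1%} per contrast (alpha 0.05)")


if __name__ == "__main__":
    main()
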