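#!/usr/bin/env python
"""Cohort descriptive statistics and fragmented presentations.

Reads results/event_log.csv, restricts each patient to the 12 months after
their first presentation, sorts canonically, extracts consecutive-attendance
transitions and reports the continuity statistics: how many patients
re-present, how many attend several providers, and the share of interactions
that are fragmented (the patient's previous interaction was elsewhere).
Writes transitions.csv, descriptive_stats.json, the per-provider fragmented
arrival shares and the per-LSOA median fragmentation table.
"""

import argparse
from pathlib import Path

from carefrag import (apply_patient_window, canonical_sort, descriptive_stats,
                      extract_transitions, lsoa_fragmentation,
                      provider_fragmented_share, read_event_log)
from carefrag.metrics import write_transitions


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--window-days", type=int, default=365)
    args = ap.parse_args()

    log = read_event_log(args.out_dir / "event_log.csv")
    log = canonical_sort(apply_patient_window(log, args.window_days))
    transitions = extract_transitions(log, check_sorted=False)
    stats = descriptive_stats(log, transitions)

    write_transitions(transitions, args.out_dir / "transitions.csv")
    stats.to_json(args.out_dir / "descriptive_stats.json")
    provider_fragmented_share(transitions).to_csv(
        args.out_dir / "provider_fragmented_share.csv")
    lsoa_fragmentation(log, transitions).to_csv(
        args.out_dir / "lsoa_fragmentation.csv")

    print(f"{stats.n_patients:,} patients, {stats.n_interactions:,} "
          f"interactions within the 12-month windows")
    print(f"  {stats.n_multi_presenters:,} patients "
          f"({stats.pct_multi_presenters:.1f}%) presented more than once; "
          f"{stats.n_multi_provider_patients:,} of those "
          f"({stats.pct_multi_provider:.1f}%) attended multiple providers")
    print(f"  {stats.n_fragmented:,} fragmented presentations = "
          f"{stats.pct_fragmented:.1f}% of multi-presenter interactions "
          f"({stats.pct_fragmented_per_transition:.1f}% of transitions)")


if __name__ == "__main__":
    main()
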