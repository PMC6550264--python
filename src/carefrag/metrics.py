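"""Fragmented-presentation extraction and descriptive continuity statistics.

A *transition* is an ordered pair of consecutive events for one patient; it
is *fragmented* when the two events are at different providers, i.e. the
patient arrives at a hospital whose clinicians do not hold the most recent
record of their care.  This module turns a canonically sorted event log into
its transition list and computes the cohort-level descriptive statistics:
how many patients present more than once, how many attend several providers,
and what share of hospital interactions are fragmented.

The headline fragmented percentage uses all interactions of patients who
present more than once as its denominator (not the transition count): a
cohort with F fragmented transitions among patients holding I interactions
in total reports 100*F/I.  The per-transition rate is exposed alongside as a
secondary quantity.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .event_log import ContractError, EventLog, is_canonically_sorted

TRANSITION_COLUMNS = (
    "patient_id", "from_provider", "to_provider", "from_date", "to_date", "fragmented",
)


def extract_transitions(log: EventLog, check_sorted: bool = True) -> pd.DataFrame:
    """Pair each patient's consecutive events into transitions.

    A patient with k >= 2 events contributes exactly k-1 transitions in event
    order; single-event patients contribute none.  The input must be in
    canonical order (sorted by patient, date, same-day tie rank) — pass
    ``check_sorted=False`` only when that is already guaranteed.
    """
    if check_sorted and not is_canonically_sorted(log):
        raise ContractError("event log must be canonically sorted before "
                            "transition extraction")
    f = log.frame
    if len(f) == 0:
        return pd.DataFrame(columns=TRANSITION_COLUMNS)
    same_patient = f["patient_id"].to_numpy()[1:] == f["patient_id"].to_numpy()[:-1]
    idx = np.flatnonzero(same_patient)  # row i -> transition (i, i+1)
    out = pd.DataFrame(
        {
            "patient_id": f["patient_id"].to_numpy()[idx],
            "from_provider": f["provider_code"].to_numpy()[idx],
            "to_provider": f["provider_code"].to_numpy()[idx + 1],
            "from_date": f["event_date"].to_numpy()[idx],
            "to_date": f["event_date"].to_numpy()[idx + 1],
        }
    )
    out["fragmented"] = out["from_provider"] != out["to_provider"]
    return out


@dataclass(frozen=True)
class DescriptiveStats:
    """Cohort-level continuity accounting.

    Counts of patients and interactions, split by whether patients presented
    more than once (``multi``) and attended more than one provider, plus the
    fragmented-presentation count.  Percentages are 100 * numerator /
    denominator with the denominators used in national reporting:
    ``pct_fragmented`` is over all interactions of multi-presenters;
    ``pct_fragmented_per_transition`` over the transition count.
    """

    n_patients: int
    n_interactions: int
    n_multi_presenters: int
    pct_multi_presenters: float
    n_multi_provider_patients: int
    pct_multi_provider: float
    n_interactions_multi: int
    pct_interactions_multi: float
    n_interactions_multi_provider: int
    pct_interactions_multi_provider: float
    n_transitions: int
    n_fragmented: int
    pct_fragmented: float
    pct_fragmented_per_transition: float

    @staticmethod
    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    @classmethod
    def from_counts(cls, *, n_patients: int, n_interactions: int,
                    n_multi_presenters: int, n_multi_provider_patients: int,
                    n_interactions_multi: int, n_interactions_multi_provider: int,
                    n_fragmented: int, n_transitions: int | None = None,
                    ) -> "DescriptiveStats":
        """Build the statistics record from raw integer counts.

        Every percentage is recomputed from the counts; nothing is stored
        that the counts do not determine.  ``n_transitions`` defaults to
        interactions-of-multi-presenters minus multi-presenters (each
        multi-presenter with k events yields k-1 transitions).
        """
        if n_transitions is None:
            n_transitions = n_interactions_multi - n_multi_presenters
        p = cls._pct
        return cls(
            n_patients=n_patients,
            n_interactions=n_interactions,
            n_multi_presenters=n_multi_presenters,
            pct_multi_presenters=p(n_multi_presenters, n_patients),
            n_multi_provider_patients=n_multi_provider_patients,
            pct_multi_provider=p(n_multi_provider_patients, n_multi_presenters),
            n_interactions_multi=n_interactions_multi,
            pct_interactions_multi=p(n_interactions_multi, n_interactions),
            n_interactions_multi_provider=n_interactions_multi_provider,
            pct_interactions_multi_provider=p(n_interactions_multi_provider,
                                              n_interactions_multi),
            n_transitions=n_transitions,
            n_fragmented=n_fragmented,
            pct_fragmented=p(n_fragmented, n_interactions_multi),
            pct_fragmented_per_transition=p(n_fragmented, n_transitions),
        )

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def descriptive_stats(log: EventLog, transitions: pd.DataFrame) -> DescriptiveStats:
    """Compute the cohort descriptive statistics from a log and its transitions."""
    f = log.frame
    per_patient = f.groupby("patient_id").agg(
        k=("event_date", "size"), n_prov=("provider_code", "nunique")
    )
    multi = per_patient[per_patient["k"] > 1]
    multi_provider = multi[multi["n_prov"] > 1]
    n_frag = int(transitions["fragmented"].sum()) if len(transitions) else 0
    return DescriptiveStats.from_counts(
        n_patients=len(per_patient),
        n_interactions=len(f),
        n_multi_presenters=len(multi),
        n_multi_provider_patients=len(multi_provider),
        n_interactions_multi=int(multi["k"].sum()),
        n_interactions_multi_provider=int(multi_provider["k"].sum()),
        n_fragmented=n_frag,
        n_transitions=len(transitions),
    )


def provider_fragmented_share(transitions: pd.DataFrame) -> pd.DataFrame:
    """Per-provider share of arriving encounters that are fragmented.

    An arrival at provider P is a transition whose destination is P.  Returns
    a table indexed by provider with columns ``n_arrivals_fragmented``,
    ``n_arrivals_total`` and ``proportion``; providers receiving no arrivals
    are omitted.
    """
    if len(transitions) == 0:
        return pd.DataFrame(
            columns=["n_arrivals_fragmented", "n_arrivals_total", "proportion"]
        )
    g = transitions.groupby("to_provider")["fragmented"]
    out = pd.DataFrame(
        {"n_arrivals_fragmented": g.sum().astype(int), "n_arrivals_total": g.size()}
    )
    out["proportion"] = out["n_arrivals_fragmented"] / out["n_arrivals_total"]
    out.index.name = "provider_code"
    return out.sort_index()


def patient_fragmented_proportion(log: EventLog,
                                  transitions: pd.DataFrame) -> pd.DataFrame:
    """Per-patient fragmented share and modal residence area.

    A patient's proportion is (their fragmented transitions) / (their total
    interactions); single-event patients score 0.  Residence is the modal
    ``lsoa_code`` over the patient's events, ties resolved to the
    lexicographically smallest code; patients with no recorded code get NA.
    """
    f = log.frame
    k = f.groupby("patient_id").size()
    frag = (
        transitions[transitions["fragmented"]].groupby("patient_id").size()
        if len(transitions) else pd.Series(dtype=int)
    )
    frag = frag.reindex(k.index, fill_value=0)

    with_lsoa = f.dropna(subset=["lsoa_code"])
    if len(with_lsoa):
        counts = (
            with_lsoa.groupby(["patient_id", "lsoa_code"]).size()
            .rename("n").reset_index()
            .sort_values(["patient_id", "n", "lsoa_code"],
                         ascending=[True, False, True], kind="mergesort")
        )
        modal = counts.drop_duplicates("patient_id").set_index("patient_id")["lsoa_code"]
    else:
        modal = pd.Series(dtype="string")
    out = pd.DataFrame({
        "n_interactions": k,
        "n_fragmented": frag,
        "proportion": frag / k,
        "lsoa_code": modal.reindex(k.index),
    })
    out.index.name = "patient_id"
    return out


def lsoa_fragmentation(log: EventLog, transitions: pd.DataFrame) -> pd.DataFrame:
    """Median patient-level fragmented proportion per residence area.

    Each resident patient contributes one value — their personal fragmented
    proportion, with single-event patients at 0 — and the area reports the
    median (mean of the central pair for even counts).  Patients without a
    residence code are excluded; an empty result if no event carries one.
    """
    per_patient = patient_fragmented_proportion(log, transitions)
    located = per_patient.dropna(subset=["lsoa_code"])
    if len(located) == 0:
        return pd.DataFrame(columns=["median_fragmented_proportion", "n_patients"])
    g = located.groupby("lsoa_code")["proportion"]
    out = pd.DataFrame(
        {"median_fragmented_proportion": g.median(), "n_patients": g.size()}
    )
    out.index.name = "lsoa_code"
    return out.sort_index()


def write_transitions(transitions: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the transition CSV dialect (ISO dates, boolean fragmented flag)."""
    out = transitions.copy()
    for col in ("from_date", "to_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
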