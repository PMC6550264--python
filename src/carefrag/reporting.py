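"""Community continuity accounting and end-to-end pipeline orchestration.

Once providers are partitioned into data-sharing communities, each
fragmented arrival can be classified by whether the patient's previous
interaction was at a provider inside or outside the destination provider's
community.  The within-community share is the continuity of data sharing
the community would achieve if its members exchanged records with one
another: the baseline without any sharing arrangement is 0.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .event_log import (EventLog, apply_merge_map, apply_patient_window,
                        canonical_sort, read_event_log, read_merge_map,
                        write_event_log)
from .metrics import (descriptive_stats, extract_transitions,
                      lsoa_fragmentation, provider_fragmented_share,
                      write_transitions)
from .network import build_network, network_summary, write_edge_list
from .communities import Partition, louvain
from .synthetic import SimulationConfig, generate_event_log


class UnassignedProviderError(KeyError):
    """A provider appearing in fragmented transitions has no community."""


@dataclass(frozen=True)
class CommunityStatsRow:
    """Continuity accounting for one data-sharing community.

    ``total_fragmented`` counts fragmented arrivals at the community's
    providers; ``previous_within`` those whose origin provider belongs to
    the same community.  ``pct_within`` = 100 * previous_within /
    total_fragmented.
    """

    community_label: int
    n_hospitals: int
    total_fragmented: int
    previous_within: int
    previous_outside: int
    pct_within: float

    @classmethod
    def from_counts(cls, community_label: int, n_hospitals: int,
                    total_fragmented: int, previous_within: int) -> "CommunityStatsRow":
        if previous_within > total_fragmented:
            raise ValueError("previous_within cannot exceed total_fragmented")
        return cls(
            community_label=community_label,
            n_hospitals=n_hospitals,
            total_fragmented=total_fragmented,
            previous_within=previous_within,
            previous_outside=total_fragmented - previous_within,
            pct_within=(100.0 * previous_within / total_fragmented
                        if total_fragmented else 0.0),
        )


def community_table(transitions: pd.DataFrame,
                    partition: Partition) -> list[CommunityStatsRow]:
    """Attribute every fragmented transition to its destination community.

    Each fragmented transition lands in exactly one row — that of its
    ``to_provider``'s community — and is counted as within-community when
    the ``from_provider`` shares that community.  Rows are sorted by
    community label; communities with no fragmented arrivals still appear
    with zero counts.
    """
    assign = partition.assignment
    frag = transitions[transitions["fragmented"]] if len(transitions) else transitions
    for col in ("from_provider", "to_provider"):
        if len(frag):
            unknown = set(frag[col]) - assign.keys()
            if unknown:
                raise UnassignedProviderError(
                    f"provider(s) not assigned to any community: {sorted(unknown)[:5]}"
                )
    sizes: dict[int, int] = {}
    for v, c in assign.items():
        sizes[c] = sizes.get(c, 0) + 1
    total: dict[int, int] = {c: 0 for c in sizes}
    within: dict[int, int] = {c: 0 for c in sizes}
    if len(frag):
        to_comm = frag["to_provider"].map(assign)
        from_comm = frag["from_provider"].map(assign)
        total_counts = to_comm.value_counts()
        within_counts = to_comm[to_comm == from_comm].value_counts()
        for c, n in total_counts.items():
            total[int(c)] = int(n)
        for c, n in within_counts.items():
            within[int(c)] = int(n)
    return [
        CommunityStatsRow.from_counts(c, sizes[c], total[c], within[c])
        for c in sorted(sizes)
    ]


def community_table_frame(rows: list[CommunityStatsRow]) -> pd.DataFrame:
    """Rows as a DataFrame in the published column layout."""
    df = pd.DataFrame([asdict(r) for r in rows])
    return df.rename(columns={"community_label": "community"})


def continuity_gain(rows: list[CommunityStatsRow]) -> dict:
    """Range and pooled mean of within-community continuity across rows.

    Without any inter-provider sharing arrangement the continuity of the
    record at a fragmented arrival is 0; community-wide interoperability
    raises it to each row's ``pct_within``.  The weighted mean pools all
    fragmented arrivals (equals 100 * sum(within) / sum(total)).
    """
    if not rows:
        raise ValueError("continuity_gain needs a non-empty table")
    pcts = [r.pct_within for r in rows]
    tot = sum(r.total_fragmented for r in rows)
    within = sum(r.previous_within for r in rows)
    return {
        "baseline_pct": 0.0,
        "min_pct_within": min(pcts),
        "max_pct_within": max(pcts),
        "weighted_mean_pct_within": 100.0 * within / tot if tot else 0.0,
    }


# ---------------------------------------------------------------------------
# end-to-end pipeline

def run_pipeline(*, input_path: str | os.PathLike | None = None,
                 config: SimulationConfig | None = None,
                 merge_map_path: str | os.PathLike | None = None,
                 window_days: int = 365, gamma: float = 1.0, seed: int = 0,
                 min_weight: float = 0.0, out_dir: str | os.PathLike = "results",
                 strict: bool = False, delimiter: str = ",") -> dict:
    """Run read → merge → window → sort → transitions → stats → network →
    Louvain → community table → LSOA table, writing all artifacts.

    Exactly one of ``input_path`` (an event-log file) and ``config`` (a
    synthetic-data configuration) must be given.  Returns the manifest,
    which is also written as ``manifest.json`` with stage-by-stage row
    counts; on a log with no fragmented transitions the network is empty and
    the community stage is skipped with a warning in the manifest.
    """
    if (input_path is None) == (config is None):
        raise ValueError("provide exactly one of input_path or config")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "carefrag_version": __version__,
        "window_days": window_days, "gamma": gamma, "seed": seed,
        "min_weight": min_weight, "stages": {}, "warnings": [],
    }

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config is not None:
        log, truth = stage("simulate", lambda: generate_event_log(config))
        truth.to_json(out / "ground_truth.json")
        write_event_log(log, out / "event_log.csv")
        manifest["config"] = log.provenance.get("config")
    else:
        log = stage("read", lambda: read_event_log(input_path, delimiter=delimiter,
                                                   strict=strict))
    manifest["stages"]["events_read"] = len(log)

    if merge_map_path is not None:
        mm = stage("merge_map", lambda: read_merge_map(merge_map_path))
        log = stage("merge", lambda: apply_merge_map(log, mm))
    log = stage("window", lambda: apply_patient_window(log, window_days))
    log = stage("sort", lambda: canonical_sort(log))
    manifest["stages"]["events_windowed"] = len(log)
    manifest["stages"]["n_patients"] = log.n_patients
    manifest["stages"]["n_providers"] = log.n_providers

    transitions = stage("transitions",
                        lambda: extract_transitions(log, check_sorted=False))
    write_transitions(transitions, out / "transitions.csv")
    manifest["stages"]["n_transitions"] = len(transitions)

    stats = stage("descriptive_stats", lambda: descriptive_stats(log, transitions))
    stats.to_json(out / "descriptive_stats.json")
    manifest["stages"]["n_fragmented"] = stats.n_fragmented

    provider_share = stage("provider_share",
                           lambda: provider_fragmented_share(transitions))
    provider_share.to_csv(out / "provider_fragmented_share.csv")
    lsoa = stage("lsoa", lambda: lsoa_fragmentation(log, transitions))
    lsoa.to_csv(out / "lsoa_fragmentation.csv")

    universe = sorted(set(log.frame["provider_code"]))
    net = stage("network", lambda: build_network(transitions, node_universe=universe))
    if min_weight > 0:
        from .network import threshold_network
        net = stage("threshold", lambda: threshold_network(net, min_weight))
    write_edge_list(net, out / "patient_sharing_edges.tsv")
    summary = stage("summary", lambda: network_summary(net))
    manifest["stages"]["network"] = summary

    if net.total_weight <= 0:
        manifest["warnings"].append(
            "no fragmented transitions: community detection skipped"
        )
    else:
        partition, score = stage("louvain", lambda: louvain(net, gamma=gamma, seed=seed))
        partition.to_csv(out / "communities.csv")
        partition.to_json(out / "communities.json")
        manifest["stages"]["n_communities"] = partition.n_communities
        manifest["stages"]["modularity"] = score.q
        rows = stage("community_table", lambda: community_table(transitions, partition))
        community_table_frame(rows).to_csv(out / "community_table.csv", index=False)
        manifest["stages"]["continuity"] = stage("continuity",
                                                 lambda: continuity_gain(rows))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
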