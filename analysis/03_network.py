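#!/usr/bin/env python
"""Build the weighted patient-sharing network.

Tallies every fragmented transition into the undirected edge weight F_AB
between its two providers and reports the network's size, density and
weight inhomogeneity (how many pairs exchange more than 10 / more than 100
patients).  Writes the edge list (TSV) and a GraphML export.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from carefrag import build_network, network_summary, read_event_log
from carefrag.network import write_edge_list, write_graphml


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    transitions = pd.read_csv(args.out_dir / "transitions.csv",
                              dtype={"from_provider": str, "to_provider": str})
    universe = sorted(set(read_event_log(args.out_dir / "event_log.csv")
                          .frame["provider_code"]))
    net = build_network(transitions, node_universe=universe)
    write_edge_list(net, args.out_dir / "patient_sharing_edges.tsv")
    write_graphml(net, args.out_dir / "patient_sharing_network.graphml")

    summary = network_summary(net, weight_thresholds=[10, 100])
    with open(args.out_dir / "network_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    print(f"patient-sharing network: {summary['n_nodes']} providers, "
          f"{summary['n_edges']:,} of {summary['n_possible']:,} possible edges "
          f"({summary['density_pct']:.1f}% dense), total weight "
          f"{summary['total_weight']:,.0f}")
    for t, row in summary["thresholds"].items():
        print(f"  edges with weight > {t}: {row['n_edges_above']:,} "
              f"({row['pct_of_edges']:.1f}%)")


if __name__ == "__main__":
    main()
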