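# carefrag

Patient-sharing networks and data-sharing communities from patient-level
hospital event logs.

## The problem

When a patient attends one hospital having last been seen at a different
hospital — a *fragmented presentation* — the clinicians treating them may
not hold the most recent record of their care. Counting how often each pair
of providers is involved in such hand-offs yields a weighted, undirected
**patient-sharing network**: providers are nodes, and the edge weight
*F*<sub>AB</sub> counts the occasions on which consecutive presentations by
a patient featured providers A and B, in either order. Groups of providers
that share many patients with one another are exactly the groups that would
benefit most from interoperable records, so partitioning the network into
**data-sharing communities** gives a data-driven blueprint for regional
health-information exchange.

`carefrag` implements the full pipeline for health-services researchers and
interoperability planners working with administrative event logs (one row
per patient interaction with a provider, in the style of English Hospital
Episode Statistics):

1. **Event-log normalisation** — schema validation, provider-merger
   mapping, restriction of each patient to the 12 months following their
   first presentation, and a deterministic canonical ordering (same-day
   ties resolved AE < IP < OP, then provider code).
2. **Fragmentation metrics** — per-patient consecutive-attendance
   transitions, cohort descriptive statistics, per-provider fragmented
   arrival shares, and per-small-area (LSOA) median fragmentation.
3. **Network construction** — *F*<sub>AB</sub> tallies, density summaries,
   weight thresholding, edge-list/GraphML I/O.
4. **Community detection** — resolution modularity
   *Q*(γ) = (1/2m) Σ<sub>ij</sub> [A<sub>ij</sub> − γ k<sub>i</sub>k<sub>j</sub>/2m] δ(c<sub>i</sub>, c<sub>j</sub>)
   and its Louvain optimisation, implemented from scratch, with an
   exhaustive set-partition oracle (≤ 10 nodes) and a multi-seed,
   multi-resolution stability sweep.
5. **Continuity reporting** — the per-community within/outside accounting
   of fragmented arrivals that quantifies how much record access a
   community-wide sharing arrangement would provide.

Because real patient-level administrative data are non-public, the package
includes a first-class synthetic generator (`carefrag.synthetic`) that
plants known provider communities and emulates realistic per-patient event
counts, so every stage is testable against ground truth.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic cohort
of 20,000 patients at 155 providers planted in 10 regional communities
(marginals mirroring national English secondary-care activity):

```bash
python analysis/01_simulate.py        # event log + planted ground truth
python analysis/02_descriptives.py    # transitions + cohort statistics
python analysis/03_network.py         # weighted patient-sharing network
python analysis/04_communities.py     # Louvain + stability sweep
python analysis/05_continuity.py      # community continuity table
```

Output of a complete run (seed 0):

```
20,000 patients, 84,044 interactions within the 12-month windows
  16,106 patients (80.5%) presented more than once; 6,796 of those (42.2%)
  attended multiple providers
  8,622 fragmented presentations = 10.8% of multi-presenter interactions
patient-sharing network: 155 providers, 2,870 of 11,935 possible edges
  (24.0% dense), total weight 8,622
Louvain at gamma=1: 10 communities, Q = 0.677
  adjusted Rand index against planted communities: 1.000
continuity of data sharing at fragmented presentations:
  0 -> 74.8-79.1% (weighted mean 77.7%)
```

Reading: four in five synthetic patients re-present within a year, and
about one in nine of their interactions arrives at a provider that was not
their previous one. Louvain at unit resolution recovers all ten planted
communities exactly (ARI 1.0), and if records were shared within each
detected community, 74.8–79.1% of fragmented arrivals would find the
previous record available — up from 0% with no sharing arrangement.

The same pipeline runs on real data via the `carefrag` console script:

```bash
carefrag run --input events.csv --merge-map mergers.csv --gamma 1.0 \
             --seed 0 --out-dir results/
```

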