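# Methods

## Fragmented presentations and the patient-sharing network

The unit of observation is a *care event*: one interaction of one patient
with one secondary-care provider on one date, in one of three settings
(emergency `AE`, inpatient `IP`, outpatient `OP`). Providers are
organisational trusts identified by 3-character codes; trusts that merged
or separated during a study period are mapped to a single canonical code
before any counting, so that organisational change is not mistaken for
patient sharing.

For each patient, events are restricted to the 12 months following their
first presentation (inclusive boundary: an event exactly 365 days after the
first is retained) and placed in a canonical total order: by patient, date,
setting rank `AE < IP < OP`, provider code, and finally residence code.
The setting rank resolves same-day ties deterministically and is clinically
plausible (emergency precedes admission precedes clinic); any fixed rule
would do, and the chosen one makes every downstream count reproducible from
an arbitrarily shuffled input file. Duplicate rows are retained as distinct
events — administrative extracts genuinely contain same-day repeat
contacts.

Consecutive events of one patient form a *transition*; a transition whose
two events are at different providers is a *fragmented presentation*. A
patient with k ≥ 2 events contributes exactly k − 1 transitions. Summing
fragmented transitions over unordered provider pairs gives the symmetric
edge weight F_AB of the patient-sharing network; weights are raw counts,
not normalised by provider volume, because F_AB is itself the quantity of
interest — the number of occasions on which a record held at one provider
was the freshest record of a patient arriving at the other.

Two denominators appear in the descriptive statistics and are easily
conflated. The headline fragmented percentage divides fragmented
transitions by **all interactions of patients who present more than once**
(this is the convention under which the national counts 14,748,791 /
126,481,078 round to 11.7%); the per-transition rate, with denominator
Σ(k_i − 1), is exposed alongside as
`pct_fragmented_per_transition` and is the quantity the generator's
`p_switch_provider` controls directly.

The per-area statistic assigns each patient the modal residence (LSOA) code
over their events (ties to the lexicographically smallest code), scores
each patient by (own fragmented transitions)/(own interactions) — single-
event patients score 0 — and reports the median over resident patients.
The median-over-patients reading was chosen over a pooled proportion
because the statistic characterises the typical resident's risk of arriving
at a provider without their record, and the median is robust to the heavy
tail of high-frequency attenders; the pooled proportion is recoverable from
the per-patient table if wanted.

## Resolution modularity and Louvain

Partition quality is resolution modularity

    Q(γ) = (1/2m) Σ_ij [ A_ij − γ k_i k_j / (2m) ] δ(c_i, c_j)

with A the weighted adjacency, k weighted degree, m total edge weight, and
γ > 0 scaling the configuration-null term. Evaluation is O(|E| + |V|) via
per-community internal-weight and degree sums. Closed-form identities used
as correctness anchors: the one-community partition has Q = 0 at γ = 1 for
any loopless graph; the all-singletons partition has Q = −Σ_i (k_i/2m)²;
the two-triangle barbell's optimum is exactly 10/28.

Louvain runs the standard two phases to convergence: single-node moves
between communities, then aggregation of communities into super-nodes with
intra-community weight carried as self-loops (a self-loop of weight w
contributes 2w to its node's degree and w to m). The move phase visits
nodes in a seeded random order, re-shuffled each pass, and accepts only
moves whose modularity gain exceeds 10⁻¹² (guarding against float cycling),
so Q increases strictly along every accepted move and across levels.

One design choice departs from the textbook greedy rule: instead of always
moving a node to the neighbouring community with *maximal* gain, the target
is drawn uniformly among all neighbouring communities with *positive* gain.
Steepest ascent funnels runs with different seeds into the same local
optimum on small dense graphs — in development, best-of-20-seed steepest
ascent reached the exhaustive-search optimum on 47/50 random weighted
5–8-node graphs, while the randomised rule reached 50/50 and left planted-
structure recovery and single-run quality unchanged. The randomised rule
retains every guarantee that matters (monotone Q, termination, seed
determinism); it simply decorrelates restarts.

Final labels are canonicalised by first appearance over lexicographically
sorted node codes, so identical partitions always serialise byte-
identically. Isolated providers (retained in the node universe so that
density and community coverage refer to all providers) end in singleton
communities.

`exhaustive_best_partition` enumerates all set partitions (restricted-
growth strings, refusing graphs above 10 nodes ≙ Bell(10) = 115,975
partitions) and is the independent optimum oracle in the tests; ties within
the gain tolerance resolve to fewer communities, then lexicographically.
The γ-limits are verified on fixtures: as γ → 0 the one-community partition
is optimal, and for γ > 2m·max A_ij / min k_i k_j over connected pairs,
singletons are.

Because the resolution used for any given published partition is generally
unstated, γ defaults to 1 and is exposed everywhere; `stability_sweep` runs
multi-seed Louvain across a γ grid and flags resolutions where the mean
pairwise adjusted Rand index across seeds reaches 0.95, substituting a
transparent stability criterion for an unexplained one. ARI is computed by
scikit-learn; modularity values are cross-checked against networkx in the
test suite (networkx plays no part in the optimisation itself).

## Continuity accounting

Each fragmented transition is attributed to the community of its
**destination** provider and classified by whether the origin provider lies
inside or outside that community: the destination is where a clinician
needs the record, the origin is where it sits. Row sums over communities
therefore conserve the national fragmented count exactly — an invariant
asserted in the tests. `continuity_gain` summarises the within-community
shares (min, max, pooled weighted mean) against a baseline of 0, i.e. no
inter-provider sharing arrangement at all.

## The synthetic cohort

The generator emulates the schema and the broad marginals of national
English secondary-care activity while planting a known community structure:

| parameter | default | rationale |
|---|---|---|
| `n_providers` / `n_communities` | 155 / 10 | national provider count and community count at study scale |
| `n_patients` | 20,000 | desk-scale cohort: large enough for stable rates, runs in seconds |
| `p_single_event` | 0.187 | 81.3% of patients nationally present more than once |
| `mean_events_per_patient` | 7.9 | mean events among multi-presenters implied by 130.2M events / 19.7M patients with 18.7% singletons |
| `p_switch_provider` | 0.134 | national per-transition fragmentation rate 14.75M / 110.5M |
| `p_within_community` | 0.81 | pooled within-community share of fragmented arrivals, 11.98M / 14.75M |
| `n_lsoas` | 300 | ≈ 1% of England's 32,844 LSOAs, keeping ~65 patients per area |
| `date_start`, `date_span_days` | 2013-04-01, 730 | two-year extract window; the 12-month per-patient rule then bites, exercising the windowing stage |

Event counts are a mixture: 1 with probability `p_single_event`, else
2 + Poisson(mean − 2) — the mixture lets the multi-presenter fraction be
tuned independently of the mean. Dates are distinct sorted days per patient
(an `allow_same_day` flag produces ties for testing the tie rule). The
first provider is uniform over the patient's home community; each later
event stays put with probability 1 − `p_switch_provider`, otherwise moves
to a different provider, within the home community with probability
`p_within_community`. Settings are uniform over AE/IP/OP and carry no
signal, matching their role in the statistics.

What the generator deliberately does **not** reproduce: spatial gravity in
provider choice (community membership, not distance, drives the planted
structure), seasonality, case-mix, real geography or real LSOA codes, and
the empirical correlation between switching and re-presenting — one visible
consequence is that the synthetic share of multi-presenters who attend
multiple providers (≈42%) exceeds the national 26%, because real switching
is concentrated in fewer patients than an i.i.d. per-transition coin
produces. Passing tests on synthetic data therefore demonstrate the
pipeline's correctness and the detectability of planted structure, not the
realism of any particular national estimate. Likewise the synthetic network
at 20,000 patients is far sparser (≈24% density) than the near-complete
national network (97.5%): density scales with cohort size, while community
recovery does not depend on it.

## Numerical and degenerate-input choices

* Modularity requires m > 0; the empty network raises, and the pipeline
  skips community detection (with a manifest warning) when a log contains
  no fragmented transitions.
* Edge thresholds are strict (`weight > t`), matching the "above t cases"
  reading of sparsified network views.
* Medians of even-sized sets are the mean of the central pair.
* Malformed event rows (blank identifiers, unparseable dates, unknown
  settings) are dropped and counted by default; `strict=True` fails fast on
  the first offender.
* All randomness flows through `numpy.random.default_rng` seeds; identical
  configuration and seed give byte-identical event logs, partitions and
  manifests (asserted in the tests).

## Problem sizes in the checks

The oracle-equivalence check uses 50 random weighted graphs of 5–8 nodes
(density 0.5, integer weights 1–9) against best-of-20-seed Louvain;
planted-partition recovery uses 20 cohorts of 5,000 patients at 40
providers in 4 communities with `p_within_community = 0.95` and
`p_switch_provider = 0.3` (≈ 210 expected fragmented arrivals per
provider); the Monte-Carlo check of the fragmentation rate uses 10,000
patients with singletons disabled, within three standard errors. These
sizes give stable pass/fail behaviour while keeping the whole suite fast.

## Known limitations

* Louvain remains a heuristic: optimality is certified only on graphs small
  enough for exhaustive search, and the oracle-agreement rate is an
  empirical statement about the sampled graph distribution.
* The published national results themselves (10 communities, Q = 0.818)
  cannot be reproduced without the non-public source data; the package
  reproduces the published arithmetic from printed counts and the full
  method on synthetic data.
* Spell/episode construction inside inpatient stays, adult/residence
  eligibility filtering and real extract layouts are out of scope; rows are
  taken at face value as interactions, with eligibility filters left to the
  caller.
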