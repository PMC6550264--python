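"""Synthetic hospital event logs with planted community structure.

Real patient-level administrative hospital data are non-public, so every
stage of the pipeline is exercised on generated pseudo-records that mimic
the schema and the broad marginals of English secondary-care activity:
pseudonymous patients, trust-level 3-character provider codes, small-area
(LSOA-like) residence codes, AE/IP/OP settings, and heavily skewed
per-patient event counts.  Providers are planted into ground-truth regional
communities and patients preferentially attend providers of their home
community, so that community detection downstream has a known answer.

Generation model, per patient:

* a home LSOA is drawn uniformly; the LSOA's planted community is the
  patient's home community;
* the number of events is 1 with probability ``p_single_event``, otherwise
  ``2 + Poisson(mean_events_per_patient - 2)``;
* event dates are distinct days drawn uniformly from the simulation window
  and sorted (a flag allows same-day ties for testing tie-break rules);
* the first event's provider is uniform over the home community; each later
  event stays at the previous provider with probability
  ``1 - p_switch_provider``, otherwise moves to a *different* provider —
  inside the home community with probability ``p_within_community``, else
  uniformly outside it;
* the care setting of each event is uniform over AE/IP/OP.

Default parameter values reflect the marginals of national English hospital
activity 2013-14: 81.3% of patients present more than once (so
``p_single_event = 0.187``), patients who re-present average about 7.9
interactions, 13.4% of consecutive-attendance pairs change provider, and
roughly 81% of provider changes stay within a regional community.
"""

from __future__ import annotations

import json
import os
import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .event_log import EventLog, SETTINGS, from_frame


class InvalidConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic event-log generator.

    All probabilities are in [0, 1]; identical config and seed produce
    byte-identical output.
    """

    n_providers: int = 155
    n_communities: int = 10
    n_patients: int = 20_000
    mean_events_per_patient: float = 7.9
    p_single_event: float = 0.187
    p_within_community: float = 0.81
    p_switch_provider: float = 0.134
    n_lsoas: int = 300
    date_start: str = "2013-04-01"
    date_span_days: int = 730
    seed: int = 0
    allow_same_day: bool = False

    def validate(self) -> None:
        for name in ("p_single_event", "p_within_community", "p_switch_provider"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name}={p} not a probability")
        for name in ("n_providers", "n_communities", "n_patients", "n_lsoas",
                     "date_span_days"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.n_communities > self.n_providers:
            raise InvalidConfigError(
                f"n_communities={self.n_communities} exceeds "
                f"n_providers={self.n_providers}"
            )
        if self.mean_events_per_patient <= 0:
            raise InvalidConfigError("mean_events_per_patient must be positive")


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic log.

    Maps every provider to its planted community, every patient to their home
    LSOA, and every LSOA to its community label (labels 0..n_communities-1).
    """

    provider_community: dict[str, int] = field(default_factory=dict)
    patient_home_lsoa: dict[str, str] = field(default_factory=dict)
    lsoa_community: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            provider_community={k: int(v) for k, v in d["provider_community"].items()},
            patient_home_lsoa=dict(d["patient_home_lsoa"]),
            lsoa_community={k: int(v) for k, v in d["lsoa_community"].items()},
        )


_CODE_ALPHABET = string.digits + string.ascii_uppercase  # base-36 provider codes


def _provider_codes(n: int) -> list[str]:
    """3-character alphanumeric codes in the style of trust-level PROCODE3."""
    if n > 36 ** 2 * 26:
        raise InvalidConfigError("too many providers for 3-character codes")
    codes = []
    for i in range(n):
        hi, rest = divmod(i, 36 * 36)
        mid, lo = divmod(rest, 36)
        codes.append(string.ascii_uppercase[hi] + _CODE_ALPHABET[mid] + _CODE_ALPHABET[lo])
    return codes


def _balanced_labels(n_items: int, n_groups: int) -> np.ndarray:
    """Group sizes as equal as possible, remainder given to groups 0 upward."""
    base, rem = divmod(n_items, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    return np.repeat(np.arange(n_groups), sizes)


def generate_providers(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Create the provider roster with planted community labels.

    Returns a table ``provider_code, community`` and a partially filled
    :class:`GroundTruth` (provider and LSOA maps; patient map is filled by
    :func:`generate_event_log`).
    """
    config.validate()
    codes = _provider_codes(config.n_providers)
    labels = _balanced_labels(config.n_providers, config.n_communities)
    table = pd.DataFrame({"provider_code": codes, "community": labels})
    lsoa_codes = [f"L{i:05d}" for i in range(config.n_lsoas)]
    lsoa_labels = _balanced_labels(config.n_lsoas, config.n_communities)
    truth = GroundTruth(
        provider_community=dict(zip(codes, (int(x) for x in labels))),
        lsoa_community=dict(zip(lsoa_codes, (int(x) for x in lsoa_labels))),
    )
    return table, truth


def _draw_event_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Event count per patient: singleton mixture plus shifted Poisson."""
    single = rng.random(config.n_patients) < config.p_single_event
    lam = max(config.mean_events_per_patient - 2.0, 0.0)
    multi = 2 + rng.poisson(lam, size=config.n_patients)
    return np.where(single, 1, multi)


def generate_event_log(config: SimulationConfig) -> tuple[EventLog, GroundTruth]:
    """Generate a synthetic event log and its planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    provider_table, truth = generate_providers(config)

    providers = provider_table["provider_code"].to_numpy()
    prov_comm = provider_table["community"].to_numpy()
    by_community = [providers[prov_comm == c] for c in range(config.n_communities)]
    lsoa_codes = np.array(sorted(truth.lsoa_community))
    lsoa_comm = np.array([truth.lsoa_community[c] for c in lsoa_codes])

    counts = _draw_event_counts(config, rng)
    patient_ids = np.array([f"P{i:07d}" for i in range(config.n_patients)])
    home_lsoa_idx = rng.integers(0, config.n_lsoas, size=config.n_patients)
    truth.patient_home_lsoa = dict(
        zip(patient_ids.tolist(), lsoa_codes[home_lsoa_idx].tolist())
    )

    start = np.datetime64(config.date_start)
    rows_patient: list[np.ndarray] = []
    rows_provider: list[np.ndarray] = []
    rows_date: list[np.ndarray] = []
    rows_lsoa: list[np.ndarray] = []

    for i in range(config.n_patients):
        k = int(counts[i])
        home_comm = int(lsoa_comm[home_lsoa_idx[i]])
        home = by_community[home_comm]

        if config.allow_same_day or k > config.date_span_days:
            days = np.sort(rng.integers(0, config.date_span_days, size=k))
        else:
            days = np.sort(rng.choice(config.date_span_days, size=k, replace=False))

        chosen = np.empty(k, dtype=providers.dtype)
        chosen[0] = rng.choice(home)
        for j in range(1, k):
            prev = chosen[j - 1]
            if rng.random() < 1.0 - config.p_switch_provider:
                chosen[j] = prev
                continue
            go_within = rng.random() < config.p_within_community
            within = home[home != prev]
            # outside set: all providers not in the home community, minus prev
            outside_arr = providers[prov_comm != home_comm]
            outside_arr = outside_arr[outside_arr != prev]
            if go_within and len(within) > 0:
                chosen[j] = rng.choice(within)
            elif len(outside_arr) > 0:
                chosen[j] = rng.choice(outside_arr)
            elif len(within) > 0:
                chosen[j] = rng.choice(within)
            else:  # single provider overall: forced to stay
                chosen[j] = prev

        rows_patient.append(np.repeat(patient_ids[i], k))
        rows_provider.append(chosen)
        rows_date.append(start + days.astype("timedelta64[D]"))
        rows_lsoa.append(np.repeat(lsoa_codes[home_lsoa_idx[i]], k))

    n_events = int(counts.sum())
    settings = np.array(SETTINGS)[rng.integers(0, len(SETTINGS), size=n_events)]
    frame = pd.DataFrame(
        {
            "patient_id": np.concatenate(rows_patient),
            "provider_code": np.concatenate(rows_provider),
            "event_date": np.concatenate(rows_date),
            "setting": settings,
            "lsoa_code": np.concatenate(rows_lsoa),
        }
    )
    log = from_frame(frame, source=f"synthetic(seed={config.seed})")
    log.provenance["config"] = asdict(config)
    return log, truth
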