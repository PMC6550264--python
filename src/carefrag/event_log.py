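"""Reading, validation and normalisation of patient-level hospital event logs.

An event log records one row per interaction of a patient with a secondary
care provider: an attendance at emergency care (``AE``), an inpatient stay
(``IP``) or an outpatient appointment (``OP``).  The functions here apply the
cohort rules used throughout the pipeline: merging of providers that changed
identity over the study period, restriction of each patient's record to the
12 months following their first presentation, and a canonical deterministic
ordering so that "consecutive attendances" is well defined even for same-day
events.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Columns of the event-log dialect, in canonical order.
EVENT_COLUMNS = ("patient_id", "provider_code", "event_date", "setting", "lsoa_code")

#: Care settings and their same-day precedence (emergency before admission
#: before clinic).
SETTINGS = ("AE", "IP", "OP")
SETTING_RANK = {s: i for i, s in enumerate(SETTINGS)}


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ContractError(ValueError):
    """An operation received input violating its stated precondition."""


@dataclass
class EventLog:
    """An ordered collection of care events plus provenance metadata.

    The payload is a :class:`pandas.DataFrame` with columns
    ``patient_id, provider_code, event_date, setting, lsoa_code``
    (``event_date`` as ``datetime64[ns]``, ``lsoa_code`` possibly missing).
    ``provenance`` accumulates a record of the filters applied and the row
    counts before and after each.
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    @property
    def n_providers(self) -> int:
        return self.frame["provider_code"].nunique()

    def copy_with(self, frame: pd.DataFrame, **extra_provenance) -> "EventLog":
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        return EventLog(frame=frame, provenance=prov)


def _coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise dtypes of an in-memory event table."""
    out = df.copy()
    if "lsoa_code" not in out.columns:
        out["lsoa_code"] = pd.NA
    out = out.loc[:, list(EVENT_COLUMNS)]
    out["patient_id"] = out["patient_id"].astype("string")
    out["provider_code"] = out["provider_code"].astype("string")
    out["setting"] = out["setting"].astype("string")
    out["lsoa_code"] = out["lsoa_code"].astype("string")
    out["event_date"] = pd.to_datetime(out["event_date"], format="ISO8601")
    return out


def from_frame(df: pd.DataFrame, source: str = "<memory>") -> EventLog:
    """Wrap an in-memory table as a validated :class:`EventLog`."""
    missing = {"patient_id", "provider_code", "event_date", "setting"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")
    frame = _coerce_frame(df).reset_index(drop=True)
    bad_setting = ~frame["setting"].isin(SETTINGS)
    if bad_setting.any():
        raise SchemaError(
            f"invalid setting value(s): {sorted(frame.loc[bad_setting, 'setting'].unique())}"
        )
    return EventLog(frame=frame, provenance={"source": source, "n_rows_read": len(frame)})


def read_event_log(path: str | os.PathLike, delimiter: str = ",",
                   strict: bool = False) -> EventLog:
    """Read a delimited event-log file.

    The header must name at least ``patient_id, provider_code, event_date,
    setting`` (any column order); ``lsoa_code`` is optional.  Rows with a
    blank patient or provider identifier, an unparseable date, or an unknown
    setting are dropped and counted — unless ``strict`` is set, in which case
    the first offending row raises :class:`SchemaError`.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype="string", keep_default_na=True)
    required = {"patient_id", "provider_code", "event_date", "setting"}
    missing = required - set(raw.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {sorted(missing)}")
    if "lsoa_code" not in raw.columns:
        raw["lsoa_code"] = pd.NA

    n_read = len(raw)
    blank_id = (
        raw["patient_id"].isna() | (raw["patient_id"].str.strip() == "")
        | raw["provider_code"].isna() | (raw["provider_code"].str.strip() == "")
    )
    dates = pd.to_datetime(raw["event_date"], format="ISO8601", errors="coerce")
    bad_date = dates.isna()
    bad_setting = ~raw["setting"].isin(SETTINGS)
    bad = blank_id | bad_date | bad_setting
    if strict and bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"{path}: malformed row at line {i + 2}: {raw.iloc[i].to_dict()}")

    kept = raw.loc[~bad].copy()
    kept["event_date"] = dates.loc[~bad]
    frame = _coerce_frame(kept).reset_index(drop=True)
    return EventLog(
        frame=frame,
        provenance={
            "source": str(path),
            "n_rows_read": n_read,
            "n_rows_kept": len(frame),
            "dropped_count": int(bad.sum()),
            "dropped_blank_id": int(blank_id.sum()),
            "dropped_bad_date": int((bad_date & ~blank_id).sum()),
            "dropped_bad_setting": int((bad_setting & ~blank_id & ~bad_date).sum()),
        },
    )


def write_event_log(log: EventLog, path: str | os.PathLike, delimiter: str = ",") -> None:
    """Write the event-log CSV dialect (UTF-8, ISO-8601 dates)."""
    out = log.frame.copy()
    out["event_date"] = out["event_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# provider merge map

def validate_merge_map(merge_map: Mapping[str, str]) -> None:
    """Raise unless the map is idempotent (canonical codes map to themselves)."""
    for raw, canon in merge_map.items():
        if merge_map.get(canon, canon) != canon:
            raise ContractError(
                f"merge map is not idempotent: {raw!r} -> {canon!r} -> "
                f"{merge_map[canon]!r}"
            )


def read_merge_map(path: str | os.PathLike, delimiter: str = ",") -> dict[str, str]:
    """Read a two-column ``raw_code,canonical_code`` merge map and validate it."""
    df = pd.read_csv(path, sep=delimiter, dtype="string")
    if not {"raw_code", "canonical_code"} <= set(df.columns):
        raise SchemaError(f"{path}: merge map needs columns raw_code, canonical_code")
    mapping = dict(zip(df["raw_code"], df["canonical_code"]))
    validate_merge_map(mapping)
    return mapping


def apply_merge_map(log: EventLog, merge_map: Mapping[str, str]) -> EventLog:
    """Replace every provider code by its canonical code.

    Providers that merged or separated over the study period are treated as a
    single provider throughout.  Event count is unchanged.
    """
    validate_merge_map(merge_map)
    frame = log.frame.copy()
    frame["provider_code"] = (
        frame["provider_code"].map(lambda c: merge_map.get(c, c)).astype("string")
    )
    return log.copy_with(frame, merge_map_applied=len(merge_map))


# ---------------------------------------------------------------------------
# per-patient follow-up window

def apply_patient_window(log: EventLog, window_days: int = 365) -> EventLog:
    """Keep, for each patient, events within ``window_days`` of their first.

    The boundary is inclusive: an event exactly ``window_days`` after the
    first presentation is retained, and the first presentation itself always
    is.
    """
    frame = log.frame
    if len(frame) == 0:
        return log.copy_with(frame.copy(), window_days=window_days, window_dropped=0)
    first = frame.groupby("patient_id")["event_date"].transform("min")
    keep = frame["event_date"] <= first + pd.Timedelta(days=window_days)
    out = frame.loc[keep].reset_index(drop=True)
    return log.copy_with(
        out, window_days=window_days, window_dropped=int((~keep).sum())
    )


# ---------------------------------------------------------------------------
# canonical ordering

def _sort_key_frame(frame: pd.DataFrame) -> pd.DataFrame:
    keys = frame.loc[:, ["patient_id", "event_date", "setting", "provider_code",
                         "lsoa_code"]].copy()
    keys["setting"] = keys["setting"].map(SETTING_RANK)
    keys["lsoa_code"] = keys["lsoa_code"].fillna("")
    return keys


def canonical_sort(log: EventLog) -> EventLog:
    """Sort events by (patient, date, setting rank AE<IP<OP, provider code).

    The full column set acts as the sort key, so the result is identical for
    any permutation of the input rows and sorting is idempotent.
    """
    keys = _sort_key_frame(log.frame)
    order = np.lexsort([keys[c].to_numpy() for c in reversed(keys.columns)])
    out = log.frame.iloc[order].reset_index(drop=True)
    return log.copy_with(out, canonical_sorted=True)


def is_canonically_sorted(log: EventLog) -> bool:
    """True if the log's rows are already in canonical order."""
    keys = _sort_key_frame(log.frame)
    order = np.lexsort([keys[c].to_numpy() for c in reversed(keys.columns)])
    return bool(np.all(order == np.arange(len(keys))))
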