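"""Reading and writing eBird Basic Dataset (EBD) style tables.

The EBD ships as two tab-separated tables: an *observation* table (one
row per species per checklist) and a *sampling-event* table (one row per
checklist, carrying location, date, protocol, effort and the
all-species-reported flag). Presence/absence inference requires
*zero-filling*: every sampling event with no row for the focal species
becomes an explicit non-detection. This module handles both tables, the
zero-fill join, and the optional collapse of shared (group) checklists.

Tables are held as :class:`pandas.DataFrame` with canonical column names
(see :data:`EVENT_COLUMNS`); actual file headers are mapped through a
configurable :class:`ColumnMap` because EBD header dialects vary between
snapshots. Counts use pandas' nullable ``Int64`` dtype, with ``pd.NA``
standing for eBird's "X" (present, count not recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

PROTOCOLS = ("stationary", "traveling", "incidental", "historical", "other")

#: canonical sampling-event columns, in writer order
EVENT_COLUMNS = [
    "checklist_id",
    "group_id",
    "protocol",
    "date",
    "duration_minutes",
    "distance_km",
    "n_observers",
    "lat",
    "lon",
    "complete",
]

OBS_COLUMNS = ["checklist_id", "species_code", "count"]


class ColumnConfigError(KeyError):
    """A mandatory column is missing from the file header."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to file header names.

    Defaults follow the official EBD header spelling; override fields to
    read other dialects.
    """

    checklist_id: str = "SAMPLING EVENT IDENTIFIER"
    group_id: str = "GROUP IDENTIFIER"
    protocol: str = "PROTOCOL TYPE"
    date: str = "OBSERVATION DATE"
    duration_minutes: str = "DURATION MINUTES"
    distance_km: str = "EFFORT DISTANCE KM"
    n_observers: str = "NUMBER OBSERVERS"
    lat: str = "LATITUDE"
    lon: str = "LONGITUDE"
    complete: str = "ALL SPECIES REPORTED"
    species_code: str = "SPECIES CODE"
    count: str = "OBSERVATION COUNT"

    def require(self, header: list[str], fields: list[str]) -> None:
        mapping = asdict(self)
        missing = [f for f in fields if mapping[f] not in header]
        if missing:
            names = ", ".join(f"{f} (expected header {mapping[f]!r})" for f in missing)
            raise ColumnConfigError(f"mandatory column(s) missing: {names}")


def _normalize_protocol(raw: pd.Series) -> pd.Series:
    """Map free-form EBD protocol labels onto the analysis enum."""
    s = raw.astype(str).str.lower()
    out = pd.Series("other", index=raw.index, dtype=object)
    for name in ("stationary", "incidental", "historical"):
        out[s.str.contains(name, regex=False)] = name
    out[s.str.contains("travel", regex=False)] = "traveling"
    return out


def _parse_counts(raw: pd.Series) -> pd.Series:
    """Parse EBD observation counts; "X" means present-but-uncounted."""
    s = raw.astype(str).str.strip()
    counts = pd.array([pd.NA] * len(s), dtype="Int64")
    is_x = s.str.upper().eq("X")
    numeric = pd.to_numeric(s.where(~is_x), errors="coerce")
    bad = numeric.isna() & ~is_x
    if bad.any():
        rows = [str(i) for i in s.index[bad][:10]]
        raise ValueError(
            f"unparseable observation count at row(s) {', '.join(rows)}"
            + (" ..." if bad.sum() > 10 else "")
        )
    neg = numeric.notna() & (numeric < 0)
    if neg.any():
        raise ValueError(f"negative count at row(s) {list(s.index[neg][:10])}")
    counts = pd.array(numeric.round(), dtype="Int64")
    return pd.Series(counts, index=s.index, name="count")


def read_observations(
    path: str | Path,
    species_code: str,
    columns: ColumnMap | None = None,
) -> pd.DataFrame:
    """Read an EBD observation table, keeping only the focal species.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    species_code
        Exact species code to retain (e.g. ``"lobcur"``).
    columns
        Header-name mapping; defaults to the official EBD spelling.

    Returns
    -------
    DataFrame with columns ``checklist_id``, ``species_code``, ``count``
    (nullable Int64; ``pd.NA`` encodes "X").
    """
    cm = columns or ColumnMap()
    df = pd.read_csv(path, sep="\t", dtype=str)
    cm.require(list(df.columns), ["checklist_id", "species_code", "count"])
    df = df.rename(
        columns={cm.checklist_id: "checklist_id", cm.species_code: "species_code", cm.count: "count"}
    )
    df = df[df["species_code"] == species_code].copy()
    if df["checklist_id"].isna().any() or (df["checklist_id"].astype(str) == "").any():
        raise ValueError("empty checklist_id in observation table")
    df["count"] = _parse_counts(df["count"])
    return df[OBS_COLUMNS].reset_index(drop=True)


def read_sampling_events(path: str | Path, columns: ColumnMap | None = None) -> pd.DataFrame:
    """Read an EBD sampling-event table into canonical columns."""
    cm = columns or ColumnMap()
    df = pd.read_csv(path, sep="\t", dtype=str)
    cm.require(
        list(df.columns),
        ["checklist_id", "protocol", "date", "lat", "lon", "complete"],
    )
    mapping = {getattr(cm, f): f for f in EVENT_COLUMNS if getattr(cm, f) in df.columns}
    df = df.rename(columns=mapping)
    for opt in ("group_id", "duration_minutes", "distance_km", "n_observers"):
        if opt not in df.columns:
            df[opt] = np.nan
    out = pd.DataFrame(
        {
            "checklist_id": df["checklist_id"].astype(str),
            "group_id": df["group_id"].where(df["group_id"].notna() & (df["group_id"] != ""), np.nan),
            "protocol": _normalize_protocol(df["protocol"]),
            "date": pd.to_datetime(df["date"], format="%Y-%m-%d"),
            "duration_minutes": pd.to_numeric(df["duration_minutes"], errors="coerce"),
            "distance_km": pd.to_numeric(df["distance_km"], errors="coerce"),
            "n_observers": pd.to_numeric(df["n_observers"], errors="coerce"),
            "lat": pd.to_numeric(df["lat"], errors="raise"),
            "lon": pd.to_numeric(df["lon"], errors="raise"),
            "complete": df["complete"].astype(str).str.strip().isin(["1", "true", "True", "TRUE"]),
        }
    )
    if out["checklist_id"].duplicated().any():
        dups = out.loc[out["checklist_id"].duplicated(), "checklist_id"].unique()[:5]
        raise ValueError(f"duplicate checklist_id in sampling events: {list(dups)}")
    if (out["lat"].abs() > 90).any() or (out["lon"].abs() > 180).any():
        raise ValueError("latitude/longitude outside valid WGS84 range")
    return out[EVENT_COLUMNS]


def zero_fill(events: pd.DataFrame, obs: pd.DataFrame) -> pd.DataFrame:
    """Join observations onto sampling events, filling non-detections.

    Every sampling event yields exactly one checklist record. An event is
    ``detected`` iff at least one observation row references it; events
    with no observation get ``count = 0``.

    Raises
    ------
    ValueError
        If an observation references a checklist_id absent from the
        sampling-event table (orphan observations indicate a mismatched
        extract).
    """
    ev_ids = set(events["checklist_id"])
    orphans = sorted(set(obs["checklist_id"]) - ev_ids)
    if orphans:
        raise ValueError(
            f"{len(orphans)} observation(s) reference unknown checklist_id(s): "
            f"{orphans[:10]}"
        )
    # one row per event even if the extract holds duplicate species rows
    per_event = (
        obs.groupby("checklist_id", sort=False)["count"].max().rename("count")
        if len(obs)
        else pd.Series(dtype="Int64", name="count")
    )
    out = events.merge(per_event, how="left", left_on="checklist_id", right_index=True)
    out["detected"] = out["checklist_id"].isin(set(obs["checklist_id"]))
    out["count"] = out["count"].astype("Int64")
    out.loc[~out["detected"], "count"] = 0
    return out.reset_index(drop=True)


def collapse_shared(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse shared (group) checklists to one representative each.

    eBird lets multiple observers share one birding event; keeping every
    copy would pseudo-replicate the same observation. Records sharing a
    non-missing ``group_id`` collapse to the lexicographically lowest
    ``checklist_id``; ``detected`` is the OR over the group and effort
    fields come from the representative row.
    """
    grouped = records[records["group_id"].notna()]
    if grouped.empty:
        return records.reset_index(drop=True)
    solo = records[records["group_id"].isna()]
    reps = []
    for _, grp in grouped.groupby("group_id", sort=False):
        rep = grp.loc[grp["checklist_id"].idxmin()].copy()
        rep["detected"] = bool(grp["detected"].any())
        if rep["detected"]:
            known = grp.loc[grp["detected"], "count"].dropna()
            rep["count"] = known.max() if len(known) else pd.NA
        else:
            rep["count"] = 0
        reps.append(rep)
    out = pd.concat([solo, pd.DataFrame(reps)], ignore_index=True)
    out["count"] = out["count"].astype("Int64")
    return out.sort_values("checklist_id", ignore_index=True)


def write_checklists(records: pd.DataFrame, path: str | Path) -> None:
    """Write zero-filled checklists as tab-separated text (canonical headers)."""
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)


def read_checklists(path: str | Path) -> pd.DataFrame:
    """Read a zero-filled checklist table written by :func:`write_checklists`."""
    df = pd.read_csv(path, sep="\t")
    df["checklist_id"] = df["checklist_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"])
    df["detected"] = df["detected"].astype(bool)
    df["complete"] = df["complete"].astype(bool)
    df["count"] = pd.array(df["count"], dtype="Int64")
    if "group_id" in df.columns:
        df["group_id"] = df["group_id"].astype(object).where(df["group_id"].notna(), np.nan)
    return df
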