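"""Checklist inclusion rules.

Semi-structured checklist data mix protocols and effort levels; trend
inference needs a comparable subset. The standard practice, followed
here, keeps only complete stationary/traveling checklists of bounded
effort (distance <= 5 km, duration <= 5 h), restricted to the focal
breeding season (May 1 - Jul 31) and study years (2010-2022). Thresholds
are boundary-inclusive for keeping, because the exclusions are phrased
strictly ("> 5 km", "longer than 5 h").

``apply_filters`` also returns a per-rule exclusion report: each dropped
record is counted once, at the first rule it fails, in the fixed order
protocol -> completeness -> distance -> duration -> season -> year. Rule
order affects only the report, never membership of the kept set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fixed report order; each excluded record is charged to its first failure
RULE_ORDER = ["protocol", "completeness", "distance", "duration", "season", "year"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for checklist inclusion.

    ``max_distance_km`` applies to traveling checklists only (stationary
    counts have no travel distance). Records with missing duration are
    excluded — their effort cannot be bounded. Season bounds are
    month-day pairs applied within every year of ``year_range``.
    """

    allowed_protocols: frozenset = frozenset({"stationary", "traveling"})
    max_distance_km: float = 5.0
    max_duration_hours: float = 5.0
    require_complete: bool = True
    season_start: tuple = (5, 1)
    season_end: tuple = (7, 31)
    year_range: tuple = (2010, 2022)

    def __post_init__(self):
        if self.max_distance_km <= 0:
            raise ValueError("max_distance_km must be > 0")
        if self.max_duration_hours <= 0:
            raise ValueError("max_duration_hours must be > 0")
        if tuple(self.season_start) > tuple(self.season_end):
            raise ValueError("season_start must not be after season_end")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (lo, hi) with lo <= hi")

    def to_dict(self) -> dict:
        return {
            "allowed_protocols": sorted(self.allowed_protocols),
            "max_distance_km": self.max_distance_km,
            "max_duration_hours": self.max_duration_hours,
            "require_complete": self.require_complete,
            "season_start": list(self.season_start),
            "season_end": list(self.season_end),
            "year_range": list(self.year_range),
        }


def _failure_masks(records: pd.DataFrame, cfg: FilterConfig) -> dict[str, np.ndarray]:
    """Boolean failure mask per rule (True = record fails that rule)."""
    protocol_fail = ~records["protocol"].isin(cfg.allowed_protocols).to_numpy()
    complete_fail = (
        ~records["complete"].to_numpy() if cfg.require_complete else np.zeros(len(records), bool)
    )
    traveling = records["protocol"].eq("traveling").to_numpy()
    dist = records["distance_km"].to_numpy(dtype=float)
    # missing distance disqualifies only traveling records
    distance_fail = traveling & (np.isnan(dist) | (dist > cfg.max_distance_km))
    dur = records["duration_minutes"].to_numpy(dtype=float)
    duration_fail = np.isnan(dur) | (dur > cfg.max_duration_hours * 60.0)
    dates = pd.to_datetime(records["date"])
    md = list(zip(dates.dt.month, dates.dt.day))
    season_fail = np.array(
        [not (tuple(cfg.season_start) <= m_d <= tuple(cfg.season_end)) for m_d in md], dtype=bool
    )
    years = dates.dt.year.to_numpy()
    year_fail = (years < cfg.year_range[0]) | (years > cfg.year_range[1])
    return {
        "protocol": protocol_fail,
        "completeness": complete_fail,
        "distance": distance_fail,
        "duration": duration_fail,
        "season": season_fail,
        "year": year_fail,
    }


def apply_filters(
    records: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply all inclusion rules; return (kept records, exclusion report).

    A record is kept iff it passes every rule; the report charges each
    excluded record to its first failing rule in :data:`RULE_ORDER` and
    always satisfies ``sum(report.values()) + len(kept) == len(records)``.
    Filtering never raises on data values.
    """
    cfg = cfg or FilterConfig()
    if len(records) == 0:
        return records.copy(), {rule: 0 for rule in RULE_ORDER}
    masks = _failure_masks(records, cfg)
    report: dict[str, int] = {}
    already_excluded = np.zeros(len(records), dtype=bool)
    for rule in RULE_ORDER:
        first_fail = masks[rule] & ~already_excluded
        report[rule] = int(first_fail.sum())
        already_excluded |= masks[rule]
    kept = records.loc[~already_excluded].reset_index(drop=True)
    return kept, report


def write_report(report: dict[str, int], n_kept: int, path) -> None:
    """Write the exclusion report as a small two-column text table."""
    rows = [{"rule": rule, "n_excluded": n} for rule, n in report.items()]
    rows.append({"rule": "kept", "n_excluded": n_kept})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
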