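import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rangeshift import ebd_io, filtering
from rangeshift.filtering import FilterConfig, RULE_ORDER, apply_filters

from conftest import make_events, make_obs


def _records(rows):
    return ebd_io.zero_fill(make_events(rows), make_obs([]))


@pytest.mark.parametrize(
    ("row", "rule"),
    [
        ({"protocol": "incidental"}, "protocol"),
        ({"protocol": "historical"}, "protocol"),
        ({"complete": False}, "completeness"),
        ({"protocol": "traveling", "distance_km": 6.0}, "distance"),
        ({"protocol": "traveling", "distance_km": np.nan}, "distance"),
        ({"duration_minutes": 330.0}, "duration"),  # 5.5 h
        ({"duration_minutes": np.nan}, "duration"),
        ({"date": pd.Timestamp("2015-08-01")}, "season"),
        ({"date": pd.Timestamp("2015-04-30")}, "season"),
        ({"date": pd.Timestamp("2009-06-15")}, "year"),
        ({"date": pd.Timestamp("2023-06-15")}, "year"),
    ],
)
def test_single_violation_charged_to_its_rule(row, rule):
    base = {"checklist_id": "S1"}
    base.update(row)
    kept, report = apply_filters(_records([base]))
    assert kept.empty
    assert report[rule] == 1
    assert sum(report.values()) == 1


def test_boundary_values_are_kept():
    """Exactly 5 km / 5 h pass: only strictly greater effort is excluded."""
    kept, report = apply_filters(
        _records(
            [
                {
                    "checklist_id": "S1",
                    "protocol": "traveling",
                    "distance_km": 5.0,
                    "duration_minutes": 300.0,
                    "date": pd.Timestamp("2010-05-01"),
                },
                {
                    "checklist_id": "S2",
                    "protocol": "traveling",
                    "distance_km": 4.9,
                    "duration_minutes": 294.0,
                    "date": pd.Timestamp("2022-07-31"),
                },
            ]
        )
    )
    assert len(kept) == 2
    assert sum(report.values()) == 0


def test_stationary_checklists_need_no_distance():
    kept, _ = apply_filters(
        _records([{"checklist_id": "S1", "protocol": "stationary", "distance_km": np.nan}])
    )
    assert len(kept) == 1


def test_first_failing_rule_wins_in_the_report():
    # incidental AND incomplete AND too long: charged to protocol only
    kept, report = apply_filters(
        _records(
            [
                {
                    "checklist_id": "S1",
                    "protocol": "incidental",
                    "complete": False,
                    "duration_minutes": 400.0,
                }
            ]
        )
    )
    assert report["protocol"] == 1
    assert report["completeness"] == 0
    assert report["duration"] == 0


def test_empty_input_gives_empty_report():
    kept, report = apply_filters(_records([{"checklist_id": "S1"}]).iloc[0:0])
    assert kept.empty
    assert all(v == 0 for v in report.values())
    assert list(report) == RULE_ORDER


@given(seed=st.integers(0, 2**16))
def test_bookkeeping_is_exact(seed):
    """Per-rule exclusions plus kept records account for every input row."""
    rng = np.random.default_rng(seed)
    n = 80
    rows = []
    for i in range(n):
        rows.append(
            {
                "checklist_id": f"S{i:03d}",
                "protocol": rng.choice(["stationary", "traveling", "incidental"]),
                "complete": bool(rng.random() < 0.8),
                "distance_km": float(rng.uniform(0, 8)),
                "duration_minutes": float(rng.uniform(0, 400)),
                "date": pd.Timestamp("2010-01-01")
                + pd.Timedelta(days=int(rng.integers(0, 5000))),
            }
        )
    records = _records(rows)
    kept, report = apply_filters(records)
    assert sum(report.values()) + len(kept) == len(records)


def test_membership_independent_of_rule_order():
    """kept equals the record-wise AND of all rules, however they are ordered."""
    rng = np.random.default_rng(11)
    rows = []
    for i in range(120):
        rows.append(
            {
                "checklist_id": f"S{i:03d}",
                "protocol": rng.choice(["stationary", "traveling", "incidental", "historical"]),
                "complete": bool(rng.random() < 0.7),
                "distance_km": float(rng.uniform(0, 10)),
                "duration_minutes": float(rng.uniform(0, 500)),
                "date": pd.Timestamp("2008-01-01")
                + pd.Timedelta(days=int(rng.integers(0, 6000))),
            }
        )
    records = _records(rows)
    kept, _ = apply_filters(records)
    cfg = FilterConfig()
    # independent oracle: evaluate each rule directly per record
    expected = set()
    for _, r in records.iterrows():
        ok = r["protocol"] in cfg.allowed_protocols
        ok &= bool(r["complete"])
        if r["protocol"] == "traveling":
            ok &= float(r["distance_km"]) <= cfg.max_distance_km if np.isfinite(r["distance_km"]) else False
        ok &= np.isfinite(r["duration_minutes"]) and r["duration_minutes"] <= cfg.max_duration_hours * 60
        md = (r["date"].month, r["date"].day)
        ok &= cfg.season_start <= md <= cfg.season_end
        ok &= cfg.year_range[0] <= r["date"].year <= cfg.year_range[1]
        if ok:
            expected.add(r["checklist_id"])
    assert set(kept["checklist_id"]) == expected


@pytest.mark.parametrize(
    "relax",
    [
        dict(max_distance_km=8.0),
        dict(max_duration_hours=7.0),
        dict(require_complete=False),
        dict(year_range=(2005, 2025)),
        dict(season_start=(4, 1)),
        dict(season_end=(8, 31)),
        dict(allowed_protocols=frozenset({"stationary", "traveling", "incidental"})),
    ],
)
def test_relaxing_a_threshold_never_shrinks_kept(relax):
    rng = np.random.default_rng(5)
    rows = []
    for i in range(150):
        rows.append(
            {
                "checklist_id": f"S{i:03d}",
                "protocol": rng.choice(["stationary", "traveling", "incidental"]),
                "complete": bool(rng.random() < 0.7),
                "distance_km": float(rng.uniform(0, 10)),
                "duration_minutes": float(rng.uniform(0, 500)),
                "date": pd.Timestamp("2008-01-01")
                + pd.Timedelta(days=int(rng.integers(0, 6000))),
            }
        )
    records = _records(rows)
    strict, _ = apply_filters(records, FilterConfig())
    relaxed, _ = apply_filters(records, FilterConfig(**relax))
    assert set(strict["checklist_id"]) <= set(relaxed["checklist_id"])


@pytest.mark.parametrize(
    "bad",
    [dict(max_distance_km=-1.0), dict(max_duration_hours=0.0), dict(year_range=(2022, 2010))],
)
def test_invalid_config_is_rejected(bad):
    with pytest.raises(ValueError):
        FilterConfig(**bad)
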