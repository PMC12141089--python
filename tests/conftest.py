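import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from rangeshift.gridding import GridSpec
from rangeshift.synthetic import SyntheticConfig, default_effort_centers

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A light simulation (sparser hotspots, fewer checklists) for unit tests."""
    return SyntheticConfig(
        n_checklists_per_year=300,
        effort_centers=default_effort_centers(n_side=8),
        seed=42,
    )


def make_events(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical sampling-event table from terse row dicts."""
    defaults = dict(
        group_id=np.nan,
        protocol="stationary",
        date=pd.Timestamp("2015-06-15"),
        duration_minutes=60.0,
        distance_km=np.nan,
        n_observers=1,
        lat=44.0,
        lon=-110.0,
        complete=True,
    )
    out = []
    for row in rows:
        rec = dict(defaults)
        rec.update(row)
        out.append(rec)
    columns = ["checklist_id"] + list(defaults)
    df = pd.DataFrame(out, columns=columns)
    df["date"] = pd.to_datetime(df["date"])
    return df


def make_obs(checklist_ids, counts=None) -> pd.DataFrame:
    counts = counts if counts is not None else [1] * len(checklist_ids)
    return pd.DataFrame(
        {
            "checklist_id": list(checklist_ids),
            "species_code": "lobcur",
            "count": pd.array(counts, dtype="Int64"),
        }
    )
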