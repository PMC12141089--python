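"""Synthetic checklist generator with known occupancy and effort drift.

Real community-science extracts cannot ship with a code artifact, and
their true range dynamics are unknown anyway. This module simulates the
joint process the pipeline must untangle:

* **Observer effort** is a mixture of Gaussian "hotspots" (birding
  locations revisited year after year, as in real checklist data, which
  is what makes the >= 5-year cell-retention rule meaningful). Hotspot
  usage fluctuates from year to year (lognormal weight noise). Effort
  drift is modelled as *reallocation*: hotspot positions stay fixed but
  their usage weights are exponentially tilted each year so the effort
  mixture's mean position moves at the configured degrees-per-year rate
  — mimicking how observer coverage really shifts (new participants in
  new areas) while keeping locations revisitable, which a wholesale
  positional shift of the hotspot field would not.
* **Species occupancy** is an isotropic Gaussian kernel: a checklist at
  distance ``d`` (projected metres) from the year's occupancy center
  detects the species with probability
  ``detection_prob_at_center * exp(-d^2 / (2 * occupancy_sd_km^2))``.
  The center moves at a configurable degrees-per-year drift — the ground
  truth a correct pipeline should recover.
* **Contaminants** — incidental-protocol, incomplete, over-distance
  (> 5 km) and over-duration (> 5 h) checklists — are injected in
  mutually exclusive slots at configured fractions, so the filter
  stage's per-rule exclusion report can be checked against the exact
  injected counts.

Randomness uses one master seed with per-year substreams, so changing
one year's sample size never perturbs another year's draws. Output
tables use the exact EBD-style dialect :mod:`rangeshift.ebd_io` reads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .projection import AlbersEqualArea

SPECIES_CODE = "lobcur"

#: domain of the default synthetic landscape (lat, lon bounds)
DOMAIN = {"lat": (38.0, 52.0), "lon": (-117.0, -103.0)}


def default_effort_centers(
    n_side: int = 16,
    sd_km: float = 8.0,
    jitter_deg: float = 0.2,
    weight_sigma: float = 0.5,
) -> list[tuple[float, float, float, float]]:
    """A fixed hotspot field: jittered n x n grid over the domain.

    Weights are lognormal (some hotspots are much busier than others)
    and normalized to sum to 1. Deterministic — the layout is part of
    the default study conditions, not of the per-run randomness.
    """
    rng = np.random.default_rng(20259)
    lat_lo, lat_hi = DOMAIN["lat"]
    lon_lo, lon_hi = DOMAIN["lon"]
    lats = np.linspace(lat_lo + 0.5, lat_hi - 0.5, n_side)
    lons = np.linspace(lon_lo + 0.5, lon_hi - 0.5, n_side)
    centers = []
    weights = rng.lognormal(0.0, weight_sigma, size=n_side * n_side)
    weights /= weights.sum()
    k = 0
    for la in lats:
        for lo in lons:
            centers.append(
                (
                    float(la + rng.uniform(-jitter_deg, jitter_deg)),
                    float(lo + rng.uniform(-jitter_deg, jitter_deg)),
                    float(weights[k]),
                    sd_km,
                )
            )
            k += 1
    return centers


@dataclass
class SyntheticConfig:
    """Parameters of the simulated checklist process.

    Drifts are in degrees per year (lat, lon); distances and kernel
    widths in kilometres. ``protocol_mix`` is the probability a clean
    checklist uses the traveling protocol. Contaminant fractions are
    probabilities of mutually exclusive corruption slots.
    """

    years: tuple[int, int] = (2010, 2022)
    n_checklists_per_year: int = 2000
    effort_centers: list = field(default_factory=default_effort_centers)
    effort_drift: tuple[float, float] = (0.0, 0.0)
    occupancy_center_0: tuple[float, float] = (44.4, -110.0)
    occupancy_drift: tuple[float, float] = (0.0, 0.0)
    occupancy_sd_km: float = 180.0
    detection_prob_at_center: float = 0.9
    protocol_mix: float = 0.75
    frac_incidental: float = 0.04
    frac_incomplete: float = 0.08
    frac_over_distance: float = 0.04
    frac_over_duration: float = 0.04
    effort_weight_sd: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        """Raise ValueError naming every invalid field."""
        bad = []
        if self.years[0] > self.years[1]:
            bad.append("years")
        if self.n_checklists_per_year <= 0:
            bad.append("n_checklists_per_year")
        if not self.effort_centers or any(c[3] <= 0 or c[2] < 0 for c in self.effort_centers):
            bad.append("effort_centers")
        if self.occupancy_sd_km <= 0:
            bad.append("occupancy_sd_km")
        if not (0.0 <= self.detection_prob_at_center <= 1.0):
            bad.append("detection_prob_at_center")
        if not (0.0 <= self.protocol_mix <= 1.0):
            bad.append("protocol_mix")
        for name in ("frac_incidental", "frac_incomplete", "frac_over_distance", "frac_over_duration"):
            if not (0.0 <= getattr(self, name) < 1.0):
                bad.append(name)
        total = (
            self.frac_incidental
            + self.frac_incomplete
            + self.frac_over_distance
            + self.frac_over_duration
        )
        if total >= 1.0:
            bad.append("contaminant fractions (sum >= 1)")
        if self.effort_weight_sd < 0:
            bad.append("effort_weight_sd")
        if self.seed < 0:
            bad.append("seed")
        if bad:
            raise ValueError(f"invalid SyntheticConfig field(s): {', '.join(bad)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effort_centers"] = [list(c) for c in self.effort_centers]
        return d


# contaminant slot -> the filter rule that must catch it
CONTAMINANT_RULES = {
    "incidental": "protocol",
    "incomplete": "completeness",
    "over_distance": "distance",
    "over_duration": "duration",
}


def _tilt_weights(
    base_w: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
    dlat: float,
    dlon: float,
) -> np.ndarray:
    """Exponentially tilt mixture weights to shift the mean position.

    Finds tilt coefficients (a, b) such that the weighted mean of the
    hotspot positions under ``base_w * exp(a*lat + b*lon)`` moves by
    (dlat, dlon) degrees from the untilted mean. Solved per axis by
    bisection with a couple of relaxation sweeps for the (weak) cross
    coupling between axes.
    """
    if dlat == 0.0 and dlon == 0.0:
        return base_w
    lat0 = float(np.dot(base_w, lats))
    lon0 = float(np.dot(base_w, lons))
    if not (lats.min() < lat0 + dlat < lats.max()) or not (
        lons.min() < lon0 + dlon < lons.max()
    ):
        raise ValueError(
            "effort_drift moves the effort centroid outside the hotspot field"
        )

    def tilted(a: float, b: float) -> np.ndarray:
        w = base_w * np.exp(a * (lats - lat0) + b * (lons - lon0))
        return w / w.sum()

    a = b = 0.0
    for _ in range(4):
        if dlat != 0.0:
            a = brentq(lambda aa: float(np.dot(tilted(aa, b), lats)) - (lat0 + dlat), -50.0, 50.0)
        if dlon != 0.0:
            b = brentq(lambda bb: float(np.dot(tilted(a, bb), lons)) - (lon0 + dlon), -50.0, 50.0)
    return tilted(a, b)


def _season_dates(rng: np.random.Generator, year: int, n: int) -> pd.Series:
    start = pd.Timestamp(year=year, month=5, day=1)
    end = pd.Timestamp(year=year, month=7, day=31)
    offsets = rng.integers(0, (end - start).days + 1, size=n)
    return pd.Series(start + pd.to_timedelta(offsets, unit="D"))


def generate(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one study's sampling-event and observation tables.

    Returns
    -------
    events, observations, truth
        ``events``/``observations`` are canonical-column DataFrames (see
        :mod:`rangeshift.ebd_io`); ``truth`` records the imposed drifts,
        per-rule contaminant counts and per-year occupancy centers.
    """
    cfg.validate()
    proj = AlbersEqualArea()
    year_lo, year_hi = cfg.years
    centers = np.array([(c[0], c[1]) for c in cfg.effort_centers], dtype=float)
    base_w = np.array([c[2] for c in cfg.effort_centers], dtype=float)
    base_w = base_w / base_w.sum()
    sd_m = np.array([c[3] for c in cfg.effort_centers], dtype=float) * 1000.0

    slot_names = list(CONTAMINANT_RULES)
    slot_p = np.array(
        [cfg.frac_incidental, cfg.frac_incomplete, cfg.frac_over_distance, cfg.frac_over_duration]
    )
    contaminant_counts = {rule: 0 for rule in CONTAMINANT_RULES.values()}

    ev_frames, obs_frames = [], []
    occupancy_centers = {}
    for year in range(year_lo, year_hi + 1):
        rng = np.random.default_rng([cfg.seed, year])
        n = cfg.n_checklists_per_year
        t = year - year_lo

        # effort drift = usage reallocation over fixed hotspots, plus
        # year-to-year fluctuation in how busy each hotspot is
        w = _tilt_weights(
            base_w, centers[:, 0], centers[:, 1],
            cfg.effort_drift[0] * t, cfg.effort_drift[1] * t,
        )
        w = w * rng.lognormal(0.0, cfg.effort_weight_sd, size=len(base_w))
        w /= w.sum()
        which = rng.choice(len(centers), size=n, p=w)
        c_lat = centers[which, 0]
        c_lon = centers[which, 1]
        cx, cy = proj.forward(c_lon, c_lat)
        x = cx + rng.normal(0.0, sd_m[which])
        y = cy + rng.normal(0.0, sd_m[which])
        lon, lat = proj.inverse(x, y)

        # detection from the Gaussian occupancy kernel (projected plane)
        occ_lat = cfg.occupancy_center_0[0] + cfg.occupancy_drift[0] * t
        occ_lon = cfg.occupancy_center_0[1] + cfg.occupancy_drift[1] * t
        occupancy_centers[year] = (occ_lat, occ_lon)
        ox, oy = proj.forward(occ_lon, occ_lat)
        d2 = (x - ox) ** 2 + (y - oy) ** 2
        sigma_m = cfg.occupancy_sd_km * 1000.0
        p_det = cfg.detection_prob_at_center * np.exp(-d2 / (2.0 * sigma_m**2))
        detected = rng.random(n) < p_det

        # mutually exclusive contaminant slots
        u = rng.random(n)
        slot = np.full(n, "clean", dtype=object)
        edges = np.concatenate([[0.0], np.cumsum(slot_p)])
        for name, lo, hi in zip(slot_names, edges[:-1], edges[1:]):
            slot[(u >= lo) & (u < hi)] = name
        for name in slot_names:
            contaminant_counts[CONTAMINANT_RULES[name]] += int((slot == name).sum())

        protocol = np.where(rng.random(n) < cfg.protocol_mix, "traveling", "stationary").astype(object)
        protocol[slot == "incidental"] = "incidental"
        protocol[slot == "over_distance"] = "traveling"

        distance = np.where(
            protocol == "traveling", rng.uniform(0.5, 5.0, size=n), np.nan
        )
        distance[slot == "over_distance"] = rng.uniform(5.5, 20.0, size=int((slot == "over_distance").sum()))
        duration = rng.uniform(10.0, 300.0, size=n)
        duration[slot == "over_duration"] = rng.uniform(301.0, 600.0, size=int((slot == "over_duration").sum()))
        complete = slot != "incomplete"
        n_observers = 1 + rng.poisson(0.8, size=n)

        ids = np.array([f"S{year}{i:06d}" for i in range(n)])
        events = pd.DataFrame(
            {
                "checklist_id": ids,
                "group_id": np.nan,
                "protocol": protocol,
                "date": _season_dates(rng, year, n),
                "duration_minutes": duration,
                "distance_km": np.round(distance, 3),
                "n_observers": n_observers,
                "lat": lat,
                "lon": lon,
                "complete": complete,
            }
        )
        ev_frames.append(events)

        det_ids = ids[detected]
        counts = 1 + rng.poisson(1.0, size=len(det_ids))
        counts = pd.array(counts, dtype="Int64")
        # a small share of present-but-uncounted ("X") reports
        x_mask = rng.random(len(det_ids)) < 0.02
        counts[x_mask] = pd.NA
        obs_frames.append(
            pd.DataFrame(
                {"checklist_id": det_ids, "species_code": SPECIES_CODE, "count": counts}
            )
        )

    events = pd.concat(ev_frames, ignore_index=True)
    obs = pd.concat(obs_frames, ignore_index=True)
    truth = {
        "seed": cfg.seed,
        "occupancy_drift": list(cfg.occupancy_drift),
        "effort_drift": list(cfg.effort_drift),
        "occupancy_centers": {str(y): list(c) for y, c in occupancy_centers.items()},
        "contaminant_counts": contaminant_counts,
        "n_events": int(len(events)),
        "n_detections": int(len(obs)),
    }
    return events, obs, truth


def write_ebd_tables(events: pd.DataFrame, obs: pd.DataFrame, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the tables in the EBD-style dialect :mod:`ebd_io` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ev = pd.DataFrame(
        {
            "SAMPLING EVENT IDENTIFIER": events["checklist_id"],
            "GROUP IDENTIFIER": events["group_id"].fillna(""),
            "PROTOCOL TYPE": events["protocol"].str.capitalize(),
            "OBSERVATION DATE": pd.to_datetime(events["date"]).dt.strftime("%Y-%m-%d"),
            "DURATION MINUTES": events["duration_minutes"],
            "EFFORT DISTANCE KM": events["distance_km"],
            "NUMBER OBSERVERS": events["n_observers"],
            "LATITUDE": events["lat"].round(6),
            "LONGITUDE": events["lon"].round(6),
            "ALL SPECIES REPORTED": events["complete"].astype(int),
        }
    )
    counts = obs["count"].astype(object).where(obs["count"].notna(), "X")
    ob = pd.DataFrame(
        {
            "SAMPLING EVENT IDENTIFIER": obs["checklist_id"],
            "SPECIES CODE": obs["species_code"],
            "OBSERVATION COUNT": counts,
        }
    )
    ev_path = out_dir / "sampling_events.txt"
    obs_path = out_dir / "observations.txt"
    ev.to_csv(ev_path, sep="\t", index=False)
    ob.to_csv(obs_path, sep="\t", index=False)
    return ev_path, obs_path


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def make_region_fixture(layout: str, path: str | Path) -> Path:
    """Write a small GeoJSON region file covering the synthetic domain.

    ``two_rectangles`` splits the domain into west/east halves;
    ``eight_band`` tiles it into eight named longitude bands, mimicking
    an eight-region (BCR-like) stratification. Polygons tile the domain
    without overlap.
    """
    lat_lo, lat_hi = DOMAIN["lat"]
    lon_lo, lon_hi = DOMAIN["lon"]
    if layout == "two_rectangles":
        edges = np.linspace(lon_lo, lon_hi, 3)
        names = ["west", "east"]
    elif layout == "eight_band":
        edges = np.linspace(lon_lo, lon_hi, 9)
        names = [f"BCR{i + 1}" for i in range(8)]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    features = []
    for name, lo, hi in zip(names, edges[:-1], edges[1:]):
        ring = [[lo, lat_lo], [hi, lat_lo], [hi, lat_hi], [lo, lat_hi], [lo, lat_lo]]
        features.append(
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path
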