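"""Ingestion of boat-based line-transect survey logs into a segment table.

The modelling unit is a fixed-length along-track *segment* (600 m for
guillemot, 1 km for harbour porpoise).  This module reads the four survey log
files (GPS track, sightings, sea state, survey-phase lookup), projects the
track to UTM zone 30N, chops each transect into half-open chainage intervals
``[k*L, (k+1)*L)``, interpolates sighting positions from their timestamps,
sums counts per segment, and classifies survey conditions from Beaufort sea
state (0-2 good, 3-5 poor).

Conventions where the field protocol is silent:

* the final partial segment of a transect is retained with its true effort
  length (models use ``log(effort/nominal)`` as an offset);
* a sighting whose chainage falls exactly on a segment boundary belongs to
  the following segment (half-open intervals); the transect end point belongs
  to the last segment;
* sea state is carried forward from the most recent record at or before a
  segment's midpoint time, matching the record-every-15-minutes protocol;
* footprint membership of a segment is decided by its midpoint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, shape

from .utm import project_to_utm

logger = logging.getLogger(__name__)

PHASES = ("preconstruction", "construction", "operation")
SPECIES = ("guillemot", "harbor_porpoise")

#: nominal along-track segment length per species, metres
NOMINAL_LENGTH = {"guillemot": 600.0, "harbor_porpoise": 1000.0}

SEGMENT_COLUMNS = [
    "segment_id",
    "survey_id",
    "transect_id",
    "phase",
    "x",
    "y",
    "effort_m",
    "condition",
    "count",
]


@dataclass
class SegmentTable:
    """One row per surveyed segment; the unit of the count models."""

    species: str
    nominal_length: float
    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if not (self.rows["effort_m"] > 0).all():
            raise ValueError("segment effort must be positive")
        if (self.rows["effort_m"] > self.nominal_length + 1.0).any():
            raise ValueError("segment effort exceeds nominal length")

    def to_csv(self, path) -> None:
        self.rows.loc[:, SEGMENT_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species: str) -> "SegmentTable":
        rows = pd.read_csv(path, dtype={"survey_id": str, "transect_id": str})
        return cls(species=species, nominal_length=NOMINAL_LENGTH[species], rows=rows)


# ---------------------------------------------------------------------------
# file readers


def _parse_time(col: pd.Series) -> pd.Series:
    ts = pd.to_datetime(col, utc=True, format="ISO8601")
    return ts.astype("int64") / 1e9


def read_track(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"survey_id": str, "transect_id": str})
    df["t"] = _parse_time(df["timestamp_iso8601"])
    if not df["lat"].between(-90, 90, inclusive="neither").all():
        raise ValueError("latitude out of range")
    if not df["lon"].between(-180, 180, inclusive="neither").all():
        raise ValueError("longitude out of range")
    df = df.sort_values(["survey_id", "transect_id", "t"], kind="stable").reset_index(drop=True)
    dup = df.groupby(["survey_id", "transect_id"])["t"].apply(
        lambda s: (np.diff(s.to_numpy()) <= 0).any()
    )
    if dup.any():
        raise ValueError("track timestamps must be strictly increasing within a transect")
    x, y = project_to_utm(df["lon"].to_numpy(), df["lat"].to_numpy())
    df["x"], df["y"] = x, y
    return df


def read_sightings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"survey_id": str})
    df["t"] = _parse_time(df["timestamp_iso8601"])
    if (df["count"] < 1).any():
        raise ValueError("sighting count must be >= 1")
    bad = (df["behavior"] == "not_applicable") & (df["species"] != "harbor_porpoise")
    if bad.any():
        raise ValueError("behavior=not_applicable is only valid for harbor_porpoise")
    return df


def read_seastate(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"survey_id": str, "transect_id": str})
    df["t"] = _parse_time(df["timestamp_iso8601"])
    if not df["beaufort"].isin(range(6)).all():
        raise ValueError("Beaufort sea state must be in 0..5")
    return df.sort_values(["survey_id", "transect_id", "t"], kind="stable")


def read_phases(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype={"survey_id": str})
    bad = set(df["phase"]) - set(PHASES)
    if bad:
        raise ValueError(f"unknown development phase(s): {sorted(bad)}")
    return dict(zip(df["survey_id"], df["phase"]))


def read_footprint(path) -> Polygon:
    """Read a GeoJSON footprint polygon (WGS84) and project it to UTM."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = shape(gj["features"][0]["geometry"])
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    lon, lat = np.array(geom.exterior.coords).T
    x, y = project_to_utm(lon, lat)
    return Polygon(np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# segmentation


_SLIVER_M = 1.0  # trailing chainage below this is treated as rounding noise


def _chainage(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    steps = np.hypot(np.diff(x), np.diff(y))
    return np.concatenate([[0.0], np.cumsum(steps)])


def segment_transects(track: pd.DataFrame, nominal_length: float) -> pd.DataFrame:
    """Divide every transect polyline into fixed-length chainage segments.

    Returns one row per segment with the along-track interval, the true
    effort length (the final segment may be partial), and the midpoint
    position/time interpolated along the track.
    """
    if nominal_length <= 0:
        raise ValueError("nominal_length must be positive")
    out = []
    for (survey, transect), grp in track.groupby(["survey_id", "transect_id"], sort=True):
        if len(grp) < 2:
            raise ValueError(f"transect {survey}/{transect} has fewer than 2 track points")
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()
        t = grp["t"].to_numpy()
        chain = _chainage(x, y)
        total = chain[-1]
        if total <= 0:
            raise ValueError(f"transect {survey}/{transect} has zero length")
        # a trailing sliver below 1 m is GPS-rounding noise, not real effort:
        # absorb it into the last full segment instead of creating a segment
        n_seg = max(1, int(np.ceil((total - _SLIVER_M) / nominal_length)))
        starts = np.arange(n_seg) * nominal_length
        ends = np.minimum(starts + nominal_length, total)
        ends[-1] = total
        mids = 0.5 * (starts + ends)
        out.append(
            pd.DataFrame(
                {
                    "segment_id": [f"{survey}-{transect}-{k:03d}" for k in range(n_seg)],
                    "survey_id": survey,
                    "transect_id": transect,
                    "seg_index": np.arange(n_seg),
                    "chain_start": starts,
                    "chain_end": ends,
                    "effort_m": ends - starts,
                    "x": np.interp(mids, chain, x),
                    "y": np.interp(mids, chain, y),
                    "t_mid": np.interp(mids, chain, t),
                    "transect_length": total,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# sighting assignment


def assign_sightings(
    sightings: pd.DataFrame,
    track: pd.DataFrame,
    segments: pd.DataFrame,
    species: str,
    on_sea_only: bool = True,
    phases: dict[str, str] | None = None,
    nominal_length: float | None = None,
) -> SegmentTable:
    """Assign sightings to segments by time-interpolated position; sum counts.

    Sightings are positioned by linear interpolation of along-track chainage
    between the bracketing GPS fixes (observation clocks were synchronised to
    the GPS).  Guillemot records 'in flight' are dropped when ``on_sea_only``;
    sightings outside any transect's time span are counted and excluded.
    """
    segs = segments.copy()
    segs["count"] = 0

    sel = sightings[sightings["species"] == species]
    if species == "guillemot" and on_sea_only:
        sel = sel[sel["behavior"] == "on_sea"]

    # per-transect time->chainage interpolators
    spans = {}
    for (survey, transect), grp in track.groupby(["survey_id", "transect_id"], sort=True):
        t = grp["t"].to_numpy()
        chain = _chainage(grp["x"].to_numpy(), grp["y"].to_numpy())
        spans[(survey, transect)] = (t, chain)

    seg_key = {}
    for i, row in segs.iterrows():
        seg_key[(row["survey_id"], row["transect_id"], int(row["seg_index"]))] = i
    n_per_transect = segs.groupby(["survey_id", "transect_id"])["seg_index"].max()
    nominal = float(nominal_length) if nominal_length is not None else NOMINAL_LENGTH[species]

    n_excluded = 0
    # deterministic order independent of input order
    sel = sel.sort_values(["survey_id", "t", "species", "count"], kind="stable")
    for _, s in sel.iterrows():
        placed = False
        for (survey, transect), (t, chain) in spans.items():
            if survey != s["survey_id"]:
                continue
            if t[0] <= s["t"] <= t[-1]:
                c = float(np.interp(s["t"], t, chain))
                k = int(c // nominal)
                k = min(k, int(n_per_transect[(survey, transect)]))
                segs.loc[seg_key[(survey, transect, k)], "count"] += int(s["count"])
                placed = True
                break
        if not placed:
            n_excluded += 1
            logger.warning(
                "sighting at t=%s (survey %s) outside any transect time span; excluded",
                s["timestamp_iso8601"],
                s["survey_id"],
            )

    if phases is not None:
        missing = set(segs["survey_id"]) - set(phases)
        if missing:
            raise ValueError(f"surveys missing from phase lookup: {sorted(missing)}")
        segs["phase"] = segs["survey_id"].map(phases)
    elif "phase" not in segs:
        segs["phase"] = "preconstruction"
    if "condition" not in segs:
        segs["condition"] = "good"

    table = SegmentTable(species=species, nominal_length=nominal, rows=segs)
    table.n_excluded = n_excluded
    return table


def classify_conditions(seastate: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Set each segment's condition from the most recent sea-state record.

    A segment takes the Beaufort value of the latest record at or before its
    midpoint time; Beaufort 0-2 maps to 'good', 3-5 to 'poor'.  If no record
    precedes the first segment, the transect's first record is used (sea state
    is logged at the start of each transect).
    """
    segs = segments.copy()
    beaufort = np.empty(len(segs), dtype=int)
    for (survey, transect), grp in segs.groupby(["survey_id", "transect_id"], sort=False):
        rec = seastate[
            (seastate["survey_id"] == survey) & (seastate["transect_id"] == transect)
        ].sort_values("t", kind="stable")
        if rec.empty:
            raise ValueError(f"no sea-state record for transect {survey}/{transect}")
        rt = rec["t"].to_numpy()
        rb = rec["beaufort"].to_numpy()
        idx = np.searchsorted(rt, grp["t_mid"].to_numpy(), side="right") - 1
        idx = np.clip(idx, 0, len(rt) - 1)  # fall back to the start-of-transect record
        beaufort[segs.index.get_indexer(grp.index)] = rb[idx]
    segs["beaufort"] = beaufort
    segs["condition"] = np.where(beaufort <= 2, "good", "poor")
    return segs


# ---------------------------------------------------------------------------
# effort ledger


def effort_ledger(table: SegmentTable, footprint: Polygon | None = None) -> pd.DataFrame:
    """Per-phase survey effort, observation totals, and encounter rates.

    Effort is the summed segment effort in km, with the bracketed column the
    effort of segments whose midpoints fall inside the footprint polygon.
    The encounter rate is the mean over surveys of each survey's individuals
    per km, with its standard error across surveys (printed rates in effort
    ledgers of this design are per-survey averages, not ratios of totals).
    """
    rows = table.rows
    recs = []

    def _one(label: str, sub: pd.DataFrame):
        effort_km = sub["effort_m"].sum() / 1000.0
        if footprint is not None:
            inside = sub.apply(lambda r: footprint.contains(Point(r["x"], r["y"])), axis=1)
            fp_km = sub.loc[inside, "effort_m"].sum() / 1000.0
        else:
            fp_km = np.nan
        per_survey = sub.groupby("survey_id").agg(
            n=("count", "sum"), km=("effort_m", lambda e: e.sum() / 1000.0)
        )
        rates = per_survey["n"] / per_survey["km"]
        se = rates.std(ddof=1) / np.sqrt(len(rates)) if len(rates) > 1 else np.nan
        recs.append(
            {
                "phase": label,
                "effort_km": effort_km,
                "footprint_km": fp_km,
                "observations": int(sub["count"].sum()),
                "rate_per_km": rates.mean(),
                "rate_se": se,
                "n_surveys": len(per_survey),
            }
        )

    for phase in PHASES:
        sub = rows[rows["phase"] == phase]
        if sub.empty:
            logger.warning("phase %s has zero effort; omitted from ledger", phase)
            continue
        _one(phase, sub)
    _one("total", rows)
    return pd.DataFrame(recs)
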