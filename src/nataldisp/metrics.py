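"""Per-individual analysis table: distances, densities and controls.

For each dispersal event the table carries

* the natal dispersal distance (geodesic km between natal and first breeding
  nest) and its natural log in metres, the response of the distance model;
* breeder densities in the year of expected recruitment (hatch year + lag,
  default lag 5): active-territory counts within 30 km of the natal nest and
  within 10 km of both natal and breeding nests;
* the density difference (breeding minus natal, 10 km), negative when the
  individual settled in a sparser neighbourhood than it hatched in;
* the expected density difference: the mean 10 km density over all active
  territories lying within the individual's observed dispersal distance of
  its natal nest, minus the natal 10 km density — what the density
  difference would look like if the individual had settled on a random
  available territory within its realised dispersal radius.  When no active
  territory lies within that radius the value is undefined (NaN) and the row
  is flagged and excluded from the density-difference model input.

Continuous covariates are attached both raw and z-scored (suffix ``_z``,
sample mean/SD over the assembled table).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spatial import buffer_density, geodesic_km, pairwise_km

__all__ = [
    "dispersal_distance",
    "density_difference",
    "expected_density_difference",
    "assemble",
]


def dispersal_distance(event) -> float:
    """Geodesic km between an event's natal and breeding nests."""
    for f in ("natal_lat", "natal_lon", "breeding_lat", "breeding_lon"):
        if pd.isna(event[f]):
            raise ValueError(f"event {event.get('individual_id', '?')}: missing {f}")
    return geodesic_km((event["natal_lat"], event["natal_lon"]),
                       (event["breeding_lat"], event["breeding_lon"]))


def density_difference(event, statuses: pd.DataFrame, radius_km: float = 10.0,
                       lag: int = 5, exclude_focal: bool = False) -> int:
    """Breeding-site minus natal-site active-territory count (10 km default)
    in the year of expected recruitment."""
    year = int(event["hatch_year"]) + lag
    excl_b = event["breeding_territory"] if exclude_focal else None
    excl_n = event["natal_territory"] if exclude_focal else None
    db = buffer_density((event["breeding_lat"], event["breeding_lon"]),
                        radius_km, year, statuses, exclude=excl_b)
    dn = buffer_density((event["natal_lat"], event["natal_lon"]),
                        radius_km, year, statuses, exclude=excl_n)
    return int(db - dn)


def expected_density_difference(event, statuses: pd.DataFrame,
                                radius_km: float = 10.0, lag: int = 5,
                                exclude_natal: bool = False) -> float:
    """Mean 10 km density over active territories within the observed
    dispersal distance of the natal nest, minus the natal 10 km density.

    Returns NaN (undefined) when no active territory lies within the
    observed dispersal radius.
    """
    year = int(event["hatch_year"]) + lag
    dist = dispersal_distance(event)
    active = statuses[(statuses["year"] == year) & statuses["active"]]
    if exclude_natal:
        active = active[active["territory_id"] != event["natal_territory"]]
    if active.empty:
        return float("nan")
    pts = active[["lat", "lon"]].to_numpy(dtype=float)
    d = pairwise_km(np.array([[event["natal_lat"], event["natal_lon"]]]), pts)[0]
    inside = d <= dist
    if not inside.any():
        return float("nan")
    dens = [buffer_density((la, lo), radius_km, year, statuses)
            for la, lo in pts[inside]]
    natal = buffer_density((event["natal_lat"], event["natal_lon"]),
                           radius_km, year, statuses)
    return float(np.mean(dens) - natal)


class _DensityIndex:
    """Per-year active-territory points with cached local density counts.

    Vectorised equivalent of repeated :func:`buffer_density` calls; the
    scalar functions above remain the reference implementation.
    """

    def __init__(self, statuses: pd.DataFrame, radius_local: float):
        self.radius_local = radius_local
        self.by_year: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for y, g in statuses[statuses["active"]].groupby("year"):
            self.by_year[int(y)] = (g["territory_id"].to_numpy(),
                                    g[["lat", "lon"]].to_numpy(float))
        self._dens_cache: dict[int, np.ndarray] = {}

    def points(self, year: int):
        return self.by_year.get(year, (np.empty(0, object), np.empty((0, 2))))

    def count(self, center, radius: float, year: int) -> int:
        _, pts = self.points(year)
        if len(pts) == 0:
            return 0
        d = pairwise_km(np.asarray([center], float), pts)[0]
        return int(np.sum(d <= radius))

    def local_densities(self, year: int) -> np.ndarray:
        """10 km (radius_local) count at each active territory's nest."""
        if year not in self._dens_cache:
            _, pts = self.points(year)
            if len(pts) == 0:
                self._dens_cache[year] = np.empty(0)
            else:
                D = pairwise_km(pts, pts)
                self._dens_cache[year] = (D <= self.radius_local).sum(axis=1)
        return self._dens_cache[year]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    valid = np.isfinite(x)
    mu = x[valid].mean()
    sd = x[valid].std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant covariate")
    return (x - mu) / sd


def assemble(events: pd.DataFrame, statuses: pd.DataFrame,
             weights: pd.Series | None = None, lag: int = 5,
             radius_broad: float = 30.0, radius_local: float = 10.0,
             exclude_focal: bool = False) -> pd.DataFrame:
    """Build the model-ready analysis table from filtered dispersal events.

    ``weights`` (predicted recruitment probability per individual id) are
    attached when given.  Raises on non-positive dispersal distances (their
    log is undefined); rows with an undefined expected density difference
    are flagged (``expected_diff_defined``) rather than dropped here.
    """
    index = _DensityIndex(statuses, radius_local)
    rows = []
    for _, ev in events.iterrows():
        dist_km = dispersal_distance(ev)
        if dist_km <= 0:
            raise ValueError(f"individual {ev['individual_id']}: non-positive "
                             f"dispersal distance {dist_km}")
        year = int(ev["hatch_year"]) + lag
        tids, pts = index.points(year)
        natal = np.asarray([[ev["natal_lat"], ev["natal_lon"]]], float)
        breed = np.asarray([[ev["breeding_lat"], ev["breeding_lon"]]], float)
        if len(pts):
            dn = pairwise_km(natal, pts)[0]
            db = pairwise_km(breed, pts)[0]
        else:
            dn = db = np.empty(0)
        if exclude_focal:
            keep_n = tids != ev["natal_territory"]
            keep_b = tids != ev["breeding_territory"]
        else:
            keep_n = keep_b = np.ones(len(tids), dtype=bool)
        d30 = int(np.sum((dn <= radius_broad) & keep_n))
        d10n = int(np.sum((dn <= radius_local) & keep_n))
        d10b = int(np.sum((db <= radius_local) & keep_b))
        inside = dn <= dist_km
        if inside.any():
            ediff = float(index.local_densities(year)[inside].mean()
                          - np.sum(dn <= radius_local))
        else:
            ediff = float("nan")
        rows.append({
            "individual_id": str(ev["individual_id"]),
            "sex": ev["sex"],
            "natal_territory": ev["natal_territory"],
            "recruit_year": year,
            "distance_km": dist_km,
            "log_distance": np.log(dist_km * 1000.0),
            "density30_natal": d30,
            "density10_natal": d10n,
            "density10_breeding": d10b,
            "density_diff": d10b - d10n,
            "expected_diff": ediff,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["expected_diff_defined"] = np.isfinite(table["expected_diff"])
    zmap = {"density30_natal": "density30_z",
            "density10_natal": "density10_natal_z",
            "recruit_year": "year_z",
            "expected_diff": "expected_diff_z"}
    for col, name in zmap.items():
        table[name] = _zscore(table[col].to_numpy())
    if weights is not None:
        w = weights.reindex(table["individual_id"]).to_numpy()
        table["weight"] = w
    return table
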