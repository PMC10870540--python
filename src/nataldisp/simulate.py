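"""Synthetic landscapes, populations and genotypes for the dispersal pipeline.

The generator emulates the statistical structure the analysis assumes for a
recovering territorial raptor population monitored over decades:

* a spatially clustered territory landscape — hotspot centres placed
  uniformly in the study region with Gaussian territory displacement around
  them (a Matern-style cluster process), giving high-density core areas and
  a sparse periphery;
* yearly territory activity with ordinal nest occupancy stages 0-3
  (0 none, 1 new nest material, 2 eggs/brood, 3 ringed nestlings);
* broods of ringed nestlings at stage-3 territory-years, each nestling with
  a 50/50 sex;
* emigration out of the study region whose log-odds decrease towards the
  designated foreign border (so recruitment probability rises with border
  distance);
* for recruits, a settlement distance drawn on the log scale (natural log
  of metres) from a linear predictor in sex, scaled natal-area breeder
  density (30 km, at the expected recruitment year = hatch year + 5) and
  scaled recruitment year, with crossed random intercepts for natal
  territory and recruitment year; the realised breeding territory is the
  active territory (excluding the natal one) nearest to the point at the
  drawn distance and a uniform random bearing;
* Mendelian microsatellite genotypes: one resident breeding pair per
  territory drawn from Hardy-Weinberg proportions, offspring inheriting one
  parental allele per locus, each observed sample re-typed with independent
  whole-locus missingness, plus a molecular sex-marker call.

All randomness flows through one explicitly passed numpy Generator; the same
configuration and seed reproduce every table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .genotyping import LocusDef
from .spatial import EARTH_RADIUS_KM, distance_to_border_km, pairwise_km, resolve_status

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_landscape",
    "simulate_population",
    "simulate_genotypes",
    "draw_allele_frequencies",
    "destination_point",
    "LOCUS_NAMES",
]

# the 14-locus panel used for white-tailed eagle identification
LOCUS_NAMES = ["Hal-01", "Hal-07", "Hal-09", "Hal-03", "Hal-13", "Aa-27", "IE-12",
               "Hal-04", "Hal-05", "IE-04", "Hal-06", "Aa-11", "IE-11", "Hal-14"]

_DEFAULT_REGION = [(60.0, 19.0), (60.0, 31.5), (66.5, 31.5), (66.5, 19.0), (60.0, 19.0)]
_DEFAULT_BORDER = [(66.5, 19.0), (60.0, 19.0)]  # western edge is the foreign border


@dataclass
class SimConfig:
    """Generative configuration; defaults emulate the study conditions
    (a ~600 x 700 km region, 1984-2022 monitoring, 14-locus genotyping,
    distance-model coefficients on the scaled-covariate scale)."""

    seed: int = 0
    region: list = field(default_factory=lambda: list(_DEFAULT_REGION))
    border: list = field(default_factory=lambda: list(_DEFAULT_BORDER))
    n_hotspots: int = 6
    territories_per_hotspot: float = 70.0
    hotspot_sd_km: float = 35.0
    years: tuple = (1984, 2022)
    hatch_years: tuple = (1984, 2015)
    activity_prob: float = 0.75
    stage_probs: tuple = (0.20, 0.35, 0.45)   # P(stage 1..3 | active)
    max_nests_per_territory: int = 2
    nest_jitter_km: float = 0.5
    mean_brood: float = 1.5
    recruitment_lag: int = 5
    n_loci: int = 14
    alleles_per_locus: tuple = (4, 9)
    missing_locus_prob: float = 0.05
    # log-distance model, natural log of metres, scaled covariates
    beta0: float = 10.821
    beta_sex: float = -0.394        # male effect
    beta_density: float = -0.267    # scaled 30 km natal density
    beta_year: float = -0.065       # scaled recruitment year
    sigma_resid: float = 0.70
    sd_territory: float = 0.255
    sd_year: float = 0.259
    # emigration: P(stay) on the logit scale vs. border distance (km)
    emigration_slope: float = 0.004
    emigration_intercept: float = -4.1
    unknown_sex_prob: float = 0.0   # marker-failure masking
    sampling_probs: dict = field(default_factory=lambda: {
        "nestling_genotype": 0.9, "adult_genotype": 0.9, "ring_resight": 0.3})

    def __post_init__(self):
        probs = [self.activity_prob, self.missing_locus_prob, self.unknown_sex_prob,
                 *self.stage_probs, *self.sampling_probs.values()]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage_probs must sum to 1")
        if self.n_hotspots < 1:
            raise ValueError("n_hotspots must be >= 1")
        if self.alleles_per_locus[0] < 1:
            raise ValueError("alleles_per_locus must be >= 1")
        poly = self.region_polygon()
        if poly.is_empty or poly.area == 0:
            raise ValueError("empty region")
        if not poly.is_valid:
            raise ValueError("region polygon is self-intersecting or invalid")

    def region_polygon(self) -> Polygon:
        # shapely wants (x, y) = (lon, lat)
        return Polygon([(lon, lat) for lat, lon in self.region])

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimOutput:
    """Bundle of simulated observation tables plus the generative truth."""

    territories: pd.DataFrame
    nestlings: pd.DataFrame
    genotypes: pd.DataFrame
    ring_resights: pd.DataFrame
    adult_detections: pd.DataFrame
    truth: dict


def _km_to_deg(lat_deg: float) -> tuple[float, float]:
    per_deg = EARTH_RADIUS_KM * np.pi / 180.0
    return 1.0 / per_deg, 1.0 / (per_deg * np.cos(np.radians(lat_deg)))


def destination_point(lat: float, lon: float, bearing_rad: float, dist_km: float):
    """Great-circle destination point from (lat, lon) at a bearing/distance."""
    delta = dist_km / EARTH_RADIUS_KM
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta)
                     + np.cos(phi1) * np.sin(delta) * np.cos(bearing_rad))
    lam2 = lam1 + np.arctan2(np.sin(bearing_rad) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    return np.degrees(phi2), (np.degrees(lam2) + 540.0) % 360.0 - 180.0


def simulate_landscape(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Clustered territory landscape with per-nest yearly occupancy stages.

    Returns one row per (territory, nest, year):
    ``territory_id, nest_id, lat, lon, year, stage``.
    """
    rng = config.rng() if rng is None else rng
    poly = config.region_polygon()
    minx, miny, maxx, maxy = poly.bounds

    centres = []
    while len(centres) < config.n_hotspots:
        lon = rng.uniform(minx, maxx)
        lat = rng.uniform(miny, maxy)
        if poly.contains(Point(lon, lat)):
            centres.append((lat, lon))

    terr = []
    for clat, clon in centres:
        n_t = max(1, int(rng.poisson(config.territories_per_hotspot)))
        for _ in range(n_t):
            for _attempt in range(200):
                if config.hotspot_sd_km == 0:
                    lat, lon = clat, clon
                else:
                    dlat, dlon = _km_to_deg(clat)
                    off = rng.normal(0.0, config.hotspot_sd_km, size=2)
                    lat = clat + off[0] * dlat
                    lon = clon + off[1] * dlon
                if poly.contains(Point(lon, lat)) or config.hotspot_sd_km == 0:
                    terr.append((lat, lon))
                    break
            else:
                terr.append((clat, clon))

    years = np.arange(config.years[0], config.years[1] + 1)
    jitter = 0.0 if config.hotspot_sd_km == 0 else config.nest_jitter_km
    rows = {k: [] for k in ("territory_id", "nest_id", "lat", "lon", "year", "stage")}
    stage_p = np.asarray(config.stage_probs)
    for i, (tlat, tlon) in enumerate(terr):
        tid = f"T{i:04d}"
        n_nests = int(rng.integers(1, config.max_nests_per_territory + 1))
        dlat, dlon = _km_to_deg(tlat)
        nests = []
        for j in range(n_nests):
            off = rng.normal(0.0, jitter, size=2) if jitter > 0 else np.zeros(2)
            nests.append((f"{tid}N{j}", tlat + off[0] * dlat, tlon + off[1] * dlon))
        active = rng.random(len(years)) < config.activity_prob
        stages = np.where(active, rng.choice([1, 2, 3], size=len(years), p=stage_p), 0)
        best = rng.integers(0, n_nests, size=len(years))
        for yi, year in enumerate(years):
            for j, (nid, nlat, nlon) in enumerate(nests):
                st = int(stages[yi]) if j == best[yi] else 0
                rows["territory_id"].append(tid)
                rows["nest_id"].append(nid)
                rows["lat"].append(nlat)
                rows["lon"].append(nlon)
                rows["year"].append(int(year))
                rows["stage"].append(st)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population


def _active_rep_nests(statuses: pd.DataFrame) -> dict[int, pd.DataFrame]:
    return {int(y): g[g["active"]].reset_index(drop=True)
            for y, g in statuses.groupby("year")}


def draw_brood_records(territories: pd.DataFrame, statuses: pd.DataFrame,
                       config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ringed-nestling records: broods hatch at stage-3 territory-years
    within the hatch window, at the representative nest."""
    stage_by_ty = territories.groupby(["territory_id", "year"])["stage"].max()
    lo, hi = config.hatch_years
    rep = statuses.set_index(["territory_id", "year"])
    born = stage_by_ty[(stage_by_ty == 3)
                       & (stage_by_ty.index.get_level_values("year") >= lo)
                       & (stage_by_ty.index.get_level_values("year") <= hi)]
    recs = []
    k = 0
    for (tid, year) in born.index:
        srow = rep.loc[(tid, year)]
        brood = 1 + rng.binomial(2, (config.mean_brood - 1.0) / 2.0)
        for _ in range(brood):
            recs.append((f"W{k:05d}", tid, srow["nest_id"], srow["lat"], srow["lon"],
                         int(year), "F" if rng.random() < 0.5 else "M"))
            k += 1
    return pd.DataFrame(recs, columns=["individual_id", "territory_id", "nest_id",
                                       "lat", "lon", "hatch_year", "sex"])


def simulate_population(territories: pd.DataFrame, config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Nestlings plus generative truth (recruitment and dispersal events).

    Returns ``(nestlings, truth)``.  ``nestlings`` has one row per ringed
    nestling: ``individual_id, territory_id, nest_id, lat, lon, hatch_year,
    sex, border_km``.  ``truth`` contains the per-individual recruitment
    table, the dispersal-event table for recruits (emigrants and failed
    settlers are kept in the recruitment table but have no event), the
    random intercepts and the generative coefficients.
    """
    rng = config.rng() if rng is None else rng
    if territories.empty:
        raise ValueError("territories table is empty")
    statuses = resolve_status(territories)
    nestlings = draw_brood_records(territories, statuses, config, rng)

    border = np.asarray(config.border, dtype=float)
    terr_pts = nestlings[["territory_id", "lat", "lon"]].drop_duplicates("territory_id")
    bdist = {r["territory_id"]: distance_to_border_km((r["lat"], r["lon"]), border)
             for _, r in terr_pts.iterrows()}
    nestlings["border_km"] = nestlings["territory_id"].map(bdist)

    p_stay = 1.0 / (1.0 + np.exp(-(config.emigration_intercept
                                   + config.emigration_slope * nestlings["border_km"].to_numpy())))
    stays = rng.random(len(nestlings)) < p_stay

    truth = _settle_recruits(nestlings, stays, statuses, config, rng)
    truth["p_stay"] = pd.Series(p_stay, index=nestlings.index)
    return nestlings, truth


def _settle_recruits(nestlings: pd.DataFrame, recruit_mask: np.ndarray,
                     statuses: pd.DataFrame, config: SimConfig,
                     rng: np.random.Generator,
                     sex_override: pd.Series | None = None) -> dict:
    """Draw settlement distances and breeding territories for recruits."""
    by_year = _active_rep_nests(statuses)
    recruits = nestlings[recruit_mask].copy()
    sexes = (sex_override if sex_override is not None else recruits["sex"]).to_numpy()
    recruit_year = recruits["hatch_year"].to_numpy() + config.recruitment_lag

    # natal 30 km density at recruitment year, z-scored within the cohort
    d30 = np.zeros(len(recruits))
    for i, (idx, r) in enumerate(recruits.iterrows()):
        act = by_year.get(int(recruit_year[i]))
        if act is None or act.empty:
            d30[i] = 0
            continue
        d = pairwise_km(np.array([[r["lat"], r["lon"]]]),
                        act[["lat", "lon"]].to_numpy(float))[0]
        d30[i] = np.sum(d <= 30.0)
    if len(recruits) > 1 and d30.std(ddof=1) > 0:
        d30_z = (d30 - d30.mean()) / d30.std(ddof=1)
    else:
        d30_z = np.zeros_like(d30)
    if len(recruits) > 1 and np.std(recruit_year, ddof=1) > 0:
        year_z = (recruit_year - recruit_year.mean()) / np.std(recruit_year, ddof=1)
    else:
        year_z = np.zeros_like(d30)

    terr_levels = nestlings["territory_id"].unique()
    u_t = dict(zip(terr_levels, rng.normal(0.0, config.sd_territory, len(terr_levels))))
    year_levels = np.unique(recruit_year)
    u_y = dict(zip(year_levels, rng.normal(0.0, config.sd_year, len(year_levels))))

    eps = rng.normal(0.0, config.sigma_resid, len(recruits))
    male = (sexes == "M").astype(float)
    log_d = (config.beta0 + config.beta_sex * male + config.beta_density * d30_z
             + config.beta_year * year_z
             + np.array([u_t[t] for t in recruits["territory_id"]])
             + np.array([u_y[y] for y in recruit_year]) + eps)
    dist_km = np.exp(log_d) / 1000.0
    bearing = rng.uniform(0.0, 2.0 * np.pi, len(recruits))

    ev_rows = []
    settled = np.zeros(len(recruits), dtype=bool)
    for i, (idx, r) in enumerate(recruits.iterrows()):
        act = by_year.get(int(recruit_year[i]))
        if act is None or act.empty:
            continue
        cand = act[act["territory_id"] != r["territory_id"]]
        if cand.empty:
            continue
        # settlement: the active territory best realising the drawn dispersal
        # distance (nearest on the log-distance scale from the natal nest),
        # ties towards the sampled bearing direction
        cpts = cand[["lat", "lon"]].to_numpy(float)
        d_nat = pairwise_km(np.array([[r["lat"], r["lon"]]]), cpts)[0]
        ring_err = np.abs(np.log(np.maximum(d_nat, 1e-3)) - np.log(dist_km[i]))
        near = np.flatnonzero(ring_err <= ring_err.min() + 0.05)
        if len(near) > 1:
            plat, plon = destination_point(r["lat"], r["lon"], bearing[i], dist_km[i])
            d_pt = pairwise_km(np.array([[plat, plon]]), cpts[near])[0]
            j = int(near[np.argmin(d_pt)])
        else:
            j = int(near[0])
        ev_rows.append({
            "individual_id": r["individual_id"],
            "sex": sexes[i],
            "natal_territory": r["territory_id"],
            "natal_lat": r["lat"], "natal_lon": r["lon"],
            "hatch_year": int(r["hatch_year"]),
            "recruit_year": int(recruit_year[i]),
            "breeding_territory": cand["territory_id"].iloc[j],
            "breeding_nest": cand["nest_id"].iloc[j],
            "breeding_lat": float(cand["lat"].iloc[j]),
            "breeding_lon": float(cand["lon"].iloc[j]),
            "drawn_log_distance": float(log_d[i]),
            "drawn_km": float(dist_km[i]),
            "density30_natal": float(d30[i]),
        })
        settled[i] = True

    individuals = nestlings.copy()
    individuals["recruited"] = False
    individuals.loc[recruits.index[settled], "recruited"] = True
    if sex_override is not None:
        individuals.loc[recruits.index, "sex"] = sexes
    events = pd.DataFrame(ev_rows)
    coeffs = {"beta0": config.beta0, "beta_sex": config.beta_sex,
              "beta_density": config.beta_density, "beta_year": config.beta_year,
              "sigma_resid": config.sigma_resid, "sd_territory": config.sd_territory,
              "sd_year": config.sd_year, "emigration_slope": config.emigration_slope,
              "emigration_intercept": config.emigration_intercept}
    return {"individuals": individuals, "events": events, "coefficients": coeffs,
            "random_intercepts": {"territory": u_t, "year": {int(k): v for k, v in u_y.items()}},
            "statuses": statuses}


# ---------------------------------------------------------------------------
# genotypes


def draw_allele_frequencies(config: SimConfig, rng: np.random.Generator) -> list[LocusDef]:
    """Random locus panel: allele counts uniform in ``alleles_per_locus``,
    frequencies Dirichlet(1), integer allele sizes in 2 bp steps."""
    lo, hi = config.alleles_per_locus
    if lo < 1:
        raise ValueError("alleles_per_locus must be >= 1")
    loci = []
    names = (LOCUS_NAMES * ((config.n_loci // len(LOCUS_NAMES)) + 1))[:config.n_loci]
    for i, name in enumerate(names):
        k = int(rng.integers(lo, hi + 1))
        freqs = rng.dirichlet(np.ones(k))
        sizes = 100 + 10 * i + 2 * np.arange(k)
        loci.append(LocusDef(name if config.n_loci <= len(LOCUS_NAMES) else f"{name}.{i}",
                             dict(zip(sizes.tolist(), freqs.tolist()))))
    return loci


def _hwe_genotype(loci: list[LocusDef], rng: np.random.Generator) -> np.ndarray:
    g = np.empty((len(loci), 2), dtype=np.int32)
    for j, locus in enumerate(loci):
        sizes = np.array(list(locus.allele_frequencies.keys()))
        p = np.array(list(locus.allele_frequencies.values()))
        g[j] = np.sort(rng.choice(sizes, size=2, p=p))
    return g


def _mendelian_offspring(mother: np.ndarray, father: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    pick_m = rng.integers(0, 2, mother.shape[0])
    pick_f = rng.integers(0, 2, father.shape[0])
    g = np.stack([mother[np.arange(len(pick_m)), pick_m],
                  father[np.arange(len(pick_f)), pick_f]], axis=1)
    return np.sort(g, axis=1)


def _observe(true_g: np.ndarray, config: SimConfig, rng: np.random.Generator,
             min_typed: int | None = None) -> np.ndarray:
    obs = true_g.copy()
    miss = rng.random(true_g.shape[0]) < config.missing_locus_prob
    if min_typed is not None and (len(miss) - miss.sum()) < min_typed:
        drop = rng.permutation(len(miss))[:len(miss) - min_typed]
        miss = np.zeros(len(miss), dtype=bool)
        miss[drop] = True
    obs[miss] = -1
    return obs


def _genotype_row(sample_id, stype, year, territory, individual, obs, sex_marker, loci):
    row = {"sample_id": sample_id, "type": stype, "year": year,
           "territory_id": territory, "individual_id": individual,
           "sex_marker": sex_marker}
    for j, locus in enumerate(loci):
        if obs[j, 0] < 0:
            row[f"{locus.name}_a1"] = np.nan
            row[f"{locus.name}_a2"] = np.nan
        else:
            row[f"{locus.name}_a1"] = int(obs[j, 0])
            row[f"{locus.name}_a2"] = int(obs[j, 1])
    return row


def simulate_genotypes(nestlings: pd.DataFrame, truth: dict, config: SimConfig,
                       rng: np.random.Generator | None = None,
                       nestling_sample_ids=None, adult_samples: pd.DataFrame | None = None,
                       unknown_sex_ids=frozenset(), min_typed_enforced: int | None = None,
                       loci: list[LocusDef] | None = None) -> tuple[pd.DataFrame, dict]:
    """Observed genotype table for nestling and adult feather samples.

    Parameters
    ----------
    nestling_sample_ids : individuals whose nestling feather is genotyped
        (default: all, thinned by ``sampling_probs['nestling_genotype']``).
    adult_samples : frame ``individual_id, territory_id, year`` of adult
        feather samples to genotype (re-observations of the same true
        genotype with a fresh missing pattern); extra rows with
        ``individual_id`` not among the nestlings are treated as immigrant
        adults with fresh Hardy-Weinberg genotypes.
    unknown_sex_ids : individuals whose sex-marker call is masked.
    min_typed_enforced : optionally guarantee this many typed loci per sample.

    Returns (genotypes frame, genotype truth dict with the locus panel,
    parental genotypes and per-individual true genotypes).
    """
    rng = config.rng() if rng is None else rng
    if loci is None:
        loci = draw_allele_frequencies(config, rng)

    parents: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tid in nestlings["territory_id"].unique():
        parents[tid] = (_hwe_genotype(loci, rng), _hwe_genotype(loci, rng))

    true_g: dict[str, np.ndarray] = {}
    for _, r in nestlings.iterrows():
        mom, dad = parents[r["territory_id"]]
        true_g[r["individual_id"]] = _mendelian_offspring(mom, dad, rng)

    sexes = nestlings.set_index("individual_id")["sex"].to_dict()
    if nestling_sample_ids is None:
        p = config.sampling_probs.get("nestling_genotype", 1.0)
        mask = rng.random(len(nestlings)) < p
        nestling_sample_ids = nestlings.loc[mask, "individual_id"].tolist()

    rows = []
    nidx = nestlings.set_index("individual_id")
    for ind in nestling_sample_ids:
        r = nidx.loc[ind]
        obs = _observe(true_g[ind], config, rng, min_typed_enforced)
        marker = "" if ind in unknown_sex_ids or rng.random() < config.unknown_sex_prob \
            else sexes[ind]
        rows.append(_genotype_row(f"N-{ind}", "nestling", int(r["hatch_year"]),
                                  r["territory_id"], ind, obs, marker, loci))

    if adult_samples is not None:
        for _, r in adult_samples.iterrows():
            ind = str(r["individual_id"])
            if ind in true_g:
                g = true_g[ind]
                marker = "" if ind in unknown_sex_ids else sexes[ind]
            else:  # immigrant breeder, never ringed here
                g = _hwe_genotype(loci, rng)
                true_g[ind] = g
                marker = "F" if rng.random() < 0.5 else "M"
            obs = _observe(g, config, rng, min_typed_enforced)
            rows.append(_genotype_row(f"A-{ind}-{int(r['year'])}", "adult",
                                      int(r["year"]), r["territory_id"],
                                      ind, obs, marker, loci))

    genotypes = pd.DataFrame(rows)
    gtruth = {"loci": loci, "parents": parents, "true_genotypes": true_g}
    return genotypes, gtruth
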