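"""Fusing genotype matches and ring re-sightings into natal dispersal events.

Each nestling is individually marked (ringed) at the natal nest; an adult can
later be identified at a breeding nest either by reading its ring from
photographs or by matching a feather genotype to the nestling genotype
archive.  This module collapses both evidence streams into one natal-to-
breeding link per individual and applies the dataset-assembly filters
(unknown sex, too young at first detection).

Conventions
-----------
* Calendar-year age at first detection = detection year - hatch year + 1
  (ringing-scheme convention: the hatch year is the bird's first calendar
  year).
* The site of first adult detection is taken as the site of the first
  breeding attempt; breeding dispersal is rare enough in site-faithful
  raptors that no detection-lag correction is applied.
* Sex comes from the molecular marker when available (the more direct
  assay), else from field determination at the ring re-sighting, else
  UNKNOWN.  Marker/field conflicts resolve to the marker with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "individual_id", "sex", "natal_territory", "natal_lat", "natal_lon",
    "hatch_year", "breeding_territory", "breeding_lat", "breeding_lon",
    "first_detection_year", "source", "age_at_first_detection",
]

__all__ = ["FilterLog", "link_individuals", "apply_filters", "EVENT_COLUMNS"]


@dataclass
class FilterLog:
    """Bookkeeping for the dataset-assembly exclusions."""

    n_input: int
    n_unknown_sex_removed: int
    n_underage_removed: int
    n_output: int
    reasons: pd.DataFrame = field(default_factory=pd.DataFrame)  # individual_id, reason

    def __post_init__(self):
        if self.n_output != self.n_input - self.n_unknown_sex_removed - self.n_underage_removed:
            raise ValueError("filter log arithmetic does not balance")

    def format(self) -> str:
        return (f"dataset assembly: {self.n_input} linked individuals; "
                f"removed {self.n_unknown_sex_removed} of unknown sex and "
                f"{self.n_underage_removed} detected at age < threshold; "
                f"{self.n_output} retained")


def _detections_from_matches(matches: pd.DataFrame, adult_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-individual adult detections implied by genotype matches."""
    if matches.empty:
        return pd.DataFrame(columns=["individual_id", "territory_id", "year", "kind", "sex"])
    usable = matches[(matches["decision"] == "MATCH") & (~matches["ambiguous"])]
    meta = adult_meta.set_index(adult_meta["sample_id"].astype(str))
    rows = []
    for _, m in usable.iterrows():
        a = str(m["adult_sample"])
        if a not in meta.index:
            raise KeyError(f"adult sample {a} has no metadata row")
        rec = meta.loc[a]
        sex = rec.get("sex_marker", "UNKNOWN")
        sex = "UNKNOWN" if pd.isna(sex) or sex == "" else str(sex)
        rows.append((str(m["nestling_individual"]), rec["territory_id"],
                     int(rec["year"]), "GENOTYPE", sex))
    return pd.DataFrame(rows, columns=["individual_id", "territory_id", "year", "kind", "sex"])


def link_individuals(matches: pd.DataFrame, adult_meta: pd.DataFrame,
                     ring_resights: pd.DataFrame, nestlings: pd.DataFrame,
                     statuses: pd.DataFrame,
                     nestling_sex_markers: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build one natal-to-breeding dispersal event per identified individual.

    Parameters
    ----------
    matches : output of :func:`nataldisp.genotyping.screen` (first frame).
    adult_meta : metadata for adult genotype samples
        (``sample_id, territory_id, year, sex_marker``).
    ring_resights : ``individual_id, territory_id, year`` plus optional
        ``field_sex``.
    nestlings : natal records, ``individual_id, territory_id, nest_id, lat,
        lon, hatch_year``.
    statuses : territory-year status table from
        :func:`nataldisp.spatial.resolve_status` (all relevant years); used
        to place the breeding nest (representative nest of the breeding
        territory in the first detection year).
    nestling_sex_markers : optional ``individual_id, sex_marker`` from
        nestling genotype samples (molecular sex known from the natal
        sample even when the adult feather failed to sex).

    Returns
    -------
    DataFrame with :data:`EVENT_COLUMNS`; individuals with conflicting
    ring-versus-genotype territory assignments in the same year are excluded
    (logged as CONFLICT).
    """
    gen_det = _detections_from_matches(matches, adult_meta)
    ring_det = pd.DataFrame(columns=["individual_id", "territory_id", "year", "kind", "sex"])
    if not ring_resights.empty:
        ring_det = pd.DataFrame({
            "individual_id": ring_resights["individual_id"].astype(str),
            "territory_id": ring_resights["territory_id"],
            "year": ring_resights["year"].astype(int),
            "kind": "RING",
            "sex": (ring_resights["field_sex"] if "field_sex" in ring_resights.columns
                    else pd.Series(["UNKNOWN"] * len(ring_resights))).fillna("UNKNOWN")
                   .replace("", "UNKNOWN"),
        })
    det = pd.concat([gen_det, ring_det], ignore_index=True)
    if det.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)

    known_territories = set(statuses["territory_id"])
    bad = det[~det["territory_id"].isin(known_territories)]
    if not bad.empty:
        r = bad.iloc[0]
        raise KeyError(f"detection of {r['individual_id']} references unknown "
                       f"territory {r['territory_id']} ({r['kind']}, {r['year']})")

    natal = nestlings.set_index(nestlings["individual_id"].astype(str))
    status_idx = statuses.set_index(["territory_id", "year"])

    marker_sex: dict[str, str] = {}
    if nestling_sex_markers is not None and not nestling_sex_markers.empty:
        for _, r in nestling_sex_markers.iterrows():
            s = r.get("sex_marker")
            if not (pd.isna(s) or s in ("", "UNKNOWN")):
                marker_sex[str(r["individual_id"])] = str(s)

    events = []
    for ind, grp in det.groupby("individual_id", sort=True):
        if ind not in natal.index:
            logger.warning("detected adult %s has no natal record; skipped", ind)
            continue
        nrec = natal.loc[ind]
        # conflict: ring vs genotype disagree on territory within a year
        conflict = False
        for year, g in grp.groupby("year"):
            ring_t = set(g.loc[g["kind"] == "RING", "territory_id"])
            gen_t = set(g.loc[g["kind"] == "GENOTYPE", "territory_id"])
            if ring_t and gen_t and ring_t != gen_t:
                conflict = True
        if conflict:
            logger.warning("individual %s: conflicting ring/genotype territories; excluded", ind)
            continue

        first_year = int(grp["year"].min())
        first = grp[grp["year"] == first_year].sort_values("territory_id")
        territory = first["territory_id"].iloc[0]
        kinds = set(grp["kind"])
        source = "BOTH" if kinds == {"GENOTYPE", "RING"} else kinds.pop()

        # sex: adult marker call > nestling marker call > field sex > UNKNOWN
        adult_marker = [s for s in grp.loc[grp["kind"] == "GENOTYPE", "sex"] if s != "UNKNOWN"]
        field_sex = [s for s in grp.loc[grp["kind"] == "RING", "sex"] if s != "UNKNOWN"]
        sex = "UNKNOWN"
        if adult_marker:
            sex = adult_marker[0]
        elif ind in marker_sex:
            sex = marker_sex[ind]
        elif field_sex:
            sex = field_sex[0]
        if sex != "UNKNOWN" and field_sex and field_sex[0] != sex:
            logger.warning("individual %s: field sex %s overridden by marker %s",
                           ind, field_sex[0], sex)

        try:
            srow = status_idx.loc[(territory, first_year)]
        except KeyError:
            raise KeyError(f"no status for territory {territory} in {first_year}") from None
        hatch = int(nrec["hatch_year"])
        events.append({
            "individual_id": ind,
            "sex": sex,
            "natal_territory": nrec["territory_id"],
            "natal_lat": float(nrec["lat"]),
            "natal_lon": float(nrec["lon"]),
            "hatch_year": hatch,
            "breeding_territory": territory,
            "breeding_lat": float(srow["lat"]),
            "breeding_lon": float(srow["lon"]),
            "first_detection_year": first_year,
            "source": source,
            "age_at_first_detection": first_year - hatch + 1,
        })
    out = pd.DataFrame(events, columns=EVENT_COLUMNS)
    if (out["first_detection_year"] < out["hatch_year"]).any():
        bad = out[out["first_detection_year"] < out["hatch_year"]]["individual_id"].tolist()
        raise ValueError(f"detection before hatch year for {bad}")
    return out


def apply_filters(events: pd.DataFrame, min_age: int = 5) -> tuple[pd.DataFrame, FilterLog]:
    """Remove unknown-sex individuals, then those first detected too young.

    ``min_age`` is in calendar years (hatch year = year 1); the default 5
    corresponds to the age of first possible recruitment in large eagles.
    """
    n_input = len(events)
    unknown = events["sex"] == "UNKNOWN"
    reasons = [(i, "UNKNOWN_SEX") for i in events.loc[unknown, "individual_id"]]
    kept = events[~unknown]
    underage = kept["age_at_first_detection"] < min_age
    reasons += [(i, "UNDERAGE") for i in kept.loc[underage, "individual_id"]]
    out = kept[~underage].reset_index(drop=True)
    log = FilterLog(
        n_input=n_input,
        n_unknown_sex_removed=int(unknown.sum()),
        n_underage_removed=int(underage.sum()),
        n_output=len(out),
        reasons=pd.DataFrame(reasons, columns=["individual_id", "reason"]),
    )
    return out, log
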