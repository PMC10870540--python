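"""Deterministic reference dataset matching the study's identification
composition.

The packaged fixture reproduces, exactly, the marginal composition of the
Finnish white-tailed eagle dataset the analysis chain was designed for:
335 natal-to-breeding links split 84 (ring re-sighting only) / 233 (genotype
matching only) / 18 (both), sexes 156 female / 141 male / 38 unknown, and
exactly 12 sex-known individuals first detected at calendar age < 5 — so
that the two dataset-assembly filters leave 285 analysis rows
(335 - 38 - 12).  Everything else (landscape, genotypes, distances,
activity) is simulated from :class:`~nataldisp.simulate.SimConfig` defaults
at a fixed seed; re-running the generator is byte-identical.

The composition is imposed by construction — sources, sexes and detection
ages are assigned to simulated recruits so the marginals hold exactly —
because these counts are bookkeeping targets for the identification and
filtering stages, not stochastic outcomes to be approximated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .simulate import (SimConfig, SimOutput, _settle_recruits, draw_brood_records,
                       simulate_genotypes, simulate_landscape)
from .spatial import distance_to_border_km, resolve_status

__all__ = ["make_study_fixture", "FIXTURE_SEED", "COMPOSITION"]

FIXTURE_SEED = 230_335

COMPOSITION = {
    "n_linked": 335,
    "ring_only": 84,
    "genotype_only": 233,
    "both": 18,
    "females": 156,
    "males": 141,
    "unknown_sex": 38,
    "underage": 12,
    "analysis": 285,
}


def make_study_fixture(config: SimConfig | None = None) -> SimOutput:
    """Build the fixed-composition reference dataset (deterministic)."""
    cfg = config or SimConfig(seed=FIXTURE_SEED)
    rng = cfg.rng()
    comp = COMPOSITION

    territories = simulate_landscape(cfg, rng)
    statuses = resolve_status(territories)

    # --- nestlings (all ringed young, the recruitment-GLM population) -----
    nestlings = draw_brood_records(territories, statuses, cfg, rng)

    border = np.asarray(cfg.border, dtype=float)
    terr_pts = nestlings[["territory_id", "lat", "lon"]].drop_duplicates("territory_id")
    bdist = {r["territory_id"]: distance_to_border_km((r["lat"], r["lon"]), border)
             for _, r in terr_pts.iterrows()}
    nestlings["border_km"] = nestlings["territory_id"].map(bdist)

    # --- recruitment: Bernoulli in border distance at the configured slope,
    # with the intercept solved so the expected recruit count equals the
    # study's 335 links, then the binomial-noise remainder trimmed/topped up
    # to the exact count ---------------------------------------------------
    d = nestlings["border_km"].to_numpy()
    intercept = brentq(
        lambda c: (1.0 / (1.0 + np.exp(-(c + cfg.emigration_slope * d)))).sum()
        - comp["n_linked"], -20.0, 5.0)
    p_stay = 1.0 / (1.0 + np.exp(-(intercept + cfg.emigration_slope * d)))
    stays = rng.random(len(nestlings)) < p_stay
    stays = _force_count(stays, p_stay, comp["n_linked"], rng)

    # --- impose the identification composition on the recruits -----------
    ridx = np.flatnonzero(stays)
    perm = rng.permutation(len(ridx))
    source = np.empty(len(ridx), dtype=object)
    source[perm[:comp["ring_only"]]] = "RING"
    source[perm[comp["ring_only"]:comp["ring_only"] + comp["genotype_only"]]] = "GENOTYPE"
    source[perm[comp["ring_only"] + comp["genotype_only"]:]] = "BOTH"

    gen_only = np.flatnonzero(source == "GENOTYPE")
    unknown_local = rng.choice(gen_only, size=comp["unknown_sex"], replace=False)
    known_local = np.setdiff1d(np.arange(len(ridx)), unknown_local)
    sex = np.empty(len(ridx), dtype=object)
    sex[unknown_local] = rng.choice(["F", "M"], size=comp["unknown_sex"])  # true sex, masked later
    kp = rng.permutation(known_local)
    sex[kp[:comp["females"]]] = "F"
    sex[kp[comp["females"]:]] = "M"
    assert (sex[known_local] == "F").sum() == comp["females"]

    nestlings.loc[nestlings.index[ridx], "sex"] = sex
    truth = _settle_recruits(nestlings, stays, statuses, cfg, rng)
    events = truth["events"]
    # settlement always succeeds on this landscape; composition depends on it
    if len(events) != comp["n_linked"]:
        raise RuntimeError(f"fixture settled {len(events)} of {comp['n_linked']} recruits")
    events = events.set_index("individual_id", drop=False)
    ind_ids = nestlings["individual_id"].to_numpy()[ridx]
    meta = pd.DataFrame({"individual_id": ind_ids, "source": source, "sex": sex},
                        ).set_index("individual_id", drop=False)
    meta["hatch_year"] = events.loc[meta.index, "hatch_year"]
    meta["breeding_territory"] = events.loc[meta.index, "breeding_territory"]
    meta["unknown_sex"] = False
    meta.loc[ind_ids[unknown_local], "unknown_sex"] = True

    # --- first detection years: exactly 12 sex-known underage ------------
    underage_ids = rng.choice(ind_ids[known_local], size=comp["underage"], replace=False)
    fdy = {}
    ymax = cfg.years[1]
    for ind in meta.index:
        hatch = int(meta.loc[ind, "hatch_year"])
        if ind in set(underage_ids):
            fdy[ind] = hatch + int(rng.integers(1, 4))        # age 2-4
        else:
            fdy[ind] = min(hatch + 4 + int(rng.integers(0, 8)), ymax)  # age >= 5
    meta["first_detection_year"] = pd.Series(fdy)

    # --- ring re-sightings ------------------------------------------------
    ring_rows = []
    for ind in meta.index[meta["source"].isin(["RING", "BOTH"])]:
        ring_rows.append({
            "individual_id": ind,
            "territory_id": meta.loc[ind, "breeding_territory"],
            "year": int(meta.loc[ind, "first_detection_year"]),
            "field_sex": meta.loc[ind, "sex"],
        })
    ring_resights = pd.DataFrame(ring_rows)

    # --- adult feather samples -------------------------------------------
    adult_rows = []
    geno_ids = meta.index[meta["source"].isin(["GENOTYPE", "BOTH"])]
    for ind in geno_ids:
        t = meta.loc[ind, "breeding_territory"]
        y = int(meta.loc[ind, "first_detection_year"])
        adult_rows.append({"individual_id": ind, "territory_id": t, "year": y})
        # repeat sampling in a later season strengthens the link
        if rng.random() < 0.15 and y + 1 <= ymax:
            adult_rows.append({"individual_id": ind, "territory_id": t, "year": y + 1})
    # immigrant breeders: feathers that match no nestling
    active_t = statuses.loc[statuses["active"], "territory_id"].unique()
    for i in range(40):
        adult_rows.append({"individual_id": f"IMM{i:03d}",
                           "territory_id": rng.choice(active_t),
                           "year": int(rng.integers(2012, ymax + 1))})
    adult_samples = pd.DataFrame(adult_rows)

    # --- genotyped nestlings: all genotype-linked recruits plus a
    # background of never-recruited young from the genotyping era ----------
    non_recruits = nestlings.loc[~stays]
    era = non_recruits[non_recruits["hatch_year"] >= 2003]
    extra = era.sample(n=min(400, len(era)), random_state=int(rng.integers(2 ** 31)))
    nestling_sample_ids = list(geno_ids) + extra["individual_id"].tolist()

    unknown_ids = frozenset(ind_ids[unknown_local])
    genotypes, gtruth = simulate_genotypes(
        nestlings, truth, cfg, rng,
        nestling_sample_ids=nestling_sample_ids,
        adult_samples=adult_samples,
        unknown_sex_ids=unknown_ids,
        min_typed_enforced=9,
    )

    adult_detections = pd.concat([
        adult_samples.assign(kind="GENOTYPE")[
            adult_samples["individual_id"].isin(meta.index)],
        ring_resights.rename(columns={"field_sex": "sex"}).assign(kind="RING")[
            ["individual_id", "territory_id", "year", "kind"]],
    ], ignore_index=True)

    truth["individuals"] = truth["individuals"].merge(
        meta[["individual_id", "source", "unknown_sex", "first_detection_year"]]
        .reset_index(drop=True),
        on="individual_id", how="left")
    truth["composition"] = dict(comp)
    truth["underage_ids"] = sorted(underage_ids.tolist())
    truth["genotypes"] = gtruth

    return SimOutput(territories=territories, nestlings=nestlings,
                     genotypes=genotypes, ring_resights=ring_resights,
                     adult_detections=adult_detections, truth=truth)


def _force_count(flags: np.ndarray, p: np.ndarray, target: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Flip the fewest flags (preferring marginal probabilities) so that
    exactly ``target`` are True."""
    flags = flags.copy()
    n_on = int(flags.sum())
    if n_on > target:
        on = np.flatnonzero(flags)
        order = on[np.argsort(p[on], kind="stable")]
        flags[order[:n_on - target]] = False
    elif n_on < target:
        off = np.flatnonzero(~flags)
        order = off[np.argsort(-p[off], kind="stable")]
        flags[order[:target - n_on]] = True
    return flags
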