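"""CSV schemas, configuration and the end-to-end pipeline driver.

All interchange is UTF-8 CSV with a header row; blank cells are missing.
Columns beyond a schema are preserved as passthrough.  Coordinates are WGS84
decimal degrees, latitude first, validated on load.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotyping, identify, metrics, models, spatial

logger = logging.getLogger("nataldisp")

__all__ = [
    "PipelineConfig",
    "read_territories", "read_nestlings", "read_resights", "read_genotypes",
    "read_border", "write_table",
    "run_pipeline",
]


class SchemaError(ValueError):
    pass


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise SchemaError(f"{path}: file not found") from None


def _require(df: pd.DataFrame, path, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _coerce(df: pd.DataFrame, path, column: str, kind: str, required=True) -> pd.Series:
    raw = df[column].replace("", np.nan)
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        i = int(bad.idxmax())
        raise SchemaError(f"{path}: column {column!r} row {i}: "
                          f"cannot parse {raw[i]!r} as {kind}")
    if required and out.isna().any():
        i = int(out.isna().idxmax())
        raise SchemaError(f"{path}: column {column!r} row {i}: value missing")
    if kind == "int":
        return out.astype("Int64") if out.isna().any() else out.astype(int)
    return out.astype(float)


def _check_coords(df, path):
    lat, lon = df["lat"], df["lon"]
    bad = (lat < -90) | (lat > 90) | (lon < -180) | (lon > 180)
    if bad.any():
        i = int(bad.idxmax())
        raise SchemaError(f"{path}: row {i}: coordinate out of range "
                          f"({lat[i]}, {lon[i]})")


def read_territories(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, path, ["territory_id", "nest_id", "lat", "lon", "year", "stage"])
    for c, k in (("lat", "float"), ("lon", "float"), ("year", "int"), ("stage", "int")):
        df[c] = _coerce(df, path, c, k)
    _check_coords(df, path)
    if ((df["stage"] < 0) | (df["stage"] > 3)).any():
        raise SchemaError(f"{path}: stage outside ordinal range 0-3")
    return df


def read_nestlings(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, path, ["individual_id", "territory_id", "nest_id", "lat", "lon", "hatch_year"])
    for c, k in (("lat", "float"), ("lon", "float"), ("hatch_year", "int")):
        df[c] = _coerce(df, path, c, k)
    _check_coords(df, path)
    return df


def read_resights(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, path, ["individual_id", "territory_id", "year"])
    df["year"] = _coerce(df, path, "year", "int")
    return df


def read_genotypes(path, min_typed_warn: int = 9) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, path, ["sample_id", "type", "year", "territory_id", "sex_marker"])
    df["year"] = _coerce(df, path, "year", "int")
    loci = genotyping.locus_columns(df)
    if not loci:
        raise SchemaError(f"{path}: no <locus>_a1/<locus>_a2 allele columns found")
    for locus in loci:
        for s in ("_a1", "_a2"):
            df[locus + s] = _coerce(df, path, locus + s, "int", required=False)
    arr = genotyping._allele_array(df, loci)
    n_typed = (arr[:, :, 0] != genotyping.MISSING).sum(axis=1)
    low = n_typed < min_typed_warn
    if low.any():
        logger.warning("%s: %d sample(s) typed at < %d loci (will be dropped by screening)",
                       path, int(low.sum()), min_typed_warn)
    df["n_typed"] = n_typed
    return df


def read_border(path) -> np.ndarray:
    df = _read_csv(path)
    _require(df, path, ["lat", "lon"])
    for c in ("lat", "lon"):
        df[c] = _coerce(df, path, c, "float")
    _check_coords(df, path)
    if len(df) < 2:
        raise SchemaError(f"{path}: border polyline needs >= 2 vertices")
    return df[["lat", "lon"]].to_numpy(float)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration and driver


@dataclass
class PipelineConfig:
    """All knobs of the analysis chain; defaults are the study's values."""

    territories: str = "territories.csv"
    nestlings: str = "nestlings.csv"
    genotypes: str = "genotypes.csv"
    resights: str = "resights.csv"
    border: str = "border.csv"
    out_dir: str = "out"
    radius_broad_km: float = 30.0     # natal-area breeder density buffer
    radius_local_km: float = 10.0     # natal/breeding density-difference buffer
    recruitment_lag: int = 5          # expected recruitment = hatch year + lag
    min_typed_loci: int = 9           # genotype retention threshold
    min_overlap: int = 9              # matching: mutually typed loci needed
    max_mismatch: int = 0             # matching: allowed mismatching loci
    min_age: int = 5                  # calendar-year age filter
    exclude_focal: bool = False       # drop the focal territory from buffers
    inverse_weights: bool = False     # use 1/p instead of p as case weights
    seed: int = 0

    def __post_init__(self):
        if self.radius_broad_km <= 0 or self.radius_local_km <= 0:
            raise ValueError("radii must be positive")
        if self.recruitment_lag < 0:
            raise ValueError("recruitment lag must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig, inputs: dict | None = None) -> dict:
    """Execute match -> link -> filter -> metrics -> models and write the
    report bundle.

    ``inputs`` may carry already-loaded tables (keys ``territories,
    nestlings, genotypes, resights, border``) to bypass file reading — used
    by the simulator-backed entry points; otherwise paths in ``config`` are
    read.  Returns the report dict (also written to the bundle).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if inputs is None:
        inputs = {
            "territories": read_territories(config.territories),
            "nestlings": read_nestlings(config.nestlings),
            "genotypes": read_genotypes(config.genotypes, config.min_typed_loci),
            "resights": read_resights(config.resights),
            "border": read_border(config.border),
        }

    territories = inputs["territories"]
    nestlings = inputs["nestlings"]
    genotypes = inputs["genotypes"]
    resights = inputs["resights"]
    border = np.asarray(inputs["border"], float)

    logger.info("stage status: resolving territory-year activity")
    statuses = spatial.resolve_status(territories)

    logger.info("stage match: screening genotypes")
    nest_g = genotypes[genotypes["type"] == "nestling"].reset_index(drop=True)
    adult_g = genotypes[genotypes["type"] == "adult"].reset_index(drop=True)
    matches, match_report = genotyping.screen(
        nest_g, adult_g, min_typed=config.min_typed_loci,
        min_overlap=config.min_overlap, max_mismatch=config.max_mismatch)

    logger.info("stage link: fusing genotype and ring evidence")
    adult_meta = adult_g[["sample_id", "territory_id", "year", "sex_marker"]]
    nestling_markers = (nest_g[["individual_id", "sex_marker"]]
                        if "individual_id" in nest_g.columns else None)
    events = identify.link_individuals(matches, adult_meta, resights,
                                       nestlings, statuses,
                                       nestling_sex_markers=nestling_markers)

    logger.info("stage filter: dataset assembly")
    filtered, flog = identify.apply_filters(events, min_age=config.min_age)

    logger.info("stage weights: recruitment GLM")
    glm_in = nestlings.copy()
    glm_in["border_km"] = [spatial.distance_to_border_km((r.lat, r.lon), border)
                           for r in glm_in.itertuples()]
    glm_in["recruited"] = glm_in["individual_id"].isin(set(events["individual_id"])).astype(int)
    glm_fit = models.fit_recruitment_glm(glm_in)
    weights = models.predict_weights(glm_fit, glm_in)
    if config.inverse_weights:
        weights = 1.0 / weights

    logger.info("stage metrics: assembling analysis rows")
    rows = metrics.assemble(filtered, statuses, weights=weights,
                            lag=config.recruitment_lag,
                            radius_broad=config.radius_broad_km,
                            radius_local=config.radius_local_km,
                            exclude_focal=config.exclude_focal)

    logger.info("stage fit: mixed models")
    dist_fit = models.fit_lmm_distance(rows, weights=rows["weight"].to_numpy())
    dd_fit = models.fit_lmm_density_diff(rows)
    defined = rows[rows["expected_diff_defined"]]
    vifs = models.vif(defined, ["density10_natal_z", "year_z", "expected_diff_z"])

    # ---- report bundle ----------------------------------------------------
    write_table(matches, out / "matches.csv")
    write_table(match_report, out / "match_report.csv")
    write_table(events, out / "events.csv")
    write_table(filtered, out / "events_filtered.csv")
    write_table(rows, out / "analysis_rows.csv")
    write_table(flog.reasons, out / "filter_log.csv")
    (out / "filter_log.txt").write_text(flog.format() + "\n")
    glm_fit.to_json(out / "model_recruitment_glm.json")
    dist_fit.to_json(out / "model_distance_lmm.json")
    dd_fit.to_json(out / "model_density_diff_lmm.json")
    (out / "model_tables.txt").write_text(
        "\n\n".join([glm_fit.format_table(), dist_fit.format_table(),
                     dd_fit.format_table()]) + "\n")

    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16],
        "counts": {
            "territories": int(territories["territory_id"].nunique()),
            "nestlings": int(len(nestlings)),
            "genotype_samples": int(len(genotypes)),
            "matches": int(len(matches)),
            "linked_individuals": int(len(events)),
            "by_source": events["source"].value_counts().to_dict(),
            "by_sex": events["sex"].value_counts().to_dict(),
            "removed_unknown_sex": flog.n_unknown_sex_removed,
            "removed_underage": flog.n_underage_removed,
            "analysis_rows": int(len(rows)),
            "density_diff_model_rows": int(rows["expected_diff_defined"].sum()),
        },
        "weights": {"mean": float(np.mean(weights)), "sd": float(np.std(weights, ddof=1))},
        "vif": vifs.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    return {"manifest": manifest, "events": events, "filtered": filtered,
            "rows": rows, "filter_log": flog, "glm": glm_fit,
            "distance_model": dist_fit, "density_diff_model": dd_fit,
            "weights": weights, "vif": vifs, "matches": matches}
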