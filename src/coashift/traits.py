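"""Species trait derivation and assembly of the analysis table.

Builds the predictor set for the comparative analysis — flocking
classifications at configurable flock-size thresholds, great-circle
migration distance between seasonal range centroids, absolute population
trend, Z-scored numeric covariates — and merges it with the COA shift
responses into one analysis-ready table per (season, model variant).

Model variant A uses binary flocking (flocking vs solo) on the full
classified pool; variant B refines flocking into mixed-age flocks,
age-separated flocks and solo, restricted to the subset with a cohort
timing classification.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger("coashift.traits")

EARTH_RADIUS_KM = 6371.0088

#: numeric covariates standardized before model fitting
NUMERIC_PREDICTORS = [
    "migration_distance_km",
    "habitat_specialism",
    "diet_specialism",
    "abs_population_trend",
    "total_range_km2",
    "sampled_range_km2",
    "generation_length_yr",
]

FACTOR_PREDICTORS = ["migration_type", "migratory_timing"]


def classify_flocking(max_travel_flock_size: int, threshold: int = 2) -> str:
    """flocking iff the maximum travelling flock size strictly exceeds
    the threshold (default 2; 5 and 10 for sensitivity analyses)."""
    if max_travel_flock_size < 1:
        raise ValueError("flock size must be >= 1")
    return "flocking" if max_travel_flock_size > threshold else "solo"


def flock_size_category(max_travel_flock_size: int) -> str:
    """solo (<= 2), small (3-9) or large (>= 10) travelling flocks.

    Size exactly 10 is assigned to large ("typically < 10" describes
    small flocks, so 10 itself falls outside them).
    """
    if max_travel_flock_size < 1:
        raise ValueError("flock size must be >= 1")
    if max_travel_flock_size <= 2:
        return "solo"
    return "small" if max_travel_flock_size < 10 else "large"


def combine_flocking_behaviour(flocking_binary: str, cohort_classification: str) -> str:
    """Three-level flocking behaviour from the binary label and the
    cohort timing class; solo dominates, insufficient_data propagates."""
    if flocking_binary == "solo":
        return "solo"
    if flocking_binary != "flocking":
        raise ValueError(f"unknown flocking_binary: {flocking_binary!r}")
    if cohort_classification == "mixed_age":
        return "mixed_age_flocks"
    if cohort_classification == "age_separated":
        return "age_separated_flocks"
    if cohort_classification == "insufficient_data":
        return "insufficient_data"
    raise ValueError(f"unknown cohort classification: {cohort_classification!r}")


def migration_distance(breeding_lonlat, nonbreeding_lonlat) -> float:
    """Great-circle (haversine) distance in km between seasonal range
    centroids, Earth radius 6,371.0088 km."""
    lon1, lat1 = breeding_lonlat
    lon2, lat2 = nonbreeding_lonlat
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not (-180 <= lon <= 180 and -90 <= lat <= 90):
            raise ValueError(f"invalid coordinates: ({lon}, {lat})")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dlat = p2 - p1
    dlon = math.radians(lon2 - lon1)
    h = math.sin(dlat / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def absolute_trend(trend: float) -> float:
    """Unsigned population trend (%/yr): direction is irrelevant, only
    the magnitude of demographic change enters the models."""
    if not np.isfinite(trend):
        raise ValueError("trend must be finite")
    return abs(trend)


def zscore_columns(table: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize columns to Z-scores with the sample SD (ddof=1).

    Returns the standardized table and a scaling record (column, mean,
    sd) so coefficients can be back-transformed to metres/year per
    natural unit. A zero-variance column raises, naming the column.
    """
    out = table.copy()
    recs = []
    for col in columns:
        x = out[col].to_numpy(float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if not sd > 0:
            raise ValueError(f"zero-variance column: {col}")
        out[col] = (x - mu) / sd
        recs.append({"column": col, "mean": mu, "sd": sd})
    return out, pd.DataFrame(recs)


def back_transform_coefficient(beta_z: float, scaling: pd.DataFrame, column: str) -> float:
    """Coefficient per natural unit from a Z-scale coefficient."""
    sd = float(scaling.set_index("column").loc[column, "sd"])
    return beta_z / sd


def assemble_analysis_table(
    traits: pd.DataFrame,
    shifts: pd.DataFrame,
    season: str,
    variant: str,
    cohort: pd.DataFrame | None = None,
    standardize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Merge traits, COA shifts (one season) and cohort classes into an
    analysis-ready table for model variant ``"A"`` or ``"B"``.

    Variant A keeps every species with a binary flocking label; variant
    B additionally requires a resolved three-level flocking behaviour
    (species whose cohort timing is ``insufficient_data`` are excluded
    with a log entry), so the A pool always contains the B pool.
    Species missing any predictor are dropped with a log entry; numeric
    predictors are Z-scored once, before any collinearity filtering.

    Returns ``(table, scaling_record)``.
    """
    if variant not in ("A", "B"):
        raise ValueError("variant must be 'A' or 'B'")
    resp = shifts[shifts["season"] == season][
        ["species", "displacement_m", "displacement_se_m", "weight"]
    ]
    df = traits.merge(resp, on="species", how="inner", suffixes=("", "_resp"))
    if "displacement_m_resp" in df.columns:
        df["displacement_m"] = df.pop("displacement_m_resp")
        df["displacement_se_m"] = df.pop("displacement_se_m_resp")

    if variant == "B" and "flocking_behaviour" not in df.columns:
        if cohort is None:
            raise ValueError("variant B needs cohort classifications or a "
                             "flocking_behaviour column")
        df = df.merge(cohort[["species", "classification"]], on="species", how="left")
        df["flocking_behaviour"] = [
            combine_flocking_behaviour(b, c if isinstance(c, str) else "insufficient_data")
            for b, c in zip(df["flocking_binary"], df["classification"])
        ]

    needed = NUMERIC_PREDICTORS + FACTOR_PREDICTORS + ["flocking_binary"]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"trait table missing predictor column(s): {missing_cols}")

    n0 = len(df)
    complete = df[needed + ["displacement_m", "displacement_se_m"]].notna().all(axis=1)
    df = df[complete]
    if n0 - int(complete.sum()):
        logger.info("assemble(%s/%s): dropped %d species with missing values",
                    season, variant, n0 - int(complete.sum()))
    if variant == "B":
        ok = df["flocking_behaviour"].isin(["solo", "age_separated_flocks", "mixed_age_flocks"])
        if (~ok).any():
            logger.info("assemble(%s/B): excluded %d species without resolved "
                        "flocking behaviour", season, int((~ok).sum()))
        df = df[ok]
    df = df.reset_index(drop=True)

    bad = df["sampled_range_km2"] > df["total_range_km2"] * (1 + 1e-9)
    if bad.any():
        raise ValueError("sampled_range_km2 exceeds total_range_km2 for "
                         f"{df.loc[bad, 'species'].tolist()}")

    scaling = None
    if standardize:
        df, scaling = zscore_columns(df, NUMERIC_PREDICTORS)
    return df, scaling
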