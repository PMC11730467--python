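"""Annual centres of abundance, their linear trends, and displacement.

The centre of abundance (COA) for one species, season and year is the
mean of stratum centroid coordinates weighted by the stratum abundance
indices, computed separately for latitude and longitude:

    COA = sum_s(I_s * x_s) / sum_s(I_s)

Posterior uncertainty in each stratum index is propagated through this
ratio by the first-order Taylor (delta) method, treating stratum
posteriors as mutually independent. Per-axis linear trends over years
are ordinary least-squares slopes, with variance propagated through the
slope's linearity in the annual COAs, and the two axis trends combine
into a single displacement vector (metres per year) by the Pythagorean
theorem with its own first-order error propagation.

:class:`COAShiftModel` wraps the whole chain for one species/season:
``COAShiftModel.from_dataframe(indices).fit()`` returns a
:class:`COAShiftResults` carrying the annual COA table, per-axis trends
with standard errors, and the combined displacement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import METRES_PER_DEGREE, RunConfig
from .io import sd_from_percentiles  # noqa: F401  (re-exported: Eq. for SD lives with schema)

logger = logging.getLogger("coashift.coa")


class UndefinedCOAError(ValueError):
    """All stratum indices are zero for a year: the COA is undefined."""


def annual_coa(indices, coords, sds=None):
    """Abundance-weighted mean coordinate with propagated SD for one year.

    Parameters
    ----------
    indices : array-like
        Stratum abundance indices (posterior medians), all >= 0.
    coords : array-like
        Stratum centroid coordinate on one axis (degrees lat or lon).
    sds : array-like, optional
        Posterior SDs of the indices; zeros if omitted.

    Returns
    -------
    (mean, sd) : tuple of float
        The weighted mean and its first-order Taylor SD. With the mean
        m = sum(I*x)/sum(I), the partial derivative wrt I_s is
        (x_s - m)/sum(I), so var(m) = sum(((x_s - m)/sum(I))^2 * sd_s^2).
    """
    I = np.asarray(indices, dtype=float)
    x = np.asarray(coords, dtype=float)
    s = np.zeros_like(I) if sds is None else np.asarray(sds, dtype=float)
    if I.shape != x.shape or I.shape != s.shape:
        raise ValueError("indices, coords and sds must have matching shapes")
    if np.any(I < 0) or np.any(s < 0):
        raise ValueError("indices and sds must be nonnegative")
    total = I.sum()
    if total <= 0:
        raise UndefinedCOAError("all stratum indices are zero")
    mean = float(np.dot(I, x) / total)
    var = float(np.sum(((x - mean) / total) ** 2 * s**2))
    return mean, math.sqrt(var)


def coa_trend(years, coas, sds=None):
    """OLS slope of annual COA on year, with propagated SE.

    slope = sum_n w_n * COA_n with w_n = (year_n - mean(year)) /
    sum((year - mean(year))^2); being linear in the COAs, its propagated
    variance is sum(w_n^2 * var(COA_n)).

    Returns ``(slope, se)`` in degrees per year.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(coas, dtype=float)
    s = np.zeros_like(y) if sds is None else np.asarray(sds, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need >= 2 distinct years with a defined COA")
    w = t - t.mean()
    w /= np.sum(w**2)
    slope = float(np.dot(w, y))
    se = math.sqrt(float(np.sum(w**2 * s**2)))
    return slope, se


def displacement(trend_lat, se_lat, trend_lon, se_lon, mean_coa_lat,
                 convention: str = "mean_coa", reference_latitude: float = 45.0):
    """Combined COA displacement (metres/year) with propagated SE.

    Per-axis degree/year trends convert to metres/year (latitude at
    111,320 m/deg; longitude additionally scaled by cos(latitude) at the
    species' mean COA latitude, or at a fixed reference latitude for the
    equirectangular sensitivity variant), then combine as
    d = sqrt(a^2 + b^2) with Var(d) = (a^2 Var(a) + b^2 Var(b)) / d^2.
    At d = 0 the gradient is undefined and se = sqrt(Var(a) + Var(b)) is
    returned as a conservative bound.
    """
    for v in (trend_lat, se_lat, trend_lon, se_lon, mean_coa_lat):
        if not np.isfinite(v):
            raise ValueError("non-finite input to displacement")
    if convention == "mean_coa":
        coslat = math.cos(math.radians(mean_coa_lat))
    elif convention == "fixed_ref":
        coslat = math.cos(math.radians(reference_latitude))
    elif convention == "none":
        coslat = 1.0
    else:
        raise ValueError(f"unknown degree-to-metre convention: {convention}")
    a = trend_lat * METRES_PER_DEGREE
    b = trend_lon * METRES_PER_DEGREE * coslat
    va = (se_lat * METRES_PER_DEGREE) ** 2
    vb = (se_lon * METRES_PER_DEGREE * coslat) ** 2
    d = math.hypot(a, b)
    if d == 0.0:
        return 0.0, math.sqrt(va + vb)
    var_d = (a * a * va + b * b * vb) / (d * d)
    return d, math.sqrt(var_d)


@dataclass
class COAShiftResults:
    """Fitted COA shift for one species and season.

    Attributes
    ----------
    annual : pandas.DataFrame
        Columns year, coa_lat, coa_lon, sd_lat, sd_lon (undefined years
        excluded).
    trend_lat, trend_lon : float
        Per-axis OLS trends, degrees/year.
    se_trend_lat, se_trend_lon : float
        Propagated trend SEs, degrees/year.
    displacement_m, displacement_se_m : float
        Combined displacement and its SE, metres/year.
    weight : float
        Reciprocal-SE weight (1/displacement_se_m) for downstream PGLS.
    dropped_years : list of int
        Years excluded because every stratum index was zero.
    """

    species: str
    season: str
    annual: pd.DataFrame
    trend_lat: float
    se_trend_lat: float
    trend_lon: float
    se_trend_lon: float
    displacement_m: float
    displacement_se_m: float
    dropped_years: list = field(default_factory=list)

    @property
    def weight(self) -> float:
        return 1.0 / self.displacement_se_m if self.displacement_se_m > 0 else np.inf

    def summary(self) -> str:
        lines = [
            f"COA shift: {self.species} ({self.season})",
            f"  years used          {len(self.annual)}"
            + (f"  (dropped: {self.dropped_years})" if self.dropped_years else ""),
            f"  trend latitude      {self.trend_lat:+.6f} ± {self.se_trend_lat:.6f} deg/yr",
            f"  trend longitude     {self.trend_lon:+.6f} ± {self.se_trend_lon:.6f} deg/yr",
            f"  displacement        {self.displacement_m:.1f} ± {self.displacement_se_m:.1f} m/yr",
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "species": self.species,
            "season": self.season,
            "trend_lat": self.trend_lat,
            "se_trend_lat": self.se_trend_lat,
            "trend_lon": self.trend_lon,
            "se_trend_lon": self.se_trend_lon,
            "displacement_m": self.displacement_m,
            "displacement_se_m": self.displacement_se_m,
            "weight": self.weight,
            "n_years": len(self.annual),
        }


class COAShiftModel:
    """Centre-of-abundance shift model for one species and season.

    Parameters
    ----------
    indices : pandas.DataFrame
        Validated stratum index table (one species/season), with columns
        stratum_id, centroid_lon, centroid_lat, year, index_median and
        either index_sd or the lo95/hi95 pair.
    config : RunConfig, optional
        Supplies the year window and the degree-to-metre convention.
    """

    def __init__(self, indices: pd.DataFrame, config: RunConfig | None = None,
                 species: str = "", season: str = ""):
        self.config = config or RunConfig()
        df = indices.copy()
        if "index_sd" not in df.columns:
            df["index_sd"] = sd_from_percentiles(
                df["index_lo95"].to_numpy(), df["index_hi95"].to_numpy()
            )
        df = df[(df["year"] >= self.config.year_start) & (df["year"] <= self.config.year_end)]
        if df.empty:
            raise ValueError("no index rows inside the configured year window")
        self.indices = df
        self.species = species or (df["species"].iloc[0] if "species" in df else "")
        self.season = season or (df["season"].iloc[0] if "season" in df else "")

    @classmethod
    def from_dataframe(cls, indices: pd.DataFrame, species: str, season: str,
                       config: RunConfig | None = None) -> "COAShiftModel":
        sub = indices
        if "species" in indices.columns:
            sub = indices[(indices["species"] == species) & (indices["season"] == season)]
            if sub.empty:
                raise ValueError(f"no rows for {species}/{season}")
        return cls(sub, config=config, species=species, season=season)

    def annual_table(self) -> tuple[pd.DataFrame, list]:
        rows, dropped = [], []
        for year, grp in self.indices.groupby("year", sort=True):
            I = grp["index_median"].to_numpy(float)
            s = grp["index_sd"].to_numpy(float)
            try:
                lat, sd_lat = annual_coa(I, grp["centroid_lat"].to_numpy(float), s)
                lon, sd_lon = annual_coa(I, grp["centroid_lon"].to_numpy(float), s)
            except UndefinedCOAError:
                dropped.append(int(year))
                continue
            rows.append({"year": int(year), "coa_lat": lat, "coa_lon": lon,
                         "sd_lat": sd_lat, "sd_lon": sd_lon})
        if dropped:
            logger.warning("%s/%s: %d year(s) with all-zero indices dropped: %s",
                           self.species, self.season, len(dropped), dropped)
        return pd.DataFrame(rows), dropped

    def fit(self) -> COAShiftResults:
        annual, dropped = self.annual_table()
        if len(annual) < 2:
            raise ValueError("fewer than 2 years with a defined COA")
        t = annual["year"].to_numpy(float)
        b_lat, se_lat = coa_trend(t, annual["coa_lat"], annual["sd_lat"])
        b_lon, se_lon = coa_trend(t, annual["coa_lon"], annual["sd_lon"])
        d, se_d = displacement(
            b_lat, se_lat, b_lon, se_lon,
            mean_coa_lat=float(annual["coa_lat"].mean()),
            convention=self.config.degree_to_metre,
            reference_latitude=self.config.reference_latitude,
        )
        return COAShiftResults(
            species=self.species, season=self.season, annual=annual,
            trend_lat=b_lat, se_trend_lat=se_lat,
            trend_lon=b_lon, se_trend_lon=se_lon,
            displacement_m=d, displacement_se_m=se_d,
            dropped_years=dropped,
        )


def shift_table(indices: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Fit :class:`COAShiftModel` for every (species, season) in a table."""
    rows = []
    for (sp, season), _ in indices.groupby(["species", "season"], sort=True):
        res = COAShiftModel.from_dataframe(indices, sp, season, config=config).fit()
        rows.append(res.to_row())
    return pd.DataFrame(rows)
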