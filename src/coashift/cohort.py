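"""Age-cohort migration timing from banding records.

Whether juveniles (hatch-year, HY) and adults (after-hatch-year, AHY)
migrate together or in temporally separated cohorts is inferred from
banding events: latitude is regressed on Julian day with a penalized
regression spline per age class, the autumn window (where the pooled
curve declines) is located, each fitted curve is min-max normalised on
that window, and the proportional overlap in area under the two curves

    overlap = integral(min(fA, fB)) / integral(max(fA, fB))

classifies the species as mixed-age (overlap strictly above the 0.85
threshold) or age-separated.

The smoother is a cubic B-spline basis (10 basis functions) with a
curvature penalty, its smoothing parameter chosen by generalized
cross-validation profiled in closed form through one symmetric
eigendecomposition per fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines

from .config import RunConfig


class DegenerateCurveError(ValueError):
    """A fitted curve is constant on the window: min-max normalisation fails."""


# ---------------------------------------------------------------------------
# Penalized spline smoother with closed-form GCV


@dataclass
class FittedCohortCurve:
    """One age class's smoothed latitude-by-day curve on an integer grid."""

    age_class: str
    days: np.ndarray
    values: np.ndarray
    basis_size: int
    alpha: float
    n_records: int

    def on_window(self, start: int, end: int) -> "FittedCohortCurve":
        m = (self.days >= start) & (self.days <= end)
        return FittedCohortCurve(self.age_class, self.days[m], self.values[m],
                                 self.basis_size, self.alpha, self.n_records)


def fit_penalized_spline(
    day: np.ndarray,
    lat: np.ndarray,
    grid: np.ndarray,
    df: int = 10,
    age_class: str = "",
) -> FittedCohortCurve:
    """Penalized cubic regression spline of latitude on day, GCV-tuned.

    Minimises ||y - Xb||^2 + alpha * b'Pb where X is a 10-column cubic
    B-spline basis and P its integrated-squared-curvature penalty. GCV
    score n*RSS/(n - edf)^2 is profiled over alpha on a log grid via the
    generalized eigendecomposition of (X'X, P), then the curve is
    evaluated on the integer day grid (clipped to the observed range).
    """
    day = np.asarray(day, float)
    lat = np.asarray(lat, float)
    n = len(day)
    ndistinct = len(np.unique(day))
    k = min(df, max(4, ndistinct - 1))
    bs = BSplines(day[:, None], df=[k], degree=[3], include_intercept=True)
    sm = bs.smoothers[0]
    X, P = sm.basis, sm.cov_der2
    XtX = X.T @ X
    Xty = X.T @ lat
    yty = float(lat @ lat)

    # simultaneous diagonalisation: R^-T P R^-1 = U diag(g) U'
    R = np.linalg.cholesky(XtX + 1e-10 * np.eye(k) * np.trace(XtX)).T
    Rinv = np.linalg.inv(R)
    g, U = np.linalg.eigh(Rinv.T @ P @ Rinv)
    g = np.clip(g, 0.0, None)
    c = U.T @ (Rinv.T @ Xty)  # rotated coordinates; edf = sum 1/(1+alpha*g)

    def gcv(alpha: float) -> float:
        shrink = 1.0 / (1.0 + alpha * g)
        rss = yty - float(np.sum((2.0 - shrink) * shrink * c**2))
        edf = float(np.sum(shrink))
        return n * max(rss, 1e-12) / (n - edf) ** 2

    alphas = np.logspace(-6, 8, 57)
    best = float(alphas[int(np.argmin([gcv(a) for a in alphas]))])
    beta = Rinv @ (U @ (c / (1.0 + best * g)))

    lo, hi = day.min(), day.max()
    grid = np.asarray(grid, float)
    clipped = np.clip(grid, lo, hi)
    values = sm.transform(clipped) @ beta
    return FittedCohortCurve(age_class=age_class, days=grid.astype(int),
                             values=values, basis_size=k, alpha=best, n_records=n)


# ---------------------------------------------------------------------------
# Stage operations


def fit_age_smoother(
    records: pd.DataFrame,
    window: tuple[int, int] | None = None,
    df: int = 10,
) -> dict[str, FittedCohortCurve]:
    """Fit one curve per age class (equivalent to a day-by-class
    interaction smooth), evaluated on a shared integer day grid."""
    if window is not None:
        records = records[records["julian_day"].between(*window)]
    lo = int(records["julian_day"].min())
    hi = int(records["julian_day"].max())
    grid = np.arange(lo, hi + 1, dtype=float)
    out = {}
    for age, grp in records.groupby("age_class"):
        out[age] = fit_penalized_spline(
            grp["julian_day"].to_numpy(float), grp["latitude"].to_numpy(float),
            grid, df=df, age_class=str(age),
        )
    return out


def detect_autumn_window(
    days: np.ndarray,
    values: np.ndarray,
    eps: float = 0.005,
    min_decline: float = 2.0,
) -> tuple[int, int] | None:
    """Longest contiguous day interval of sustained latitude decline.

    A day belongs to a declining run when the curve's first difference
    is below ``-eps`` degrees/day; runs whose total decline is at least
    ``min_decline`` degrees qualify, and the longest qualifying run
    (ties broken by larger total decline) is returned. ``None`` when no
    run qualifies (e.g. a flat curve). Spring increases never qualify
    because the sign rule only admits declines.
    """
    days = np.asarray(days)
    values = np.asarray(values, float)
    declining = np.diff(values) < -eps
    best: tuple[int, float, tuple[int, int]] | None = None
    i = 0
    while i < len(declining):
        if not declining[i]:
            i += 1
            continue
        j = i
        while j < len(declining) and declining[j]:
            j += 1
        start, end = int(days[i]), int(days[j])
        decline = float(values[i] - values[j])
        if decline >= min_decline:
            cand = (end - start, decline, (start, end))
            if best is None or cand[:2] > best[:2]:
                best = cand
        i = j
    return best[2] if best else None


def overlap_index(
    curve_a: FittedCohortCurve,
    curve_b: FittedCohortCurve,
    window: tuple[int, int] | None = None,
    form: str = "min_over_max",
) -> float:
    """Proportional overlap in area under two min-max-normalised curves.

    Each curve is normalised to [0, 1] on the (shared) window, then the
    index is trapezoid-rule integral(min)/integral(max) — symmetric in
    its arguments and invariant to affine transforms of either raw
    curve. The ``min_over_mean`` variant divides by the mean of the two
    individual areas instead.
    """
    a, b = curve_a, curve_b
    if window is not None:
        a, b = a.on_window(*window), b.on_window(*window)
    if not np.array_equal(a.days, b.days):
        raise ValueError("curves must share a day grid")
    if len(a.days) < 2:
        raise ValueError("window too short for overlap")

    def norm(v: np.ndarray) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        if hi - lo <= 1e-12:
            raise DegenerateCurveError("curve is constant on the window")
        return (v - lo) / (hi - lo)

    fa, fb = norm(a.values), norm(b.values)
    x = a.days.astype(float)
    # refine the grid with curve crossings so min/max of the two
    # piecewise-linear curves integrate exactly
    d = fa - fb
    cross = []
    for i in range(len(x) - 1):
        if d[i] * d[i + 1] < 0:
            cross.append(x[i] + d[i] / (d[i] - d[i + 1]) * (x[i + 1] - x[i]))
    xs = np.unique(np.concatenate([x, np.asarray(cross)]))
    fa = np.interp(xs, x, fa)
    fb = np.interp(xs, x, fb)
    lower = np.trapezoid(np.minimum(fa, fb), xs)
    if form == "min_over_max":
        denom = np.trapezoid(np.maximum(fa, fb), xs)
    elif form == "min_over_mean":
        denom = 0.5 * (np.trapezoid(fa, xs) + np.trapezoid(fb, xs))
    else:
        raise ValueError(f"unknown overlap form: {form}")
    if denom <= 0:
        return 0.0
    return float(np.clip(lower / denom, 0.0, 1.0))


def classify_cohort_timing(index: float, threshold: float = 0.85) -> str:
    """mixed_age iff the overlap index strictly exceeds the threshold."""
    if not 0.0 <= index <= 1.0:
        raise ValueError("overlap index must be in [0, 1]")
    return "mixed_age" if index > threshold else "age_separated"


# ---------------------------------------------------------------------------
# Model / Results wrapper


@dataclass
class CohortTimingResults:
    """Cohort-timing classification for one species."""

    species: str
    classification: str  # mixed_age | age_separated | insufficient_data
    overlap_index: float | None
    window: tuple[int, int] | None
    n_by_class: dict
    curves: dict | None = None
    reason: str | None = None

    def summary(self) -> str:
        lines = [f"Cohort timing: {self.species}",
                 f"  records (HY/AHY)   {self.n_by_class.get('HY', 0)}/{self.n_by_class.get('AHY', 0)}"]
        if self.window:
            lines.append(f"  autumn window      days {self.window[0]}-{self.window[1]}")
        if self.overlap_index is not None:
            lines.append(f"  overlap index      {self.overlap_index:.3f}")
        lines.append(f"  classification     {self.classification}"
                     + (f" ({self.reason})" if self.reason else ""))
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "species": self.species,
            "overlap_index": self.overlap_index,
            "window_start": self.window[0] if self.window else None,
            "window_end": self.window[1] if self.window else None,
            "n_HY": self.n_by_class.get("HY", 0),
            "n_AHY": self.n_by_class.get("AHY", 0),
            "classification": self.classification,
        }


class CohortTimingModel:
    """Classify one species' migration timing from its banding records.

    The fit proceeds: pooled full-year curve -> autumn-window detection
    (or the configured manual window) -> per-age-class curves inside the
    window -> overlap index -> threshold classification. Sample-size
    shortfalls yield an ``insufficient_data`` result, never an
    exception.
    """

    def __init__(self, records: pd.DataFrame, config: RunConfig | None = None,
                 species: str = ""):
        self.config = config or RunConfig()
        self.records = records
        self.species = species or (records["species"].iloc[0] if "species" in records and len(records) else "")

    @classmethod
    def from_dataframe(cls, banding: pd.DataFrame, species: str,
                       config: RunConfig | None = None) -> "CohortTimingModel":
        sub = banding[banding["species"] == species] if "species" in banding.columns else banding
        return cls(sub, config=config, species=species)

    def fit(self, keep_curves: bool = False) -> CohortTimingResults:
        cfg = self.config
        rec = self.records
        counts = rec["age_class"].value_counts().to_dict() if len(rec) else {}

        def insufficient(reason: str, window=None, index=None) -> CohortTimingResults:
            return CohortTimingResults(self.species, "insufficient_data", index,
                                       window, counts, reason=reason)

        if len(rec) < cfg.min_banding_records:
            return insufficient(f"only {len(rec)} records (< {cfg.min_banding_records})")

        if cfg.autumn_window is not None:
            window = tuple(cfg.autumn_window)
        else:
            pooled = fit_penalized_spline(
                rec["julian_day"].to_numpy(float), rec["latitude"].to_numpy(float),
                np.arange(rec["julian_day"].min(), rec["julian_day"].max() + 1, dtype=float),
            )
            window = detect_autumn_window(pooled.days, pooled.values,
                                          eps=cfg.autumn_eps,
                                          min_decline=cfg.autumn_min_decline)
            if window is None:
                return insufficient("no sustained latitude decline found")

        in_win = rec[rec["julian_day"].between(*window)]
        counts_win = in_win["age_class"].value_counts().to_dict()
        if min(counts_win.get("HY", 0), counts_win.get("AHY", 0)) < cfg.min_records_per_age_class:
            return insufficient("too few records per age class in window", window=window)

        curves = fit_age_smoother(in_win, window=window)
        try:
            idx = overlap_index(curves["HY"], curves["AHY"], form=cfg.overlap_form)
        except DegenerateCurveError:
            return insufficient("constant fitted curve in window", window=window)
        cls_label = classify_cohort_timing(idx, threshold=cfg.overlap_threshold)
        return CohortTimingResults(self.species, cls_label, idx, window, counts,
                                   curves=curves if keep_curves else None)


def cohort_table(banding: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Fit :class:`CohortTimingModel` for every species in a banding table."""
    rows = []
    for sp in sorted(banding["species"].unique()):
        rows.append(CohortTimingModel.from_dataframe(banding, sp, config=config).fit().to_row())
    return pd.DataFrame(rows)
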