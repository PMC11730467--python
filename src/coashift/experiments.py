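"""Reusable simulation experiments: calibration, recovery, power.

Each function runs one of the package's standard validation studies on
synthetic data with known ground truth and returns plain dictionaries
of summary numbers. They are deliberately deterministic given a seed,
so the same experiments back both the test suite and the reproduction
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coa import COAShiftModel, annual_coa, coa_trend, displacement
from .config import METRES_PER_DEGREE
from .pgls import PGLS, brownian_correlation, build_design
from .simulate import SimScenario, simulate_index_series, simulate_traits, simulate_tree
from .cohort import CohortTimingModel
from .simulate import simulate_banding
from .traits import FACTOR_PREDICTORS, NUMERIC_PREDICTORS, zscore_columns


def taylor_vs_monte_carlo(seed: int, n_instances: int = 21,
                          n_draws: int = 10**5) -> dict:
    """Worst relative disagreement between first-order Taylor SEs and
    Monte-Carlo SDs over random small instances of the weighted-mean,
    trend and displacement operations."""
    rng = np.random.default_rng(seed)
    rel = {"coa": [], "trend": [], "displacement": []}
    per = int(np.ceil(n_instances / 3))
    for _ in range(per):
        k = int(rng.integers(2, 11))
        I = rng.uniform(1.0, 5.0, k)
        x = rng.uniform(0.0, 20.0, k)
        s = rng.uniform(0.02, 0.10) * I
        _, sd = annual_coa(I, x, s)
        draws = np.clip(rng.normal(I, s, size=(n_draws, k)), 0.0, None)
        mc = (draws @ x / draws.sum(axis=1)).std()
        rel["coa"].append(abs(sd - mc) / mc)
    for _ in range(per):
        ny = int(rng.integers(5, 51))
        years = np.arange(1970, 1970 + ny).astype(float)
        mu = 40.0 + 0.01 * (years - years.mean())
        sds = rng.uniform(0.05, 0.3, ny)
        _, se = coa_trend(years, mu, sds)
        draws = rng.normal(mu, sds, size=(n_draws, ny))
        w = years - years.mean()
        w /= np.sum(w**2)
        rel["trend"].append(abs(se - (draws @ w).std()) / (draws @ w).std())
    for _ in range(per):
        a, b = rng.uniform(500, 3000, 2)
        sa, sb = rng.uniform(50, 300, 2)
        _, se = displacement(a / METRES_PER_DEGREE, sa / METRES_PER_DEGREE,
                             b / METRES_PER_DEGREE, sb / METRES_PER_DEGREE,
                             mean_coa_lat=0.0)
        mc = np.hypot(rng.normal(a, sa, n_draws), rng.normal(b, sb, n_draws)).std()
        rel["displacement"].append(abs(se - mc) / mc)
    return {
        "n_instances": 3 * per,
        "max_rel_error": float(max(max(v) for v in rel.values())),
        "max_rel_error_by_op": {k: float(max(v)) for k, v in rel.items()},
    }


def planted_shift_recovery(seed: int, n_reps: int = 200,
                           velocity_north: float = 5000.0) -> dict:
    """Recover a planted northward drift from noisy synthetic indices.

    Reports the noiseless recovery error, the mean relative bias over
    noisy replicates and the fraction of 1.96*SE intervals covering the
    planted speed.
    """
    noiseless = SimScenario(velocity_north=velocity_north, velocity_east=0.0,
                            index_noise=0.0, ci_width=0.0, seed=seed)
    res0 = COAShiftModel(simulate_index_series(noiseless, "sp")).fit()
    scen = SimScenario(velocity_north=velocity_north, velocity_east=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    est, cover = [], 0
    for _ in range(n_reps):
        sub = int(rng.integers(2**31 - 1))
        res = COAShiftModel(simulate_index_series(scen, "sp", seed=sub)).fit()
        est.append(res.displacement_m)
        cover += abs(res.displacement_m - velocity_north) <= 1.96 * res.displacement_se_m
    est = np.asarray(est)
    return {
        "planted_m_per_yr": velocity_north,
        "noiseless_rel_error": float(abs(res0.displacement_m - velocity_north)
                                     / velocity_north),
        "mean_rel_bias": float((est.mean() - velocity_north) / velocity_north),
        "coverage_95": cover / n_reps,
        "n_reps": n_reps,
    }


def cohort_classification_rates(seed: int, n_species: int = 100,
                                n_records: int = 1500) -> dict:
    """End-to-end timing classification of synthetic species with
    concurrent (0-day) vs separated (40-day) cohort passage."""
    scen = SimScenario(seed=seed)
    rng = np.random.default_rng(seed)
    hits = {0.0: 0, 40.0: 0}
    want = {0.0: "mixed_age", 40.0: "age_separated"}
    for _ in range(n_species):
        sub = int(rng.integers(2**31 - 1))
        for sep in (0.0, 40.0):
            band = simulate_banding(scen, "sp", seed=sub, n_records=n_records,
                                    cohort_separation=sep)
            res = CohortTimingModel(band).fit()
            hits[sep] += res.classification == want[sep]
    return {
        "n_species": n_species,
        "rate_mixed_age_at_sep0": hits[0.0] / n_species,
        "rate_age_separated_at_sep40": hits[40.0] / n_species,
    }


def pgls_calibration(seed: int, n_reps: int = 500, n_tips: int = 50,
                     beta: float = 2.0, se_y: float = 0.5) -> dict:
    """Bias and CI coverage for a planted slope under Brownian residuals
    plus known measurement error."""
    rng = np.random.default_rng(seed)
    ests, cover = [], 0
    for rep in range(n_reps):
        tree = simulate_tree(n_tips, seed=seed * 1000 + rep)
        C = brownian_correlation(tree).to_numpy()
        x = rng.normal(size=n_tips)
        resid = rng.multivariate_normal(np.zeros(n_tips),
                                        C + np.diag(np.full(n_tips, se_y**2)))
        y = 1.0 + beta * x + resid
        X = pd.DataFrame({"Intercept": np.ones(n_tips), "x": x})
        res = PGLS(y, X, C, se_y=np.full(n_tips, se_y)).fit()
        ests.append(float(res.params["x"]))
        ci = res.conf_int().loc["x"]
        cover += ci["lower"] <= beta <= ci["upper"]
    ests = np.asarray(ests)
    return {
        "planted_beta": beta,
        "rel_bias": float((ests.mean() - beta) / beta),
        "coverage_95": cover / n_reps,
        "n_reps": n_reps,
    }


def _global_flocking_fit(scenario: SimScenario, seed: int):
    """One trait simulation plus the global variant-B PGLS fit."""
    tree = simulate_tree(scenario.n_species, seed)
    traits, truth = simulate_traits(tree, scenario, seed=seed)
    traits, _ = zscore_columns(traits, list(NUMERIC_PREDICTORS))
    C = brownian_correlation(tree, order=traits["species"].tolist())
    factors = {"migration_type": "partial", "migratory_timing": "day",
               "flocking_behaviour": "solo"}
    X, _ = build_design(traits, list(NUMERIC_PREDICTORS), factors)
    res = PGLS(traits["displacement_m"].to_numpy(float), X, C,
               se_y=traits["displacement_se_m"].to_numpy(float)).fit()
    return res, truth


def flocking_effect_calibration(seed: int, n_reps: int = 200,
                                n_species: int = 81,
                                mixed_age_effect: float = 2660.0) -> dict:
    """Null false-positive rate and power for the mixed-age flocking
    term in the global PGLS fit at the study's pool size.

    The null scenario plants zero class effects; the power scenario
    plants ``mixed_age_effect`` metres/year for mixed-age flocks (and
    the study's 800 m/yr for age-separated flocks). A run counts as a
    detection when the term's 95% CI excludes zero.
    """
    term = "flocking_behaviour[mixed_age_flocks]"
    out = {}
    for label, effects in (
        ("null", {"solo": 0.0, "age_separated_flocks": 0.0, "mixed_age_flocks": 0.0}),
        ("power", {"solo": 0.0, "age_separated_flocks": 800.0,
                   "mixed_age_flocks": mixed_age_effect}),
    ):
        scen = SimScenario(n_species=n_species, flocking_effects=effects, seed=seed)
        rng = np.random.default_rng(seed + (0 if label == "null" else 1))
        hits, used, est = 0, 0, []
        attempts = 0
        while used < n_reps:
            attempts += 1
            if attempts > 4 * n_reps:
                raise RuntimeError("too many degenerate trait draws")
            sub = int(rng.integers(2**31 - 1))
            try:
                res, _ = _global_flocking_fit(scen, sub)
            except ValueError:
                continue  # a factor level (e.g. solo reference) absent
            if term not in res.params.index:
                continue  # degenerate class draw without mixed-age species
            used += 1
            ci = res.conf_int().loc[term]
            hits += not (ci["lower"] <= 0.0 <= ci["upper"])
            est.append(float(res.params[term]))
        out[label] = {"rate": hits / n_reps, "mean_estimate": float(np.mean(est)),
                      "n_reps": n_reps}
    return {
        "false_positive_rate": out["null"]["rate"],
        "power": out["power"]["rate"],
        "mean_mixed_age_estimate": out["power"]["mean_estimate"],
        "planted_mixed_age_effect": mixed_age_effect,
        "n_species": n_species,
        "n_reps": n_reps,
    }
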