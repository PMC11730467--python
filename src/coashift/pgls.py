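"""SE-weighted phylogenetic generalized least squares and AICc averaging.

The comparative analysis regresses per-species COA shift rates on
traits while (a) accounting for shared ancestry and (b) weighting each
species by the confidence in its shift estimate. Under Brownian-motion
trait evolution on an ultrametric tree, residuals are correlated in
proportion to shared root-to-ancestor path length; with per-species
measurement error the residual covariance is

    V = sigma^2 * C + diag(se_y^2)

where C is the Brownian correlation matrix from the tree and se_y the
reported standard errors of the response. sigma^2 is profiled by
maximum likelihood with a 1-D optimisation; coefficients are GLS,
beta = (X'V^-1 X)^-1 X'V^-1 y, with SEs from (X'V^-1 X)^-1.

Inference follows an information-theoretic recipe: the global model is
screened for collinearity (VIF above 5 removed stepwise), all nested
submodels are ranked by AICc, candidates within 2 units of the best are
averaged with Akaike weights, and a term is significant when its 95%
confidence interval excludes zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .config import RunConfig

logger = logging.getLogger("coashift.pgls")

Z95 = 1.959963984540054


class RankError(ValueError):
    """The design matrix is rank-deficient."""


class ConvergenceError(RuntimeError):
    """The sigma^2 profile optimisation failed."""


# ---------------------------------------------------------------------------
# Brownian correlation from the tree


def brownian_correlation(tree: dendropy.Tree, order: list[str] | None = None) -> pd.DataFrame:
    """Expected Brownian-motion correlation among tips.

    C[i, j] is the shared root-to-MRCA path length of tips i and j,
    scaled so the diagonal is 1 (divide by depth for an ultrametric
    tree). For a non-ultrametric tree the shared path is scaled by the
    geometric mean of the two tip depths, with a warning.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances()
    tips = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in tips]
    depth = {lb: lf.root_distance for lb, lf in zip(labels, tips)}
    depths = np.array([depth[lb] for lb in labels])
    if depths.max() - depths.min() > 1e-8 * depths.max():
        logger.warning("tree is not ultrametric; scaling by per-tip depths")

    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    C = np.eye(n)
    taxa = {lf.taxon.label: lf.taxon for lf in tips}
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            shared = 0.5 * (depths[i] + depths[j] - d)
            C[i, j] = C[j, i] = shared / math.sqrt(depths[i] * depths[j])
    out = pd.DataFrame(C, index=labels, columns=labels)
    if order is not None:
        missing = [s for s in order if s not in out.index]
        if missing:
            raise KeyError(f"species not in tree: {missing}")
        out = out.loc[order, order]
    return out


# ---------------------------------------------------------------------------
# Design matrices


def build_design(
    df: pd.DataFrame,
    numeric: list[str],
    factors: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Treatment-coded design matrix plus predictor blocks.

    ``factors`` maps column name to its reference level (dropped dummy).
    Returns (X, blocks) where X includes an Intercept column and blocks
    maps each predictor name to its design column(s) — factor dummies
    always enter and leave candidate models together.
    """
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    blocks: dict[str, list[str]] = {}
    for col in numeric:
        X[col] = df[col].to_numpy(float)
        blocks[col] = [col]
    for col, ref in factors.items():
        levels = [lv for lv in pd.unique(df[col]) if lv != ref]
        if ref not in set(df[col]):
            raise ValueError(f"reference level {ref!r} absent from {col}")
        cols = []
        for lv in sorted(map(str, levels)):
            name = f"{col}[{lv}]"
            X[name] = (df[col].astype(str) == lv).astype(float)
            cols.append(name)
        if cols:
            blocks[col] = cols
    return X, blocks


# ---------------------------------------------------------------------------
# PGLS model


@dataclass
class PGLSResults:
    """Fitted SE-weighted PGLS model.

    ``params``/``bse`` are indexed by design column; ``sigma2`` is the
    ML Brownian rate; ``k`` counts estimated parameters (coefficients
    plus sigma^2) for AICc.
    """

    params: pd.Series
    bse: pd.Series
    sigma2: float
    llf: float
    nobs: int
    k: int
    cov_params: pd.DataFrame
    model: "PGLS" = field(repr=False, default=None)
    method: str = "reml"  # AICc comparisons across designs require "ml" fits

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k
        if n - k - 1 <= 0:
            return math.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    def conf_int(self, z: float = Z95) -> pd.DataFrame:
        return pd.DataFrame({
            "lower": self.params - z * self.bse,
            "upper": self.params + z * self.bse,
        })

    def pvalues(self) -> pd.Series:
        from scipy.stats import norm
        zval = self.params / self.bse.replace(0.0, np.nan)
        return pd.Series(2 * norm.sf(np.abs(zval)), index=self.params.index)

    def summary(self) -> str:
        ci = self.conf_int()
        p = self.pvalues()
        lines = [
            "PGLS (Brownian correlation + response measurement error)",
            f"  n = {self.nobs}, k = {self.k}, sigma^2 = {self.sigma2:.6g}",
            f"  logL = {self.llf:.4f}, AICc = {self.aicc:.4f}",
            f"  {'term':<28}{'coef':>12}{'se':>11}{'z-p':>9}{'95% CI':>26}",
        ]
        for t in self.params.index:
            lines.append(
                f"  {t:<28}{self.params[t]:>12.4f}{self.bse[t]:>11.4f}"
                f"{p[t]:>9.3f}    [{ci.loc[t, 'lower']:>9.2f}, {ci.loc[t, 'upper']:>9.2f}]"
            )
        return "\n".join(lines)


class PGLS:
    """Phylogenetic GLS with response measurement error.

    Parameters
    ----------
    y : array-like
        Response (COA shift, metres/year).
    X : DataFrame
        Design matrix including an intercept column.
    corr : DataFrame or ndarray
        Brownian correlation matrix aligned with ``y``.
    se_y : array-like, optional
        Per-observation response SEs (zeros if omitted).
    error_model : str
        ``"additive"`` (V = sigma^2 C + diag(se^2)) or
        ``"fixed_weights"`` (V = sigma^2 diag(se^2): pure reciprocal-SE
        weighting sensitivity variant, ignoring phylogeny off-diagonal).
    """

    def __init__(self, y, X: pd.DataFrame, corr, se_y=None,
                 error_model: str = "additive"):
        self.y = np.asarray(y, dtype=float)
        self.X = X.astype(float)
        self.names = list(X.columns)
        self.C = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
        n = len(self.y)
        self.se_y = np.zeros(n) if se_y is None else np.asarray(se_y, float)
        if np.any(self.se_y < 0):
            raise ValueError("se_y must be nonnegative")
        if self.X.shape[0] != n or self.C.shape != (n, n) or len(self.se_y) != n:
            raise ValueError("dimension mismatch between y, X, corr, se_y")
        if np.linalg.matrix_rank(self.X.to_numpy()) < self.X.shape[1]:
            raise RankError("design matrix is rank deficient")
        if error_model not in ("additive", "fixed_weights"):
            raise ValueError(f"unknown error model: {error_model}")
        self.error_model = error_model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, numeric: list[str],
                       factors: dict[str, str], corr, se: str | None = None,
                       error_model: str = "additive") -> "PGLS":
        X, blocks = build_design(df, numeric, factors)
        se_y = df[se].to_numpy(float) if se else None
        model = cls(df[response].to_numpy(float), X, corr, se_y=se_y,
                    error_model=error_model)
        model.blocks = blocks
        return model

    # -- likelihood machinery -------------------------------------------

    def _gls(self, V: np.ndarray, reml: bool = False):
        n, p = self.X.shape
        L = np.linalg.cholesky(V)
        Xw = np.linalg.solve(L, self.X.to_numpy())
        yw = np.linalg.solve(L, self.y)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        r = yw - Xw @ beta
        rss = float(r @ r)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        llf = -0.5 * (n * math.log(2 * math.pi) + logdet + rss)
        if reml:
            sign, logdet_xtx = np.linalg.slogdet(XtX)
            llf += 0.5 * p * math.log(2 * math.pi) - 0.5 * logdet_xtx
        cov = np.linalg.inv(XtX)
        return beta, cov, llf

    def _V(self, sigma2: float) -> np.ndarray:
        if self.error_model == "fixed_weights":
            base = np.diag(np.maximum(self.se_y, 1e-12) ** 2)
            return sigma2 * base
        return sigma2 * self.C + np.diag(self.se_y**2)

    def fit(self, method: str = "reml") -> PGLSResults:
        """Estimate sigma^2 and the coefficients.

        ``method="reml"`` (default) profiles the restricted likelihood,
        which removes the downward bias of sigma^2 when the design has
        many (tree-structured) covariates and is the right choice for
        coefficient inference; ``"ml"`` profiles the full likelihood and
        must be used when the resulting AICc values are compared across
        models with different fixed effects.
        """
        if method not in ("reml", "ml"):
            raise ValueError(f"unknown method: {method}")
        reml = method == "reml"
        n = len(self.y)
        yvar = float(np.var(self.y)) or 1.0

        if self.error_model == "fixed_weights":
            # sigma^2 has a closed-form ML profile for V = sigma^2 * W
            W = np.diag(np.maximum(self.se_y, 1e-12) ** 2)
            L = np.linalg.cholesky(W)
            Xw = np.linalg.solve(L, self.X.to_numpy())
            yw = np.linalg.solve(L, self.y)
            beta = np.linalg.solve(Xw.T @ Xw, Xw.T @ yw)
            rss = float(np.sum((yw - Xw @ beta) ** 2))
            s2 = rss / (n - self.X.shape[1] if reml else n)
            beta, cov, llf = self._gls(self._V(s2), reml=reml)
            sigma2 = s2
        else:
            def neg_llf(log_s2: float) -> float:
                try:
                    return -self._gls(self._V(math.exp(log_s2)), reml=reml)[2]
                except np.linalg.LinAlgError:
                    return np.inf

            lo, hi = math.log(yvar) - 18.0, math.log(yvar) + 8.0
            opt = minimize_scalar(neg_llf, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            if not opt.success or not np.isfinite(opt.fun):
                raise ConvergenceError(f"sigma^2 profile failed: {opt.message}")
            sigma2 = math.exp(opt.x)
            beta, cov, llf = self._gls(self._V(sigma2), reml=reml)

        k = self.X.shape[1] + 1  # coefficients + sigma^2
        return PGLSResults(
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=self.names),
            sigma2=sigma2, llf=llf, nobs=n, k=k,
            cov_params=pd.DataFrame(cov, index=self.names, columns=self.names),
            model=self, method=method,
        )


# ---------------------------------------------------------------------------
# Collinearity screening


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors 1/(1 - R^2_j) for each non-intercept
    column regressed (with intercept) on the other non-intercept ones."""
    cols = [c for c in X.columns if c != "Intercept"]
    out = {}
    for col in cols:
        others = [c for c in cols if c != col]
        A = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in others])
        yj = X[col].to_numpy(float)
        beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_filter(X: pd.DataFrame, blocks: dict[str, list[str]],
               cutoff: float = 5.0) -> tuple[pd.DataFrame, dict[str, list[str]], list[dict]]:
    """Stepwise removal of the worst collinear predictor until all VIF
    values are at or below the cutoff.

    At each step the design column with the largest VIF above the
    cutoff is identified (ties broken by reverse column order, so the
    later column goes first) and its whole predictor block is removed.
    Returns (reduced X, reduced blocks, removal log).
    """
    X = X.copy()
    blocks = {k: list(v) for k, v in blocks.items()}
    log: list[dict] = []
    while True:
        cols = [c for c in X.columns if c != "Intercept"]
        if len(cols) < 2:
            break
        v = vif(X)
        over = v[v > cutoff]
        if over.empty:
            break
        worst_val = over.max()
        tied = [c for c in cols if np.isclose(v[c], worst_val) or
                (np.isinf(v[c]) and np.isinf(worst_val))]
        worst = tied[-1]  # reverse column order tie-break
        block = next(b for b, cs in blocks.items() if worst in cs)
        log.append({"removed": block, "columns": blocks[block],
                    "vif": float(worst_val) if np.isfinite(worst_val) else np.inf})
        X = X.drop(columns=blocks.pop(block))
    return X, blocks, log


# ---------------------------------------------------------------------------
# Candidate models and averaging


def candidate_designs(
    X: pd.DataFrame,
    blocks: dict[str, list[str]],
    n: int,
    min_samples_per_variable: int = 10,
    max_predictors: int = 20,
) -> list[tuple[tuple[str, ...], pd.DataFrame]]:
    """All nested submodels of the (VIF-filtered) global design.

    The intercept is always included; factor dummy blocks enter or
    leave whole. Subsets whose rows-per-predictor-column ratio falls
    below ``min_samples_per_variable`` are excluded.
    """
    names = list(blocks)
    if len(names) > max_predictors:
        raise ValueError(f"{len(names)} predictors exceeds the 2^{max_predictors} "
                         "enumeration cap")
    out = []
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            cols = ["Intercept"] + [c for b in subset for c in blocks[b]]
            ncols = len(cols) - 1
            if ncols and n / ncols < min_samples_per_variable:
                continue
            out.append((subset, X[cols]))
    if not out:
        raise ValueError("no admissible candidate models")
    return out


@dataclass
class AveragedResults:
    """Akaike-weighted model average over the retained candidate set."""

    candidates: pd.DataFrame  # one row per fitted candidate
    coefficients: pd.DataFrame  # term, estimate, se, ci_lower, ci_upper, significant
    retained: int
    averaging: str
    vif_log: list = field(default_factory=list)

    def significant_terms(self) -> list[str]:
        return self.coefficients.loc[self.coefficients["significant"], "term"].tolist()

    def summary(self) -> str:
        lines = [
            f"Model averaging: {self.retained} of {len(self.candidates)} candidates "
            f"within window ({self.averaging} averaging)",
        ]
        if self.vif_log:
            removed = ", ".join(e["removed"] for e in self.vif_log)
            lines.append(f"  VIF-removed predictors: {removed}")
        lines.append(f"  {'term':<28}{'coef':>12}{'se':>11}{'95% CI':>26}  sig")
        for _, row in self.coefficients.iterrows():
            mark = "*" if row["significant"] else ""
            lines.append(
                f"  {row['term']:<28}{row['estimate']:>12.4f}{row['se']:>11.4f}"
                f"    [{row['ci_lower']:>9.2f}, {row['ci_upper']:>9.2f}]  {mark}"
            )
        return "\n".join(lines)


def model_average(
    fits: list[tuple[tuple[str, ...], PGLSResults]],
    window: float = 2.0,
    averaging: str = "full",
) -> AveragedResults:
    """Average coefficients across candidates within ``window`` AICc of
    the best model.

    Akaike weights w_i are exp(-delta_i/2) renormalised over the
    retained set. ``full`` averaging substitutes zero (and zero SE) for
    a term absent from a candidate; ``conditional`` renormalises over
    the candidates containing the term. Unconditional SEs use the
    revised estimator sum_i w_i * sqrt(se_i^2 + (b_i - bbar)^2); 95% CI
    is estimate +/- 1.96 SE and a term is significant when its CI
    excludes zero.
    """
    if not fits:
        raise ValueError("no fitted candidates")
    rows = []
    for subset, res in fits:
        rows.append({"terms": "+".join(subset) or "(intercept)", "subset": subset,
                     "k": res.k, "logL": res.llf, "AICc": res.aicc})
    cand = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    cand["delta"] = cand["AICc"] - cand["AICc"].iloc[0]
    retained_mask = cand["delta"] <= window
    w = np.exp(-0.5 * cand.loc[retained_mask, "delta"].to_numpy())
    w /= w.sum()
    cand["weight"] = 0.0
    cand.loc[retained_mask, "weight"] = w

    by_subset = {subset: res for subset, res in fits}
    retained = [(tuple(cand.loc[i, "subset"]), by_subset[tuple(cand.loc[i, "subset"])],
                 cand.loc[i, "weight"]) for i in cand.index[retained_mask]]

    all_terms: list[str] = []
    for _, res, _ in retained:
        for t in res.params.index:
            if t not in all_terms:
                all_terms.append(t)

    out_rows = []
    for term in all_terms:
        bs, ses, ws = [], [], []
        for _, res, wt in retained:
            present = term in res.params.index
            bs.append(float(res.params[term]) if present else 0.0)
            ses.append(float(res.bse[term]) if present else 0.0)
            ws.append((wt, present))
        if averaging == "full":
            weights = np.array([wt for wt, _ in ws])
        elif averaging == "conditional":
            weights = np.array([wt if p else 0.0 for wt, p in ws])
            if weights.sum() == 0:
                continue
            weights = weights / weights.sum()
        else:
            raise ValueError(f"unknown averaging: {averaging}")
        b = np.asarray(bs)
        s = np.asarray(ses)
        est = float(np.sum(weights * b))
        se = float(np.sum(weights * np.sqrt(s**2 + (b - est) ** 2)))
        lo, hi = est - Z95 * se, est + Z95 * se
        out_rows.append({"term": term, "estimate": est, "se": se,
                         "ci_lower": lo, "ci_upper": hi,
                         "significant": bool(lo > 0 or hi < 0)})

    coef = pd.DataFrame(out_rows)
    cand_out = cand.drop(columns=["subset"])
    return AveragedResults(candidates=cand_out, coefficients=coef,
                           retained=int(retained_mask.sum()), averaging=averaging)


# ---------------------------------------------------------------------------
# High-level trait-model driver


def fit_trait_models(
    table: pd.DataFrame,
    corr: pd.DataFrame,
    variant: str,
    config: RunConfig | None = None,
    numeric: list[str] | None = None,
) -> AveragedResults:
    """Global PGLS -> VIF filter -> all-subsets AICc averaging for one
    analysis table (one season, variant A or B).

    The flocking factor uses treatment coding with "solo" as reference,
    so its coefficients read as shift-rate increments over solo
    migrants in metres/year.
    """
    from .traits import FACTOR_PREDICTORS, NUMERIC_PREDICTORS

    cfg = config or RunConfig()
    numeric = list(NUMERIC_PREDICTORS if numeric is None else numeric)
    factors = {c: ref for c, ref in
               (("migration_type", "partial"), ("migratory_timing", "day"))
               if c in table.columns and c in FACTOR_PREDICTORS}
    flock_col = "flocking_binary" if variant == "A" else "flocking_behaviour"
    factors[flock_col] = "solo"

    order = table["species"].tolist()
    C = corr.loc[order, order]
    X, blocks = build_design(table, numeric, factors)
    Xr, blocks_r, removal_log = vif_filter(X, blocks, cutoff=cfg.vif_cutoff)
    n = len(table)
    cands = candidate_designs(Xr, blocks_r, n,
                              min_samples_per_variable=cfg.min_samples_per_variable)
    y = table["displacement_m"].to_numpy(float)
    se_y = table["displacement_se_m"].to_numpy(float)
    fits = []
    for subset, Xc in cands:
        res = PGLS(y, Xc, C, se_y=se_y, error_model=cfg.pgls_error_model).fit(method="ml")
        fits.append((subset, res))
    avg = model_average(fits, window=cfg.aicc_window, averaging=cfg.averaging)
    avg.vif_log = removal_log
    return avg


def marginal_means(res: PGLSResults, blocks: dict[str, list[str]],
                   factor: str) -> pd.DataFrame:
    """Estimated marginal mean response per level of ``factor``.

    Numeric covariates sit at 0 (their Z-score mean); other factors are
    averaged over their levels with equal weight. SEs come from the
    coefficient covariance.
    """
    terms = res.params.index
    base = pd.Series(0.0, index=terms)
    base["Intercept"] = 1.0
    for blk, cols in blocks.items():
        if blk == factor or len(cols) == 1 and cols[0] == blk:
            continue
        n_levels = len(cols) + 1  # dummies + reference
        for c in cols:
            if c in base.index:
                base[c] = 1.0 / n_levels
    levels = ["(reference)"] + blocks.get(factor, [])
    rows = []
    for lv in levels:
        v = base.copy()
        if lv != "(reference)":
            v[lv] = 1.0
        est = float(v @ res.params)
        se = math.sqrt(float(v @ res.cov_params.to_numpy() @ v))
        label = lv if lv == "(reference)" else lv.split("[", 1)[1].rstrip("]")
        rows.append({"level": label, "mean": est, "se": se})
    return pd.DataFrame(rows)
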