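"""Per-analyte regression models with group-specific residual variances.

The differential model regresses each standardized analyte on subject-group
indicators (PD-CN/PD-MCI/PD-D vs controls, or a single all-PD indicator),
acute-levodopa indicators for non-demented and demented PD (cortex only),
and covariates (age, sex, education, BMI, four comorbidity flags, and the
logs of the post-mortem collection interval and freezer storage time).
Residual variances are allowed to differ between subject groups and are
estimated by iterative feasible generalized least squares (FGLS). The
progression model replaces the group/levodopa terms by a single score
regressor that is standardized over PD subjects and zero for controls, so
controls inform the covariates but not the score effect; its coefficient is
therefore two-way standardized (control SDs of the analyte per PD-SD of the
score).

False discovery rate control uses Storey q-values, run separately per
coefficient family and per (acquisition method x analyte type) stratum.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GROUPS, AnalyteTable, SampleMeta
from .preprocess import LevodopaStatus, ProcessedData

logger = logging.getLogger(__name__)

PD_GROUPS = ("PD-CN", "PD-MCI", "PD-D")

COVARIATES = ["age", "sexM", "education", "bmi", "hyperlipidemia", "diabetes",
              "renal_insufficiency", "hypothyroidism", "log_pmci", "log_storage"]


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Heteroscedastic linear model (iterative FGLS)
# ---------------------------------------------------------------------------

@dataclass
class HeteroFit:
    """Full fit of one model: coefficients, covariance, and diagnostics."""

    params: pd.Series
    cov: pd.DataFrame
    df_resid: int
    n: int
    group_variances: dict
    converged: bool
    n_iter: int
    df_coef: pd.Series | None = None  # per-coefficient Satterthwaite df

    def _df(self, name) -> float:
        if self.df_coef is not None and name in self.df_coef.index:
            return float(self.df_coef[name])
        return float(self.df_resid)

    def summary_rows(self, terms=None) -> list[dict]:
        rows = []
        for name in (terms if terms is not None else self.params.index):
            if name not in self.params.index:
                continue
            df = self._df(name)
            tcrit = stats.t.ppf(0.975, df)
            b = self.params[name]
            se = float(np.sqrt(self.cov.loc[name, name]))
            tval = b / se if se > 0 else np.inf
            p = float(2 * stats.t.sf(abs(tval), df))
            rows.append({
                "term": name, "beta": float(b), "se": se,
                "ci_low": float(b - tcrit * se), "ci_high": float(b + tcrit * se),
                "p": max(p, np.finfo(float).tiny),
                "n_effective": self.n, "converged": self.converged,
            })
        return rows

    def wald_joint(self, terms) -> tuple[float, float]:
        """Joint F-type Wald test that the named coefficients are all zero."""
        terms = [t for t in terms if t in self.params.index]
        b = self.params[terms].to_numpy()
        V = self.cov.loc[terms, terms].to_numpy()
        stat = float(b @ np.linalg.solve(V, b)) / len(terms)
        p = float(stats.f.sf(stat, len(terms), self.df_resid))
        return stat, p


def _check_rank(X: pd.DataFrame):
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise ModelError(f"design is rank deficient; collinear columns: {bad}")


def fit_hetero_lm(y, X: pd.DataFrame, variance_groups=None,
                  max_iter: int = 1, tol: float = 1e-8,
                  max_variance_ratio: float = 16.0,
                  df_method: str = "satterthwaite") -> HeteroFit:
    """Fit y = X b with per-group residual variances by feasible GLS.

    Rows with any missing value are dropped. Starting from OLS, per-group
    variances are estimated as RSS_g / (n_g - sum of leverages in g)
    (leverage-corrected, so the estimator is unbiased under
    homoscedasticity) and the weighted least squares problem is re-solved.
    The default ``max_iter=1`` is the classical two-step FGLS: one
    variance estimate from the OLS residuals, then one weighted solve.
    Larger ``max_iter`` iterates to convergence of the variances (relative
    change < ``tol``); because a group with barely more observations than
    the model has parameters can be interpolated by an upweighted fit
    (driving its variance estimate to zero), iterated variances are
    floored at pooled/``max_variance_ratio`` and the two-step default is
    the statistically safer choice at this study's group sizes.

    Inference: per-coefficient Wald t. ``df_method='satterthwaite'``
    (default) uses a Welch-Satterthwaite effective df built from the
    group-variance degrees of freedom, which matters for contrasts carried
    by small groups; ``'residual'`` uses n - p, ``'normal'`` the z
    approximation. With ``variance_groups=None`` the fit is exactly OLS
    with df = n - p.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    keep = y.notna() & X.notna().all(axis=1)
    y = y[keep]
    Xd = X.loc[keep]
    n, p = Xd.shape
    if n <= p:
        raise ModelError(f"too few complete rows ({n}) for {p} parameters")
    _check_rank(Xd)
    arr = Xd.to_numpy(dtype=float)
    yv = y.to_numpy()

    if variance_groups is None:
        beta, *_ = np.linalg.lstsq(arr, yv, rcond=None)
        resid = yv - arr @ beta
        sigma2 = float(resid @ resid) / (n - p)
        XtX_inv = np.linalg.inv(arr.T @ arr)
        cov = sigma2 * XtX_inv
        return HeteroFit(pd.Series(beta, index=Xd.columns),
                         pd.DataFrame(cov, index=Xd.columns, columns=Xd.columns),
                         n - p, n, {"pooled": sigma2}, True, 1)

    g = pd.Series(variance_groups, index=X.index)[keep]
    labels = g.unique()
    for lab in labels:
        if (g == lab).sum() < 2:
            raise ModelError(f"variance group {lab!r} has fewer than 2 samples")
    gidx = {lab: (g == lab).to_numpy() for lab in labels}

    w = np.ones(n)
    sigma2 = {lab: 1.0 for lab in labels}
    df_g = {lab: 1.0 for lab in labels}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Xw = arr * w[:, None]
        XtWX = arr.T @ Xw
        XtWX_inv = np.linalg.inv(XtWX)
        beta = XtWX_inv @ (Xw.T @ yv)
        resid = yv - arr @ beta
        hat = np.einsum("ij,jk,ik->i", arr, XtWX_inv, Xw)
        pooled = float(resid @ resid) / (n - p)
        floor = pooled / max_variance_ratio if max_variance_ratio else 0.0
        new_sigma2 = {}
        for lab in labels:
            m = gidx[lab]
            df_g[lab] = max(float(m.sum() - hat[m].sum()), 1.0)
            est = float((resid[m] ** 2).sum() / df_g[lab])
            new_sigma2[lab] = max(est, floor) if max_iter > 1 else est
        rel = max(abs(new_sigma2[lab] - sigma2[lab]) / max(sigma2[lab], 1e-300)
                  for lab in labels)
        sigma2 = new_sigma2
        for lab in labels:
            w[gidx[lab]] = 1.0 / max(sigma2[lab], 1e-300)
        if rel < tol:
            converged = True
            break
    converged = converged or max_iter == 1
    if not converged:
        logger.warning("fit_hetero_lm: no convergence after %d iterations", max_iter)
    Xw = arr * w[:, None]
    XtWX_inv = np.linalg.inv(arr.T @ Xw)
    beta = XtWX_inv @ (Xw.T @ yv)
    cov = XtWX_inv  # weights are inverse variance estimates

    df_coef = None
    if df_method == "satterthwaite":
        # b = U y with U = (X'WX)^-1 X'W; Var(b_j) = sum_g a_jg sigma2_g,
        # a_jg = sum_{i in g} U_ji^2; Welch-Satterthwaite combines the
        # group-variance degrees of freedom per coefficient.
        U = XtWX_inv @ Xw.T
        dfs = {}
        for j, name in enumerate(Xd.columns):
            a = {lab: float((U[j, gidx[lab]] ** 2).sum()) for lab in labels}
            num = sum(a[lab] * sigma2[lab] for lab in labels) ** 2
            den = sum((a[lab] * sigma2[lab]) ** 2 / df_g[lab] for lab in labels)
            dfs[name] = num / den if den > 0 else n - p
        df_coef = pd.Series(dfs)
    elif df_method == "normal":
        df_coef = pd.Series(np.inf, index=Xd.columns)
    elif df_method != "residual":
        raise ModelError(f"unknown df_method {df_method!r}")
    return HeteroFit(pd.Series(beta, index=Xd.columns),
                     pd.DataFrame(cov, index=Xd.columns, columns=Xd.columns),
                     n - p, n, sigma2, converged, it, df_coef)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _covariate_frame(sub: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=sub.index)
    X["age"] = sub["age"].astype(float)
    X["sexM"] = (sub["sex"] == "M").astype(float)
    X["education"] = sub["education"].astype(float)
    X["bmi"] = sub["bmi"].astype(float)
    for c in ("hyperlipidemia", "diabetes", "renal_insufficiency", "hypothyroidism"):
        X[c] = sub[c].astype(float)
    X["log_pmci"] = np.log(sub["pmci"].astype(float))
    X["log_storage"] = np.log(sub["storage"].astype(float))
    return X


def differential_design(sub: pd.DataFrame, lstatus: LevodopaStatus,
                        mode: str = "by_cognition") -> tuple[pd.DataFrame, pd.Series,
                                                             list[str]]:
    """Design matrix for the differential model on one region's subjects.

    Returns (X, variance-group labels, names of the effect terms). The
    levodopa-in-dementia interaction term exists only where demented
    subjects do (cortex); group indicators appear only for groups present.
    """
    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    terms = []
    present = set(sub["group"])
    if mode == "by_cognition":
        for grp in PD_GROUPS:
            if grp in present:
                name = f"g_{grp}"
                X[name] = (sub["group"] == grp).astype(float)
                terms.append(name)
    elif mode == "all_pd":
        X["g_PD"] = sub["group"].isin(PD_GROUPS).astype(float)
        terms.append("g_PD")
    else:
        raise ModelError(f"unknown mode {mode!r}")
    lp = lstatus.flags.reindex(sub.index).eq("L+").fillna(False)
    is_pdd = sub["group"] == "PD-D"
    is_pdnd = sub["group"].isin(("PD-CN", "PD-MCI"))
    if is_pdnd.any():
        X["lplus_PD-ND"] = (lp & is_pdnd).astype(float)
        terms.append("lplus_PD-ND")
    if is_pdd.any():
        X["lplus_PD-D"] = (lp & is_pdd).astype(float)
        terms.append("lplus_PD-D")
    X = pd.concat([X, _covariate_frame(sub)], axis=1)
    return X, sub["group"], terms


def progression_design(sub: pd.DataFrame, score) -> tuple[pd.DataFrame,
                                                          pd.Series, list[str]]:
    """Design for a progression model: covariates for everyone, a PD
    membership indicator, and PD-standardized score regressors (0 for
    controls), so controls inform the covariates but not the score effect.

    ``score`` may be a single name or a list fitted jointly (a combined
    model, e.g. a cognitive and a staging score side by side). PD subjects
    missing any requested score are dropped from this model only.
    """
    scores = [score] if isinstance(score, str) else list(score)
    is_pd = sub["group"].isin(PD_GROUPS)
    standardizers = {}
    for sc in scores:
        ok = sub.loc[is_pd, sc].astype(float).dropna()
        if len(ok) < 10:
            raise ModelError(f"score {sc}: fewer than 10 PD subjects with values")
        if ok.std(ddof=1) == 0:
            raise ModelError(f"score {sc}: constant among PD subjects")
        standardizers[sc] = (ok.mean(), ok.std(ddof=1))
    keep = ~is_pd | sub[scores].notna().all(axis=1)
    sub = sub[keep]
    is_pd = sub["group"].isin(PD_GROUPS)
    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    X["g_PD"] = is_pd.astype(float)
    terms = []
    for sc in scores:
        mean, sd = standardizers[sc]
        z = (sub[sc].astype(float) - mean) / sd
        X[f"score_{sc}"] = np.where(is_pd, z, 0.0)
        terms.append(f"score_{sc}")
    X = pd.concat([X, _covariate_frame(sub)], axis=1)
    return X, sub["group"], terms


# ---------------------------------------------------------------------------
# Runners
# ---------------------------------------------------------------------------

def run_differential(processed: ProcessedData, mode: str = "by_cognition",
                     equal_variances: bool = False) -> pd.DataFrame:
    """Fit the differential model for every retained analyte in every region."""
    out = []
    for region, pr in processed.regions.items():
        sub = processed.meta.subjects(region)
        sub = sub.loc[sub.index.intersection(pr.table.values.index)]
        X, vgroups, terms = differential_design(sub, processed.lstatus, mode)
        for m in pr.table.analyte_ids:
            y = pr.table.values.loc[sub.index, m]
            try:
                fit = fit_hetero_lm(y, X, None if equal_variances else vgroups)
            except ModelError as exc:
                logger.warning("differential %s/%s skipped: %s", region, m, exc)
                continue
            for row in fit.summary_rows(terms):
                row.update(analyte_id=m, region=region,
                           method=pr.table.annotations.loc[m, "method"],
                           analyte_type=pr.table.annotations.loc[m, "analyte_type"])
                out.append(row)
    if not out:
        raise ModelError("run_differential produced no fits")
    df = pd.DataFrame(out)
    return add_qvalues(df)


def run_progression(processed: ProcessedData, scores=None,
                    combined: bool = False,
                    equal_variances: bool = False) -> pd.DataFrame:
    """Fit progression-score models; coefficients are two-way standardized.

    By default one model per score; ``combined=True`` puts all requested
    scores into a single model (mutually adjusted score effects).
    """
    from .io_formats import SCORES
    scores = list(scores) if scores is not None else list(SCORES)
    specs = [scores] if combined else [[s] for s in scores]
    out = []
    for region, pr in processed.regions.items():
        sub = processed.meta.subjects(region)
        sub = sub.loc[sub.index.intersection(pr.table.values.index)]
        for spec in specs:
            try:
                X, vgroups, terms = progression_design(sub, spec)
            except ModelError as exc:
                logger.warning("progression %s/%s skipped: %s", region, spec, exc)
                continue
            for m in pr.table.analyte_ids:
                y = pr.table.values.loc[X.index, m]
                try:
                    fit = fit_hetero_lm(y, X,
                                        None if equal_variances else vgroups.loc[X.index])
                except ModelError as exc:
                    logger.warning("progression %s/%s/%s skipped: %s",
                                   region, spec, m, exc)
                    continue
                for row in fit.summary_rows(terms):
                    row.update(analyte_id=m, region=region,
                               method=pr.table.annotations.loc[m, "method"],
                               analyte_type=pr.table.annotations.loc[m, "analyte_type"])
                    out.append(row)
    if not out:
        raise ModelError("run_progression produced no fits")
    return add_qvalues(pd.DataFrame(out))


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_pi0(p, evaluate_at: float = 0.95, min_tests: int = 100) -> float:
    """Estimate the null proportion pi0 by smoothing pi0(lambda).

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over lambda = 0.05,
    0.10, ..., 0.95 is smoothed with a cubic least-squares fit and read off
    at lambda = 0.95, clipped into (0, 1]. Below ``min_tests`` p-values the
    estimate is fixed at 1 (the Benjamini-Hochberg limit): the tail count
    behind pi0(0.95) has sampling SD ~ sqrt(pi0/(0.05 m)), which at m = 30
    approaches 0.8 — far too noisy to support an FDR estimate, and prone
    to collapsing a whole stratum's q-values toward 0.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m < min_tests:
        return 1.0
    lam = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([(p > l).mean() / (1 - l) for l in lam])
    coef = np.polyfit(lam, pi0_l, 3)
    pi0 = float(np.polyval(coef, evaluate_at))
    return float(np.clip(pi0, np.finfo(float).tiny, 1.0))


def qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = min over {j : p_j >= p_i} of pi0 m p_j / rank_j.

    Monotone nondecreasing in p and invariant to input ordering; with
    ``pi0=1`` the result equals Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ModelError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def add_qvalues(df: pd.DataFrame,
                strata=("term", "method", "analyte_type")) -> pd.DataFrame:
    """Attach q-values, computed separately per coefficient family and per
    (acquisition method x analyte type) stratum."""
    df = df.copy()
    df["q"] = np.nan
    for _, idx in df.groupby(list(strata)).groups.items():
        df.loc[idx, "q"] = qvalues(df.loc[idx, "p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Collinearity
# ---------------------------------------------------------------------------

def collinearity_check(X: pd.DataFrame, terms: dict | None = None,
                       r_limit: float = 0.6, gvif_limit: float = 1.5) -> dict:
    """Pearson correlations and adjusted GVIFs of the design regressors.

    ``terms`` maps a term name to its design columns (a categorical factor
    contributes one term with several dummy columns); by default every
    column is its own term. GVIF for a term is det(R11) det(R22) / det(R)
    over the regressor correlation matrix (Fox-Monette), and the adjusted
    value GVIF^(1/(2 df)) is comparable across dfs. The pairwise Pearson
    screen covers the continuous regressors. Any |r| >= ``r_limit`` or
    adjusted GVIF >= ``gvif_limit`` is flagged; a duplicated column makes
    R singular and GVIF infinite.
    """
    cols = [c for c in X.columns if X[c].nunique() > 1]
    if terms is None:
        terms = {c: [c] for c in cols}
    else:
        terms = {t: [c for c in tc if c in cols] for t, tc in terms.items()}
        terms = {t: tc for t, tc in terms.items() if tc}
    Z = X[cols].astype(float)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    corr = pd.DataFrame(R, index=cols, columns=cols)
    detR = np.linalg.det(R)
    pos = {c: j for j, c in enumerate(cols)}
    rows = []
    for t, tcols in terms.items():
        own = [pos[c] for c in tcols]
        others = [j for j in range(len(cols)) if j not in own]
        det11 = np.linalg.det(R[np.ix_(own, own)]) if len(own) > 1 else 1.0
        det22 = np.linalg.det(R[np.ix_(others, others)]) if others else 1.0
        gvif = np.inf if detR <= 0 else float(det11 * det22 / detR)
        df = len(own)
        adj = gvif ** (1.0 / (2.0 * df)) if np.isfinite(gvif) else np.inf
        rows.append({"term": t, "df": df, "gvif": gvif, "adjusted_gvif": adj,
                     "flagged": not (adj < gvif_limit)})
    gvif_df = pd.DataFrame(rows).set_index("term")
    continuous = [c for c in cols if Z[c].nunique() > 2]
    pairs = []
    for a, b in itertools.combinations(continuous, 2):
        r = corr.loc[a, b]
        pairs.append({"a": a, "b": b, "r": float(r),
                      "flagged": not (abs(r) < r_limit)})
    pair_df = pd.DataFrame(pairs, columns=["a", "b", "r", "flagged"])
    return {"pearson": pair_df, "gvif": gvif_df,
            "ok": not (gvif_df["flagged"].any() or bool(pair_df["flagged"].any()))}


# ---------------------------------------------------------------------------
# Cohort characteristics
# ---------------------------------------------------------------------------

def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-tailed Fisher's exact test for a 2 x k table.

    k = 2 delegates to scipy; larger k uses the Freeman-Halton extension by
    exact enumeration over all tables with the observed margins, summing
    the probabilities of tables no more probable than the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2:
        raise ModelError("fisher_exact_2xk expects a 2 x k table")
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t)[1])
    col = t.sum(axis=0)
    n1 = int(t[0].sum())
    N = int(t.sum())
    from math import lgamma

    def lchoose(n, k):
        if k < 0 or k > n:
            return -np.inf
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    denom = lchoose(N, n1)

    def logprob(cells):
        return sum(lchoose(col[j], cells[j]) for j in range(len(col))) - denom

    obs = logprob(t[0])
    total = 0.0
    k = len(col)

    def rec(j, remaining, acc):
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                lp = acc + lchoose(col[j], remaining) - denom
                if lp <= obs + 1e-9:
                    total += np.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1:].sum()))
        hi = min(col[j], remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, acc + lchoose(col[j], a))

    rec(0, n1, 0.0)
    return float(min(total, 1.0))


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-tailed Welch's t-test (Welch-Satterthwaite df)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          equal_var=False, nan_policy="omit")
    return float(res.statistic), float(res.pvalue)


_CONTINUOUS = ["age", "education", "bmi", "pmci", "storage",
               "pd_duration", "updrs_m", "usslb", "mmse",
               "plaque_density", "tangle_density"]
_BINARY = ["sexM", "hyperlipidemia", "diabetes", "renal_insufficiency",
           "hypothyroidism"]


def _aov_hetero(values: pd.Series, groups: pd.Series) -> float:
    """Heteroscedastic one-way ANOVA p: Wald test on group terms in FGLS."""
    keep = values.notna()
    v, g = values[keep], groups[keep]
    labs = [lab for lab in g.unique() if (g == lab).sum() >= 2]
    if len(labs) < 2:
        return np.nan
    keep2 = g.isin(labs)
    v, g = v[keep2], g[keep2]
    X = pd.DataFrame({"const": 1.0}, index=v.index)
    terms = []
    for lab in labs[1:]:
        X[f"g_{lab}"] = (g == lab).astype(float)
        terms.append(f"g_{lab}")
    fit = fit_hetero_lm(v, X, g)
    return fit.wald_joint(terms)[1]


def cohort_table(meta: SampleMeta, region: str | None = None) -> pd.DataFrame:
    """Group-wise cohort characteristics with all-groups and PD-only tests.

    Continuous characteristics report mean (SD) per group and a
    heteroscedastic ANOVA p-value; binary ones report counts (%) and a
    two-tailed Fisher's exact p-value. Subjects are deduplicated across
    regions unless a single region is requested.
    """
    sub = meta.subjects(region)
    sub = sub.drop_duplicates(subset="subject_id")
    sub = sub.assign(sexM=(sub["sex"] == "M").astype(float))
    groups_present = [g for g in GROUPS if (sub["group"] == g).any()]
    pd_present = [g for g in groups_present if g != "CTRL"]
    rows = []
    for ch in _CONTINUOUS + _BINARY:
        if ch not in sub or sub[ch].dropna().empty:
            logger.info("cohort_table: %s entirely missing; omitted", ch)
            continue
        row = {"characteristic": ch}
        for g in groups_present:
            v = sub.loc[sub["group"] == g, ch].astype(float).dropna()
            if ch in _BINARY:
                row[g] = f"{int(v.sum())} ({100 * v.mean():.0f}%)" if len(v) else "-"
            else:
                row[g] = f"{v.mean():.1f} ({v.std(ddof=1):.1f})" if len(v) else "-"
        for label, gset in (("p_all", groups_present), ("p_pd", pd_present)):
            mask = sub["group"].isin(gset)
            v = sub.loc[mask, ch].astype(float)
            g = sub.loc[mask, "group"]
            if len(gset) < 2:
                row[label] = np.nan
            elif ch in _BINARY:
                keep = v.notna()
                tab = np.array([
                    [int(v[keep & (g == lab)].sum()) for lab in gset],
                    [int((1 - v[keep & (g == lab)]).sum()) for lab in gset]])
                row[label] = fisher_exact_2xk(tab) if tab.sum() else np.nan
            else:
                try:
                    row[label] = _aov_hetero(v, g)
                except ModelError:
                    row[label] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("characteristic")
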