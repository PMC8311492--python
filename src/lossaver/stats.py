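"""Statistical chain linking age, loss aversion and cortical thickness.

Covers the demographic covariate screens, the hierarchical linear-vs-
quadratic age regression with nested F test, per-ROI GLMs with
Holm-Bonferroni correction, the age-thinning fits, quasi-Bayesian causal
mediation (ACME/ADE with percentile intervals), and the descriptive
age-split correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "holm_bonferroni",
    "ScreenResult",
    "demographic_screen",
    "QuadraticAgeFit",
    "fit_quadratic_age",
    "roi_glms",
    "ThinningFit",
    "fit_thinning",
    "MediationResult",
    "mediate",
    "age_split_summary",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# multiple comparisons


def holm_bonferroni(pvals, alpha: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Bonferroni adjustment.

    Returns (adjusted p-values, reject flags at ``alpha``).  Adjusted values
    are monotone in the raw ordering and never smaller than the raw values.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj, adj <= alpha


# ---------------------------------------------------------------------------
# demographic screens


@dataclass
class ScreenResult:
    table: pd.DataFrame  # covariate, kind, stat, p, retained
    alpha: float

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table["retained"], "covariate"].tolist()


def _one_way_anova(y: np.ndarray, groups: np.ndarray) -> tuple[float, float, int, int]:
    levels = pd.unique(groups)
    samples = [y[groups == g] for g in levels]
    n, k = len(y), len(samples)
    grand = y.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    dfb, dfw = k - 1, n - k
    if ssb <= 1e-12 * max(1.0, ssw):
        return 0.0, 1.0, dfb, dfw
    if ssw <= 0:
        return np.inf, 0.0, dfb, dfw
    f = (ssb / dfb) / (ssw / dfw)
    return float(f), float(sps.f.sf(f, dfb, dfw)), dfb, dfw


def demographic_screen(
    data: pd.DataFrame,
    outcome: str = "lam",
    categorical: tuple[str, ...] = ("sex", "race_ethnicity", "smoking"),
    continuous: tuple[str, ...] = ("iq", "mother_education"),
    alpha: float = ALPHA,
) -> ScreenResult:
    """ANOVA (categorical) or Pearson correlation (continuous) screens of the
    outcome against each demographic covariate; covariates with p < alpha
    are retained for downstream models.

    Categories with fewer than 2 observations are dropped with a warning.
    """
    rows = []
    for cov in categorical:
        if cov not in data.columns:
            continue
        sub = data[[outcome, cov]].dropna()
        counts = sub[cov].value_counts()
        small = counts[counts < 2].index.tolist()
        if small:
            warnings.warn(f"{cov}: dropping categories with < 2 observations: {small}", stacklevel=2)
            sub = sub[~sub[cov].isin(small)]
        f, p, *_ = _one_way_anova(sub[outcome].to_numpy(), sub[cov].to_numpy())
        rows.append({"covariate": cov, "kind": "anova", "stat": f, "p": p})
    for cov in continuous:
        if cov not in data.columns:
            continue
        sub = data[[outcome, cov]].dropna()
        r, p = sps.pearsonr(sub[outcome], sub[cov])
        rows.append({"covariate": cov, "kind": "pearson", "stat": float(r), "p": float(p)})
    table = pd.DataFrame(rows)
    table["retained"] = table["p"] < alpha
    return ScreenResult(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# design-matrix helpers


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy(dtype=float)) == rank:
                raise ValueError(f"design matrix is rank deficient: column {col!r} is collinear")
        raise ValueError("design matrix is rank deficient")


def _covariate_frame(
    data: pd.DataFrame, covariates: tuple[str, ...], numeric_coding: bool
) -> pd.DataFrame:
    """Expand covariates; categoricals are dummy-coded unless numeric coding
    (reproduction mode) is requested."""
    parts = []
    for cov in covariates:
        col = data[cov]
        if numeric_coding or pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(cov))
        else:
            parts.append(pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=data.index)


def _ols(y: pd.Series, X: pd.DataFrame):
    X = sm.add_constant(X)
    _check_full_rank(X)
    return sm.OLS(y.astype(float), X.astype(float)).fit()


# ---------------------------------------------------------------------------
# quadratic age regression


@dataclass
class QuadraticAgeFit:
    beta_age: float
    beta_age2: float
    t_age: float
    t_age2: float
    p_age: float
    p_age2: float
    f_stat: float
    df_num: int
    df_den: int
    f_pvalue: float
    delta_r2: float
    vertex_age: float | None
    linear_result: object
    quadratic_result: object


def fit_quadratic_age(
    data: pd.DataFrame,
    outcome: str = "lam",
    age_col: str = "age",
    covariates: tuple[str, ...] = ("race_ethnicity",),
    reproduction_mode: bool = False,
) -> QuadraticAgeFit:
    """Hierarchical linear-then-quadratic regression of the outcome on age.

    Step 1 fits outcome ~ age + covariates, step 2 adds age^2; the nested
    F statistic (numerator df 1) compares them.  In default mode age is
    mean-centered before squaring and categorical covariates are
    dummy-coded; reproduction mode uses raw age and the study's numeric
    covariate coding.  The vertex (minimum of the fitted parabola) is
    reported on the raw-age scale.
    """
    sub = data[[outcome, age_col, *covariates]].dropna().reset_index(drop=True)
    n = len(sub)
    age_raw = sub[age_col].astype(float)
    center = 0.0 if reproduction_mode else float(age_raw.mean())
    age = age_raw - center

    cov = _covariate_frame(sub, covariates, numeric_coding=reproduction_mode)
    if n <= cov.shape[1] + 4:
        raise ValueError("too few observations for the quadratic age model")

    X1 = pd.concat([age.rename("age"), cov], axis=1)
    X2 = pd.concat([age.rename("age"), (age**2).rename("age2"), cov], axis=1)
    lin = _ols(sub[outcome], X1)
    quad = _ols(sub[outcome], X2)

    df_den = int(quad.df_resid)
    f = ((lin.ssr - quad.ssr) / 1.0) / (quad.ssr / df_den)
    f_p = float(sps.f.sf(f, 1, df_den))
    b1, b2 = float(quad.params["age"]), float(quad.params["age2"])
    vertex = None if b2 == 0 else center - b1 / (2.0 * b2)
    return QuadraticAgeFit(
        beta_age=b1,
        beta_age2=b2,
        t_age=float(quad.tvalues["age"]),
        t_age2=float(quad.tvalues["age2"]),
        p_age=float(quad.pvalues["age"]),
        p_age2=float(quad.pvalues["age2"]),
        f_stat=float(f),
        df_num=1,
        df_den=df_den,
        f_pvalue=f_p,
        delta_r2=float(quad.rsquared - lin.rsquared),
        vertex_age=vertex,
        linear_result=lin,
        quadratic_result=quad,
    )


# ---------------------------------------------------------------------------
# per-ROI GLMs


def roi_glms(
    data: pd.DataFrame,
    roi_cols: tuple[str, ...] = ("insula", "ofc", "acc", "pcc"),
    outcome: str = "lam",
    covariates: tuple[str, ...] = ("etiv",),
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-ROI GLM of the outcome on linear + quadratic thickness terms.

    Raw p-values of the linear and quadratic thickness terms are
    Holm-adjusted across the ROI family (separately per term).

    Raises
    ------
    ValueError
        With fewer than 2 ROIs or a constant thickness column.
    """
    if len(roi_cols) < 2:
        raise ValueError("roi_glms needs >= 2 ROIs to form a correction family")
    rows = []
    for roi in roi_cols:
        sub = data[[outcome, roi, *covariates]].dropna()
        th = sub[roi].astype(float)
        if th.nunique() < 2:
            raise ValueError(f"ROI {roi!r} thickness is constant")
        cov = _covariate_frame(sub, covariates, numeric_coding=False)
        X = pd.concat([th.rename("thickness"), (th**2).rename("thickness2"), cov], axis=1)
        res = _ols(sub[outcome], X)
        for term, label in (("thickness", "linear"), ("thickness2", "quadratic")):
            rows.append(
                {
                    "roi": roi,
                    "term": label,
                    "beta": float(res.params[term]),
                    "t": float(res.tvalues[term]),
                    "p_raw": float(res.pvalues[term]),
                }
            )
    table = pd.DataFrame(rows)
    table["p_holm"] = np.nan
    table["reject"] = False
    for label in ("linear", "quadratic"):
        mask = table["term"] == label
        adj, rej = holm_bonferroni(table.loc[mask, "p_raw"].to_numpy(), alpha=alpha)
        table.loc[mask, "p_holm"] = adj
        table.loc[mask, "reject"] = rej
    return table


# ---------------------------------------------------------------------------
# age-related thinning


@dataclass
class ThinningFit:
    roi: str
    slope: float
    t: float
    p: float
    quadratic_beta: float | None
    quadratic_t: float | None
    quadratic_p: float | None
    result: object


def fit_thinning(
    data: pd.DataFrame,
    roi_col: str = "pcc",
    age_col: str = "age",
    covariates: tuple[str, ...] = ("sex", "race_ethnicity", "etiv"),
    quadratic: bool = False,
    reproduction_mode: bool = False,
) -> ThinningFit:
    """Linear (optionally + quadratic) regression of ROI thickness on age
    with demographic and head-size covariates."""
    sub = data[[roi_col, age_col, *covariates]].dropna().reset_index(drop=True)
    age = sub[age_col].astype(float)
    cov = _covariate_frame(sub, covariates, numeric_coding=reproduction_mode)
    cols = [age.rename("age")]
    if quadratic:
        cols.append((age**2).rename("age2"))
    X = pd.concat(cols + [cov], axis=1)
    res = _ols(sub[roi_col], X)
    return ThinningFit(
        roi=roi_col,
        slope=float(res.params["age"]),
        t=float(res.tvalues["age"]),
        p=float(res.pvalues["age"]),
        quadratic_beta=float(res.params["age2"]) if quadratic else None,
        quadratic_t=float(res.tvalues["age2"]) if quadratic else None,
        quadratic_p=float(res.pvalues["age2"]) if quadratic else None,
        result=res,
    )


# ---------------------------------------------------------------------------
# quasi-Bayesian causal mediation


@dataclass
class MediationResult:
    acme: float
    acme_ci: tuple[float, float]
    acme_p: float
    ade: float
    ade_ci: tuple[float, float]
    ade_p: float
    total: float
    total_ci: tuple[float, float]
    total_p: float
    n_sims: int
    t0: float
    t1: float

    def to_dict(self) -> dict:
        return {
            "acme": self.acme,
            "acme_ci": list(self.acme_ci),
            "acme_p": self.acme_p,
            "ade": self.ade,
            "ade_ci": list(self.ade_ci),
            "ade_p": self.ade_p,
            "total": self.total,
            "total_ci": list(self.total_ci),
            "total_p": self.total_p,
            "n_sims": self.n_sims,
            "t0": self.t0,
            "t1": self.t1,
        }


def _sim_p(draws: np.ndarray) -> float:
    frac_le = (draws <= 0).mean()
    frac_ge = (draws >= 0).mean()
    return float(min(1.0, 2.0 * min(frac_le, frac_ge)))


def mediate(
    data: pd.DataFrame,
    outcome: str,
    mediator: str,
    treatment: str,
    covariates: tuple[str, ...] = (),
    n_sims: int = 1000,
    seed: int | None = None,
    t0: float | None = None,
    t1: float | None = None,
    mediator_squared: bool = True,
    ci: float = 0.95,
) -> MediationResult:
    """Quasi-Bayesian causal mediation for linear mediator/outcome models.

    Fits M ~ T + covariates and Y ~ T + M (+ M^2) + covariates by OLS, draws
    parameter vectors from their asymptotic normal sampling distributions,
    simulates potential mediator values at treatment levels t1/t0 (with
    mediator-model error draws), and forms the average causal mediation
    effect (ACME), average direct effect (ADE) and total effect per draw.
    Point estimates are draw means; intervals are 2.5/97.5 percentiles;
    p-values are 2 * min(frac <= 0, frac >= 0).

    Treatment levels default to the 25th/75th percentiles of the treatment.

    Raises
    ------
    ValueError
        If the treatment is constant, n_sims < 1000, or a model is singular.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    cols = [outcome, mediator, treatment, *covariates]
    sub = data[cols].dropna().reset_index(drop=True)
    tr = sub[treatment].astype(float)
    if tr.nunique() < 2:
        raise ValueError("treatment is constant")
    if t0 is None:
        t0 = float(tr.quantile(0.25))
    if t1 is None:
        t1 = float(tr.quantile(0.75))
    rng = np.random.default_rng(seed)

    cov = _covariate_frame(sub, covariates, numeric_coding=False)
    Xm = pd.concat([tr.rename("treat"), cov], axis=1)
    med = sub[mediator].astype(float)
    ycols = [tr.rename("treat"), med.rename("med")]
    if mediator_squared:
        ycols.append((med**2).rename("med2"))
    Xy = pd.concat(ycols + [cov], axis=1)

    try:
        mfit = _ols(med, Xm)
        yfit = _ols(sub[outcome], Xy)
    except ValueError as exc:
        raise ValueError(f"singular mediation model: {exc}") from exc

    bm = rng.multivariate_normal(mfit.params.to_numpy(), mfit.cov_params().to_numpy(), size=n_sims)
    by = rng.multivariate_normal(yfit.params.to_numpy(), yfit.cov_params().to_numpy(), size=n_sims)
    sigma_m = np.sqrt(mfit.scale)

    n = len(sub)
    covA = sm.add_constant(cov).to_numpy(dtype=float)  # const + covariates, (n, 1+q)
    m_names = list(sm.add_constant(Xm).columns)
    y_names = list(sm.add_constant(Xy).columns)
    it_m = m_names.index("treat")

    # mediator-model predictions: mu_M(t) = const + b_t * t + covariate part
    cov_idx_m = [m_names.index(c) for c in (["const"] + list(cov.columns))]
    base_m = bm[:, cov_idx_m] @ covA.T  # (J, n)
    mu_m1 = base_m + bm[:, [it_m]] * t1
    mu_m0 = base_m + bm[:, [it_m]] * t0
    m1 = mu_m1 + sigma_m * rng.standard_normal(size=mu_m1.shape)
    m0 = mu_m0 + sigma_m * rng.standard_normal(size=mu_m0.shape)

    cov_idx_y = [y_names.index(c) for c in (["const"] + list(cov.columns))]
    base_y = by[:, cov_idx_y] @ covA.T  # (J, n)
    bt = by[:, [y_names.index("treat")]]
    bmed = by[:, [y_names.index("med")]]
    bmed2 = by[:, [y_names.index("med2")]] if mediator_squared else 0.0

    def y_pred(t: float, m: np.ndarray) -> np.ndarray:
        out = base_y + bt * t + bmed * m
        if mediator_squared:
            out = out + bmed2 * m**2
        return out

    acme1 = (y_pred(t1, m1) - y_pred(t1, m0)).mean(axis=1)
    acme0 = (y_pred(t0, m1) - y_pred(t0, m0)).mean(axis=1)
    ade1 = (y_pred(t1, m1) - y_pred(t0, m1)).mean(axis=1)
    ade0 = (y_pred(t1, m0) - y_pred(t0, m0)).mean(axis=1)
    total = (y_pred(t1, m1) - y_pred(t0, m0)).mean(axis=1)
    acme = 0.5 * (acme1 + acme0)
    ade = 0.5 * (ade1 + ade0)

    lo, hi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2

    def summarize(draws: np.ndarray) -> tuple[float, tuple[float, float], float]:
        return (
            float(draws.mean()),
            (float(np.percentile(draws, lo)), float(np.percentile(draws, hi))),
            _sim_p(draws),
        )

    a, a_ci, a_p = summarize(acme)
    d, d_ci, d_p = summarize(ade)
    tt, t_ci, t_p = summarize(total)
    return MediationResult(
        acme=a, acme_ci=a_ci, acme_p=a_p,
        ade=d, ade_ci=d_ci, ade_p=d_p,
        total=tt, total_ci=t_ci, total_p=t_p,
        n_sims=n_sims, t0=t0, t1=t1,
    )


# ---------------------------------------------------------------------------
# descriptive age split


def age_split_summary(
    data: pd.DataFrame,
    outcome: str = "lam",
    roi_col: str = "pcc",
    age_col: str = "age",
    split_age: float = 35.0,
) -> dict:
    """Pearson correlation of the outcome with ROI thickness within age
    strata below/above ``split_age`` (the vertex of the age-outcome
    quadratic).  Groups smaller than 3 are flagged with the correlation
    omitted.

    Raises
    ------
    ValueError
        If either stratum is empty.
    """
    sub = data[[outcome, roi_col, age_col]].dropna()
    out = {"split_age": float(split_age)}
    groups = {
        "younger": sub[sub[age_col] < split_age],
        "older": sub[sub[age_col] >= split_age],
    }
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("both age strata must be non-empty")
    for name, g in groups.items():
        if len(g) < 3:
            out[name] = {"n": len(g), "r": None, "p": None, "flagged": True}
            continue
        r, p = sps.pearsonr(g[outcome], g[roi_col])
        out[name] = {"n": len(g), "r": float(r), "p": float(p), "flagged": False}
    return out
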