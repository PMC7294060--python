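"""Statistical layer: transforms, regressions, mediation, reliability.

All continuous variables are passed through the Yeo-Johnson power transform
(maximum-likelihood lambda) before modelling, to approximate normality.
Cross-sectional structure is tested with standardized simple regressions
under Bonferroni correction over the 10 network-measure combinations
(5 networks x 2 measures; the density sweep is not counted because
measures are strongly dependent across thresholds), followed -- where both
pairwise families are significant -- by a bootstrap mediation path model
(outcome ~ mediator + predictor).  Longitudinal data are summarized by a
linear mixed model with random intercept and slope, the one-way-ANOVA
intraclass correlation ICC(1,1), and per-subject across-visit variability
regressed on subject-level covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

N_COMPARISONS = 10  # 5 networks x 2 graph measures


class StatsError(ValueError):
    pass


# --------------------------------------------------------------------------
# Yeo-Johnson transform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformSpec:
    lmbda: float


def _yj_apply(x: np.ndarray, lmbda: float) -> np.ndarray:
    """The Yeo-Johnson transform at a fixed power parameter.

    x >= 0: ((x+1)^l - 1)/l, or log(x+1) at l = 0;
    x <  0: -(((-x+1)^(2-l) - 1)/(2-l)), or -log(-x+1) at l = 2.
    """
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lmbda) < 1e-12:
        out[pos] = np.log1p(x[pos])
    else:
        out[pos] = (np.power(x[pos] + 1.0, lmbda) - 1.0) / lmbda
    if abs(lmbda - 2.0) < 1e-12:
        out[~pos] = -np.log1p(-x[~pos])
    else:
        out[~pos] = -(np.power(-x[~pos] + 1.0, 2.0 - lmbda) - 1.0) / (2.0 - lmbda)
    return out


def yeo_johnson(x, lmbda: float | None = None, bounds: tuple = (-5.0, 5.0)):
    """Yeo-Johnson power transform.

    With ``lmbda=None`` the parameter is chosen by maximum likelihood under
    the normality objective, searched over ``bounds`` (default [-5, 5],
    tolerance 1e-6 on lambda).  Returns the transformed vector and the spec
    holding the lambda used.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise StatsError("input to yeo_johnson contains non-finite values")
    if lmbda is None:
        if np.ptp(x) == 0:
            # degenerate constant input: identity transform
            return x.copy(), TransformSpec(lmbda=1.0)
        n = len(x)
        jac = np.sign(x) * np.log1p(np.abs(x))  # log d/dx of the transform, summed below

        def neg_llf(l):
            z = _yj_apply(x, l)
            var = z.var()
            if not np.isfinite(var) or var <= 0:
                return np.inf
            return 0.5 * n * np.log(var) - (l - 1.0) * jac.sum()

        from scipy.optimize import minimize_scalar

        res = minimize_scalar(neg_llf, bounds=bounds, method="bounded", options={"xatol": 1e-6})
        lmbda = float(res.x)
    out = _yj_apply(x, float(lmbda))
    return out, TransformSpec(lmbda=float(lmbda))


def zscore(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("zero-variance input")
    return (x - x.mean()) / sd


# --------------------------------------------------------------------------
# Standardized simple regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    std_beta: float
    adj_r2: float
    p_raw: float
    p_bonferroni: float
    n_comparisons: int = N_COMPARISONS
    term: str = ""


def standardized_regression(y, x, n_comparisons: int = N_COMPARISONS) -> RegressionResult:
    """Slope of z-scored y on z-scored x (the Pearson r), with adjusted R^2,
    a two-sided p, and Bonferroni correction."""
    yz, xz = zscore(y), zscore(x)
    n = len(yz)
    if n < 3 or len(xz) != n:
        raise StatsError(f"need matched samples with n >= 3, got {len(xz)} and {n}")
    r, p = sps.pearsonr(xz, yz)
    r2 = r * r
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        std_beta=float(r),
        adj_r2=float(adj_r2),
        p_raw=float(p),
        p_bonferroni=min(1.0, n_comparisons * float(p)),
        n_comparisons=n_comparisons,
    )


# --------------------------------------------------------------------------
# Bootstrap mediation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MediationResult:
    """Standardized path estimates with percentile-bootstrap inference.

    a: mediator ~ predictor; b and direct c' from outcome ~ mediator +
    predictor; indirect = a*b; total = a*b + c' (= the simple outcome ~
    predictor slope on standardized data).
    """

    path_a: float
    path_b: float
    direct: float
    indirect: float
    total: float
    p_boot: dict = field(default_factory=dict)
    p_normal: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    n_degenerate_redraws: int = 0


def _paths_from_corr(r_xm, r_ym, r_xy):
    denom = 1.0 - r_xm**2
    degenerate = np.abs(denom) < 1e-12
    safe = np.where(degenerate, 1.0, denom)
    a = r_xm
    b = np.where(degenerate, r_ym, (r_ym - r_xy * r_xm) / safe)
    # with a perfectly collinear mediator the whole effect is carried by it
    direct = np.where(degenerate, r_xy - a * b, (r_xy - r_ym * r_xm) / safe)
    return a, b, direct, a * b, r_xy


def _pairwise_corrs(X, M, Y):
    def corr(u, v):
        uc = u - u.mean(axis=-1, keepdims=True)
        vc = v - v.mean(axis=-1, keepdims=True)
        num = (uc * vc).sum(axis=-1)
        den = np.sqrt((uc**2).sum(axis=-1) * (vc**2).sum(axis=-1))
        return num / den

    return corr(X, M), corr(M, Y), corr(X, Y)


def mediation_bootstrap(x, m, y, n_boot: int = 50_000, seed: int | None = None) -> MediationResult:
    """Mediation path model with subject-resampling bootstrap.

    Point estimates are OLS on standardized variables (pure correlation
    algebra for one predictor and one mediator).  The bootstrap resamples
    subjects with replacement; each path is re-estimated on the resample's
    own standardization.  Two-sided percentile p-values
    ``2 * min(Pr*(theta <= 0), Pr*(theta >= 0))`` and percentile CIs are
    reported per path, alongside normal-approximation p-values.
    """
    x, m, y = (np.asarray(v, dtype=float) for v in (x, m, y))
    n = len(x)
    if n < 10 or len(m) != n or len(y) != n:
        raise StatsError("mediation needs matched complete cases with n >= 10")
    r_xm, r_my, r_xy = _pairwise_corrs(x, m, y)
    a, b, direct, indirect, total = _paths_from_corr(r_xm, r_my, r_xy)

    rng = np.random.default_rng(seed)
    n_redraws = 0
    paths = {}
    if n_boot > 0:
        # chunk to bound memory at large n_boot
        chunks = []
        remaining = n_boot
        while remaining > 0:
            B = min(remaining, 20_000)
            idx = rng.integers(0, n, size=(B, n))
            Xb, Mb, Yb = x[idx], m[idx], y[idx]
            # redraw degenerate resamples (zero variance in any variable)
            for _ in range(100):
                bad = (
                    (Xb.std(axis=1) == 0) | (Mb.std(axis=1) == 0) | (Yb.std(axis=1) == 0)
                )
                if not bad.any():
                    break
                n_redraws += int(bad.sum())
                idx_new = rng.integers(0, n, size=(int(bad.sum()), n))
                Xb[bad], Mb[bad], Yb[bad] = x[idx_new], m[idx_new], y[idx_new]
            rxm, rmy, rxy = _pairwise_corrs(Xb, Mb, Yb)
            chunks.append(np.column_stack(_paths_from_corr(rxm, rmy, rxy)))
            remaining -= B
        boot = np.vstack(chunks)  # columns: a, b, direct, indirect, total
        names = ("a", "b", "direct", "indirect", "total")
        p_boot, p_normal, ci = {}, {}, {}
        for col, name in enumerate(names):
            theta = boot[:, col]
            theta = theta[np.isfinite(theta)]
            p_boot[name] = float(
                min(1.0, 2.0 * min(np.mean(theta <= 0), np.mean(theta >= 0)))
            )
            sd = theta.std(ddof=1)
            est = (a, b, direct, indirect, total)[col]
            p_normal[name] = float(2.0 * sps.norm.sf(abs(est) / sd)) if sd > 0 else 1.0
            lo, hi = np.percentile(theta, [2.5, 97.5])
            ci[name] = (float(lo), float(hi))
        paths = dict(p_boot=p_boot, p_normal=p_normal, ci=ci)
    return MediationResult(
        path_a=float(a),
        path_b=float(b),
        direct=float(direct),
        indirect=float(indirect),
        total=float(total),
        n_boot=n_boot,
        seed=seed,
        n_degenerate_redraws=n_redraws,
        **paths,
    )


# --------------------------------------------------------------------------
# ICC(1,1): one-way random-effects ANOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_between: float
    ms_within: float
    k0: float
    n_subjects: int


def icc_oneway(values: pd.DataFrame, subject_col: str = "subject_id", value_col: str = "value") -> ICCResult:
    """ICC(1,1) from a one-way ANOVA decomposition of a long table.

    The ICC is the ratio of between-subject variance to total variance.
    Unbalanced designs use the effective replicate count
    ``k0 = (N - sum(k_i^2)/N) / (n - 1)``.  The 95% CI follows from the
    F-distribution of MS_between/MS_within.  Subjects with a single visit
    carry no within-subject information and are excluded with a warning.
    """
    df = values[[subject_col, value_col]].dropna()
    counts = df.groupby(subject_col, sort=False)[value_col].count()
    singles = counts.index[counts < 2]
    if len(singles):
        warnings.warn(
            f"excluding {len(singles)} subject(s) with a single visit from ICC",
            RuntimeWarning,
            stacklevel=2,
        )
        df = df[~df[subject_col].isin(singles)]
    groups = df.groupby(subject_col, sort=False)[value_col]
    n = groups.ngroups
    if n < 2:
        raise StatsError("ICC needs at least 2 subjects with >= 2 visits")
    k_i = groups.count().to_numpy(float)
    N = k_i.sum()
    grand = df[value_col].mean()
    means = groups.mean().to_numpy(float)
    ss_b = float((k_i * (means - grand) ** 2).sum())
    ss_w = float(((df[value_col] - groups.transform("mean")) ** 2).sum())
    df_b, df_w = n - 1, N - n
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    k0 = (N - (k_i**2).sum() / N) / (n - 1)
    if ms_w == 0:
        icc, ci = 1.0, (1.0, 1.0)
    else:
        icc = (ms_b - ms_w) / (ms_b + (k0 - 1) * ms_w)
        F = ms_b / ms_w
        fl = F / sps.f.ppf(0.975, df_b, df_w)
        fu = F * sps.f.ppf(0.975, df_w, df_b)
        ci = ((fl - 1) / (fl + k0 - 1), (fu - 1) / (fu + k0 - 1))
    return ICCResult(
        icc=float(icc),
        ci_low=float(min(ci)),
        ci_high=float(min(1.0, max(ci))),
        ms_between=float(ms_b),
        ms_within=float(ms_w),
        k0=float(k0),
        n_subjects=int(n),
    )


# --------------------------------------------------------------------------
# Longitudinal mixed-model trend
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LongitudinalFit:
    beta_time: float
    se_time: float
    p_time: float
    variance_components: dict
    method: str
    random_slope: bool
    converged: bool


def fit_longitudinal_trend(
    values: pd.DataFrame,
    subject_col: str = "subject_id",
    time_col: str = "time",
    value_col: str = "value",
) -> LongitudinalFit:
    """Linear mixed model ``y = b0 + b1*time + u0_i + u1_i*time + eps``.

    Time is measured from each analysis's baseline (days).  Inference on
    the fixed slope uses a Wald t statistic with between-within degrees of
    freedom (n_subjects - 2), recorded in the output; a singular
    random-slope fit falls back to a random-intercept-only model, flagged
    via ``random_slope``.
    """
    import statsmodels.formula.api as smf

    df = values[[subject_col, time_col, value_col]].dropna().copy()
    df.columns = ["subj", "time", "y"]
    n_subj = df["subj"].nunique()
    if n_subj < 3:
        raise StatsError("mixed model needs at least 3 subjects")
    # rescale time to [0, 1] internally: slope variances in raw days are
    # tiny and make the REML optimization badly conditioned
    scale = float(df["time"].abs().max()) or 1.0
    df["time"] = df["time"] / scale

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ time", df, groups=df["subj"], re_formula=re_formula)
            return model.fit(reml=True)

    random_slope = True
    try:
        res = _fit("~time")
        singular = (
            not res.converged
            or not np.all(np.isfinite(res.bse_fe))
            or np.any(np.diag(res.cov_re) < 1e-10)
        )
    except Exception:
        singular = True
        res = None
    if singular or res is None:
        random_slope = False
        res = _fit("~1")

    beta = float(res.fe_params["time"]) / scale
    se = float(res.bse_fe["time"]) / scale
    dof = n_subj - 2
    t = beta / se if se > 0 else np.inf
    p = float(2.0 * sps.t.sf(abs(t), dof))
    vc = {"random_intercept": float(res.cov_re.iloc[0, 0]), "residual": float(res.scale)}
    if random_slope and res.cov_re.shape[0] > 1:
        vc["random_slope"] = float(res.cov_re.iloc[1, 1]) / scale**2
    return LongitudinalFit(
        beta_time=beta,
        se_time=se,
        p_time=p,
        variance_components=vc,
        method=f"wald-t, between-within df={dof}",
        random_slope=random_slope,
        converged=bool(res.converged),
    )


# --------------------------------------------------------------------------
# Across-visit variability
# --------------------------------------------------------------------------

def visit_variability(
    values: pd.DataFrame,
    subject_col: str = "subject_id",
    value_col: str = "value",
    min_visits: int = 3,
) -> pd.DataFrame:
    """Per-subject sample SD and coefficient of variation across visits.

    Subjects with fewer than ``min_visits`` visits are excluded (the serial
    analysis requires at least three time points)."""
    grouped = values.groupby(subject_col, sort=False)[value_col]
    out = grouped.agg(n_visits="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    excluded = out.loc[out["n_visits"] < min_visits, subject_col].tolist()
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} subject(s) with < {min_visits} visits: {excluded}",
            RuntimeWarning,
            stacklevel=2,
        )
    out = out[out["n_visits"] >= min_visits].copy()
    out["cv"] = out["sd"] / out["mean"]
    return out


#: Canonical explanatory variables for the variability regression.
VARIABILITY_COVARIATES = (
    "age",
    "sex",
    "mean_fd",
    "fw",
    "brain_volume",
    "wmh_volume",
    "hypertension",
    "diabetes",
    "hypercholesterolemia",
    "smoking",
)
BINARY_COVARIATES = {"sex", "hypertension", "diabetes", "hypercholesterolemia", "smoking"}


def variability_regression(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_names=VARIABILITY_COVARIATES,
    n_comparisons: int = N_COMPARISONS,
) -> dict[str, RegressionResult]:
    """Regress per-subject across-visit SDs on the subject covariates.

    One multiple regression per outcome including all explanatory variables
    simultaneously; the SD outcome and the continuous covariates are
    Yeo-Johnson transformed, everything is z-scored so coefficients are
    standardized, and each covariate's p is Bonferroni corrected with
    n = 10 (the 5 networks x 2 measures over which each variable is tested).
    """
    import statsmodels.api as sm

    merged = records.merge(covariates, on="subject_id", how="inner")
    if merged["sd"].std(ddof=1) == 0:
        raise StatsError("across-visit SD outcome has zero variance")
    y, _ = yeo_johnson(merged["sd"].to_numpy())
    y = zscore(y)
    cols = {}
    for name in covariate_names:
        v = merged[name].to_numpy(float)
        if name not in BINARY_COVARIATES:
            v, _ = yeo_johnson(v)
        cols[name] = zscore(v)
    X = pd.DataFrame(cols)
    corr = X.corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    worst = np.argmax(np.abs(corr[iu]))
    if np.abs(corr[iu][worst]) > 0.999:
        pair = (X.columns[iu[0][worst]], X.columns[iu[1][worst]])
        raise StatsError(f"collinear covariates: {pair}")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    out = {}
    for name in covariate_names:
        p = float(fit.pvalues[name])
        out[name] = RegressionResult(
            std_beta=float(fit.params[name]),
            adj_r2=float(fit.rsquared_adj),
            p_raw=p,
            p_bonferroni=min(1.0, n_comparisons * p),
            n_comparisons=n_comparisons,
            term=name,
        )
    return out
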