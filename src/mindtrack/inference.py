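"""Statistical models linking pattern expression to thoughts of loss.

The central model is a mixed-effects logistic regression of the per-block
yes/no loss-thought report on the full factorial of block-wise d-MR
expression, d-SA expression and subject avoidance (IES-A), with a subject
random intercept — the avoidance-moderated interaction hypothesis is the
three-way term.  Supporting analyses: a covariate-adjusted refit, high/low
avoidance median-split subgroup models, a mask-mean-BOLD specificity
control, a subject-level multiple linear regression for the continuous
SART, and clinical correlations.

The random-intercept logistic likelihood is maximized by Gauss-Hermite
quadrature over the random effect (analytic gradient, numerical Hessian for
Wald inference).  Predictors are standardized across the pooled analysis
table so coefficients and odds ratios are per one standard deviation of the
predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm, pearsonr
from statsmodels.tools.numdiff import approx_hess1

from .exceptions import DataError, DesignError, InsufficientDataError

_FACTORIAL_TERMS = ["mr", "sa", "av", "mr:sa", "mr:av", "sa:av", "mr:sa:av"]


@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect row: log-odds (or linear) coefficient per 1 s.d."""
    term: str
    b: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class ModelResult:
    effects: list[EffectEstimate]
    random_intercept_var: float
    n_blocks: int
    n_subjects: int
    converged: bool
    loglik: float = np.nan

    def __getitem__(self, term: str) -> EffectEstimate:
        for e in self.effects:
            if e.term == term:
                return e
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"term": e.term, "B": e.b, "se": e.se,
                              "OR": e.or_value, "ci95_low": e.ci_low,
                              "ci95_high": e.ci_high, "p": e.p}
                             for e in self.effects])


def coef_to_or(b: float) -> float:
    """Odds ratio for a one-s.d. change in the predictor: exp(B)."""
    if not np.isfinite(b):
        raise DataError("coefficient must be finite")
    return float(np.exp(b))


# --------------------------------------------------------------------------
# analysis-table preparation
# --------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def standardize_predictors(blocks: pd.DataFrame,
                           subjects: pd.DataFrame) -> pd.DataFrame:
    """Join block records to the clinical table, drop error blocks, and
    z-score d-MR, d-SA and avoidance across the analysis sample."""
    if "avoidance" not in subjects.columns or subjects["avoidance"].isna().any():
        raise DataError("avoidance (IES-A) missing from the clinical table")
    tab = blocks[~blocks["error"].astype(bool)].copy()
    subjects = subjects.reset_index(drop=True)
    clin_cols = [c for c in ("avoidance", "age", "months_since_loss", "cesd",
                             "loss_type", "medication", "education_years")
                 if c in subjects.columns]
    tab = tab.merge(subjects[["subject_id"] + clin_cols], on="subject_id",
                    how="left", validate="many_to_one")
    if tab["avoidance"].isna().any():
        raise DataError("blocks reference subjects missing from clinical table")
    tab["avoidance_raw"] = tab["avoidance"]
    for col, out in (("mr", "mr"), ("sa", "sa"), ("avoidance", "av")):
        tab[out] = _zscore(tab[col].to_numpy(dtype=float))
    tab["y"] = tab["probe_deceased"].astype(int)
    return tab


# --------------------------------------------------------------------------
# random-intercept logistic via Gauss-Hermite quadrature
# --------------------------------------------------------------------------

def _group_index(ids) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd.factorize(ids)
    order = np.argsort(codes, kind="stable")
    return codes, order


def _gh_nll_grad(params, X, y, codes, z_nodes, log_w):
    """Negative marginal log-likelihood and analytic gradient.

    params = (beta..., log_sigma); random intercepts integrated with
    Gauss-Hermite nodes z_k (already sorted groups assumed).
    """
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    eta0 = X @ beta
    a = eta0[:, None] + np.sqrt(2.0) * sigma * z_nodes[None, :]   # (n, K)
    ll_obs = y[:, None] * a - np.logaddexp(0.0, a)                # (n, K)
    n_groups = codes.max() + 1
    starts = np.searchsorted(codes, np.arange(n_groups))
    S = np.add.reduceat(ll_obs, starts, axis=0)                   # (G, K)
    M = log_w[None, :] + S
    m_max = M.max(axis=1, keepdims=True)
    lse = m_max[:, 0] + np.log(np.exp(M - m_max).sum(axis=1))
    nll = -lse.sum()

    C = np.exp(M - lse[:, None])                                  # (G, K) softmax
    U = C[codes]                                                  # (n, K)
    R = y[:, None] - expit(a)                                     # (n, K)
    wr = (U * R)
    grad_beta = -(X.T @ wr.sum(axis=1))
    grad_lsig = -np.sum(wr * (np.sqrt(2.0) * sigma * z_nodes[None, :]))
    return nll, np.concatenate([grad_beta, [grad_lsig]])


def fit_random_intercept_logit(X: np.ndarray, y: np.ndarray, group_ids,
                               term_names: list[str], n_quad: int = 40
                               ) -> ModelResult:
    """Maximum marginal likelihood for a random-intercept logistic model.

    ``X`` must include an intercept column; ``term_names`` labels the
    non-intercept columns in order.  Wald standard errors come from the
    numerical Hessian at the optimum.  Non-convergence is flagged on the
    result rather than raised.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise DataError("outcome is constant")
    codes, order = _group_index(group_ids)
    X, y, codes = X[order], y[order], codes[order]
    counts = np.bincount(codes)
    if (counts >= 2).sum() < 2:
        raise InsufficientDataError("need >= 2 subjects with >= 2 blocks")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("fixed-effects design is rank deficient")

    z_nodes, w_nodes = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(w_nodes) - 0.5 * np.log(np.pi)

    # plain-logistic start values
    from statsmodels.api import GLM, families
    start_beta = GLM(y, X, family=families.Binomial()).fit().params
    x0 = np.concatenate([start_beta, [np.log(0.5)]])

    res = optimize.minimize(
        _gh_nll_grad, x0, args=(X, y, codes, z_nodes, log_w),
        jac=True, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})

    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    hess = approx_hess1(res.x, lambda p: _gh_nll_grad(
        p, X, y, codes, z_nodes, log_w)[0])
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(res.x.size, np.nan)
    converged = bool(res.success) and np.isfinite(se_all[:-1]).all()
    if not converged:
        warnings.warn("mixed logistic fit did not fully converge; "
                      "result flagged")

    effects = []
    names = ["intercept"] + list(term_names)
    for i, name in enumerate(names):
        b, se = float(beta[i]), float(se_all[i])
        ci = (b - 1.96 * se, b + 1.96 * se)
        p = 2 * norm.sf(abs(b) / se) if se > 0 else np.nan
        effects.append(EffectEstimate(term=name, b=b, se=se,
                                      or_value=coef_to_or(b),
                                      ci_low=ci[0], ci_high=ci[1], p=float(p)))
    return ModelResult(effects=effects, random_intercept_var=sigma ** 2,
                       n_blocks=int(y.size), n_subjects=int(counts.size),
                       converged=converged, loglik=float(-res.fun))


def _design_from_terms(tab: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(tab))]
    for t in terms:
        parts = t.split(":")
        col = np.ones(len(tab))
        for p in parts:
            col = col * tab[p].to_numpy(dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def fit_three_way_mixed_logit(tab: pd.DataFrame, n_quad: int = 40) -> ModelResult:
    """Full factorial of d-MR, d-SA and avoidance with a random intercept.

    ``tab`` is the standardized analysis table (error blocks already
    dropped); the hypothesis term is ``mr:sa:av``.
    """
    X = _design_from_terms(tab, _FACTORIAL_TERMS)
    return fit_random_intercept_logit(X, tab["y"].to_numpy(),
                                      tab["subject_id"], _FACTORIAL_TERMS,
                                      n_quad=n_quad)


DEFAULT_COVARIATES = ("age", "loss_type", "months_since_loss", "cesd")


def fit_adjusted_model(tab: pd.DataFrame,
                       covariates=DEFAULT_COVARIATES,
                       n_quad: int = 40) -> ModelResult:
    """Factorial model with clinical covariate main effects added.

    Continuous covariates are standardized; loss type is coded suicide = 1.
    """
    tab = tab.copy()
    cov_terms = []
    for cov in covariates:
        name = f"cov_{cov}"
        if cov == "loss_type":
            tab[name] = (tab[cov] == "suicide").astype(float)
        elif cov == "medication":
            tab[name] = tab[cov].astype(float)
        else:
            x = tab[cov].to_numpy(dtype=float)
            tab[name] = _zscore(x) if x.std() > 0 else x
        cov_terms.append(name)
    terms = _FACTORIAL_TERMS + cov_terms
    X = _design_from_terms(tab, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("covariates are collinear with the design")
    return fit_random_intercept_logit(X, tab["y"].to_numpy(),
                                      tab["subject_id"], terms, n_quad=n_quad)


def median_split_models(tab: pd.DataFrame, n_quad: int = 40
                        ) -> tuple[ModelResult, ModelResult]:
    """High/low avoidance subgroup models with terms {mr, sa, mr:sa}.

    Subjects at or above the median raw avoidance form the high group.
    """
    subj = tab.groupby("subject_id")["avoidance_raw"].first()
    if subj.size < 4:
        raise InsufficientDataError("median split requires >= 4 subjects")
    if subj.nunique() == 1:
        raise DesignError("avoidance is constant; split is degenerate")
    med = subj.median()
    high_ids = subj.index[subj >= med]
    low_ids = subj.index[subj < med]
    results = []
    for ids in (high_ids, low_ids):
        if ids.size < 2:
            raise DesignError("a median-split group has < 2 subjects")
        sub = tab[tab["subject_id"].isin(ids)]
        terms = ["mr", "sa", "mr:sa"]
        X = _design_from_terms(sub, terms)
        results.append(fit_random_intercept_logit(
            X, sub["y"].to_numpy(), sub["subject_id"], terms, n_quad=n_quad))
    return results[0], results[1]


# --------------------------------------------------------------------------
# specificity control: mask-mean BOLD instead of pattern expression
# --------------------------------------------------------------------------

def specificity_control(cohort, dsa_mask, dmr_mask,
                        n_quad: int = 40) -> ModelResult:
    """Refit the three-way model with mask-mean BOLD in place of patterns.

    Replaces each pattern expression by the average standardized BOLD over
    its feature mask (a uniform-weight pattern), block-averaged over the
    identical delayed windows, and refits the factorial model.  A specific
    pattern effect should not survive this substitution.
    """
    from . import designgen as dg
    from .decode import (apply_pattern, block_average, clean_standardize,
                         winsorize_iqr)
    from .mvpa import PatternModel

    def mean_model(mask3d):
        n = int(mask3d.sum())
        return PatternModel(w=np.full(n, 1.0 / n), mask=mask3d, family="mean",
                            regularization=0.0, cv_scheme="none",
                            performance=np.nan)

    dsa_m = mean_model(getattr(dsa_mask, "mask", dsa_mask))
    dmr_m = mean_model(getattr(dmr_mask, "mask", dmr_mask))
    tabs = []
    for s in cohort.subjects:
        bold, motion = s.probes_run
        schedule = dg.TrSchedule(tr=bold.tr, n_volumes=bold.n_volumes)
        clean = clean_standardize(bold, motion)
        out = s.probes_blocks[["subject_id", "block", "probe_deceased",
                               "error"]].copy()
        out["sa"] = block_average(apply_pattern(dsa_m, clean), s.probes_design,
                                  schedule)
        out["mr"] = block_average(apply_pattern(dmr_m, clean), s.probes_design,
                                  schedule)
        tabs.append(out)
    blocks = pd.concat(tabs, ignore_index=True)
    for name in ("sa", "mr"):
        blocks[name], _ = winsorize_iqr(blocks[name].to_numpy())
    tab = standardize_predictors(blocks, cohort.clinical)
    return fit_three_way_mixed_logit(tab, n_quad=n_quad)


# --------------------------------------------------------------------------
# continuous-SART subject-level regression and clinical correlations
# --------------------------------------------------------------------------

def fit_sart_linear(table: pd.DataFrame) -> pd.DataFrame:
    """OLS of post-task loss-thought reports on mean d-MR, d-SA and IES-A.

    One row per subject (columns ``report``, ``mr``, ``sa``, ``avoidance``).
    Returns the coefficient table with each predictor's squared semi-partial
    correlation (the increment in R-squared when that predictor is added
    last).
    """
    import statsmodels.api as sm
    if len(table) < 5:
        raise InsufficientDataError("need >= 5 subjects")
    predictors = ["mr", "sa", "avoidance"]
    X = sm.add_constant(table[predictors].astype(float))
    if np.linalg.cond(X.to_numpy()) > 1e8:
        warnings.warn("predictors are near-collinear (high condition number)")
    fit = sm.OLS(table["report"].astype(float), X).fit()
    rows = []
    for name in predictors:
        reduced = sm.OLS(table["report"].astype(float),
                         X.drop(columns=[name])).fit()
        rows.append({"term": name, "B": fit.params[name],
                     "se": fit.bse[name], "t": fit.tvalues[name],
                     "p": fit.pvalues[name],
                     "ci95_low": fit.conf_int().loc[name, 0],
                     "ci95_high": fit.conf_int().loc[name, 1],
                     "semipartial_r2": max(0.0, fit.rsquared - reduced.rsquared)})
    out = pd.DataFrame(rows)
    out.attrs["r2"] = fit.rsquared
    return out


CLINICAL_CORRELATES = ["age", "months_since_loss", "cesd", "avoidance",
                       "education_years", "medication", "errors"]


def loss_thought_rate(blocks: pd.DataFrame) -> pd.Series:
    """Per-subject proportion of error-free blocks reporting thoughts of loss."""
    ok = blocks[~blocks["error"].astype(bool)]
    return ok.groupby("subject_id")["probe_deceased"].mean()


def clinical_correlations(subjects: pd.DataFrame,
                          blocks: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of the loss-thought rate with clinical variables."""
    if subjects["subject_id"].nunique() < 4:
        raise InsufficientDataError("need >= 4 subjects")
    rate = loss_thought_rate(blocks).rename("loss_rate")
    tab = subjects.set_index("subject_id", drop=False) if \
        subjects.index.name != "subject_id" else subjects
    tab = tab.join(rate, how="inner")
    tab["errors"] = blocks.groupby("subject_id")["error"].sum()
    tab["medication"] = tab["medication"].astype(float)
    rows = []
    for var in CLINICAL_CORRELATES:
        if var not in tab.columns:
            continue
        x = tab[var].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(tab["loss_rate"]) == 0:
            warnings.warn(f"zero variance for {var}; correlation omitted")
            rows.append({"variable": var, "r": np.nan, "p": np.nan})
            continue
        r, p = pearsonr(x, tab["loss_rate"])
        rows.append({"variable": var, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
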