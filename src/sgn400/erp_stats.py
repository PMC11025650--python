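"""Single-trial N400 regression: baseline-covaried linear mixed models with
crossed random effects, nested model comparison, and FDR correction.

Model.  For trial (subject s, word w):

    n400 = b0 + b_base*baseline + sum_j b_j x_j + u_s + sum_k c_{k,s} x_k
           + v_w + eps,

with independent Gaussian random terms: by-subject intercepts ``u_s``,
by-subject slopes ``c_{k,s}`` for the requested predictors of interest,
by-word intercepts ``v_w``, and residual ``eps``.  The baseline (mean EEG
amplitude in the 100 ms before word onset) is a fixed covariate of no
interest rather than being subtracted from the response.  Fitting is
maximum likelihood (not REML) so that likelihood-ratio tests and AIC
between models differing in fixed effects are valid.

The estimator profiles out the fixed effects and the residual variance:
writing V = I + sum_j lam2_j Z_j Z_j', the deviance as a function of the
variance ratios lam2 alone is

    n log(2 pi sigma^2(lam2)) + log|V(lam2)| + n,

evaluated through the Cholesky factor of the q x q system
M = I_q + Lam Z'Z Lam (Woodbury), so each evaluation costs O(q^3) with
q = n_subjects + n_words + slopes — independent of the trial count after a
one-time computation of Z'Z, Z'X, Z'y.  A Nelder-Mead search over
log(lam2) finishes the fit.  statsmodels' MixedLM (variance-components
formulation, ML) serves as the independent oracle for this solver in the
test suite; it agrees to numerical tolerance but is orders of magnitude
slower at the simulation sizes used here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("sgn400")

_TINY = 1e-300


@dataclass
class FixedEffect:
    beta: float
    se: float
    t: float
    p: float
    df: float = np.inf     # Satterthwaite df; inf = normal approximation

    @property
    def ci95(self) -> tuple[float, float]:
        mult = stats.t.ppf(0.975, self.df) if np.isfinite(self.df) \
            else 1.959963984540054
        return (self.beta - mult * self.se, self.beta + mult * self.se)


@dataclass
class MixedModelResult:
    fixed: dict[str, FixedEffect]
    llf: float
    aic: float
    n_params: int
    n_obs: int
    sigma2: float
    re_var: dict[str, float]      # variance components on the response scale
    converged: bool
    fallback: str | None
    meta: dict = field(default_factory=dict)

    @property
    def fixed_names(self) -> tuple[str, ...]:
        return tuple(self.fixed)


@dataclass
class ComparisonResult:
    chi2: float
    df: int
    p: float
    delta_aic: float              # AIC(smaller) - AIC(larger); > 0 favors larger


# ---------------------------------------------------------------------------
# Trial assembly
# ---------------------------------------------------------------------------

def assemble_trials(
    erp: pd.DataFrame,
    predictors: pd.DataFrame,
    standardize: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Join an ERP table (subject, word, n400, baseline) with per-word
    model predictors (word, su[, surprisal, internal_update]).

    The SU column is multiplied by -1 before any standardization (the N400
    is a negative deflection).  Predictor and baseline columns are z-scored
    by default so coefficient magnitudes are comparable; scaling constants
    land in the metadata.  Rows whose word has no predictor entry are
    dropped with a logged count.
    """
    pred_cols = [c for c in ("su", "surprisal", "internal_update")
                 if c in predictors.columns]
    merged = erp.merge(predictors[["word"] + pred_cols], on="word", how="left")
    missing = merged[pred_cols].isna().any(axis=1)
    n_dropped = int(missing.sum())
    if n_dropped:
        logger.info("assemble_trials: dropped %d unmatched rows", n_dropped)
    trials = merged.loc[~missing].reset_index(drop=True).copy()
    if trials.empty:
        raise ValueError("no ERP rows matched the predictor table")
    if "su" in trials:
        trials["su"] = -trials["su"]
    meta = {"n_dropped": n_dropped, "standardized": standardize, "scaling": {}}
    if standardize:
        for col in pred_cols + ["baseline"]:
            mu, sd = float(trials[col].mean()), float(trials[col].std(ddof=0))
            if sd > 0:
                trials[col] = (trials[col] - mu) / sd
            meta["scaling"][col] = {"mean": mu, "sd": sd}
    return trials, meta


# ---------------------------------------------------------------------------
# Mixed-model fit
# ---------------------------------------------------------------------------

def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _gls_components(eta, blocks, XtX, Xty, yty, ZtZ, ZtX, Zty):
    """GLS pieces for variance ratios exp(eta): log|V|, the residual
    quadratic form, the GLS coefficients, and the X'V^-1X factor."""
    lam = np.exp(0.5 * np.clip(eta, -30.0, 20.0))
    s = np.concatenate([np.full(sz, lam[j]) for j, sz in enumerate(blocks)])
    q = s.size
    M = np.eye(q) + (s[:, None] * ZtZ) * s[None, :]
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return None
    U1 = solve_triangular(L, s[:, None] * ZtX, lower=True)
    u2 = solve_triangular(L, s * Zty, lower=True)
    XtVX = XtX - U1.T @ U1
    XtVy = Xty - U1.T @ u2
    ytVy = yty - u2 @ u2
    try:
        cf = cho_factor(XtVX)
    except np.linalg.LinAlgError:
        return None
    beta = cho_solve(cf, XtVy)
    rss = max(ytVy - beta @ XtVy, _TINY)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return {"beta": beta, "rss": rss, "logdet": logdet, "XtVX": XtVX, "cf": cf}


def _profiled_deviance(eta, blocks, XtX, Xty, yty, ZtZ, ZtX, Zty, n):
    comp = _gls_components(eta, blocks, XtX, Xty, yty, ZtZ, ZtX, Zty)
    if comp is None:
        return np.inf, None
    sigma2 = comp["rss"] / n
    dev = n * np.log(2.0 * np.pi * sigma2) + comp["logdet"] + n
    return dev, (comp["beta"], sigma2, comp["XtVX"], comp["cf"])


def _satterthwaite_df(eta_hat, log_s2_hat, blocks, XtX, Xty, yty,
                      ZtZ, ZtX, Zty, n, p_fixed):
    """Satterthwaite degrees of freedom for each fixed effect.

    df_i = 2 c_i^2 / (g_i' A g_i) with c_i the squared SE of effect i as a
    function of the variance parameters phi = (log variance ratios,
    log sigma^2), g_i its gradient, and A the asymptotic covariance of
    phi (twice the inverse Hessian of the -2 log-likelihood).  Both
    derivative objects are obtained by central finite differences.
    """
    phi_hat = np.append(eta_hat, log_s2_hat)
    m = phi_hat.size

    def dev_full(phi):
        comp = _gls_components(phi[:-1], blocks, XtX, Xty, yty, ZtZ, ZtX, Zty)
        if comp is None:
            return np.nan
        s2 = np.exp(phi[-1])
        return n * np.log(2.0 * np.pi * s2) + comp["logdet"] + comp["rss"] / s2

    def se2_vec(phi):
        comp = _gls_components(phi[:-1], blocks, XtX, Xty, yty, ZtZ, ZtX, Zty)
        if comp is None:
            return np.full(p_fixed, np.nan)
        inv = cho_solve(comp["cf"], np.eye(p_fixed))
        return np.exp(phi[-1]) * np.diag(inv)

    h = 1e-4 * np.maximum(1.0, np.abs(phi_hat))
    H = np.zeros((m, m))
    f0 = dev_full(phi_hat)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            if i == j:
                val = (dev_full(phi_hat + ei) - 2 * f0
                       + dev_full(phi_hat - ei)) / h[i] ** 2
            else:
                val = (dev_full(phi_hat + ei + ej) - dev_full(phi_hat + ei - ej)
                       - dev_full(phi_hat - ei + ej)
                       + dev_full(phi_hat - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    if not np.isfinite(H).all():
        return np.full(p_fixed, np.inf)
    A = 2.0 * np.linalg.pinv(H)

    grads = np.zeros((p_fixed, m))
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        grads[:, i] = (se2_vec(phi_hat + ei) - se2_vec(phi_hat - ei)) / (2 * h[i])
    c = se2_vec(phi_hat)
    df = np.full(p_fixed, np.inf)
    for k in range(p_fixed):
        denom = grads[k] @ A @ grads[k]
        if np.isfinite(denom) and denom > 0:
            df[k] = max(2.0 * c[k] ** 2 / denom, 1.0)
    return df


def fit_mixed_model(
    trials: pd.DataFrame,
    fixed: Sequence[str] = ("su",),
    random_slopes: Sequence[str] = ("su",),
    response: str = "n400",
    include_baseline: bool = True,
    _allow_fallback: bool = True,
) -> MixedModelResult:
    """ML fit of the crossed mixed model.

    ``fixed`` are the predictors of interest (the intercept and, by
    default, the baseline covariate are always included); ``random_slopes``
    (a subset of ``fixed``) get independent by-subject slopes.  On an
    optimizer failure the fallback ladder drops slopes, then fits
    intercepts only, recording which rung was used.
    """
    subj, s_levels = pd.factorize(trials["subject"], sort=True)
    word, w_levels = pd.factorize(trials["word"], sort=True)
    S, W = len(s_levels), len(w_levels)
    if S < 2 or W < 2:
        raise ValueError("need at least 2 subjects and 2 words")
    # Slopes usually sit on predictors of interest, but a slope without the
    # fixed effect is allowed so nested fixed-effect comparisons can hold
    # the random structure constant.
    bad = set(random_slopes) - set(trials.columns)
    if bad:
        raise ValueError(f"random-slope columns not in table: {sorted(bad)}")

    cols = (["baseline"] if include_baseline else []) + list(fixed)
    for c in cols:
        if trials[c].std(ddof=0) == 0:
            raise ValueError(f"predictor column {c!r} is constant across trials")
    X = np.column_stack([np.ones(len(trials))] +
                        [trials[c].to_numpy(float) for c in cols])
    names = ["intercept"] + cols
    y = trials[response].to_numpy(float)
    n = y.size

    Zs = [_indicator(subj, S), _indicator(word, W)]
    block_names = ["subject", "word"]
    for sl in random_slopes:
        Zs.append(_indicator(subj, S) * trials[sl].to_numpy(float)[:, None])
        block_names.append(f"subject_slope:{sl}")
    Z = np.concatenate(Zs, axis=1)
    blocks = [z.shape[1] for z in Zs]

    ZtZ, ZtX, Zty = Z.T @ Z, Z.T @ X, Z.T @ y
    XtX, Xty, yty = X.T @ X, X.T @ y, y @ y

    def obj(eta):
        return _profiled_deviance(eta, blocks, XtX, Xty, yty, ZtZ, ZtX, Zty, n)[0]

    x0 = np.full(len(blocks), np.log(0.5))
    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9,
                                     "maxiter": 2000, "maxfev": 4000})
    dev, sol = _profiled_deviance(res.x, blocks, XtX, Xty, yty,
                                  ZtZ, ZtX, Zty, n)
    if sol is None:
        if _allow_fallback and random_slopes:
            out = fit_mixed_model(trials, fixed, (), response, include_baseline,
                                  _allow_fallback=True)
            out.fallback = "dropped-random-slopes"
            return out
        raise np.linalg.LinAlgError("mixed-model fit failed")
    beta, sigma2, XtVX, cf = sol
    cov = sigma2 * cho_solve(cf, np.eye(XtVX.shape[0]))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    df_method = "satterthwaite"
    try:
        dfs = _satterthwaite_df(res.x, np.log(sigma2), blocks, XtX, Xty, yty,
                                ZtZ, ZtX, Zty, n, X.shape[1])
    except (np.linalg.LinAlgError, FloatingPointError):
        dfs = np.full(X.shape[1], np.inf)
    if not np.isfinite(dfs).any():
        df_method = "normal-approximation"
    with np.errstate(invalid="ignore"):
        pvals = np.where(np.isfinite(dfs),
                         2.0 * stats.t.sf(np.abs(tvals), np.maximum(dfs, 1.0)),
                         2.0 * stats.norm.sf(np.abs(tvals)))
    lam2 = np.exp(np.clip(res.x, -30.0, 20.0))
    llf = -0.5 * dev
    k = X.shape[1] + len(blocks) + 1
    return MixedModelResult(
        fixed={nm: FixedEffect(float(b), float(s_), float(t_), float(p_),
                               float(d_))
               for nm, b, s_, t_, p_, d_ in zip(names, beta, se, tvals,
                                                pvals, dfs)},
        llf=float(llf),
        aic=float(2 * k - 2 * llf),
        n_params=k,
        n_obs=n,
        sigma2=float(sigma2),
        re_var={nm: float(sigma2 * l2) for nm, l2 in zip(block_names, lam2)},
        converged=bool(res.success),
        fallback=None,
        meta={"df_method": df_method, "estimation": "ML",
              "response": response, "optimizer_nfev": int(res.nfev)},
    )


def compare_models(m0: MixedModelResult, m1: MixedModelResult) -> ComparisonResult:
    """Likelihood-ratio test and AIC difference between nested ML fits.

    ``m0`` must be nested in ``m1`` (same rows, fixed effects a subset);
    chi2 = 2(llf1 - llf0) clipped at zero, df = parameter-count difference,
    delta AIC = AIC0 - AIC1 (positive favors the larger model).
    """
    if m0.n_obs != m1.n_obs:
        raise ValueError("models were fit on different row counts")
    if not set(m0.fixed_names) <= set(m1.fixed_names) or m0.n_params >= m1.n_params:
        raise ValueError("m0 is not nested in m1")
    chi2 = max(0.0, 2.0 * (m1.llf - m0.llf))
    df = m1.n_params - m0.n_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return ComparisonResult(chi2=float(chi2), df=df, p=p,
                            delta_aic=float(m0.aic - m1.aic))


def fdr_correct(pvalues: Sequence[float], alpha: float = 0.05
                ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# statsmodels oracle (used by the test suite as an independent cross-check)
# ---------------------------------------------------------------------------

def fit_mixed_model_statsmodels(
    trials: pd.DataFrame,
    fixed: Sequence[str] = ("su",),
    random_slopes: Sequence[str] = ("su",),
    response: str = "n400",
    include_baseline: bool = True,
):
    """Same model through statsmodels MixedLM (ML, variance components with
    a single grouping).  Slow; intended for validation on small datasets."""
    import statsmodels.formula.api as smf

    cols = (["baseline"] if include_baseline else []) + list(fixed)
    formula = f"{response} ~ " + " + ".join(cols)
    vc = {"subject": "0 + C(subject)", "word": "0 + C(word)"}
    for sl in random_slopes:
        vc[f"slope_{sl}"] = f"0 + C(subject):{sl}"
    df = trials.copy()
    df["_g"] = 1
    model = smf.mixedlm(formula, df, groups="_g", vc_formula=vc)
    return model.fit(reml=False, method="bfgs", maxiter=1000, disp=False)
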