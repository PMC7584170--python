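"""Obesity EWAS models, cross-tissue mixed model, interaction scan and
reference-based cell-composition deconvolution.

Three regression surfaces share one design-specification object:

* single-tissue OLS per probe (methylation ~ obesity + covariates), the
  replication-group model, with estimated blood cell fractions entering the
  blood design;
* a linear mixed model per probe across both tissues
  (methylation ~ tissue + age + batch + obesity + (1 | individual)); for the
  balanced complete-pair design this is fitted in closed form via the
  pair-mean / pair-difference decomposition, which reproduces the REML fit
  and gives the exact Satterthwaite degrees of freedom
  (n_individuals - p_between) for individual-level coefficients;
* an interaction scan per probe (blood ~ sperm * obesity + age + batch) with
  a leave-one-out diagnostic on the interaction t statistic, since such
  interactions tend to be driven by individual outliers.

Cell composition is estimated from a cell-type reference profile matrix by
non-negative least squares with a projection onto the simplex {x >= 0,
sum x <= 1} (a documented simplification of the constrained quadratic
program used in reference-based deconvolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .paired import EPIC_ALPHA

__all__ = [
    "DesignSpec",
    "build_design_matrix",
    "encode_binary",
    "cell_fraction_covariates",
    "estimate_cell_composition",
    "ewas_single_tissue",
    "ewas_mixed",
    "interaction_scan",
    "prior_probe_enrichment",
    "effect_concordance",
]


@dataclass
class DesignSpec:
    """Design variables for the per-probe regressions.

    ``covariates`` holds one row per sample (or per individual for the mixed
    model), ``predictor`` names the coefficient of interest (obesity
    indicator coded lean = 0, or continuous BMI), ``categorical`` lists
    columns to dummy-code (reference level dropped), ``random_intercept``
    names the grouping column for mixed models.
    """

    covariates: pd.DataFrame
    predictor: str = "obesity"
    categorical: tuple[str, ...] = ("batch",)
    random_intercept: str | None = None

    def __post_init__(self):
        if self.predictor not in self.covariates.columns:
            raise ValueError(f"predictor {self.predictor!r} not in covariates")


def encode_binary(series: pd.Series, reference: str) -> pd.Series:
    """0/1-code a two-level factor with ``reference`` as 0."""
    levels = set(series.unique())
    if reference not in levels or len(levels) > 2:
        raise ValueError(f"cannot binary-code levels {sorted(map(str, levels))} "
                         f"with reference {reference!r}")
    return (series != reference).astype(float)


def cell_fraction_covariates(fractions: pd.DataFrame,
                             drop: str | None = None) -> pd.DataFrame:
    """Cell fractions as model covariates, dropping one column.

    Fractions sum to ~1 per sample, so one column (default: the largest-mean
    cell type) is dropped to avoid collinearity with the intercept.
    """
    drop = drop or fractions.mean().idxmax()
    return fractions.drop(columns=[drop])


def build_design_matrix(design: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix; raises on rank deficiency.

    The error names columns whose removal would restore full rank.
    """
    cov = design.covariates
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cov))}
    ordered = [design.predictor] + [c for c in cov.columns
                                    if c != design.predictor
                                    and c != design.random_intercept]
    for name in ordered:
        col = cov[name]
        if name in design.categorical or col.dtype == object or isinstance(
                col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), prefix=name,
                                     drop_first=True)
            for dname in dummies.columns:
                cols[dname] = dummies[dname].to_numpy(dtype=float)
        else:
            cols[name] = col.to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offenders = []
        for j, name in enumerate(names):
            if name == "intercept":
                continue
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                offenders.append(name)
        raise ValueError(f"collinear design; offending columns: {offenders}")
    return X, names


def _ols_multi(Y: np.ndarray, X: np.ndarray, j: int):
    """OLS of every row of Y on X; returns stats for coefficient ``j``.

    Y is probes x samples, X samples x p.  Returns (effect, se, t, p, df)
    arrays plus the residual matrix and full coefficient matrix.
    """
    n, p = X.shape
    Ainv = np.linalg.inv(X.T @ X)
    B = Y @ X @ Ainv                      # probes x p
    resid = Y - B @ X.T
    df = n - p
    rss = (resid ** 2).sum(axis=1)
    sigma2 = rss / df
    se = np.sqrt(sigma2 * Ainv[j, j])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = B[:, j] / se
    pval = 2 * stats.t.sf(np.abs(t), df)
    pval = np.where(se == 0, np.where(B[:, j] == 0, 1.0, 0.0), pval)
    return B[:, j], se, t, pval, df, resid, B


def ewas_single_tissue(
    beta: pd.DataFrame,
    design: DesignSpec,
    alpha: float = EPIC_ALPHA,
) -> pd.DataFrame:
    """OLS per probe of methylation on the design; effect = predictor slope.

    ``design.covariates`` rows must align with the columns of ``beta``
    (positionally or by index).
    """
    cov = design.covariates
    if list(cov.index) != list(beta.columns):
        if set(cov.index) >= set(beta.columns):
            design = DesignSpec(cov.loc[list(beta.columns)], design.predictor,
                                design.categorical, design.random_intercept)
        elif len(cov) != beta.shape[1]:
            raise ValueError("covariate rows do not match beta columns")
    X, names = build_design_matrix(design)
    j = names.index(design.predictor)
    Y = beta.to_numpy(dtype=float)
    effect, se, t, p, df, _, _ = _ols_multi(Y, X, j)
    return pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "t": t,
            "df": df,
            "p": p,
            "significant": p < alpha,
            "model": "ols_single",
        },
        index=beta.index,
    )


def ewas_mixed(
    beta_blood: pd.DataFrame,
    beta_sperm: pd.DataFrame | None,
    design: DesignSpec,
    alpha: float = EPIC_ALPHA,
    method: str = "auto",
) -> pd.DataFrame:
    """Random-intercept-per-individual mixed model across the two tissues.

    ``design.covariates`` has one row per individual (columns aligned with
    the matched columns of both matrices); the tissue main effect is implicit
    in the paired structure.  For the balanced complete-pair design
    (``method="auto"`` or ``"paired"``), the model is fitted via the
    pair-mean / pair-difference decomposition: individual-level coefficients
    come from OLS of pair means (exact REML fixed effects), with Satterthwaite
    df = n_individuals - p_between; variance components sigma2 (residual) and
    tau2 (random intercept) are recovered from the two strata.  With
    ``beta_sperm=None`` the model collapses to single-tissue OLS.
    ``method="mixedlm"`` fits statsmodels MixedLM per probe instead
    (normal-approximation p, ``converged`` flag).
    """
    if beta_sperm is None:
        out = ewas_single_tissue(beta_blood, design, alpha)
        out["model"] = "lmm_collapsed_ols"
        return out
    common = beta_blood.index.intersection(beta_sperm.index)
    B = beta_blood.loc[common].to_numpy(dtype=float)
    S = beta_sperm.loc[common].to_numpy(dtype=float)
    if B.shape[1] != S.shape[1] or B.shape[1] != len(design.covariates):
        raise ValueError("blood/sperm columns and covariate rows must pair up")

    if method == "mixedlm":
        return _ewas_mixedlm(common, B, S, design, alpha)

    X, names = build_design_matrix(design)
    j = names.index(design.predictor)
    n = X.shape[0]
    M = (B + S) / 2.0
    D = S - B
    effect, se, t, p, df, resid_m, _ = _ols_multi(M, X, j)
    s2_mean = (resid_m ** 2).sum(axis=1) / df
    d_resid = D - D.mean(axis=1, keepdims=True)
    var_d = (d_resid ** 2).sum(axis=1) / (n - 1)
    sigma2 = var_d / 2.0
    tau2 = np.maximum(s2_mean - sigma2 / 2.0, 0.0)
    d_mean = D.mean(axis=1)
    d_se = np.sqrt(var_d / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_t = d_mean / d_se
    tissue_p = 2 * stats.t.sf(np.abs(d_t), n - 1)
    return pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "df": df,
            "t": t,
            "p": p,
            "significant": p < alpha,
            "tissue_effect": d_mean,
            "tissue_p": tissue_p,
            "tau2": tau2,
            "sigma2": sigma2,
            "converged": True,
            "model": "lmm_paired_reml",
        },
        index=common,
    )


def _ewas_mixedlm(common, B, S, design: DesignSpec, alpha: float) -> pd.DataFrame:
    """Per-probe statsmodels MixedLM fallback (unbalanced-safe)."""
    import statsmodels.api as sm
    import warnings as _warnings

    X, names = build_design_matrix(design)
    j = names.index(design.predictor)
    n = X.shape[0]
    Xl = np.vstack([np.hstack([X, np.zeros((n, 1))]),
                    np.hstack([X, np.ones((n, 1))])])
    names_l = names + ["tissue"]
    groups = np.concatenate([np.arange(n), np.arange(n)])
    rows = []
    for i in range(len(common)):
        y = np.concatenate([B[i], S[i]])
        conv = True
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                res = sm.MixedLM(y, Xl, groups=groups).fit(reml=True)
            eff, se = res.fe_params[j], res.bse_fe[j]
            z = eff / se
            p = 2 * stats.norm.sf(abs(z))
            tau2 = float(np.asarray(res.cov_re)[0, 0])
            sig2 = float(res.scale)
            conv = bool(res.converged)
        except Exception:
            eff = se = z = p = tau2 = sig2 = np.nan
            conv = False
        rows.append((eff, se, np.nan, z, p, conv and p < alpha, np.nan,
                     np.nan, tau2, sig2, conv, "lmm_mixedlm_normal"))
    return pd.DataFrame(
        rows,
        columns=["effect", "se", "df", "t", "p", "significant",
                 "tissue_effect", "tissue_p", "tau2", "sigma2", "converged",
                 "model"],
        index=common,
    )


def interaction_scan(
    beta_blood: pd.DataFrame,
    beta_sperm: pd.DataFrame,
    covariates: pd.DataFrame,
    predictor: str = "obesity",
    categorical: tuple[str, ...] = ("batch",),
    alpha: float = EPIC_ALPHA,
    loo_diagnostic: bool = True,
) -> pd.DataFrame:
    """Per-probe OLS: blood ~ sperm * obesity + covariates.

    The reported effect is the sperm x obesity interaction coefficient; the
    diagnostic is the maximal leave-one-out change in the interaction t
    statistic (closed-form downdates), large when a single pair drives the
    interaction.  Probes with fewer usable pairs than covariates + 3 get NA.
    """
    common = beta_blood.index.intersection(beta_sperm.index)
    B = beta_blood.loc[common].to_numpy(dtype=float)
    S = beta_sperm.loc[common].to_numpy(dtype=float)
    design = DesignSpec(covariates, predictor, categorical)
    Xbase, names = build_design_matrix(design)
    g = Xbase[:, names.index(predictor)]
    n = Xbase.shape[0]
    p_total = Xbase.shape[1] + 2    # + sperm + interaction
    min_n = (p_total - 1) + 3       # covariates + 3 pairs
    rows = []
    for i in range(len(common)):
        x = S[i]
        y = B[i]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < max(min_n, p_total + 1):
            rows.append((np.nan, np.nan, np.nan, np.nan, False, np.nan,
                         int(ok.sum())))
            continue
        X = np.column_stack([Xbase[ok], x[ok], (x * g)[ok]])
        yy = y[ok]
        m, q = X.shape
        Ainv = np.linalg.pinv(X.T @ X)
        beta_hat = Ainv @ X.T @ yy
        e = yy - X @ beta_hat
        rss = float(e @ e)
        dfree = m - q
        jj = q - 1                    # interaction column
        sigma2 = rss / dfree
        se = np.sqrt(sigma2 * Ainv[jj, jj])
        t = beta_hat[jj] / se if se > 0 else 0.0
        pv = 2 * stats.t.sf(abs(t), dfree) if se > 0 else 1.0
        diag = np.nan
        if loo_diagnostic and dfree > 1:
            V = X @ Ainv
            h = np.einsum("ij,ij->i", V, X)
            denom = np.clip(1.0 - h, 1e-12, None)
            c = V[:, jj]
            b_loo = beta_hat[jj] - c * e / denom
            rss_loo = np.maximum(rss - e ** 2 / denom, 0.0)
            ainv_loo = Ainv[jj, jj] + c ** 2 / denom
            s2_loo = rss_loo / (dfree - 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_loo = b_loo / np.sqrt(s2_loo * ainv_loo)
            diag = float(np.nanmax(np.abs(t - t_loo)))
        rows.append((beta_hat[jj], se, t, pv, pv < alpha, diag, int(ok.sum())))
    return pd.DataFrame(
        rows,
        columns=["effect", "se", "t", "p", "significant", "loo_max_t_change",
                 "n_pairs"],
        index=common,
    ).astype({"n_pairs": int})


# ---------------------------------------------------------------------------
# cell-composition deconvolution


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex {x >= 0, sum = 1}."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, len(v) + 1) > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


def estimate_cell_composition(
    beta: pd.DataFrame,
    reference: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample cell-type fractions from a reference profile matrix.

    Solves non-negative least squares per sample over the shared probes,
    then projects onto {x >= 0, sum x <= 1}.  Returns (fractions samples x
    cell types, per-sample RMS residual).  Deterministic; raises on a
    rank-deficient reference.
    """
    common = reference.index.intersection(beta.index)
    k = reference.shape[1]
    if k < 1:
        raise ValueError("need at least one cell type")
    if len(common) < k:
        raise ValueError("fewer shared probes than cell types")
    R = reference.loc[common].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < k:
        raise ValueError("rank-deficient reference profile matrix")
    fracs = np.empty((beta.shape[1], k))
    resid = np.empty(beta.shape[1])
    Y = beta.loc[common].to_numpy(dtype=float)
    for s in range(beta.shape[1]):
        x, _ = nnls(R, Y[:, s])
        if x.sum() > 1.0:
            x = _project_simplex(x)
        fracs[s] = x
        resid[s] = np.sqrt(np.mean((R @ x - Y[:, s]) ** 2))
    fractions = pd.DataFrame(fracs, index=beta.columns,
                             columns=reference.columns)
    return fractions, pd.Series(resid, index=beta.columns, name="rms_residual")


# ---------------------------------------------------------------------------
# prior-study comparison


def prior_probe_enrichment(pvals: pd.Series, prior_set) -> dict:
    """Wilcoxon rank-sum test for lower-ranked p-values in a prior probe set.

    Compares the p-value ranks of probes in ``prior_set`` against all
    remaining tested probes (two-sided).  Returns the U statistic of the
    prior set, the p-value and the group sizes.
    """
    prior = pd.Index(prior_set).intersection(pvals.dropna().index)
    if len(prior) < 3:
        raise ValueError("fewer than 3 prior probes among tested probes")
    rest = pvals.dropna().index.difference(prior)
    if len(rest) == 0:
        raise ValueError("no non-prior probes to compare against")
    u, p = stats.mannwhitneyu(pvals.loc[prior], pvals.loc[rest],
                              alternative="two-sided")
    return {"statistic": float(u), "p": float(p),
            "n_prior": int(len(prior)), "n_rest": int(len(rest))}


def effect_concordance(effects_local: pd.Series,
                       effects_prior: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation of effect sizes over the shared probes."""
    common = effects_local.dropna().index.intersection(
        effects_prior.dropna().index)
    if len(common) < 3:
        raise ValueError("fewer than 3 shared probes")
    rho, p = stats.spearmanr(effects_local.loc[common],
                             effects_prior.loc[common])
    return float(rho), float(p)
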