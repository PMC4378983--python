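"""Per-analyte covariate-adjusted group comparison pooled by Rubin's rules.

The reference analysis accompanying the network tests: each analyte's
log-concentration is explained by the group indicator plus covariates
(ANCOVA).  Analytes with missing cells are fitted once per imputed copy and
the ``M`` estimates pooled — pooled effect is the mean, total variance the
within-imputation variance plus ``(1 + 1/M)`` times the between-imputation
variance, with Barnard–Rubin small-sample degrees of freedom for the Wald
test.  Fully observed analytes need a single fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .impute import ImputationSet
from .io import MissingCode


@dataclass
class PooledEstimate:
    """Rubin-pooled group effect for one analyte."""

    beta: float
    within_var: float
    between_var: float
    total_var: float
    statistic: float  # t = beta / sqrt(total_var)
    df: float
    p_value: float
    M: int

    def __post_init__(self) -> None:
        if self.between_var < 0:
            raise ValueError("negative between-imputation variance")
        if self.total_var < self.within_var - 1e-12:
            raise ValueError("total variance below within-imputation variance")


def rubin_pool(estimates, variances, df_com: float | None = None) -> PooledEstimate:
    """Pool ``M`` point estimates and their squared standard errors.

    ``beta = mean(estimates)``, ``W = mean(variances)``,
    ``B = sample variance of estimates``, ``T = W + (1 + 1/M) B``.  The Wald
    statistic ``beta / sqrt(T)`` is referred to a t distribution with
    Barnard–Rubin adjusted degrees of freedom when the complete-data residual
    df ``df_com`` is given (otherwise the older Rubin df).  ``M = 1`` passes
    the single fit through with its complete-data df.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    if np.any(var < 0):
        raise ValueError("negative input variance")
    M = est.size
    beta = float(est.mean())
    W = float(var.mean())
    if M == 1:
        T, B = W, 0.0
        df = df_com if df_com is not None else np.inf
    else:
        B = float(est.var(ddof=1))
        T = W + (1 + 1 / M) * B
        if B == 0:
            df = df_com if df_com is not None else np.inf
        else:
            lam = (1 + 1 / M) * B / T  # fraction of missing information
            df_old = (M - 1) / lam**2
            if df_com is None or not np.isfinite(df_com):
                df = df_old
            else:
                df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
                df = df_old * df_obs / (df_old + df_obs)
    tstat = beta / np.sqrt(T) if T > 0 else np.inf * np.sign(beta)
    p = 2 * stats.t.sf(abs(tstat), df) if np.isfinite(df) else 2 * stats.norm.sf(abs(tstat))
    return PooledEstimate(
        beta=beta, within_var=W, between_var=B, total_var=T,
        statistic=float(tstat), df=float(df), p_value=float(p), M=M,
    )


def ancova_per_lipid(imp: ImputationSet, covariate_columns=None) -> dict:
    """Fit the ANCOVA once per imputed copy for each analyte.

    Returns ``{analyte: (estimates, variances, df_com)}`` for the group
    coefficient.  Fully observed analytes get a single fit (their ``M``
    copies are identical by construction).
    """
    src = imp.source
    arr = src.arrays()
    cov = src.covariates
    if covariate_columns is not None:
        cov = cov[list(covariate_columns)]
    X = sm.add_constant(
        np.column_stack([arr["y"], cov.to_numpy(dtype=float)])
        if cov.shape[1]
        else arr["y"][:, None],
        has_constant="add",
    )
    df_com = src.n - X.shape[1]
    fully_observed = (arr["code"] == int(MissingCode.OBSERVED)).all(axis=0)
    out = {}
    for j, analyte in enumerate(src.analyte_ids):
        copies = imp.completed[:1] if fully_observed[j] else imp.completed
        est, var = [], []
        for c in copies:
            fit = sm.OLS(c[:, j], X).fit()
            est.append(fit.params[1])  # column 1: the group indicator
            var.append(fit.bse[1] ** 2)
        out[analyte] = (np.array(est), np.array(var), df_com)
    return out


def marginal_analysis(imp: ImputationSet, covariate_columns=None) -> pd.DataFrame:
    """Rubin-pooled ANCOVA table (analyte, beta, var, t, df, p), sorted by p."""
    fits = ancova_per_lipid(imp, covariate_columns)
    rows = []
    for analyte, (est, var, df_com) in fits.items():
        pe = rubin_pool(est, var, df_com)
        rows.append(
            {
                "analyte": analyte,
                "beta": pe.beta,
                "var_beta": pe.total_var,
                "statistic": pe.statistic,
                "df": pe.df,
                "p_value": pe.p_value,
                "n_fits": pe.M,
            }
        )
    return pd.DataFrame(rows).set_index("analyte").sort_values("p_value")
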