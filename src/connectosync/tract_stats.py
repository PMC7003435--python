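"""Tract-wise diffusion-measure association with diagnosis.

Each (tract, measure) column of a subject table is regressed on diagnosis
severity (CN=0, MCI=1, Dementia=2) adjusting for age, sex and total brain
volume, after removing observations more than 3.5 SD from the measure mean.
P-values are Benjamini-Hochberg adjusted within a cohort, and a replication
check requires significance in both cohorts with concordant effect direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

DIFFUSION_MEASURES = ("volume", "length", "AxD", "RD", "MD", "FA")
DIAGNOSIS_CODE = {"CN": 0, "MCI": 1, "Dementia": 2}
DEFAULT_COVARIATES = ("age", "sex", "TBV")


def measure_column(tract: str, measure: str) -> str:
    return f"{tract}:{measure}"


@dataclass
class AssociationResult:
    tract: str
    measure: str
    beta: float
    p: float
    n_used: int
    q: float | None = None


def _design(table: pd.DataFrame, columns: tuple[str, ...]) -> np.ndarray:
    parts = []
    for c in columns:
        col = table[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            parts.append(dummies.to_numpy())
        else:
            parts.append(col.to_numpy(dtype=float)[:, None])
    return np.column_stack(parts) if parts else np.empty((len(table), 0))


def remove_outliers(y: np.ndarray, sd_limit: float = 3.5) -> np.ndarray:
    """Boolean keep-mask: observations within ``sd_limit`` SDs of the mean.

    Applied once to the raw measure (no iterative re-trimming); values at
    exactly the limit are retained.
    """
    mu, sd = np.nanmean(y), np.nanstd(y, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.isfinite(y)
    return np.isfinite(y) & (np.abs(y - mu) <= sd_limit * sd)


def diagnosis_association(
    table: pd.DataFrame,
    tract: str,
    measure: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    outlier_sd: float = 3.5,
) -> AssociationResult:
    """Linear-model association between diagnosis severity and one measure.

    Fits ``measure ~ intercept + diagnosis + covariates`` by least squares on
    the outlier-trimmed rows and returns the Wald p-value and effect size
    (beta) for the diagnosis coefficient.
    """
    col = measure_column(tract, measure)
    y = table[col].to_numpy(dtype=float)
    keep = remove_outliers(y, outlier_sd)
    sub = table.loc[keep]
    if len(sub) < 10:
        raise ValueError(f"{col}: fewer than 10 usable subjects")
    dx = sub["diagnosis"].map(DIAGNOSIS_CODE).to_numpy(dtype=float)
    X = np.column_stack([dx, _design(sub, covariates)])
    X = sm.add_constant(X, prepend=False)
    fit = sm.OLS(y[keep], X).fit()
    if fit.df_resid <= 0:
        raise ValueError(f"{col}: zero residual degrees of freedom")
    return AssociationResult(
        tract=tract,
        measure=measure,
        beta=float(fit.params[0]),
        p=float(fit.pvalues[0]),
        n_used=int(len(sub)),
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def associate_all(
    table: pd.DataFrame,
    tracts: list[str] | None = None,
    measures: tuple[str, ...] = DIFFUSION_MEASURES,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    outlier_sd: float = 3.5,
) -> pd.DataFrame:
    """All (tract, measure) diagnosis associations with cohort-wide FDR."""
    if tracts is None:
        tracts = sorted(
            {c.split(":")[0] for c in table.columns if ":" in c}
        )
    rows = [
        diagnosis_association(table, t, m, covariates, outlier_sd)
        for t in tracts
        for m in measures
        if measure_column(t, m) in table.columns
    ]
    out = pd.DataFrame([vars(r) for r in rows]).drop(columns="q")
    out["q"] = fdr_adjust(out["p"])
    return out


def replication_check(
    discovery: pd.DataFrame, replication: pd.DataFrame, q_cut: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Associations significant in both cohorts with the same beta sign.

    Returns the replicated (tract, measure) table and an effect-size
    concordance table joining betas of the two cohorts for all shared keys.
    """
    keys = ["tract", "measure"]
    merged = discovery.merge(
        replication, on=keys, suffixes=("_disc", "_repl")
    )
    if merged.empty:
        raise ValueError("no shared (tract, measure) keys between cohorts")
    concordance = merged[
        keys + ["beta_disc", "q_disc", "beta_repl", "q_repl"]
    ].copy()
    concordance["replicated"] = (
        (merged.q_disc < q_cut)
        & (merged.q_repl < q_cut)
        & (np.sign(merged.beta_disc) == np.sign(merged.beta_repl))
    )
    replicated = concordance.loc[concordance.replicated, keys].reset_index(
        drop=True
    )
    return replicated, concordance


def _single_covariate_p(y: np.ndarray, x: np.ndarray) -> float:
    if np.nanstd(x) == 0:
        return 1.0
    X = sm.add_constant(x[:, None], prepend=False)
    fit = sm.OLS(y, X, missing="drop").fit()
    return float(fit.pvalues[0])


def covariate_screen(
    table: pd.DataFrame,
    covariates: list[str],
    adjust: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Single-covariate association screen over all (tract, measure) columns.

    For every covariate and measure column, reports -log10 p from a simple
    linear model before and after residualizing the measure on the
    adjustment covariates (age, sex, TBV by default).  Constant covariates
    are flagged with p = 1.
    """
    measure_cols = [c for c in table.columns if ":" in c]
    Z = _design(table, tuple(adjust))
    Z = sm.add_constant(Z, prepend=False)
    rows = []
    for col in measure_cols:
        y = table[col].to_numpy(dtype=float)
        resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        tract, measure = col.split(":", 1)
        for cov in covariates:
            x = _design(table, (cov,))
            if x.shape[1] == 0 or np.all(np.nanstd(x, axis=0) == 0):
                warnings.warn(f"constant covariate {cov!r}; p set to 1")
                p_raw = p_adj = 1.0
            else:
                x1 = x[:, 0] if x.shape[1] == 1 else x.mean(axis=1)
                p_raw = _single_covariate_p(y, x1)
                p_adj = _single_covariate_p(resid, x1)
            rows.append(
                {
                    "covariate": cov,
                    "tract": tract,
                    "measure": measure,
                    "neglog10_p_raw": -np.log10(max(p_raw, 1e-300)),
                    "neglog10_p_adjusted": -np.log10(max(p_adj, 1e-300)),
                }
            )
    return pd.DataFrame(rows)
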