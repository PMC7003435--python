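"""Blood gene-set association with tract diffusion measures.

Probe-level blood expression is collapsed to gene level by the mean-max rule
(the probe with the highest mean expression represents the gene).  Each
gene's expression is tested against a diffusion measure in a linear model
with sex, age, RNA integrity number and array-plate covariates, yielding a
Wald chi-square (beta/SE)^2 for the expression coefficient.  A gene set's
aggregate effect is the sum of its per-gene chi-squares, with significance
from whole-subject permutations of the expression matrix (rows kept
together, preserving inter-gene correlation) against the fixed measure and
covariates.  The permutation p uses the add-one convention, so it is never
zero and respects the 1/(1 + n_perm) floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

BLOOD_COVARIATES = ("sex", "age", "RIN", "plate")

#: Wald chi-square reported when the expression fit is numerically degenerate
#: (residual variance ~ 0, e.g. expression duplicated as the measure).
CHI2_CAP = 1e12


def mean_max_collapse(
    probes: pd.DataFrame, probe_map: pd.DataFrame
) -> pd.DataFrame:
    """Collapse a probe x subject matrix to gene level by mean-max.

    ``probe_map`` has columns ``probe_id``, ``gene``.  For each gene the
    probe with the highest mean expression across subjects is used verbatim;
    mean ties resolve to the smallest probe id.  Probes without a gene
    mapping are dropped (count logged via a warning).
    """
    mapping = probe_map.set_index("probe_id")["gene"]
    mapped = probes.index.intersection(mapping.index)
    n_unmapped = len(probes.index) - len(mapped)
    if n_unmapped:
        warnings.warn(f"dropped {n_unmapped} unmapped probes")
    sub = probes.loc[mapped]
    frame = pd.DataFrame(
        {
            "probe_id": mapped,
            "gene": mapping.loc[mapped].to_numpy(),
            "mean": sub.mean(axis=1).to_numpy(),
        }
    )
    frame = frame.sort_values(
        ["gene", "mean", "probe_id"], ascending=[True, False, True]
    )
    best = frame.groupby("gene", sort=True).head(1)
    out = sub.loc[best.probe_id]
    out.index = best.gene.to_numpy()
    return out.sort_index()


def covariate_design(
    covariates: pd.DataFrame, columns=BLOOD_COVARIATES
) -> np.ndarray:
    """Intercept + dummy-coded covariate design matrix.

    A categorical covariate with fewer than two observed levels is dropped
    (it would be aliased with the intercept).
    """
    parts = [np.ones((len(covariates), 1))]
    for c in columns:
        if c not in covariates.columns:
            continue
        col = covariates[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            if col.nunique() < 2:
                warnings.warn(f"covariate {c!r} constant; dropped")
                continue
            parts.append(
                pd.get_dummies(col, drop_first=True, dtype=float).to_numpy()
            )
        else:
            parts.append(col.to_numpy(dtype=float)[:, None])
    return np.column_stack(parts)


def _residualizer(X: np.ndarray) -> np.ndarray:
    """Annihilator (residual-forming) matrix of a design, via pinv so
    collinear columns are absorbed rather than fatal."""
    return np.eye(X.shape[0]) - X @ np.linalg.pinv(X)


def gene_chisq(
    expression: np.ndarray,
    measure: np.ndarray,
    design: np.ndarray,
) -> np.ndarray:
    """Per-gene Wald chi-square for the expression coefficient.

    ``expression`` is genes x subjects.  By Frisch-Waugh-Lovell, the t
    statistic of the expression term in
    ``measure ~ design + expression`` equals
    r * sqrt(df / (1 - r^2)) with r the correlation of the
    design-residualized measure and expression, df = n - rank(design) - 1.
    Returns t^2, capped at ``CHI2_CAP`` for numerically degenerate fits.
    """
    M = _residualizer(design)
    y = M @ np.asarray(measure, dtype=float)
    E = np.asarray(expression, dtype=float) @ M.T  # residualized rows
    df = len(y) - int(np.linalg.matrix_rank(design)) - 1
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    y_norm = np.linalg.norm(y)
    e_norm = np.linalg.norm(E, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (E @ y) / (e_norm * y_norm)
    r = np.clip(np.nan_to_num(r), -1.0, 1.0)
    one_minus = np.maximum(1.0 - r**2, 1.0 / CHI2_CAP)
    chi2 = df * r**2 / one_minus
    return np.minimum(chi2, CHI2_CAP)


def gene_diffusion_assoc(
    gene_row: np.ndarray,
    measure: np.ndarray,
    covariates: pd.DataFrame,
) -> float:
    """Wald chi-square of a single gene's association with a measure."""
    X = covariate_design(covariates)
    return float(gene_chisq(np.atleast_2d(gene_row), measure, X)[0])


@dataclass
class PermutationResult:
    """Sum-of-chi-square gene-set statistic with permutation inference."""

    statistic: float
    p: float
    n_perm: int
    per_gene: pd.Series
    measure: str = ""

    def __post_init__(self) -> None:
        assert self.p >= 1.0 / (1 + self.n_perm) - 1e-12


def sumchisq_permutation(
    expression: pd.DataFrame,
    set_genes: list[str],
    measure: np.ndarray,
    covariates: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
    measure_name: str = "",
) -> PermutationResult:
    """Aggregate gene-set effect on a diffusion measure.

    The observed statistic sums per-gene Wald chi-squares over the set.  The
    null re-assigns whole expression profiles to subjects (one permutation of
    subjects applied to every gene simultaneously), keeping the measure and
    covariates fixed, so inter-gene correlation within the set is preserved.
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable permutation p-values")
    missing = [g for g in set_genes if g not in expression.index]
    if missing:
        raise KeyError(f"set genes absent after collapse: {missing[:5]}")
    E = expression.loc[list(set_genes)].to_numpy(dtype=float)
    y = np.asarray(measure, dtype=float)
    X = covariate_design(covariates)
    M = _residualizer(X)
    df = len(y) - int(np.linalg.matrix_rank(X)) - 1
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    y_res = M @ y
    y_norm = np.linalg.norm(y_res)

    def stat(E_cols: np.ndarray) -> tuple[float, np.ndarray]:
        R = E_cols @ M.T
        e_norm = np.linalg.norm(R, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (R @ y_res) / (e_norm * y_norm)
        r = np.clip(np.nan_to_num(r), -1.0, 1.0)
        one_minus = np.maximum(1.0 - r**2, 1.0 / CHI2_CAP)
        chi2 = np.minimum(df * r**2 / one_minus, CHI2_CAP)
        return float(chi2.sum()), chi2

    observed, per_gene = stat(E)
    rng = np.random.default_rng(seed)
    n = E.shape[1]
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s, _ = stat(E[:, perm])
        if s >= observed:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return PermutationResult(
        statistic=observed,
        p=p,
        n_perm=n_perm,
        per_gene=pd.Series(per_gene, index=list(set_genes)),
        measure=measure_name,
    )
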