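"""Tissue-to-tissue correlation (TTC): the genomic connectome.

For every unordered pair of brain regions, all cross-region gene pairs are
scored by Spearman correlation on the shared subjects after residualizing
expression on demographic and neuropathological covariates (age, sex,
post-mortem interval, pH, ethnicity, Braak stage).  Gene pairs below a
stringent p-value threshold (1e-8 genome-wide in the original study) are the
significant TTC pairs; their per-region-pair counts define the strength of
genomic connectivity, and the top decile of region pairs by count is tested
for enrichment in tract-bound pairs with a Fisher exact test.

All-pairs correlation is computed blockwise on rank-transformed matrices so
memory stays proportional to one block of gene pairs, not to all pairs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from connectosync.reach_probability import RegionPairClasses

TTC_COVARIATES = ("age", "sex", "PMI", "pH", "ethnicity", "braak")


@dataclass
class RegionExpressionSet:
    """Per-region gene x subject expression plus a shared covariate table.

    ``df_loss`` records how many degrees of freedom covariate
    residualization removed (design rank minus intercept); correlation
    p-values downstream subtract it, partial-correlation style.
    """

    expression: dict[str, pd.DataFrame]  # region -> genes x subjects
    covariates: pd.DataFrame  # indexed by subject id
    df_loss: int = 0

    @property
    def regions(self) -> list[str]:
        return sorted(self.expression)

    def shared_subjects(self, region_a: str, region_b: str) -> list[str]:
        cols_a = set(self.expression[region_a].columns)
        cols_b = set(self.expression[region_b].columns)
        return sorted(cols_a & cols_b)


@dataclass
class TTCResult:
    """Significant TTC gene pairs for one region pair."""

    region_a: str
    region_b: str
    n_shared: int
    pairs: pd.DataFrame  # columns gene_a, gene_b, rho, p
    n_skipped: int = 0

    @property
    def count(self) -> int:
        return len(self.pairs)

    @property
    def pair_id(self) -> str:
        return f"{self.region_a}|{self.region_b}"


def _covariate_design(cov: pd.DataFrame, columns=TTC_COVARIATES) -> np.ndarray:
    parts = [np.ones((len(cov), 1))]
    for c in columns:
        if c not in cov.columns:
            continue
        col = cov[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            parts.append(
                pd.get_dummies(col, drop_first=True, dtype=float).to_numpy()
            )
        else:
            parts.append(col.to_numpy(dtype=float)[:, None])
    return np.column_stack(parts)


def residualize_expression(
    expr_set: RegionExpressionSet, covariates=TTC_COVARIATES
) -> RegionExpressionSet:
    """Replace each gene's values by least-squares covariate residuals.

    Categorical covariates are dummy coded; aliased (rank-deficient) design
    columns are handled by the pseudo-inverse solution with a warning.
    Residual means are zero per gene by construction.
    """
    out = {}
    max_rank = 1
    for region, mat in expr_set.expression.items():
        cov = expr_set.covariates.loc[mat.columns]
        X = _covariate_design(cov, covariates)
        rank = int(np.linalg.matrix_rank(X))
        max_rank = max(max_rank, rank)
        if rank < X.shape[1]:
            warnings.warn(
                f"region {region}: covariate design rank-deficient "
                f"({rank}/{X.shape[1]}); aliased columns absorbed"
            )
        Y = mat.to_numpy(dtype=float).T  # subjects x genes
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        resid = Y - X @ beta
        out[region] = pd.DataFrame(
            resid.T, index=mat.index, columns=mat.columns
        )
    return RegionExpressionSet(
        expression=out,
        covariates=expr_set.covariates,
        df_loss=max_rank - 1,
    )


def _rank_standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-tie ranks per row, centered and scaled to unit norm.

    Returns the standardized ranks and a boolean mask of constant
    (zero-rank-variance) rows, which cannot be correlated.
    """
    ranks = stats.rankdata(mat, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    constant = norms == 0
    norms[constant] = 1.0
    return ranks / norms[:, None], constant


def spearman_p_from_rho(
    rho: np.ndarray, n: int, df_loss: int = 0
) -> np.ndarray:
    """Two-sided p via the t approximation t = rho*sqrt(df/(1-rho^2)).

    ``df = n - 2 - df_loss``: on residualized expression the degrees of
    freedom consumed by the covariate fit are subtracted
    (partial-correlation convention), keeping the null calibrated at the
     30-50 subject scale of post-mortem cohorts.
    """
    rho = np.clip(rho, -1.0, 1.0)
    df = n - 2 - df_loss
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / np.maximum(1e-300, 1.0 - rho**2))
    return 2.0 * stats.t.sf(np.abs(t), df=df)


def ttc_pairs(
    region_a: str,
    mat_a: pd.DataFrame,
    region_b: str,
    mat_b: pd.DataFrame,
    alpha: float = 1e-8,
    block_size: int = 512,
    df_loss: int = 0,
) -> TTCResult:
    """Significant cross-region Spearman gene pairs on shared subjects.

    Gene pairs with two-sided p < ``alpha`` (t approximation, degrees of
    freedom reduced by ``df_loss`` for residualized input) are retained.
    Rows are processed in blocks of ``block_size`` genes so the full
    genes_a x genes_b correlation matrix is never materialized at once.
    Constant genes are skipped and counted.
    """
    shared = sorted(set(mat_a.columns) & set(mat_b.columns))
    n = len(shared)
    if n < 10:
        raise ValueError(
            f"({region_a}, {region_b}): only {n} shared subjects (< 10)"
        )
    A = mat_a[shared].to_numpy(dtype=float)
    B = mat_b[shared].to_numpy(dtype=float)
    ra, const_a = _rank_standardize(A)
    rb, const_b = _rank_standardize(B)
    n_skipped = int(const_a.sum() + const_b.sum())

    genes_a = mat_a.index.to_numpy()
    genes_b = mat_b.index.to_numpy()
    keep_b = ~const_b
    rb = rb[keep_b]
    genes_b = genes_b[keep_b]

    frames = []
    for start in range(0, ra.shape[0], block_size):
        stop = min(start + block_size, ra.shape[0])
        block_keep = ~const_a[start:stop]
        rho = ra[start:stop][block_keep] @ rb.T
        p = spearman_p_from_rho(rho, n, df_loss)
        ii, jj = np.nonzero(p < alpha)
        if ii.size:
            block_genes = genes_a[start:stop][block_keep]
            frames.append(
                pd.DataFrame(
                    {
                        "gene_a": block_genes[ii],
                        "gene_b": genes_b[jj],
                        "rho": rho[ii, jj],
                        "p": p[ii, jj],
                    }
                )
            )
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["gene_a", "gene_b", "rho", "p"])
    )
    return TTCResult(
        region_a=region_a,
        region_b=region_b,
        n_shared=n,
        pairs=pairs,
        n_skipped=n_skipped,
    )


def ttc_all(
    expr_set: RegionExpressionSet,
    alpha: float = 1e-8,
    block_size: int = 512,
    residualize: bool = True,
) -> list[TTCResult]:
    """TTC results for every unordered region pair."""
    data = residualize_expression(expr_set) if residualize else expr_set
    results = []
    for a, b in itertools.combinations(data.regions, 2):
        results.append(
            ttc_pairs(
                a,
                data.expression[a],
                b,
                data.expression[b],
                alpha,
                block_size,
                df_loss=data.df_loss,
            )
        )
    return results


def count_table(results: list[TTCResult]) -> pd.DataFrame:
    """Per-region-pair significant-pair counts, ranked descending."""
    df = pd.DataFrame(
        {
            "region_a": [r.region_a for r in results],
            "region_b": [r.region_b for r in results],
            "pair_id": [r.pair_id for r in results],
            "n_shared": [r.n_shared for r in results],
            "count": [r.count for r in results],
        }
    )
    df = df.sort_values(
        ["count", "pair_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class DecileEnrichment:
    klass: str
    table: np.ndarray  # 2x2 [[top&class, top&other], [rest&class, rest&other]]
    p: float
    n_top: int
    top_pairs: list[str] = field(default_factory=list)


def top_decile_enrichment(
    results: list[TTCResult],
    classes: RegionPairClasses,
    klass: str,
    alternative: str = "greater",
) -> DecileEnrichment:
    """Fisher test: is the top count-decile enriched for a binding class?

    Region pairs are ranked by significant TTC pair count (ties broken by
    lexicographic pair id); the top ceil(0.1 * N) pairs form the decile, and
    a one-sided (greater) Fisher exact test compares decile membership
    against membership in ``klass`` (tract-bound or AD-tract-bound).
    """
    counts = count_table(results)
    n = len(counts)
    n_top = math.ceil(0.1 * n)
    counts["in_top"] = counts["rank"] <= n_top
    klass_of = {
        f"{r.region_a}|{r.region_b}": r.klass
        for r in classes.pairs.itertuples()
    }
    counts["in_class"] = counts.pair_id.map(klass_of) == klass

    in_class = counts.in_class.to_numpy()
    if in_class.all() or not in_class.any():
        warnings.warn(f"degenerate class {klass!r}: Fisher p set to 1")
        p = 1.0
        table = np.zeros((2, 2), dtype=int)
    else:
        top = counts.in_top.to_numpy()
        table = np.array(
            [
                [(top & in_class).sum(), (top & ~in_class).sum()],
                [(~top & in_class).sum(), (~top & ~in_class).sum()],
            ]
        )
        p = float(stats.fisher_exact(table, alternative=alternative)[1])
    return DecileEnrichment(
        klass=klass,
        table=table,
        p=p,
        n_top=n_top,
        top_pairs=counts.loc[counts.in_top, "pair_id"].tolist(),
    )
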