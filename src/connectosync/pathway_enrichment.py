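"""Pathway over-representation of pooled TTC-module genes.

Pooled module genes of each (region pair, side) are tested for
over-representation in each curated pathway with a one-sided Fisher exact
test against a fixed background of all human genes (20,996 in the original
catalog).  P-values are Benjamini-Hochberg adjusted per gene list and
binarized at FDR < 0.05, yielding a binary pathway x (region pair, side)
association matrix.  Pathways carry one of eight broad categories plus a
signaling subtype, supporting the category-fraction (signaling enrichment)
test and the symmetric/asymmetric synchronization calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from connectosync.tract_stats import fdr_adjust

#: Drosophila-specific catalog entries removed at load time.
DROSOPHILA_PATHWAYS = (
    "P06209",
    "P06211",
    "P06212",
    "P06213",
    "P06214",
    "P06215",
    "P06216",
    "P06217",
)

PATHWAY_CATEGORIES = (
    "biosynthesis",
    "signaling",
    "disease",
    "physiology",
    "development",
    "gene regulation",
    "metabolism",
    "catabolism",
)

DEFAULT_BACKGROUND_N = 20996


@dataclass
class PathwayDB:
    """Curated pathway catalog with category/subtype annotations."""

    gene_sets: dict[str, frozenset[str]]
    categories: dict[str, str]
    signaling_subtypes: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)
    background_n: int = DEFAULT_BACKGROUND_N

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.gene_sets)

    @classmethod
    def from_gmt(
        cls,
        gmt_path,
        category_path=None,
        background_n: int = DEFAULT_BACKGROUND_N,
        exclude: tuple[str, ...] = DROSOPHILA_PATHWAYS,
    ) -> "PathwayDB":
        """Load a GMT gene-set file plus an optional category TSV.

        GMT lines are ``pathway_id<TAB>description<TAB>gene...``.  The
        category TSV has columns ``pathway_id``, ``category``,
        ``signaling_subtype``.  Excluded (e.g. Drosophila-specific) ids are
        filtered at load.
        """
        gene_sets: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        with open(gmt_path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or parts[0] in exclude:
                    continue
                gene_sets[parts[0]] = frozenset(g for g in parts[2:] if g)
                names[parts[0]] = parts[1]
        categories: dict[str, str] = {}
        subtypes: dict[str, str] = {}
        if category_path is not None:
            cat = pd.read_csv(category_path, sep="\t", dtype=str)
            for row in cat.itertuples():
                categories[row.pathway_id] = row.category
                subtypes[row.pathway_id] = getattr(
                    row, "signaling_subtype", "none"
                )
        return cls(
            gene_sets=gene_sets,
            categories=categories,
            signaling_subtypes=subtypes,
            names=names,
            background_n=background_n,
        )


def fisher_enrichment(
    gene_list, pathway_genes, background_n: int
) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test for over-representation.

    2x2 table: membership in the gene list crossed with membership in the
    pathway, over a background of ``background_n`` genes.  Returns
    (odds ratio, p).  An empty gene list yields p = 1 with a warning.
    """
    genes = set(gene_list)
    pathway = set(pathway_genes)
    if not genes:
        warnings.warn("empty gene list: enrichment p set to 1")
        return np.nan, 1.0
    if background_n < len(genes):
        raise ValueError("background smaller than the gene list")
    overlap = len(genes & pathway)
    table = np.array(
        [
            [overlap, len(genes) - overlap],
            [
                len(pathway) - overlap,
                background_n - len(genes) - len(pathway) + overlap,
            ],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


@dataclass
class EnrichmentMatrix:
    """Long-format pathway x (region pair, side) enrichment results."""

    results: pd.DataFrame  # pair_id, side, pathway, p, q, significant
    fdr: float
    totals: dict = field(default_factory=dict)

    def significant(self) -> pd.DataFrame:
        return self.results.loc[self.results.significant]


def enrich_all(
    gene_lists: dict[tuple[str, str], list[str]],
    db: PathwayDB,
    fdr: float = 0.05,
    family: str = "per_list",
) -> EnrichmentMatrix:
    """Fisher enrichment of every gene list against the whole catalog.

    ``gene_lists`` maps (region-pair id, side) -> pooled module genes.  BH
    adjustment runs across pathways within each list (``family="per_list"``,
    the default) or across all tests at once (``family="global"``).
    """
    rows = []
    for (pair_id, side), genes in sorted(gene_lists.items()):
        for pid in db.pathway_ids:
            _, p = fisher_enrichment(genes, db.gene_sets[pid], db.background_n)
            rows.append(
                {"pair_id": pair_id, "side": side, "pathway": pid, "p": p}
            )
    results = pd.DataFrame(rows)
    if results.empty:
        results = pd.DataFrame(
            columns=["pair_id", "side", "pathway", "p", "q", "significant"]
        )
        return EnrichmentMatrix(results=results, fdr=fdr, totals={})
    if family == "per_list":
        results["q"] = results.groupby(["pair_id", "side"])["p"].transform(
            lambda p: fdr_adjust(p.to_numpy())
        )
    elif family == "global":
        results["q"] = fdr_adjust(results["p"].to_numpy())
    else:
        raise ValueError(f"unknown FDR family {family!r}")
    results["significant"] = results["q"] < fdr
    sig = results.loc[results.significant]
    # a pathway-to-pair association counts once even if both sides hit
    pair_level = sig.drop_duplicates(["pair_id", "pathway"])
    totals = {
        "n_tests": len(db.pathway_ids)
        * len({k[0] for k in gene_lists}),
        "n_significant": int(len(pair_level)),
        "n_pathways_covered": int(sig.pathway.nunique()),
        "n_pairs_covered": int(sig.pair_id.nunique()),
    }
    return EnrichmentMatrix(results=results, fdr=fdr, totals=totals)


def synchronization_type(enrichment: EnrichmentMatrix) -> pd.DataFrame:
    """Per (pair, pathway): symmetric (both sides), asymmetric (one), none."""
    res = enrichment.results
    sig = (
        res.groupby(["pair_id", "pathway"])["significant"]
        .sum()
        .reset_index(name="n_sides")
    )
    sig["sync"] = sig.n_sides.map({0: "none", 1: "asymmetric", 2: "symmetric"})
    return sig[["pair_id", "pathway", "sync"]]


def category_fraction_test(
    enrichment: EnrichmentMatrix, db: PathwayDB, category: str
) -> tuple[float, float, np.ndarray]:
    """Fraction of enriched pathways in a category, with Fisher p.

    Counts distinct pathways with at least one significant association,
    computes the fraction belonging to ``category``, and tests enrichment of
    the category among enriched pathways (vs the full catalog) with a
    one-sided Fisher exact test.  Returns (fraction, p, 2x2 table).
    """
    if category not in set(db.categories.values()):
        raise LookupError(f"category {category!r} absent from pathway DB")
    enriched = set(enrichment.significant().pathway)
    if not enriched:
        raise ValueError("no enriched pathways")
    catalog = set(db.pathway_ids)
    in_cat = {p for p in catalog if db.categories.get(p) == category}
    a = len(enriched & in_cat)
    b = len(enriched - in_cat)
    c = len(in_cat - enriched)
    d = len(catalog - in_cat - enriched)
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="greater")
    return a / len(enriched), float(p), table
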