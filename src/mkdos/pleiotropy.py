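"""Pleiotropy as the number of distinct phenotype categories per gene.

A gene knocked down in several screens may affect phenotypes from one or
several functional categories; the distinct-category count operationalizes
the breadth of its pleiotropic effects.  This module compares DoS
distributions across pleiotropy classes (Mann-Whitney U), tests whether
adaptively evolving genes are over-represented among multi-category genes
(one-tailed Fisher's exact test), and checks that category count is not a
simple artifact of gene length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, linregress, mannwhitneyu

from .phenotype_enrichment import GeneSet

__all__ = [
    "CategoryMap",
    "assign_categories",
    "build_pleiotropy_table",
    "mwu_compare",
    "adaptive_enrichment",
    "length_bias_check",
    "effect_direction_table",
]


@dataclass(frozen=True)
class CategoryMap:
    """Mapping from phenotype name to functional category code.

    Category codes follow the convention CR (circadian rhythm), SR (cell
    surface receptor signaling), IS (intracellular signal transduction),
    GR (extent of cell growth), TE (transposon integration), IM (innate
    immune response), HY (hypoxia-inducible factor signaling).
    """

    phenotype_to_category: Mapping[str, str]

    def category_of(self, phenotype: str) -> str:
        try:
            return self.phenotype_to_category[phenotype]
        except KeyError:
            raise KeyError(f"phenotype {phenotype!r} missing from category map") from None

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.phenotype_to_category.values())))

    @classmethod
    def from_tsv(cls, path) -> "CategoryMap":
        df = pd.read_csv(path, sep="\t")
        if not {"phenotype", "category"} <= set(df.columns):
            raise ValueError(f"category map {path} needs 'phenotype' and 'category'")
        return cls(dict(zip(df["phenotype"].astype(str), df["category"].astype(str))))


def assign_categories(
    gene_sets: Sequence[GeneSet],
    category_map: CategoryMap,
    all_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Count distinct phenotype categories per gene across gene sets.

    Several phenotypes in the same category count once.  Genes listed in
    ``all_genes`` but in no set are kept with a count of zero.  A gene set
    whose phenotype cannot be resolved through the map is an error.
    """
    per_gene: dict[str, set[str]] = {}
    if all_genes is not None:
        for g in all_genes:
            per_gene.setdefault(str(g), set())
    for gs in gene_sets:
        cat = category_map.category_of(gs.phenotype)
        for g in gs.members:
            per_gene.setdefault(g, set()).add(cat)
    rows = [
        {"gene": g, "n_categories": len(cats)} for g, cats in sorted(per_gene.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "n_categories"])


def build_pleiotropy_table(
    gene_sets: Sequence[GeneSet],
    category_map: CategoryMap,
    gene_table: pd.DataFrame,
    mk_alpha: float = 0.01,
) -> pd.DataFrame:
    """Join category counts with per-gene selection statistics.

    ``gene_table`` is an annotated counts table (columns ``gene, n_codons,
    dos, mk_p, has_power``).  A gene is called adaptive when its MK test is
    significant at ``mk_alpha`` among powered genes, mirroring the
    convention that only P_FET < 0.01 is treated as evidence of recurrent
    positive selection.
    """
    counts = assign_categories(gene_sets, category_map, all_genes=gene_table["gene"])
    merged = counts.merge(
        gene_table[["gene", "n_codons", "dos", "mk_p", "has_power"]],
        on="gene",
        how="left",
    )
    merged["adaptive"] = (
        merged["has_power"].fillna(False).astype(bool)
        & (merged["mk_p"] < mk_alpha).fillna(False)
    )
    return merged


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a: #{a_i > b_j} + 0.5 #{a_i == b_j}."""
    gt = np.sum(a[:, None] > b[None, :])
    eq = np.sum(a[:, None] == b[None, :])
    return float(gt + 0.5 * eq)


def mwu_compare(group_a, group_b, exact_limit: int = 8) -> float:
    """Two-sided Mann-Whitney U p-value.

    When both groups have at most ``exact_limit`` observations the p-value
    is exact: every split of the pooled sample is enumerated (ties handled
    by mid-counting in U) and p = min(1, 2 * min(Pr(U <= u), Pr(U >= u)))
    with inclusive tails.  Larger samples use the tie-corrected normal
    approximation.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    nm = a.size * b.size
    u_obs = _u_statistic(a, b)
    if math.isclose(u_obs, nm / 2.0):
        return 1.0
    if a.size <= exact_limit and b.size <= exact_limit:
        pooled = np.concatenate([a, b])
        idx = range(pooled.size)
        lower = upper = total = 0
        for pick in combinations(idx, a.size):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u <= u_obs + 1e-12:
                lower += 1
            if u >= u_obs - 1e-12:
                upper += 1
            total += 1
        return min(1.0, 2.0 * min(lower, upper) / total)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def adaptive_enrichment(records: pd.DataFrame) -> float:
    """One-tailed FET for excess adaptive genes among multi-category genes.

    ``records`` must contain boolean ``adaptive`` and integer
    ``n_categories``; genes with no category are ignored.  The table is

        [[adaptive & multi, non-adaptive & multi],
         [adaptive & single, non-adaptive & single]]

    with multi meaning two or more categories; the p-value is the inclusive
    upper hypergeometric tail on the adaptive-and-multi cell.  A degenerate
    table (any zero margin) yields p = 1 with a warning.
    """
    df = records[records["n_categories"] >= 1]
    multi = df["n_categories"] >= 2
    adaptive = df["adaptive"].astype(bool)
    a = int((adaptive & multi).sum())
    b = int((~adaptive & multi).sum())
    c = int((adaptive & ~multi).sum())
    d = int((~adaptive & ~multi).sum())
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate 2x2 table in adaptive_enrichment; p = 1")
        return 1.0
    total = a + b + c + d
    return float(min(1.0, hypergeom.sf(a - 1, total, a + c, a + b)))


def length_bias_check(records: pd.DataFrame) -> tuple[float, float]:
    """Regress category count on gene length (codons).

    Returns ``(r_squared, p)`` from ordinary least squares; with zero
    variance in either variable r^2 is 0 and p undefined (NaN).
    """
    df = records.dropna(subset=["n_codons", "n_categories"])
    if len(df) < 3:
        raise ValueError("need at least 3 records for the length-bias check")
    x = df["n_codons"].to_numpy(dtype=float)
    y = df["n_categories"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, math.nan
    fit = linregress(x, y)
    return float(fit.rvalue**2), float(fit.pvalue)


def effect_direction_table(
    gene_sets: Sequence[GeneSet], screens, genes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Long-format (gene, phenotype, direction) table for tile plots.

    Direction is the sign of the gene's Z score in the screen that called
    it significant; no statistics are computed on it.
    """
    z_by_screen = {s.phenotype: s.z_scores for s in screens}
    keep = set(str(g) for g in genes) if genes is not None else None
    rows = []
    for gs in gene_sets:
        z_scores = z_by_screen.get(gs.phenotype, {})
        for g in gs.members:
            if keep is not None and g not in keep:
                continue
            z = z_scores.get(g)
            direction = "none" if z is None else ("positive" if z > 0 else "negative")
            rows.append({"gene": g, "phenotype": gs.phenotype, "direction": direction})
    return pd.DataFrame(rows, columns=["gene", "phenotype", "direction"])
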