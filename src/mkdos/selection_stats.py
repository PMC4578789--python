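"""Per-gene selection statistics on MK count tables.

Implements the direction-of-selection statistic

    DoS = D_N / (D_N + D_S) - P_N / (P_N + P_S),

the one-tailed MK Fisher's exact test (inclusive upper hypergeometric tail
for an excess of nonsynonymous divergence), the zero-power filter on small
tables, and pi0 / false-discovery-rate accounting over a genome-wide set of
tests.  DoS is positive under recurrent positive selection, negative when
weakly deleterious amino-acid variants segregate, and zero under strict
neutrality; it is undefined (NaN) when a gene has no divergence or no
polymorphism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .mk_counting import MKCounts

__all__ = [
    "GeneRecord",
    "FDRReport",
    "compute_dos",
    "mk_test",
    "power_filter",
    "estimate_pi0",
    "fdr_report",
    "annotate_gene_table",
]


@dataclass(frozen=True)
class GeneRecord:
    """MK counts for one gene augmented with its selection statistics."""

    gene: str
    counts: MKCounts
    dos: float  # NaN when undefined
    mk_p: float
    has_power: bool


@dataclass(frozen=True)
class FDRReport:
    """Genome-wide false-discovery accounting at one significance level.

    ``fdr = min(1, pi0 * m * alpha / n_rejected)``; ``fdr`` is None when
    nothing is rejected.
    """

    m: int
    pi0: float
    alpha: float
    n_rejected: int
    fdr: float | None

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "pi0": self.pi0,
            "alpha": self.alpha,
            "n_rejected": self.n_rejected,
            "fdr": self.fdr,
        }


def compute_dos(counts: MKCounts) -> float:
    """Direction of selection; NaN if either proportion's denominator is 0."""
    div = counts.d_n + counts.d_s
    poly = counts.p_n + counts.p_s
    if div == 0 or poly == 0:
        return math.nan
    return counts.d_n / div - counts.p_n / poly


def mk_test(counts: MKCounts) -> float:
    """One-tailed MK Fisher's exact test.

    Returns the inclusive upper-tail probability ``P(X >= D_N)`` for the
    nonsynonymous-divergence cell of the 2x2 table
    ``[[D_N, D_S], [P_N, P_S]]`` with all margins fixed, i.e. the
    probability of a nonsynonymous excess among fixed differences at least
    as large as observed.  An all-zero table carries no evidence (p = 1).
    """
    total = counts.total
    if total == 0:
        return 1.0
    # X ~ Hypergeom(population=total, successes=nonsyn sites, draws=divergence)
    p = hypergeom.sf(
        counts.d_n - 1, total, counts.d_n + counts.p_n, counts.d_n + counts.d_s
    )
    return float(min(1.0, p))


def power_filter(counts: MKCounts, rule: str = "margins", minimum: int = 6) -> bool:
    """Zero-power screen for small MK tables.

    A table has power only when every marginal count of the 2x2 table is at
    least ``minimum`` (default 6).  ``rule="cells"`` applies the same
    threshold to the four cells instead — an alternative reading of the
    filter kept as an option.
    """
    if rule == "margins":
        values = (
            counts.d_n + counts.d_s,
            counts.p_n + counts.p_s,
            counts.d_n + counts.p_n,
            counts.d_s + counts.p_s,
        )
    elif rule == "cells":
        values = (counts.d_n, counts.d_s, counts.p_n, counts.p_s)
    else:
        raise ValueError(f"unknown power rule {rule!r}")
    return all(v >= minimum for v in values)


def estimate_pi0(
    pvalues, method: str = "conservative", lambdas=None
) -> float:
    """Estimate the proportion of truly null hypotheses from p-values.

    ``method="conservative"`` (default) assumes the tests are conservative,
    so null p-values are stochastically >= Uniform(0, 1), and estimates
    pi0 = min(1, 2 * mean(p > 0.5)): under a uniform null half the mass
    lies above 0.5, and alternatives contribute almost nothing there.

    ``method="storey"`` evaluates pi0(lambda) = #{p > lambda} / (m (1 -
    lambda)) on a lambda grid and extrapolates to lambda -> 1 with a cubic
    polynomial smoother.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("cannot estimate pi0 from an empty p-value list")
    if np.any((p <= 0) & ~np.isclose(p, 0)) or np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "conservative":
        return float(min(1.0, 2.0 * np.mean(p > 0.5)))
    if method == "storey":
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        pi0_grid = np.array(
            [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
        )
        coeffs = np.polynomial.polynomial.polyfit(lambdas, pi0_grid, deg=3)
        pi0 = np.polynomial.polynomial.polyval(lambdas.max(), coeffs)
        return float(min(1.0, max(0.0, pi0)))
    raise ValueError(f"unknown pi0 method {method!r}")


def fdr_report(pvalues, pi0: float, alpha: float) -> FDRReport:
    """False discovery rate at threshold ``alpha`` given an external pi0."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(list(pvalues), dtype=float)
    m = int(p.size)
    n_rejected = int(np.sum(p <= alpha))
    if n_rejected == 0:
        fdr = None
    else:
        fdr = float(min(1.0, pi0 * m * alpha / n_rejected))
    return FDRReport(m=m, pi0=float(pi0), alpha=float(alpha), n_rejected=n_rejected, fdr=fdr)


def annotate_gene_table(
    counts_table: pd.DataFrame,
    power_rule: str = "margins",
    power_minimum: int = 6,
) -> pd.DataFrame:
    """Add ``dos``, ``mk_p`` and ``has_power`` columns to a counts table.

    Expects columns ``gene, n_codons, D_N, D_S, P_N, P_S`` (the output of
    :func:`mkdos.mk_counting.count_alignments`).  Undefined DoS values are
    stored as NaN and skipped by downstream mean/bootstrap consumers.
    """
    required = {"gene", "n_codons", "D_N", "D_S", "P_N", "P_S"}
    missing = required - set(counts_table.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    out = counts_table.copy()
    dos, mk_p, has_power = [], [], []
    for row in out.itertuples(index=False):
        c = MKCounts(
            gene=str(row.gene),
            n_codons=int(row.n_codons),
            d_n=int(row.D_N),
            d_s=int(row.D_S),
            p_n=int(row.P_N),
            p_s=int(row.P_S),
        )
        dos.append(compute_dos(c))
        mk_p.append(mk_test(c))
        has_power.append(power_filter(c, rule=power_rule, minimum=power_minimum))
    out["dos"] = dos
    out["mk_p"] = mk_p
    out["has_power"] = has_power
    return out
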