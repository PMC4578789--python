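"""Gene-set enrichment of DoS against a genome-wide bootstrap null.

An RNAi screen assigns each gene a standardized Z score; genes beyond the
screen's significance threshold (|Z| > 3 by convention, in the tail the
phenotype calls for) form its significant-gene set.  The set's mean DoS is
compared with a null distribution of mean DoS over random same-size gene
samples drawn without replacement from the genome-wide table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeScreen",
    "GeneSet",
    "BootstrapResult",
    "select_significant_genes",
    "mean_dos",
    "bootstrap_test",
    "read_screen",
    "read_screen_manifest",
]

_TAILS = ("lower", "upper", "both")


@dataclass(frozen=True)
class PhenotypeScreen:
    """One RNAi screen: phenotype, functional category, tail, Z per gene."""

    phenotype: str
    category: str
    tail: str
    z_scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.tail not in _TAILS:
            raise ValueError(f"tail must be one of {_TAILS}, got {self.tail!r}")


@dataclass(frozen=True)
class GeneSet:
    """Genes significantly affecting one phenotype."""

    phenotype: str
    category: str
    members: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class BootstrapResult:
    phenotype: str
    observed_mean: float
    n_genes: int  # members with defined DoS
    n_sampled: int  # null sample size (set size)
    replicates: int
    q_low: float
    q_high: float
    significant: bool
    p_value: float


def select_significant_genes(screen: PhenotypeScreen, threshold: float = 3.0) -> GeneSet:
    """Threshold a screen's Z scores into its significant-gene set.

    Strict inequalities at the threshold: ``lower`` keeps Z < -threshold,
    ``upper`` keeps Z > threshold, ``both`` keeps |Z| > threshold.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if screen.tail == "lower":
        keep = [g for g, z in screen.z_scores.items() if z < -threshold]
    elif screen.tail == "upper":
        keep = [g for g, z in screen.z_scores.items() if z > threshold]
    else:
        keep = [g for g, z in screen.z_scores.items() if abs(z) > threshold]
    return GeneSet(
        phenotype=screen.phenotype, category=screen.category, members=tuple(keep)
    )


def _dos_lookup(genome: pd.DataFrame) -> pd.Series:
    if "gene" not in genome.columns or "dos" not in genome.columns:
        raise ValueError("genome table needs 'gene' and 'dos' columns")
    return genome.set_index("gene")["dos"]


def mean_dos(gene_set: GeneSet, genome: pd.DataFrame) -> tuple[float, int]:
    """Mean DoS over the set's members with a defined (non-NaN) value.

    Returns ``(mean, n_used)``; mean is NaN when no member has a defined
    DoS.  A member absent from the genome table is an error.
    """
    if gene_set.n == 0:
        raise ValueError("gene set is empty")
    lookup = _dos_lookup(genome)
    missing = [g for g in gene_set.members if g not in lookup.index]
    if missing:
        raise KeyError(f"genes absent from genome table: {missing}")
    values = lookup.loc[list(gene_set.members)].to_numpy(dtype=float)
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        return float("nan"), 0
    return float(defined.mean()), int(defined.size)


def _null_means(
    pool: np.ndarray, n: int, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``replicates`` samples of size ``n`` drawn without
    replacement from ``pool``, vectorized in chunks.

    Each replicate ranks independent uniform keys; the ``n`` smallest keys
    select the sample, which is an exact without-replacement draw.
    """
    g = pool.size
    means = np.empty(replicates, dtype=float)
    chunk = max(1, int(4_000_000 // max(g, 1)))
    done = 0
    while done < replicates:
        r = min(chunk, replicates - done)
        keys = rng.random((r, g))
        if n < g:
            idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        else:
            idx = np.tile(np.arange(g), (r, 1))
        means[done : done + r] = pool[idx].mean(axis=1)
        done += r
    return means


def bootstrap_test(
    gene_set: GeneSet,
    genome: pd.DataFrame,
    replicates: int = 10000,
    seed: int = 0,
    two_sided: bool = True,
) -> BootstrapResult:
    """Randomization test of a set's mean DoS against the genome.

    The null distribution is the mean DoS of ``replicates`` random samples
    of N genes (N = set size) drawn without replacement from the genes with
    defined DoS.  With ``two_sided`` (default) the observed mean is
    significant when it falls outside the central 95% interval
    [2.5%, 97.5%] of the null; otherwise only an observed mean above the
    97.5% quantile rejects.  The empirical p-value is
    ``min(1, 2 * min(Pr(null <= obs), Pr(null >= obs)))`` with inclusive
    ties.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    observed, n_used = mean_dos(gene_set, genome)
    pool = _dos_lookup(genome).to_numpy(dtype=float)
    pool = pool[~np.isnan(pool)]
    n = gene_set.n
    if pool.size < n:
        raise ValueError(
            f"genome has only {pool.size} genes with defined DoS, need {n}"
        )
    rng = np.random.default_rng(seed)
    null = _null_means(pool, n, replicates, rng)
    q_low, q_high = np.quantile(null, [0.025, 0.975])
    p = 2.0 * min(np.mean(null <= observed), np.mean(null >= observed))
    p = float(min(1.0, p))
    if two_sided:
        significant = bool(observed < q_low or observed > q_high)
    else:
        significant = bool(observed > q_high)
    return BootstrapResult(
        phenotype=gene_set.phenotype,
        observed_mean=observed,
        n_genes=n_used,
        n_sampled=n,
        replicates=replicates,
        q_low=float(q_low),
        q_high=float(q_high),
        significant=significant,
        p_value=p,
    )


def read_screen(
    path: str | Path, phenotype: str, category: str, tail: str
) -> PhenotypeScreen:
    """Read a two-column TSV (gene, Z) into a :class:`PhenotypeScreen`."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "Z"} <= set(df.columns):
        raise ValueError(f"screen {path} needs columns 'gene' and 'Z'")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene ids in screen {path}: {dups}")
    return PhenotypeScreen(
        phenotype=phenotype,
        category=category,
        tail=tail,
        z_scores=dict(zip(df["gene"].astype(str), df["Z"].astype(float))),
    )


def read_screen_manifest(path: str | Path) -> list[PhenotypeScreen]:
    """Read a screen manifest TSV (phenotype, category, tail, file).

    ``file`` paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    manifest = pd.read_csv(path, sep="\t")
    required = {"phenotype", "category", "tail", "file"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest {path} needs columns {sorted(required)}")
    screens = []
    for row in manifest.itertuples(index=False):
        screens.append(
            read_screen(
                path.parent / str(row.file),
                phenotype=str(row.phenotype),
                category=str(row.category),
                tail=str(row.tail),
            )
        )
    return screens
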