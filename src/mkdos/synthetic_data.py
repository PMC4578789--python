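"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three kinds of real input: per-gene codon
alignments with planted polymorphisms and fixed differences, genome-wide
MK count tables, and RNAi screens of standardized Z scores with planted
effect genes.  The generators target the statistical structure the
analysis assumes — Poisson counts with gene-length-proportional means, a
3:1 nonsynonymous:synonymous opportunity ratio, normal Z noise — not
coalescent-level population-genetic realism.

Every function takes an explicit seed and uses one local generator; there
is no global random state, and identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mk_counting import CODON_TO_AA, CodonAlignment
from .phenotype_enrichment import PhenotypeScreen

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "EVENT_KINDS",
    "simulate_counts_table",
    "simulate_codon_alignment",
    "simulate_random_alignment",
    "simulate_rnai_screen",
    "write_alignment_fasta",
    "write_counts_table",
    "write_screen",
    "write_truth",
    "simulate_study_inputs",
]

SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TO_AA.items() if aa != "*"))
EVENT_KINDS = (
    "synonymous-poly",
    "nonsynonymous-poly",
    "synonymous-fixed",
    "nonsynonymous-fixed",
)
_BASES = "ACGT"

# Nonsynonymous:synonymous mutational opportunity before selection scaling;
# an approximate codon-table average.  Only relative rates matter for DoS.
NONSYN_OPPORTUNITY = 3.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated genome-wide count table.

    Rates are per codon: ``theta_poly`` is the expected number of
    polymorphic sites and ``lambda_div`` the expected number of
    lineage-specific substitutions.  Adaptive genes multiply the
    nonsynonymous substitution rate by ``adaptive_boost``.
    """

    n_genes: int
    n_strains: int = 15
    codons_per_gene: int | tuple[int, int] = (100, 1500)
    theta_poly: float = 0.04
    lambda_div: float = 0.04
    adaptive_fraction: float = 0.0
    adaptive_boost: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_genes, int) or self.n_genes < 1:
            raise ValueError(f"n_genes must be a positive integer, got {self.n_genes!r}")
        if not isinstance(self.n_strains, int) or self.n_strains < 2:
            raise ValueError(
                f"n_strains must be an integer >= 2, got {self.n_strains!r}"
            )
        cpg = self.codons_per_gene
        if isinstance(cpg, int):
            if cpg < 1:
                raise ValueError(f"codons_per_gene must be positive, got {cpg!r}")
        else:
            try:
                lo, hi = cpg
            except (TypeError, ValueError):
                raise ValueError(
                    f"codons_per_gene must be an int or (low, high) pair, got {cpg!r}"
                ) from None
            if lo < 1 or hi < lo:
                raise ValueError(f"codons_per_gene range invalid: {cpg!r}")
        if self.theta_poly < 0:
            raise ValueError(f"theta_poly must be nonnegative, got {self.theta_poly!r}")
        if self.lambda_div < 0:
            raise ValueError(f"lambda_div must be nonnegative, got {self.lambda_div!r}")
        if not 0.0 <= self.adaptive_fraction <= 1.0:
            raise ValueError(
                f"adaptive_fraction must be in [0, 1], got {self.adaptive_fraction!r}"
            )
        if self.adaptive_boost <= 1.0 and self.adaptive_fraction > 0:
            raise ValueError(
                f"adaptive_boost must exceed 1, got {self.adaptive_boost!r}"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one simulated gene."""

    gene: str
    d_n: int
    d_s: int
    p_n: int
    p_s: int
    adaptive: bool = False
    categories: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "D_N": self.d_n,
            "D_S": self.d_s,
            "P_N": self.p_n,
            "P_S": self.p_s,
            "adaptive": self.adaptive,
            "categories": list(self.categories),
        }


def simulate_counts_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Draw a genome-wide MK count table under the configured regime.

    Counts are Poisson with gene-length-proportional means.  Neutral genes
    have the same expected nonsynonymous proportion (3/4) in divergence and
    polymorphism, so their expected DoS is zero; adaptive genes multiply
    the nonsynonymous divergence rate by ``adaptive_boost``, shifting DoS
    upward.
    """
    rng = np.random.default_rng(config.seed)
    f_nonsyn = NONSYN_OPPORTUNITY / (1.0 + NONSYN_OPPORTUNITY)
    rows, truths = [], []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene = f"gene_{i:0{width}d}"
        if isinstance(config.codons_per_gene, int):
            n_codons = config.codons_per_gene
        else:
            lo, hi = config.codons_per_gene
            n_codons = int(rng.integers(lo, hi + 1))
        adaptive = bool(rng.random() < config.adaptive_fraction)
        boost = config.adaptive_boost if adaptive else 1.0
        mu_div = config.lambda_div * n_codons
        mu_poly = config.theta_poly * n_codons
        d_n = int(rng.poisson(mu_div * f_nonsyn * boost))
        d_s = int(rng.poisson(mu_div * (1.0 - f_nonsyn)))
        p_n = int(rng.poisson(mu_poly * f_nonsyn))
        p_s = int(rng.poisson(mu_poly * (1.0 - f_nonsyn)))
        rows.append(
            {
                "gene": gene,
                "n_codons": n_codons,
                "D_N": d_n,
                "D_S": d_s,
                "P_N": p_n,
                "P_S": p_s,
            }
        )
        truths.append(
            TruthRecord(gene=gene, d_n=d_n, d_s=d_s, p_n=p_n, p_s=p_s, adaptive=adaptive)
        )
    table = pd.DataFrame(rows, columns=["gene", "n_codons", "D_N", "D_S", "P_N", "P_S"])
    return table, truths


def _candidate_bases(codon: str, position: int, synonymous: bool) -> list[str]:
    """Derived bases realizing a (non)synonymous sense change at a site."""
    out = []
    for base in _BASES:
        if base == codon[position]:
            continue
        derived = codon[:position] + base + codon[position + 1 :]
        if CODON_TO_AA[derived] == "*":
            continue
        if (CODON_TO_AA[derived] == CODON_TO_AA[codon]) == synonymous:
            out.append(base)
    return out


def _apply_events(
    anc_codons: list[str],
    events: Sequence[tuple[int, int, str]],
    n_strains: int,
    rng: np.random.Generator,
    gene: str,
) -> tuple[CodonAlignment, TruthRecord]:
    ancestral = "".join(anc_codons)
    strains = [bytearray(ancestral, "ascii") for _ in range(n_strains)]
    tallies = dict.fromkeys(EVENT_KINDS, 0)
    for codon_index, position, kind in events:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event type {kind!r}")
        codon = anc_codons[codon_index]
        synonymous = kind.startswith("synonymous")
        candidates = _candidate_bases(codon, position, synonymous)
        if not candidates:
            raise ValueError(
                f"unrealizable event {kind!r} at codon {codon_index} position "
                f"{position}: ancestral codon {codon} admits no such change"
            )
        derived = candidates[int(rng.integers(len(candidates)))]
        site = 3 * codon_index + position
        if kind.endswith("fixed"):
            carriers = range(n_strains)
        else:
            # derived-allele count uniform on {1, ..., n_strains - 1} so the
            # site is guaranteed to segregate
            k = int(rng.integers(1, n_strains))
            carriers = rng.choice(n_strains, size=k, replace=False)
        for s in carriers:
            strains[s][site] = ord(derived)
        tallies[kind] += 1
    alignment = CodonAlignment(
        gene=gene,
        ingroup=tuple(s.decode("ascii") for s in strains),
        outgroup1=ancestral,
        outgroup2=ancestral,
    )
    truth = TruthRecord(
        gene=gene,
        d_n=tallies["nonsynonymous-fixed"],
        d_s=tallies["synonymous-fixed"],
        p_n=tallies["nonsynonymous-poly"],
        p_s=tallies["synonymous-poly"],
    )
    return alignment, truth


def _validate_events(events: Sequence[tuple[int, int, str]], n_codons: int) -> None:
    seen = set()
    for codon_index, position, kind in events:
        if not 0 <= codon_index < n_codons:
            raise ValueError(f"event codon index {codon_index} out of range")
        if position not in (0, 1, 2):
            raise ValueError(f"event position {position} out of range")
        if (codon_index, position) in seen:
            raise ValueError(
                f"duplicate event position (codon {codon_index}, offset {position})"
            )
        seen.add((codon_index, position))


def simulate_codon_alignment(
    n_codons: int,
    n_strains: int,
    planted_events: Sequence[tuple[int, int, str]],
    seed: int = 0,
    gene: str = "gene",
) -> tuple[CodonAlignment, TruthRecord]:
    """Build an alignment differing from its ancestor exactly by the
    planted events.

    The ancestral sequence is drawn uniformly over sense codons; both
    outgroups carry it unchanged.  Fixed events place the derived base in
    every ingroup strain; polymorphic events place it in a random nonempty
    proper subset.  An event that cannot be realized from the generated
    ancestral codon (e.g. a synonymous change at a position with none)
    raises ``ValueError``.
    """
    if n_codons < 1 or n_strains < 2:
        raise ValueError("need n_codons >= 1 and n_strains >= 2")
    _validate_events(planted_events, n_codons)
    rng = np.random.default_rng(seed)
    anc_codons = [
        SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)
    ]
    return _apply_events(anc_codons, planted_events, n_strains, rng, gene)


def simulate_random_alignment(
    n_codons: int,
    n_strains: int,
    n_events: int,
    seed: int = 0,
    gene: str = "gene",
) -> tuple[CodonAlignment, TruthRecord]:
    """Plant ``n_events`` random realizable events at distinct sites.

    Event types are drawn uniformly; each is placed at a random unused
    site where the generated ancestral codon admits a change of that type.
    When a drawn type cannot be hosted anywhere (synonymous-capable sites
    are scarce in short sequences) another type is tried; ``ValueError``
    is raised only when no event of any type fits.
    """
    if n_events > 3 * n_codons:
        raise ValueError("more events than sites")
    rng = np.random.default_rng(seed)
    anc_codons = [
        SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)
    ]
    free = [(ci, p) for ci in range(n_codons) for p in range(3)]
    rng.shuffle(free)
    events: list[tuple[int, int, str]] = []
    for _ in range(n_events):
        order = list(rng.permutation(len(EVENT_KINDS)))
        placed = False
        for k in order:
            kind = EVENT_KINDS[k]
            synonymous = kind.startswith("synonymous")
            for j, (ci, p) in enumerate(free):
                if _candidate_bases(anc_codons[ci], p, synonymous):
                    events.append((ci, p, kind))
                    free.pop(j)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise ValueError(
                f"no remaining site can host any event in gene {gene!r}"
            )
    return _apply_events(anc_codons, events, n_strains, rng, gene)


def simulate_rnai_screen(
    gene_ids: Sequence[str],
    effect_genes: Iterable[str],
    effect_size: float,
    seed: int = 0,
    phenotype: str = "synthetic phenotype",
    category: str = "IS",
    tail: str = "upper",
) -> PhenotypeScreen:
    """Simulate standardized Z scores with planted effect genes.

    Genes without an effect draw Z ~ Normal(0, 1); effect genes draw
    Z ~ Normal(effect_size, 1).
    """
    gene_ids = [str(g) for g in gene_ids]
    effect = {str(g) for g in effect_genes}
    unknown = effect - set(gene_ids)
    if unknown:
        raise ValueError(f"effect genes not in screen: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, size=len(gene_ids))
    shift = np.array([effect_size if g in effect else 0.0 for g in gene_ids])
    return PhenotypeScreen(
        phenotype=phenotype,
        category=category,
        tail=tail,
        z_scores=dict(zip(gene_ids, (z + shift).tolist())),
    )


# ---------------------------------------------------------------------------
# writers

def write_alignment_fasta(alignment: CodonAlignment, path: str | Path) -> None:
    """Write one gene's alignment as multi-FASTA (ids strain_1..n plus the
    two outgroup roles)."""
    path = Path(path)
    with path.open("w") as fh:
        for i, seq in enumerate(alignment.ingroup, start=1):
            fh.write(f">strain_{i}\n{seq}\n")
        fh.write(f">outgroup_sim\n{alignment.outgroup1}\n")
        fh.write(f">outgroup_yak\n{alignment.outgroup2}\n")


def write_counts_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_screen(screen: PhenotypeScreen, path: str | Path) -> None:
    df = pd.DataFrame(
        {"gene": list(screen.z_scores), "Z": list(screen.z_scores.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=1, sort_keys=True)
        fh.write("\n")


def simulate_study_inputs(
    out_dir: str | Path,
    config: SimulationConfig,
    screens: Sequence[Mapping] = (),
) -> dict:
    """Write a complete synthetic input set for the end-to-end pipeline.

    Produces per-gene alignment FASTAs (event counts drawn from the
    config's Poisson regime), RNAi screen TSVs with a manifest, a category
    map covering the screens, and the planted truth as JSON.  Each screen
    spec is a mapping with keys ``phenotype, category, tail, n_effect,
    effect_size``.

    Returns a dict of the paths written plus the truth records.
    """
    out_dir = Path(out_dir)
    aln_dir = out_dir / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    f_nonsyn = NONSYN_OPPORTUNITY / (1.0 + NONSYN_OPPORTUNITY)
    width = len(str(config.n_genes))
    truths: list[TruthRecord] = []
    gene_ids: list[str] = []
    for i in range(config.n_genes):
        gene = f"gene_{i:0{width}d}"
        gene_ids.append(gene)
        if isinstance(config.codons_per_gene, int):
            n_codons = config.codons_per_gene
        else:
            lo, hi = config.codons_per_gene
            n_codons = int(rng.integers(lo, hi + 1))
        adaptive = bool(rng.random() < config.adaptive_fraction)
        boost = config.adaptive_boost if adaptive else 1.0
        n_by_kind = {
            "nonsynonymous-fixed": rng.poisson(
                config.lambda_div * n_codons * f_nonsyn * boost
            ),
            "synonymous-fixed": rng.poisson(
                config.lambda_div * n_codons * (1 - f_nonsyn)
            ),
            "nonsynonymous-poly": rng.poisson(
                config.theta_poly * n_codons * f_nonsyn
            ),
            "synonymous-poly": rng.poisson(
                config.theta_poly * n_codons * (1 - f_nonsyn)
            ),
        }
        aln_seed = int(rng.integers(2**31))
        aln, truth = _simulate_alignment_with_kind_counts(
            n_codons, config.n_strains, n_by_kind, aln_seed, gene
        )
        truths.append(
            TruthRecord(
                gene=gene,
                d_n=truth.d_n,
                d_s=truth.d_s,
                p_n=truth.p_n,
                p_s=truth.p_s,
                adaptive=adaptive,
            )
        )
        write_alignment_fasta(aln, aln_dir / f"{gene}.fasta")

    manifest_rows = []
    categories = {}
    for k, spec in enumerate(screens):
        effect = list(
            rng.choice(gene_ids, size=int(spec["n_effect"]), replace=False)
        )
        screen = simulate_rnai_screen(
            gene_ids,
            effect,
            float(spec["effect_size"]),
            seed=int(rng.integers(2**31)),
            phenotype=str(spec["phenotype"]),
            category=str(spec["category"]),
            tail=str(spec.get("tail", "upper")),
        )
        fname = f"screen_{k}.tsv"
        write_screen(screen, out_dir / fname)
        manifest_rows.append(
            {
                "phenotype": screen.phenotype,
                "category": screen.category,
                "tail": screen.tail,
                "file": fname,
            }
        )
        categories[screen.phenotype] = screen.category
    pd.DataFrame(
        manifest_rows, columns=["phenotype", "category", "tail", "file"]
    ).to_csv(out_dir / "screens.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"phenotype": p, "category": c} for p, c in categories.items()],
        columns=["phenotype", "category"],
    ).to_csv(out_dir / "categories.tsv", sep="\t", index=False)
    write_truth(truths, out_dir / "truth.json")
    return {
        "alignment_dir": aln_dir,
        "screen_manifest": out_dir / "screens.tsv",
        "category_map": out_dir / "categories.tsv",
        "truth": out_dir / "truth.json",
        "truth_records": truths,
    }


def _simulate_alignment_with_kind_counts(
    n_codons: int,
    n_strains: int,
    n_by_kind: Mapping[str, int],
    seed: int,
    gene: str,
) -> tuple[CodonAlignment, TruthRecord]:
    """Plant a fixed number of events of each kind at random distinct sites."""
    rng = np.random.default_rng(seed)
    anc_codons = [
        SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)
    ]
    free = [(ci, p) for ci in range(n_codons) for p in range(3)]
    rng.shuffle(free)
    events: list[tuple[int, int, str]] = []
    for kind in EVENT_KINDS:
        synonymous = kind.startswith("synonymous")
        for _ in range(int(n_by_kind.get(kind, 0))):
            for j, (ci, p) in enumerate(free):
                if _candidate_bases(anc_codons[ci], p, synonymous):
                    events.append((ci, p, kind))
                    free.pop(j)
                    break
            else:
                raise ValueError(
                    f"gene {gene!r}: too many events for {n_codons} codons"
                )
    return _apply_events(anc_codons, events, n_strains, rng, gene)
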