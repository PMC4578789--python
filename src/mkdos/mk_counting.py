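"""Polarized McDonald-Kreitman counting from codon alignments.

A per-gene alignment holds an ingroup population sample (here, *D.
melanogaster* strains) plus two outgroup sequences (the *D. simulans* and
*D. yakuba* roles).  Every alignment column is classified as an invariant
site, a polymorphism segregating within the ingroup, a fixed difference on
the ingroup lineage, or excluded, and the synonymous / nonsynonymous status
of each change is decided by translating the inferred ancestral codon with
the focal base swapped.

Polarization rule: a fixed difference is counted only where both outgroups
carry the same base and it differs from the ingroup's fixed base.  Columns
where the outgroups disagree are excluded from divergence counting but
remain eligible as polymorphisms.  An ``unpolarized`` mode counts pairwise
differences against the first outgroup alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "MKCounts",
    "SiteClassification",
    "read_codon_alignment",
    "classify_site",
    "count_gene",
    "count_alignments",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

_BASES = "ACGT"
_MISSING = frozenset("N-")
_ALPHABET = frozenset("ACGTN-")


@dataclass(frozen=True)
class MKCounts:
    """The 2x2 MK table for one gene plus the number of codons analyzed."""

    gene: str
    n_codons: int
    d_n: int
    d_s: int
    p_n: int
    p_s: int

    def __post_init__(self) -> None:
        for field in ("n_codons", "d_n", "d_s", "p_n", "p_s"):
            value = getattr(self, field)
            if not isinstance(value, (int,)) or value < 0:
                raise ValueError(f"{field} must be a nonnegative integer, got {value!r}")

    @property
    def divergence(self) -> int:
        return self.d_n + self.d_s

    @property
    def polymorphism(self) -> int:
        return self.p_n + self.p_s

    @property
    def total(self) -> int:
        return self.divergence + self.polymorphism


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned coding sequences: ingroup strains plus two outgroups.

    All sequences must have equal length divisible by three over the
    alphabet ``{A, C, G, T, N, -}``.
    """

    gene: str
    ingroup: tuple[str, ...]
    outgroup1: str
    outgroup2: str

    def __post_init__(self) -> None:
        if len(self.ingroup) < 2:
            raise ValueError("an alignment needs at least two ingroup sequences")
        seqs = (*self.ingroup, self.outgroup1, self.outgroup2)
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError(f"unequal sequence lengths in alignment {self.gene!r}")
        if length % 3 != 0:
            raise ValueError(
                f"alignment {self.gene!r} length {length} is not divisible by 3"
            )
        for s in seqs:
            bad = set(s) - _ALPHABET
            if bad:
                raise ValueError(
                    f"illegal characters {sorted(bad)} in alignment {self.gene!r}"
                )

    @property
    def n_strains(self) -> int:
        return len(self.ingroup)

    @property
    def length(self) -> int:
        return len(self.outgroup1)

    @property
    def n_codons(self) -> int:
        return self.length // 3


@dataclass(frozen=True)
class SiteClassification:
    """Outcome for one alignment column.

    ``kind`` is one of ``invariant``, ``polymorphism``, ``substitution``,
    ``excluded``.  Multi-allelic columns can contribute more than one
    polymorphism (one per derived allele), hence integer effect counts.
    """

    kind: str
    syn_poly: int = 0
    nonsyn_poly: int = 0
    syn_div: int = 0
    nonsyn_div: int = 0


def read_codon_alignment(
    path: str | Path,
    ingroup_ids: Sequence[str] | None = None,
    outgroup1_id: str = "outgroup_sim",
    outgroup2_id: str = "outgroup_yak",
    gene: str | None = None,
) -> CodonAlignment:
    """Load a per-gene multi-FASTA into a validated :class:`CodonAlignment`.

    When ``ingroup_ids`` is omitted, every record other than the two
    outgroups is treated as an ingroup strain, in file order.
    """
    path = Path(path)
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    for out_id in (outgroup1_id, outgroup2_id):
        if out_id not in records:
            raise ValueError(f"outgroup id {out_id!r} missing from {path}")
    if ingroup_ids is None:
        ingroup_ids = [i for i in records if i not in (outgroup1_id, outgroup2_id)]
    else:
        missing = [i for i in ingroup_ids if i not in records]
        if missing:
            raise ValueError(f"ingroup ids {missing} missing from {path}")
    return CodonAlignment(
        gene=gene if gene is not None else path.stem,
        ingroup=tuple(records[i] for i in ingroup_ids),
        outgroup1=records[outgroup1_id],
        outgroup2=records[outgroup2_id],
    )


def _consensus(bases: Iterable[str]) -> str:
    """Majority base; ties broken lexicographically for determinism."""
    counts = Counter(bases)
    top = max(counts.values())
    return min(b for b, c in counts.items() if c == top)


def classify_site(
    alignment: CodonAlignment,
    codon_index: int,
    position: int,
    polarization: str = "polarized",
) -> SiteClassification:
    """Classify one alignment column (0-based codon index and offset).

    Exclusion rules, applied in order:

    * any N/gap in any ingroup strain anywhere in the codon excludes all
      three of the codon's sites;
    * N/gap in a required outgroup excludes divergence classification
      (a monomorphic column then has no call at all and is excluded);
    * a monomorphic column where the two outgroups disagree is excluded
      (polarization failure);
    * columns whose ancestral or derived codon is a stop are excluded.

    Synonymous/nonsynonymous status is decided in the ancestral codon
    context: the other two positions are set to the inferred ancestral
    base and only the focal base is swapped.
    """
    if polarization not in ("polarized", "unpolarized"):
        raise ValueError(f"unknown polarization mode {polarization!r}")
    if not 0 <= codon_index < alignment.n_codons:
        raise IndexError(f"codon index {codon_index} out of range")
    if position not in (0, 1, 2):
        raise IndexError(f"within-codon position {position} out of range")

    start = 3 * codon_index
    ing = [s[start : start + 3] for s in alignment.ingroup]
    if any(ch in _MISSING for codon in ing for ch in codon):
        return SiteClassification("excluded")

    out1 = alignment.outgroup1[start : start + 3]
    out2 = alignment.outgroup2[start : start + 3]
    if polarization == "polarized":
        out_ok = not any(ch in _MISSING for ch in out1 + out2)
    else:
        out_ok = not any(ch in _MISSING for ch in out1)

    # Ancestral codon context: shared outgroup base where available,
    # otherwise the ingroup consensus.
    anc = []
    for p in range(3):
        if out_ok and (polarization == "unpolarized" or out1[p] == out2[p]):
            anc.append(out1[p])
        else:
            anc.append(_consensus(codon[p] for codon in ing))
    anc_codon = "".join(anc)

    alleles = sorted({codon[position] for codon in ing})

    if len(alleles) >= 2:
        # Segregating in the ingroup: a polymorphism regardless of the
        # outgroup state (fixed differences require ingroup monomorphism).
        if CODON_TO_AA[anc_codon] == "*":
            return SiteClassification("excluded")
        anc_aa = CODON_TO_AA[anc_codon]
        syn = nonsyn = 0
        for base in alleles:
            if base == anc[position]:
                continue
            derived = anc_codon[:position] + base + anc_codon[position + 1 :]
            aa = CODON_TO_AA[derived]
            if aa == "*":
                continue
            if aa == anc_aa:
                syn += 1
            else:
                nonsyn += 1
        if syn + nonsyn == 0:
            return SiteClassification("excluded")
        return SiteClassification("polymorphism", syn_poly=syn, nonsyn_poly=nonsyn)

    base = alleles[0]
    if not out_ok:
        return SiteClassification("excluded")
    if polarization == "polarized" and out1[position] != out2[position]:
        return SiteClassification("excluded")
    if CODON_TO_AA[anc_codon] == "*":
        return SiteClassification("excluded")
    if base == anc[position]:
        return SiteClassification("invariant")
    derived = anc_codon[:position] + base + anc_codon[position + 1 :]
    if CODON_TO_AA[derived] == "*":
        return SiteClassification("excluded")
    if CODON_TO_AA[derived] == CODON_TO_AA[anc_codon]:
        return SiteClassification("substitution", syn_div=1)
    return SiteClassification("substitution", nonsyn_div=1)


def count_gene(alignment: CodonAlignment, polarization: str = "polarized") -> MKCounts:
    """Sum site classifications into the gene's MK table.

    ``n_codons`` counts codons with at least one non-excluded position.
    """
    d_n = d_s = p_n = p_s = 0
    n_codons = 0
    for ci in range(alignment.n_codons):
        codon_used = False
        for pos in range(3):
            site = classify_site(alignment, ci, pos, polarization=polarization)
            if site.kind != "excluded":
                codon_used = True
            d_n += site.nonsyn_div
            d_s += site.syn_div
            p_n += site.nonsyn_poly
            p_s += site.syn_poly
        if codon_used:
            n_codons += 1
    return MKCounts(
        gene=alignment.gene, n_codons=n_codons, d_n=d_n, d_s=d_s, p_n=p_n, p_s=p_s
    )


def count_alignments(
    alignments: Iterable[CodonAlignment], polarization: str = "polarized"
):
    """Count a collection of alignments into a tidy table.

    Returns a pandas DataFrame with columns
    ``gene, n_codons, D_N, D_S, P_N, P_S``.
    """
    import pandas as pd

    rows = []
    for aln in alignments:
        c = count_gene(aln, polarization=polarization)
        rows.append(
            {
                "gene": c.gene,
                "n_codons": c.n_codons,
                "D_N": c.d_n,
                "D_S": c.d_s,
                "P_N": c.p_n,
                "P_S": c.p_s,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "n_codons", "D_N", "D_S", "P_N", "P_S"]
    )
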