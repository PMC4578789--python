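"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity over speed and deliberately avoids
the code paths it checks: exact rational hypergeometric tails, full
enumeration of Mann-Whitney splits, and a column-by-column alignment
audit using Biopython's translation.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

from Bio.Seq import Seq

MISSING = set("N-")


def exact_upper_tail(d_n: int, d_s: int, p_n: int, p_s: int) -> Fraction:
    """P(X >= d_n) for the 2x2 table with all margins fixed, as an exact
    rational computed by direct summation of hypergeometric masses."""
    total = d_n + d_s + p_n + p_s
    if total == 0:
        return Fraction(1)
    row = d_n + d_s  # divergence draws
    col = d_n + p_n  # nonsynonymous successes
    denom = comb(total, row)
    tail = Fraction(0)
    for x in range(d_n, min(row, col) + 1):
        if row - x > total - col:
            continue
        tail += Fraction(comb(col, x) * comb(total - col, row - x), denom)
    return tail


def mwu_exact_two_sided(a, b) -> float:
    """Two-sided Mann-Whitney p as 2 * min(tail) over full enumeration of
    every assignment of the pooled sample to the two groups."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)

    def u_stat(xs, ys):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in xs for y in ys
        )

    u_obs = u_stat(a, b)
    lower = upper = total = 0
    for pick in combinations(range(len(pooled)), n1):
        chosen = set(pick)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = u_stat(xs, ys)
        if u <= u_obs + 1e-12:
            lower += 1
        if u >= u_obs - 1e-12:
            upper += 1
        total += 1
    return min(1.0, 2.0 * min(lower, upper) / total)


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def audit_alignment(alignment, polarization: str = "polarized"):
    """Per-column audit of an alignment; returns (n_codons, D_N, D_S, P_N,
    P_S) under the documented classification rules."""
    n_strains = len(alignment.ingroup)
    d_n = d_s = p_n = p_s = 0
    codons_used = 0
    for ci in range(alignment.n_codons):
        ing = [seq[3 * ci : 3 * ci + 3] for seq in alignment.ingroup]
        o1 = alignment.outgroup1[3 * ci : 3 * ci + 3]
        o2 = alignment.outgroup2[3 * ci : 3 * ci + 3]
        if any(ch in MISSING for codon in ing for ch in codon):
            continue  # whole codon excluded
        if polarization == "polarized":
            outgroups_usable = all(ch not in MISSING for ch in o1 + o2)
        else:
            outgroups_usable = all(ch not in MISSING for ch in o1)

        def ancestral_base(p):
            if outgroups_usable and (polarization == "unpolarized" or o1[p] == o2[p]):
                return o1[p]
            column = [codon[p] for codon in ing]
            best = max(set(column), key=lambda base: (column.count(base), -ord(base)))
            return best

        anc = "".join(ancestral_base(p) for p in range(3))
        used = False
        for p in range(3):
            column = [codon[p] for codon in ing]
            distinct = set(column)
            if len(distinct) > 1:
                if _translate(anc) == "*":
                    continue
                counted = False
                for allele in sorted(distinct - {anc[p]}):
                    mutant = anc[:p] + allele + anc[p + 1 :]
                    if _translate(mutant) == "*":
                        continue
                    if _translate(mutant) == _translate(anc):
                        p_s += 1
                    else:
                        p_n += 1
                    counted = True
                used = used or counted
            else:
                if not outgroups_usable:
                    continue
                if polarization == "polarized" and o1[p] != o2[p]:
                    continue
                if _translate(anc) == "*":
                    continue
                fixed = column[0]
                if fixed == anc[p]:
                    used = True  # invariant site still analyzed
                    continue
                mutant = anc[:p] + fixed + anc[p + 1 :]
                if _translate(mutant) == "*":
                    continue
                if _translate(mutant) == _translate(anc):
                    d_s += 1
                else:
                    d_n += 1
                used = True
        if used:
            codons_used += 1
    return codons_used, d_n, d_s, p_n, p_s
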