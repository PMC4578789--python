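"""Bundled reference count tables for *Drosophila melanogaster* genes.

Two small tables from a published population-genomic survey of RNAi
knockdown phenotypes (15 *D. melanogaster* strains polarized against
*D. simulans* and *D. yakuba*) ship with the package as worked examples
and regression fixtures:

* :func:`positive_selection_table` — the 11 genes called adaptively
  evolving by the per-gene MK test (counts plus the printed one-tailed
  FET p-value and affected phenotypes);
* :func:`pleiotropic_gene_table` — the 20 genes significantly affecting
  three distinct phenotype categories (counts plus the printed DoS).

One row of the pleiotropic table (*eIF-4a*) is flagged
``dos_consistent=False``: its printed DoS cannot be reproduced from any
reading of its printed counts, so it is excluded from numeric checks.

The module also carries the survey-level single- vs multi-category
contingency counts and the phenotype -> category map used by the
pleiotropy examples.
"""

from __future__ import annotations

import pandas as pd

from .mk_counting import MKCounts
from .pleiotropy import CategoryMap

__all__ = [
    "positive_selection_table",
    "pleiotropic_gene_table",
    "mk_counts_for",
    "drosophila_category_map",
    "PLEIOTROPY_CONTINGENCY",
]

# gene -> (n_codons, D_N, D_S, P_N, P_S, printed one-tailed FET p, phenotypes)
_POSITIVE_SELECTION = {
    "nonC": (1852, 31, 39, 8, 53, 0.000076, ("Hippo signaling decrease", "Hedgehog signaling increase")),
    "Set2": (1408, 27, 37, 17, 73, 0.001521, ("Hedgehog signaling increase",)),
    "Nup153": (1294, 49, 49, 8, 30, 0.001623, ("Hedgehog signaling decrease", "RTK-Ras-ERK signaling decrease", "RTK-Ras-ERK signaling increase")),
    "Kib": (1076, 5, 26, 0, 62, 0.003269, ("Cell growth and viability",)),
    "pcm": (1072, 29, 28, 4, 19, 0.005061, ("Blood TE activity increase",)),
    "Cnot4": (860, 20, 20, 9, 34, 0.005227, ("Hippo signaling decrease",)),
    "ZC3H3": (414, 9, 8, 6, 31, 0.007610, ("Hippo signaling increase", "RTK-Ras-ERK signaling decrease")),
    "Nup205": (781, 11, 21, 2, 28, 0.007613, ("Wnt signaling activity",)),
    "Dref": (554, 6, 20, 0, 29, 0.007942, ("Hedgehog signaling increase", "RTK-Ras-ERK signaling decrease")),
    "Sik3": (571, 6, 7, 4, 37, 0.008072, ("Hippo signaling decrease",)),
    "RasGAP1": (979, 6, 26, 1, 54, 0.009106, ("Innate immunity", "RTK-Ras-ERK signaling increase")),
}

# gene -> (category codes, D_N, D_S, P_N, P_S, printed DoS, dos_consistent)
_PLEIOTROPIC = {
    "u-shaped": ("CR-IM-SR", 9, 25, 5, 34, 0.137, True),
    "kayak": ("SR-IM-IS", 5, 11, 5, 26, 0.151, True),
    "alphaCOP": ("SR-IM-IS", 2, 16, 5, 67, 0.042, True),
    "E(Pc)": ("SR-IM-IS", 14, 44, 9, 45, 0.075, True),
    "Rpn6": ("SR-CR-IS", 0, 6, 1, 15, -0.063, True),
    "CG30053": ("SR-CR-IS", 3, 10, 12, 8, -0.369, True),
    "nejire": ("GR-IS-TE", 16, 79, 9, 80, 0.067, True),
    "Tak1": ("GR-IM-IS", 6, 13, 3, 9, 0.066, True),
    "eIF-4a": ("GR-IM-IS", 14, 44, 9, 45, 0.273, False),
    "Rpt3": ("GR-CR-IS", 2, 7, 0, 16, 0.222, True),
    "Jra": ("GR-CR-IS", 6, 6, 0, 4, 0.500, True),
    "CG12054": ("GR-SR-IS", 0, 10, 4, 12, -0.250, True),
    "RpL22": ("GR-SR-IS", 1, 6, 0, 3, 0.143, True),
    "RpL7": ("GR-SR-IS", 3, 6, 0, 8, 0.333, True),
    "RpS13": ("GR-SR-IS", 2, 3, 0, 1, 0.400, True),
    "Sos": ("GR-SR-IS", 1, 31, 2, 49, -0.008, True),
    "zeste": ("GR-SR-IS", 3, 22, 0, 14, 0.120, True),
    "CG2807": ("GR-SR-IS", 1, 27, 0, 60, 0.036, True),
    "CycT": ("GR-SR-IS", 5, 29, 5, 15, -0.103, True),
    "Rpn12": ("GR-SR-CR", 1, 9, 0, 1, 0.100, True),
}

# Survey-level pleiotropy contingency: of 723 single-category genes 7 are
# adaptively evolving; of the 105 multi-category genes (85 two-category +
# 20 three-category) 4 are.
PLEIOTROPY_CONTINGENCY = {
    "adaptive_multi": 4,
    "multi": 105,
    "adaptive_single": 7,
    "single": 723,
}

_CATEGORY_MAP = {
    "Akt-TOR signaling decrease": "IS",
    "Akt-TOR signaling increase": "IS",
    "Hippo signaling decrease": "IS",
    "Hippo signaling increase": "IS",
    "JAK/STAT signaling decrease": "IS",
    "JAK/STAT signaling increase": "IS",
    "RTK-Ras-ERK signaling decrease": "IS",
    "RTK-Ras-ERK signaling increase": "IS",
    "Hedgehog signaling decrease": "SR",
    "Hedgehog signaling increase": "SR",
    "Notch signaling decrease": "SR",
    "Notch signaling increase": "SR",
    "Toll signaling decrease": "SR",
    "Toll signaling increase": "SR",
    "Wnt signaling activity": "SR",
    "Blood TE activity increase": "TE",
    "Burdock TE activity increase": "TE",
    "HeTA TE activity increase": "TE",
    "TAHRE TE activity increase": "TE",
    "Influenza replication decrease": "IM",
    "Innate immunity": "IM",
    "M. fortuitum infection decrease": "IM",
    "Cell size regulation": "GR",
    "Cell growth and viability": "GR",
    "CRY degradation": "CR",
    "Hypoxia induced transcription": "HY",
}


def positive_selection_table() -> pd.DataFrame:
    """The 11 adaptively evolving genes with counts and printed FET p."""
    rows = [
        {
            "gene": g,
            "n_codons": nc,
            "D_N": dn,
            "D_S": ds,
            "P_N": pn,
            "P_S": ps,
            "p_fet_printed": p,
            "phenotypes": ";".join(phen),
        }
        for g, (nc, dn, ds, pn, ps, p, phen) in _POSITIVE_SELECTION.items()
    ]
    return pd.DataFrame(rows)


def pleiotropic_gene_table() -> pd.DataFrame:
    """The 20 three-category genes with counts and printed DoS."""
    rows = [
        {
            "gene": g,
            "categories": cats,
            "D_N": dn,
            "D_S": ds,
            "P_N": pn,
            "P_S": ps,
            "dos_printed": dos,
            "dos_consistent": ok,
        }
        for g, (cats, dn, ds, pn, ps, dos, ok) in _PLEIOTROPIC.items()
    ]
    return pd.DataFrame(rows)


def mk_counts_for(gene: str) -> MKCounts:
    """Look a bundled gene up by name and return its :class:`MKCounts`."""
    if gene in _POSITIVE_SELECTION:
        nc, dn, ds, pn, ps, _, _ = _POSITIVE_SELECTION[gene]
        return MKCounts(gene=gene, n_codons=nc, d_n=dn, d_s=ds, p_n=pn, p_s=ps)
    if gene in _PLEIOTROPIC:
        _, dn, ds, pn, ps, _, _ = _PLEIOTROPIC[gene]
        return MKCounts(gene=gene, n_codons=0, d_n=dn, d_s=ds, p_n=pn, p_s=ps)
    raise KeyError(f"no bundled counts for gene {gene!r}")


def drosophila_category_map() -> CategoryMap:
    """Phenotype -> category map for the 26 surveyed RNAi phenotypes."""
    return CategoryMap(dict(_CATEGORY_MAP))
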