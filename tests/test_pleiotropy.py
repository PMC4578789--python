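"""Category counting, group comparisons, and the adaptive-enrichment FET."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from mkdos.datasets import drosophila_category_map, PLEIOTROPY_CONTINGENCY
from mkdos.phenotype_enrichment import GeneSet
from mkdos.pleiotropy import (
    CategoryMap,
    adaptive_enrichment,
    assign_categories,
    build_pleiotropy_table,
    length_bias_check,
    mwu_compare,
)

from conftest import random_mk_table
from oracles import exact_upper_tail, mwu_exact_two_sided


CMAP = drosophila_category_map()


def _set(phenotype, members):
    return GeneSet(phenotype=phenotype, category=CMAP.category_of(phenotype),
                   members=tuple(members))


class TestAssignCategories:
    def test_distinct_categories_counted_once(self):
        sets = [
            _set("Hippo signaling decrease", ["nonC", "x"]),   # IS
            _set("Hedgehog signaling increase", ["nonC"]),      # SR
            _set("Hippo signaling increase", ["x"]),            # IS again
        ]
        table = assign_categories(sets, CMAP)
        counts = dict(zip(table["gene"], table["n_categories"]))
        assert counts["nonC"] == 2  # IS + SR
        assert counts["x"] == 1     # two IS phenotypes collapse

    def test_gene_in_no_set_counts_zero(self):
        table = assign_categories([], CMAP, all_genes=["lonely"])
        assert table.loc[table["gene"] == "lonely", "n_categories"].item() == 0

    def test_unmapped_phenotype_named_in_error(self):
        bad = GeneSet(phenotype="unknown phenotype", category="??", members=("a",))
        with pytest.raises(KeyError, match="unknown phenotype"):
            assign_categories([bad], CMAP)

    def test_order_independent_and_idempotent(self):
        sets = [
            _set("Toll signaling decrease", ["a", "b"]),
            _set("CRY degradation", ["b", "c"]),
            _set("Innate immunity", ["a"]),
        ]
        forward = assign_categories(sets, CMAP)
        backward = assign_categories(sets[::-1], CMAP)
        doubled = assign_categories(sets + sets, CMAP)
        pd.testing.assert_frame_equal(forward, backward)
        pd.testing.assert_frame_equal(forward, doubled)


class TestMWU:
    def test_identical_multisets_give_one(self):
        assert mwu_compare([1, 2, 2, 3], [1, 2, 2, 3]) == 1.0

    def test_disjoint_small_groups_match_enumeration(self):
        # {1,2,3} vs {4,5,6}: 2 of the 20 splits are as extreme
        assert mwu_compare([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_symmetry(self):
        a, b = [1.0, 5.0, 2.0, 8.0], [3.0, 3.0, 7.0]
        assert mwu_compare(a, b) == pytest.approx(mwu_compare(b, a))

    def test_exact_path_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            a = rng.integers(0, 4, size=n1).astype(float)
            b = rng.integers(0, 4, size=n2).astype(float)
            assert mwu_compare(a, b) == pytest.approx(
                mwu_exact_two_sided(a, b), abs=1e-12
            )

    def test_large_sample_calibration(self):
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            if mwu_compare(a, b) < 0.05:
                rejections += 1
        # binomial 99.9% band around 0.05
        assert 5 <= rejections <= 40

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_compare([], [1.0])


class TestAdaptiveEnrichment:
    @staticmethod
    def _records(a, multi, c, single):
        return pd.DataFrame(
            {
                "n_categories": [2] * multi + [1] * single,
                "adaptive": [True] * a + [False] * (multi - a)
                + [True] * c + [False] * (single - c),
            }
        )

    def test_reproduces_published_contingency(self):
        k = PLEIOTROPY_CONTINGENCY
        records = self._records(
            k["adaptive_multi"], k["multi"], k["adaptive_single"], k["single"]
        )
        assert adaptive_enrichment(records) == pytest.approx(0.0397, abs=5e-4)

    def test_no_adaptive_genes_uninformative(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert adaptive_enrichment(self._records(0, 10, 0, 50)) == 1.0

    def test_matches_hypergeometric_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c, d = random_mk_table(rng, max_total=60)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            records = self._records(a, a + b, c, c + d)
            assert adaptive_enrichment(records) == pytest.approx(
                float(exact_upper_tail(a, b, c, d)), rel=1e-9, abs=1e-12
            )

    def test_nominal_rejection_rate_under_independence(self):
        # adaptive status assigned independently of category count
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 300
        for _ in range(reps):
            multi = rng.random(400) < 0.15
            adaptive = rng.random(400) < 0.05
            records = pd.DataFrame(
                {"n_categories": np.where(multi, 2, 1), "adaptive": adaptive}
            )
            if adaptive_enrichment(records) < 0.05:
                rejections += 1
        # FET is conservative: at or below nominal, allowing binomial noise
        assert rejections <= reps * 0.05 + 3 * math.sqrt(reps * 0.05 * 0.95)


class TestLengthBias:
    def test_constant_category_count_gives_zero_r2(self):
        records = pd.DataFrame(
            {"n_codons": [100, 200, 300, 400], "n_categories": [1, 1, 1, 1]}
        )
        r2, p = length_bias_check(records)
        assert r2 == 0.0 and math.isnan(p)

    def test_perfect_linear_relation_gives_r2_one(self):
        records = pd.DataFrame(
            {"n_codons": [100, 200, 300, 400], "n_categories": [1, 2, 3, 4]}
        )
        r2, _ = length_bias_check(records)
        assert r2 == pytest.approx(1.0)

    def test_independent_variables_give_tiny_r2(self):
        rng = np.random.default_rng(10)
        records = pd.DataFrame(
            {
                "n_codons": rng.integers(100, 2000, size=800),
                "n_categories": rng.integers(1, 4, size=800),
            }
        )
        r2, p = length_bias_check(records)
        assert r2 < 0.02
        assert 0.0 <= p <= 1.0

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            length_bias_check(pd.DataFrame({"n_codons": [1], "n_categories": [1]}))


def test_build_pleiotropy_table_flags_adaptive_powered_genes():
    sets = [
        _set("Hippo signaling decrease", ["g1", "g2"]),
        _set("Hedgehog signaling increase", ["g1"]),
    ]
    gene_table = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3"],
            "n_codons": [500, 300, 200],
            "dos": [0.2, -0.1, 0.0],
            "mk_p": [0.001, 0.5, 0.005],
            "has_power": [True, True, False],
        }
    )
    records = build_pleiotropy_table(sets, CMAP, gene_table, mk_alpha=0.01)
    by_gene = records.set_index("gene")
    assert by_gene.loc["g1", "n_categories"] == 2
    assert bool(by_gene.loc["g1", "adaptive"])
    assert not bool(by_gene.loc["g2", "adaptive"])  # p too large
    assert not bool(by_gene.loc["g3", "adaptive"])  # no power
    assert by_gene.loc["g3", "n_categories"] == 0
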