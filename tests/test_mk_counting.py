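"""Alignment parsing and column classification into the MK 2x2 table."""

import numpy as np
import pytest

from mkdos.mk_counting import (
    CodonAlignment,
    classify_site,
    count_gene,
    read_codon_alignment,
)
from mkdos.synthetic_data import simulate_codon_alignment, simulate_random_alignment

from oracles import audit_alignment


def _aln(ingroup, out1, out2, gene="g"):
    return CodonAlignment(gene=gene, ingroup=tuple(ingroup), outgroup1=out1, outgroup2=out2)


class TestReadCodonAlignment:
    def test_reads_strains_and_outgroups(self, tmp_path):
        path = tmp_path / "g1.fasta"
        seqs = {f"strain_{i}": "ATGAAA" for i in range(1, 16)}
        seqs["outgroup_sim"] = "ATGAAG"
        seqs["outgroup_yak"] = "ATGAAG"
        path.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        aln = read_codon_alignment(path)
        assert aln.n_strains == 15
        assert aln.n_codons == 2
        assert aln.gene == "g1"

    def test_missing_outgroup_id_names_it(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">strain_1\nATG\n>strain_2\nATG\n>outgroup_sim\nATG\n")
        with pytest.raises(ValueError, match="outgroup_yak"):
            read_codon_alignment(path)

    @pytest.mark.parametrize(
        "seqs, message",
        [
            (["ATGAA", "ATGAAA", "ATGAAA", "ATGAAA"], "unequal"),
            (["ATGA", "ATGA", "ATGA", "ATGA"], "divisible by 3"),
            (["ATGAAX", "ATGAAA", "ATGAAA", "ATGAAA"], "illegal"),
        ],
    )
    def test_rejects_malformed_alignments(self, tmp_path, seqs, message):
        path = tmp_path / "g.fasta"
        ids = ["strain_1", "strain_2", "outgroup_sim", "outgroup_yak"]
        path.write_text("".join(f">{i}\n{s}\n" for i, s in zip(ids, seqs)))
        with pytest.raises(ValueError, match=message):
            read_codon_alignment(path)


class TestClassifySite:
    def test_identical_column_is_invariant(self):
        aln = _aln(["GGT"] * 4, "GGT", "GGT")
        assert classify_site(aln, 0, 2).kind == "invariant"

    def test_fourfold_third_position_substitution_is_synonymous(self):
        # Gly codon GGx: ingroup fixed for T, both outgroups C
        aln = _aln(["GGT"] * 4, "GGC", "GGC")
        site = classify_site(aln, 0, 2)
        assert site.kind == "substitution"
        assert site.syn_div == 1 and site.nonsyn_div == 0

    def test_first_position_substitution_is_nonsynonymous(self):
        aln = _aln(["TTG"] * 4, "ATG", "ATG")  # Met -> Leu
        site = classify_site(aln, 0, 0)
        assert site.nonsyn_div == 1

    def test_outgroup_disagreement_excludes_monomorphic_site(self):
        aln = _aln(["AAA"] * 4, "GAA", "TAA")
        assert classify_site(aln, 0, 0).kind == "excluded"

    def test_segregating_site_is_polymorphism_even_when_derived(self):
        # ingroup segregates A/G, outgroups agree on C: two derived alleles
        aln = _aln(["AGG", "GGG", "GGG", "AGG"], "CGG", "CGG")
        site = classify_site(aln, 0, 0)
        assert site.kind == "polymorphism"
        assert site.syn_poly + site.nonsyn_poly == 2

    def test_ingroup_missing_data_excludes_whole_codon(self):
        aln = _aln(["ANA", "AAA", "AAA", "AAA"], "AAA", "AAA")
        for pos in range(3):
            assert classify_site(aln, 0, pos).kind == "excluded"

    def test_outgroup_gap_excludes_divergence_not_polymorphism(self):
        aln = _aln(["AAA", "AAG", "AAA", "AAA"], "AA-", "AAA")
        assert classify_site(aln, 0, 2).kind == "polymorphism"
        assert classify_site(aln, 0, 0).kind == "excluded"

    def test_stop_ancestral_codon_excluded(self):
        aln = _aln(["TGG"] * 4, "TGA", "TGA")  # ancestral TGA is a stop
        assert classify_site(aln, 0, 2).kind == "excluded"

    def test_out_of_range_indices_raise(self):
        aln = _aln(["AAA"] * 4, "AAA", "AAA")
        with pytest.raises(IndexError):
            classify_site(aln, 1, 0)
        with pytest.raises(IndexError):
            classify_site(aln, 0, 3)

    def test_unpolarized_mode_counts_pairwise_divergence(self):
        aln = _aln(["GGT"] * 4, "GGC", "GGA")
        assert classify_site(aln, 0, 2).kind == "excluded"
        site = classify_site(aln, 0, 2, polarization="unpolarized")
        assert site.kind == "substitution" and site.syn_div == 1


class TestCountGene:
    def test_identical_alignment_counts_nothing(self):
        aln = _aln(["ATGAAACCC"] * 5, "ATGAAACCC", "ATGAAACCC")
        c = count_gene(aln)
        assert (c.d_n, c.d_s, c.p_n, c.p_s) == (0, 0, 0, 0)
        assert c.n_codons == 3

    def test_all_codons_hit_by_missing_strain_count_zero(self):
        # one strain is entirely N: every codon excluded
        aln = _aln(["ATGAAA", "ATGAAA", "NNNNNN"], "ATGAAG", "ATGAAG")
        c = count_gene(aln)
        assert (c.n_codons, c.d_n, c.d_s, c.p_n, c.p_s) == (0, 0, 0, 0, 0)

    @pytest.mark.parametrize(
        "kind, expected",
        [
            ("synonymous-fixed", (0, 1, 0, 0)),
            ("nonsynonymous-fixed", (1, 0, 0, 0)),
            ("synonymous-poly", (0, 0, 0, 1)),
            ("nonsynonymous-poly", (0, 0, 1, 0)),
        ],
    )
    def test_single_planted_event_counts_once(self, kind, expected):
        pos = 1 if kind.startswith("non") else 2
        aln, _ = simulate_codon_alignment(10, 8, [(4, pos, kind)], seed=5)
        c = count_gene(aln)
        assert (c.d_n, c.d_s, c.p_n, c.p_s) == expected

    def test_strain_order_invariance(self):
        aln, _ = simulate_random_alignment(25, 12, 10, seed=11)
        base = count_gene(aln)
        rng = np.random.default_rng(0)
        for _ in range(5):
            order = rng.permutation(aln.n_strains)
            shuffled = CodonAlignment(
                gene=aln.gene,
                ingroup=tuple(aln.ingroup[i] for i in order),
                outgroup1=aln.outgroup1,
                outgroup2=aln.outgroup2,
            )
            assert count_gene(shuffled) == base

    def test_appending_invariant_codon_only_increments_n_codons(self):
        aln, _ = simulate_random_alignment(10, 6, 5, seed=2)
        extended = CodonAlignment(
            gene=aln.gene,
            ingroup=tuple(s + "ATG" for s in aln.ingroup),
            outgroup1=aln.outgroup1 + "ATG",
            outgroup2=aln.outgroup2 + "ATG",
        )
        before, after = count_gene(aln), count_gene(extended)
        assert after.n_codons == before.n_codons + 1
        assert (after.d_n, after.d_s, after.p_n, after.p_s) == (
            before.d_n, before.d_s, before.p_n, before.p_s,
        )

    def test_every_column_has_exactly_one_classification(self):
        aln, _ = simulate_random_alignment(15, 8, 8, seed=3)
        kinds = {"invariant", "polymorphism", "substitution", "excluded"}
        for ci in range(aln.n_codons):
            for pos in range(3):
                assert classify_site(aln, ci, pos).kind in kinds


@pytest.mark.parametrize("polarization", ["polarized", "unpolarized"])
def test_counts_match_column_audit_on_random_alignments(polarization):
    """Counting agrees with an independent per-column audit, including on
    alignments with injected missing data and outgroup disagreements."""
    rng = np.random.default_rng(42)
    for trial in range(300):
        n_codons = int(rng.integers(2, 31))
        n_strains = int(rng.integers(3, 12))
        n_events = int(rng.integers(0, min(12, 3 * n_codons // 2) + 1))
        aln, _ = simulate_random_alignment(
            n_codons, n_strains, n_events, seed=int(rng.integers(2**31))
        )
        seqs = [bytearray(s, "ascii") for s in aln.ingroup]
        out1 = bytearray(aln.outgroup1, "ascii")
        out2 = bytearray(aln.outgroup2, "ascii")
        # inject missing data and outgroup disagreements
        for _ in range(int(rng.integers(0, 6))):
            target = int(rng.integers(len(seqs) + 2))
            site = int(rng.integers(3 * n_codons))
            char = ord("N") if rng.random() < 0.5 else ord("-")
            if target < len(seqs):
                seqs[target][site] = char
            elif target == len(seqs):
                out1[site] = char
            else:
                out2[site] = char
        for _ in range(int(rng.integers(0, 4))):
            site = int(rng.integers(3 * n_codons))
            out2[site] = ord("ACGT"[int(rng.integers(4))])
        messy = CodonAlignment(
            gene=aln.gene,
            ingroup=tuple(s.decode() for s in seqs),
            outgroup1=out1.decode(),
            outgroup2=out2.decode(),
        )
        c = count_gene(messy, polarization=polarization)
        audit = audit_alignment(messy, polarization=polarization)
        assert (c.n_codons, c.d_n, c.d_s, c.p_n, c.p_s) == audit, f"trial {trial}"
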