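"""Translated search, HSP chaining, splice refinement, and GFF3 emission."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from ferlinkit.assembly import (
    HSP,
    AssemblyError,
    ContigTooLargeError,
    chain_hsps,
    emit_gene_model,
    read_gene_model,
    read_tabular_hits,
    refine_boundaries,
    translated_search,
    write_tabular_hits,
)
from ferlinkit.simulate import generate_locus


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestTranslatedSearch:
    def test_perfect_locus_one_hsp_per_exon(self, perfect_family):
        p = perfect_family[0]
        locus = generate_locus(p, 5, seed=99)
        hsps = translated_search(p.sequence, locus.contig_sequence)
        spans = sorted((h.s_start, h.s_end) for h in hsps if h.s_end - h.s_start > 60)
        truth = sorted(locus.truth_exons)
        assert len(spans) == len(truth)
        for (gs, ge), (ts, te) in zip(spans, truth):
            # split codons and trimmed low-scoring edge columns allowed:
            # junction refinement searches well beyond this slop
            assert abs(gs - ts) <= 12 and abs(ge - te) <= 12

    def test_minus_strand_hits_report_minus(self, perfect_family):
        p = perfect_family[0]
        locus = generate_locus(p, 3, strand="-", seed=7)
        hsps = translated_search(p.sequence, locus.contig_sequence)
        assert hsps
        assert all(h.strand == "-" for h in hsps)

    def test_random_contigs_give_zero_hsps(self, perfect_family):
        rng = np.random.default_rng(17)
        query = perfect_family[0].sequence
        for _ in range(15):
            contig = _random_dna(rng, 4000)
            assert translated_search(query, contig) == []

    def test_contig_over_cap_directs_to_tabular_input(self):
        with pytest.raises(ContigTooLargeError):
            translated_search("MKVL" * 10, "A" * 100, max_contig=50)


class TestTabularHits:
    def test_reversed_subject_coordinates_mean_minus_strand(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q\tc\t95.0\t100\t5\t0\t1\t100\t600\t301\t1e-50\t200\n"
        )
        (h,) = read_tabular_hits(path)
        assert h.strand == "-"
        assert (h.s_start, h.s_end) == (300, 600)
        assert (h.q_start, h.q_end) == (0, 100)

    def test_round_trip_identity(self, tmp_path):
        hsps = [
            HSP("q", "c", 0, 100, 300, 600, "+", 0, 150.0),
            HSP("q", "c", 120, 220, 900, 1200, "-", 0, 98.5),
        ]
        path = tmp_path / "hits.tsv"
        write_tabular_hits(hsps, path)
        assert read_tabular_hits(path) == hsps

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert read_tabular_hits(path) == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q\tc\tnot_enough_columns\n")
        with pytest.raises(AssemblyError, match="line 1"):
            read_tabular_hits(path)


def _enumerate_chains(hsps, max_intron=50_000, max_q_overlap=10):
    """Oracle: brute-force the best feasible chain by subset enumeration."""
    from ferlinkit.assembly import _chain_feasible

    best, best_score = None, -1.0
    for r in range(1, len(hsps) + 1):
        for combo in itertools.permutations(hsps, r):
            ok = all(
                _chain_feasible(a, b, max_intron, max_q_overlap)
                for a, b in zip(combo, combo[1:])
            )
            if ok:
                score = sum(h.score for h in combo)
                if score > best_score:
                    best, best_score = list(combo), score
    return best, best_score


class TestChaining:
    def test_single_hsp_single_chain(self):
        h = HSP("q", "c", 0, 50, 100, 250, "+", 1, 80.0)
        assert chain_hsps([h]) == [[h]]

    def test_two_colinear_hsps_form_one_chain(self):
        a = HSP("q", "c", 0, 50, 100, 250, "+", 1, 80.0)
        b = HSP("q", "c", 50, 100, 500, 650, "+", 2, 90.0)
        assert chain_hsps([a, b]) == [[a, b]]

    def test_opposite_strand_hsps_split_into_two_chains(self):
        a = HSP("q", "c", 0, 100, 100, 400, "+", 1, 120.0)
        b = HSP("q", "c", 5, 95, 1000, 1270, "-", 0, 110.0)
        chains = chain_hsps([a, b])
        assert len(chains) == 2
        assert {c[0].strand for c in chains} == {"+", "-"}

    def test_empty_input_rejected(self):
        with pytest.raises(AssemblyError):
            chain_hsps([])

    @pytest.mark.parametrize("seed", range(6))
    def test_best_chain_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hsps = []
        for _ in range(int(rng.integers(2, 6))):
            q0 = int(rng.integers(0, 300))
            qlen = int(rng.integers(10, 80))
            s0 = int(rng.integers(0, 20000))
            hsps.append(
                HSP("q", "c", q0, q0 + qlen, s0, s0 + 3 * qlen,
                    "+" if rng.random() < 0.7 else "-",
                    s0 % 3, float(rng.integers(30, 200)))
            )
        got = chain_hsps(hsps)[0]
        want, want_score = _enumerate_chains(hsps)
        assert sum(h.score for h in got) == want_score


class TestRefinement:
    def test_perfect_locus_all_junctions_refined_exactly(self, perfect_family):
        p = perfect_family[0]
        for strand, seed in (("+", 31), ("-", 32)):
            locus = generate_locus(p, 6, strand=strand, seed=seed)
            hsps = translated_search(p.sequence, locus.contig_sequence)
            chain = chain_hsps(hsps)[0]
            model = refine_boundaries(chain, locus.contig_sequence, p.sequence)
            assert model.exons == locus.truth_exons
            assert all(model.junction_refined)
            assert model.protein_sequence == p.sequence
            assert all(c == "refined" for c in model.exon_confidence)

    def test_window_zero_leaves_all_junctions_raw(self, perfect_family):
        p = perfect_family[0]
        locus = generate_locus(p, 4, seed=33)
        hsps = translated_search(p.sequence, locus.contig_sequence)
        chain = chain_hsps(hsps)[0]
        model = refine_boundaries(chain, locus.contig_sequence, p.sequence, window=0)
        assert not any(model.junction_refined)

    def test_noncanonical_intron_left_raw(self, perfect_family):
        p = perfect_family[0]
        locus = generate_locus(p, 4, seed=34)
        contig = list(locus.contig_sequence)
        # break the first intron's donor: GT -> GC, wiping every candidate
        # GT the refinement window around the (possibly trimmed) HSP end
        # could reach
        first_end = locus.truth_exons[0][1]
        for i in range(first_end - 48, first_end + 36):
            if contig[i] == "G" and contig[i + 1] == "T":
                contig[i + 1] = "C"
        contig = "".join(contig)
        hsps = translated_search(p.sequence, contig)
        chain = chain_hsps(hsps)[0]
        model = refine_boundaries(chain, contig, p.sequence)
        assert model.junction_refined[0] is False
        assert all(model.junction_refined[1:])

    def test_translation_round_trip_enforced(self, perfect_family):
        p = perfect_family[0]
        locus = generate_locus(p, 3, seed=35)
        hsps = translated_search(p.sequence, locus.contig_sequence)
        model = refine_boundaries(chain_hsps(hsps)[0], locus.contig_sequence, p.sequence)
        assert str(Seq(model.cds_sequence).translate()) == model.protein_sequence


class TestEmission:
    def _model(self, family, strand="+", seed=36, n_exons=3):
        p = family[0]
        locus = generate_locus(p, n_exons, strand=strand, seed=seed)
        hsps = translated_search(p.sequence, locus.contig_sequence)
        return (
            refine_boundaries(
                chain_hsps(hsps)[0], locus.contig_sequence, p.sequence,
                contig_id=locus.contig_id,
            ),
            locus,
        )

    def test_exon_rows_ascend_even_on_minus(self, perfect_family):
        for strand in "+-":
            model, locus = self._model(perfect_family, strand=strand)
            gff, fasta = emit_gene_model(model)
            starts = [
                int(line.split("\t")[3])
                for line in gff.splitlines()
                if not line.startswith("#") and line.split("\t")[2] == "exon"
            ]
            assert starts == sorted(starts)
            assert f"\t{strand}\t" in gff

    def test_gff_round_trip_equal_model(self, perfect_family):
        model, locus = self._model(perfect_family, strand="-", seed=37, n_exons=4)
        gff, _ = emit_gene_model(model, gene_id="g1")
        back = read_gene_model(gff, locus.contig_sequence)
        assert back.exons == model.exons
        assert back.cds_sequence == model.cds_sequence
        assert back.protein_sequence == model.protein_sequence
        assert back.exon_confidence == model.exon_confidence
        assert back.junction_refined == model.junction_refined
        assert back.strand == model.strand

    def test_invariant_violation_rejected(self):
        from ferlinkit.assembly import GeneModel

        with pytest.raises(AssemblyError):
            GeneModel(
                contig_id="c", strand="+", exons=((10, 5),),
                cds_sequence="ATG", protein_sequence="M",
                exon_confidence=("refined",),
            )
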