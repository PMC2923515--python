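"""Synthetic family/locus generator: planted truth and invariants."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import spearmanr

from ferlinkit.simulate import (
    PhylogenySpec,
    SimulatedProtein,
    TemplateError,
    default_template,
    generate_locus,
    plant_calcium_states,
    read_truth,
    simulate_family,
    validate_locus,
    write_truth,
)


class TestTemplates:
    def test_default_templates_valid_for_all_subtypes(self):
        for ftype in (1, 2):
            for st in "ABCDEF":
                tpl = default_template(ftype, st)
                assert tpl.ferlin_type == ftype
                assert "FerI" in tpl.ordered_domains

    def test_type2_template_never_contains_dysf(self):
        for st in "ABCDEF":
            assert not any(
                "DysF" in d for d in default_template(2, st).ordered_domains
            )

    def test_templates_end_c2e_c2f_tm_except_truncated(self):
        for ftype in (1, 2):
            for st in "ABCDE":
                assert default_template(ftype, st).ordered_domains[-3:] == (
                    "C2E", "C2F", "TM",
                )
            assert "TM" not in default_template(ftype, "F").ordered_domains

    def test_invalid_template_rejected(self):
        from ferlinkit.simulate import ArchitectureTemplate

        with pytest.raises(TemplateError):
            ArchitectureTemplate(1, "A", ("C2A", "C2B", "FerI", "C2C"))


class TestFamilySimulation:
    def test_one_protein_per_leaf_paralog(self, templates):
        t1, t2 = templates
        fam = simulate_family(
            t1, t2, PhylogenySpec("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);"), seed=0
        )
        assert len(fam) == 8
        assert {p.species_label for p in fam} == {"a", "b", "c", "d"}
        assert {p.paralog_label for p in fam} == {"F1", "F2"}

    def test_zero_rate_leaves_equal_ancestor(self, templates):
        t1, t2 = templates
        fam = simulate_family(
            t1, t2, PhylogenySpec("(a:0.7,b:0.7);"), rate_scale=0.0, seed=3
        )
        by_paralog = {}
        for p in fam:
            by_paralog.setdefault(p.paralog_label, set()).add(p.sequence)
        for seqs in by_paralog.values():
            assert len(seqs) == 1

    def test_duplication_two_to_six(self, templates):
        t1, t2 = templates
        ph = PhylogenySpec(
            "((v1:0.1,v2:0.1)vert:0.2,out:0.3);", duplication_events=(("vert", 3),)
        )
        fam = simulate_family(t1, t2, ph, seed=1)
        per_species = {}
        for p in fam:
            per_species.setdefault(p.species_label, []).append(p.paralog_label)
        assert len(per_species["v1"]) == 6
        assert len(per_species["v2"]) == 6
        assert len(per_species["out"]) == 2

    def test_reproducible_given_seed(self, templates):
        t1, t2 = templates
        ph = PhylogenySpec("(a:0.2,b:0.2);")
        one = simulate_family(t1, t2, ph, seed=9)
        two = simulate_family(t1, t2, ph, seed=9)
        assert [p.sequence for p in one] == [p.sequence for p in two]

    def test_truth_intervals_ordered_nonoverlapping(self, diverged_family):
        for p in diverged_family:
            prev = 0
            for _, s, e in p.truth_architecture:
                assert prev <= s < e
                prev = e

    def test_pdistance_monotone_in_path_length(self, templates):
        # expected divergence grows with tree path length (Spearman >= 0.9);
        # truth path lengths come from dendropy's patristic distances
        t1, t2 = templates
        newick = (
            "((a:0.02,b:0.04):0.03,((c:0.06,d:0.1):0.05,(e:0.12,f:0.2):0.02):0.04);"
        )
        spec = PhylogenySpec(newick)
        tree = spec.tree()
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        paths = []
        pdists = []
        for seed in range(5):
            fam = simulate_family(t1, t2, spec, seed=seed)
            seqs = {(p.species_label, p.paralog_label): p.sequence for p in fam}
            for x, y in itertools.combinations("abcdef", 2):
                a, b = seqs[(x, "F1")], seqs[(y, "F1")]
                pdists.append(sum(u != v for u, v in zip(a, b)) / len(a))
                paths.append(pdm.patristic_distance(taxa[x], taxa[y]))
        assert len(paths) >= 50
        rho = spearmanr(paths, pdists).statistic
        assert rho >= 0.9

    def test_c2ef_more_conserved_than_c2ab(self, templates):
        t1, t2 = templates
        diffs = []
        for seed in range(20):
            fam = simulate_family(t1, t2, PhylogenySpec("(a:0.25,b:0.25);"), seed=seed)
            by = {(p.species_label, p.paralog_label): p for p in fam}
            for paralog in ("F1", "F2"):
                pa, pb = by[("a", paralog)], by[("b", paralog)]
                for tail, head in (("C2E", "C2A"), ("C2F", "C2B")):
                    d_tail = _domain_pdist(pa, pb, tail)
                    d_head = _domain_pdist(pa, pb, head)
                    diffs.append(d_head - d_tail)
        assert np.mean(diffs) > 0
        # mean p-distance strictly lower in the C-terminal C2 domains
        assert np.mean([d for d in diffs]) > 0.05

    def test_anchor_states_never_mutated(self, templates):
        t1, t2 = templates
        fam = simulate_family(t1, t2, PhylogenySpec("(a:0.9,b:0.9);"), seed=4)
        for p in fam:
            for dom, states in p.truth_calcium_states.items():
                positions = p.truth_anchor_positions[dom]
                assert "".join(p.sequence[i] for i in positions) == states
                assert states == "DDDDD"


def _domain_pdist(pa, pb, name):
    a, b = pa.domain_sequence(name), pb.domain_sequence(name)
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestPlantCalcium:
    def test_planted_states_written_to_sequence(self, diverged_family):
        p = plant_calcium_states(diverged_family[0], {"C2A": "DDSDE"})
        pos = p.truth_anchor_positions["C2A"]
        assert "".join(p.sequence[i] for i in pos) == "DDSDE"
        assert p.truth_calcium_states["C2A"] == "DDSDE"

    def test_single_inactivating_position(self, diverged_family):
        p = plant_calcium_states(diverged_family[0], {"C2B": "DDSDE"})
        bad = [s for s in p.truth_calcium_states["C2B"] if s in "SN"]
        assert len(bad) == 1

    def test_random_states_deterministic(self, diverged_family):
        one = plant_calcium_states(diverged_family[0], {"C2E": None}, seed=7)
        two = plant_calcium_states(diverged_family[0], {"C2E": None}, seed=7)
        assert one.truth_calcium_states == two.truth_calcium_states

    def test_absent_domain_raises(self, diverged_family):
        with pytest.raises(KeyError):
            plant_calcium_states(diverged_family[0], {"C2Z": "DDDDD"})


class TestLocus:
    def test_single_exon_contains_uninterrupted_cds(self, perfect_family):
        p = perfect_family[0]
        locus = generate_locus(p, 1, seed=2)
        assert len(locus.truth_exons) == 1
        validate_locus(locus, p.sequence)
        s, e = locus.truth_exons[0]
        assert str(Seq(locus.contig_sequence[s:e]).translate()) == p.sequence

    @pytest.mark.parametrize("strand,n_exons", [("+", 4), ("-", 4), ("+", 9), ("-", 9)])
    def test_locus_invariants_hold(self, perfect_family, strand, n_exons):
        p = perfect_family[1]
        locus = generate_locus(p, n_exons, strand=strand, seed=13)
        validate_locus(locus, p.sequence)
        for intron in locus.intron_sequences():
            assert intron.startswith("GT") and intron.endswith("AG")

    def test_minus_strand_recovered_only_on_reverse_frames(self, perfect_family):
        # six-frame oracle: translate all frames, look for a long query chunk
        p = perfect_family[0]
        locus = generate_locus(p, 1, strand="-", seed=5)
        probe = p.sequence[100:160]
        fwd = str(Seq(locus.contig_sequence))
        rev = str(Seq(locus.contig_sequence).reverse_complement())
        in_forward = any(
            probe in str(Seq(fwd[f : f + 3 * ((len(fwd) - f) // 3)]).translate())
            for f in range(3)
        )
        in_reverse = any(
            probe in str(Seq(rev[f : f + 3 * ((len(rev) - f) // 3)]).translate())
            for f in range(3)
        )
        assert not in_forward
        assert in_reverse

    def test_protein_too_short_raises(self):
        tiny = SimulatedProtein(
            id="t", sequence="M" * 40, truth_architecture=(),
            truth_calcium_states={}, truth_anchor_positions={},
            paralog_label="F1", species_label="x",
        )
        with pytest.raises(ValueError):
            generate_locus(tiny, 10, seed=0)


class TestTruthRoundTrip:
    def test_round_trip_equal_objects(self, tmp_path, diverged_family, perfect_family):
        loci = [
            generate_locus(perfect_family[0], 3, seed=1),
            generate_locus(perfect_family[1], 4, strand="-", seed=2),
        ]
        write_truth(list(diverged_family[:3]), loci, tmp_path)
        proteins, read_loci = read_truth(tmp_path)
        by_id = {p.id: p for p in diverged_family[:3]}
        assert {p.id for p in proteins} == set(by_id)
        for p in proteins:
            assert p == by_id[p.id]
        assert sorted(l.contig_id for l in read_loci) == sorted(l.contig_id for l in loci)
        orig = {l.contig_id: l for l in loci}
        for l in read_loci:
            assert l == orig[l.contig_id]

    def test_empty_inputs_give_valid_empty_files(self, tmp_path):
        write_truth([], [], tmp_path)
        proteins, loci = read_truth(tmp_path)
        assert proteins == [] and loci == []

    def test_gff_exon_rows_sorted_by_start(self, tmp_path, perfect_family):
        locus = generate_locus(perfect_family[0], 6, strand="-", seed=3)
        write_truth([], [locus], tmp_path)
        starts = [
            int(line.split("\t")[3])
            for line in (tmp_path / "loci.gff3").read_text().splitlines()
            if not line.startswith("#") and line.split("\t")[2] == "exon"
        ]
        assert starts == sorted(starts)
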