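"""Synthetic ferlin families, genomes, and planted truth.

The generator emulates the statistical structure the downstream analysis
assumes: a two-paralog ancestral family (one DysF-bearing "Type 1" ferlin,
one non-DysF "Type 2") evolved along a species tree, an optional duplication
event expanding two paralogs to six on a vertebrate stem, per-domain
divergence with the C-terminal C2E/C2F domains evolving at half the family
rate and inter-domain linkers at twice it, planted calcium-anchor residue
states that the substitution process never touches, subtype-specific domain
losses, and genomic loci with canonical GT..AG introns.

Substitutions are a Poisson-style per-site process: a site at evolutionary
distance d is replaced with probability 1 - exp(-d) by a uniformly chosen
different residue.  Indels are confined to linker regions so that planted
domain coordinates and anchor offsets stay exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .library import (
    AMINO_ACIDS,
    C2_ANCHOR_OFFSETS,
    DYSF_NAMES,
    DomainSpec,
    build_default_library,
    is_c2_name,
    library_by_name,
)

#: per-domain substitution-rate multipliers; C-terminal C2 domains are the
#: most conserved modules of real ferlins, linkers the least.
DEFAULT_RATE_MULTIPLIERS = {"C2E": 0.5, "C2F": 0.5}
LINKER_MULTIPLIER = 2.0

DNA = "ACGT"

_T1_ORDER = (
    "C2A", "C2B", "FerI", "C2C", "FerA", "FerB",
    "DysF_outer_N", "DysF_inner_N", "DysF_inner_C", "DysF_outer_C",
    "C2D", "C2DE", "C2E", "C2F", "TM",
)
_T2_ORDER = (
    "C2A", "C2B", "FerI", "C2C", "FerB",
    "C2D", "C2DE", "C2E", "C2F", "TM",
)

#: presence/absence grammar of the topology subtypes: which optional
#: domains each subtype lacks.  Subtype F is the truncated form that also
#: loses the C-terminal TM.
SUBTYPE_ABSENT = {
    "A": frozenset(),
    "B": frozenset({"C2DE"}),
    "C": frozenset({"C2A"}),
    "D": frozenset({"C2A", "C2DE"}),
    "E": frozenset({"C2A", "C2DE", "FerB"}),
    "F": frozenset({"C2A", "C2D", "C2DE", "C2E", "C2F"}),
}


class TemplateError(ValueError):
    pass


@dataclass(frozen=True)
class ArchitectureTemplate:
    """Ordered domain plan for one simulated ferlin paralog."""

    ferlin_type: int
    subtype: str
    ordered_domains: tuple[str, ...]
    linker_length_range: tuple[int, int] = (15, 60)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.ferlin_type not in (1, 2):
            raise TemplateError("ferlin_type must be 1 or 2")
        if self.subtype not in SUBTYPE_ABSENT:
            raise TemplateError(f"unknown subtype {self.subtype!r}")
        dom = self.ordered_domains
        has_dysf = any(d in DYSF_NAMES for d in dom)
        if self.ferlin_type == 1 and not has_dysf:
            raise TemplateError("Type 1 template must contain the DysF block")
        if self.ferlin_type == 2 and has_dysf:
            raise TemplateError("Type 2 template must not contain DysF")
        for absent in SUBTYPE_ABSENT[self.subtype]:
            if absent in dom:
                raise TemplateError(
                    f"subtype {self.subtype} forbids domain {absent}"
                )
        if self.subtype != "F" and tuple(dom[-3:]) != ("C2E", "C2F", "TM"):
            raise TemplateError("template must end ...C2E,C2F,TM")
        joined = ",".join(dom)
        if "C2B,FerI,C2C" not in joined:
            raise TemplateError("template must contain C2B,FerI,C2C consecutively")
        lo, hi = self.linker_length_range
        if not (0 <= lo <= hi):
            raise TemplateError("bad linker length range")


def default_template(
    ferlin_type: int,
    subtype: str = "A",
    linker_length_range: tuple[int, int] = (15, 60),
) -> ArchitectureTemplate:
    base = _T1_ORDER if ferlin_type == 1 else _T2_ORDER
    absent = SUBTYPE_ABSENT[subtype]
    dom = tuple(d for d in base if d not in absent)
    if subtype == "F":
        dom = tuple(d for d in dom if d != "TM")
    return ArchitectureTemplate(ferlin_type, subtype, dom, linker_length_range)


@dataclass(frozen=True)
class PhylogenySpec:
    """Species tree plus duplication events.

    ``newick`` carries branch lengths in expected substitutions per site.
    Each duplication event is ``(edge_id, multiplicity)``: on the edge above
    the node identified by ``edge_id`` (an internal/leaf label, or the
    comma-joined sorted leaf labels of its clade), every paralog lineage is
    copied into ``multiplicity`` lineages that then diverge independently.
    """

    newick: str
    duplication_events: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        for _, m in self.duplication_events:
            if m < 1:
                raise ValueError("duplication multiplicity must be >= 1")
        t = self.tree()
        for edge in t.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    def tree(self) -> dendropy.Tree:
        t = dendropy.Tree.get(data=self.newick, schema="newick")
        if not t.leaf_nodes():
            raise ValueError("empty tree")
        return t


@dataclass(frozen=True)
class SimulatedProtein:
    id: str
    sequence: str
    truth_architecture: tuple[tuple[str, int, int], ...]
    truth_calcium_states: dict[str, str]
    truth_anchor_positions: dict[str, tuple[int, ...]]
    paralog_label: str
    species_label: str

    def __post_init__(self):
        prev = 0
        for _, s, e in self.truth_architecture:
            if not (prev <= s < e <= len(self.sequence)):
                raise ValueError("truth intervals must be ordered, non-overlapping")
            prev = e

    def domain_sequence(self, name: str) -> str:
        for dom, s, e in self.truth_architecture:
            if dom == name:
                return self.sequence[s:e]
        raise KeyError(name)


@dataclass(frozen=True)
class SimulatedLocus:
    contig_id: str
    contig_sequence: str
    gene_strand: str
    truth_exons: tuple[tuple[int, int], ...]  # ascending genomic coordinates
    encoded_protein_id: str

    def coding_sequence(self) -> str:
        cds = "".join(self.contig_sequence[s:e] for s, e in self.truth_exons)
        if self.gene_strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def intron_sequences(self) -> list[str]:
        introns = []
        for (s1, e1), (s2, e2) in zip(self.truth_exons, self.truth_exons[1:]):
            introns.append(self.contig_sequence[e1:s2])
        if self.gene_strand == "-":
            introns = [str(Seq(i).reverse_complement()) for i in reversed(introns)]
        return introns


# ---------------------------------------------------------------------------
# internal mutable representation


class _Lineage:
    """Residues plus parallel per-site domain labels and anchor ordinals."""

    __slots__ = ("residues", "labels", "anchor")

    def __init__(self, residues, labels, anchor):
        self.residues = residues  # list[str]
        self.labels = labels      # list[str | None]; None == linker
        self.anchor = anchor      # list[int]; -1 or anchor ordinal 0..4

    def clone(self) -> "_Lineage":
        return _Lineage(list(self.residues), list(self.labels), list(self.anchor))


def _assemble_ancestor(
    template: ArchitectureTemplate,
    lib: dict[str, DomainSpec],
    rng: np.random.Generator,
    ancestral_divergence: float,
) -> _Lineage:
    residues: list[str] = []
    labels: list[str | None] = []
    anchor: list[int] = []
    lo, hi = template.linker_length_range

    def add_linker():
        n = int(rng.integers(lo, hi + 1))
        for _ in range(n):
            residues.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
            labels.append(None)
            anchor.append(-1)

    add_linker()
    for name in template.ordered_domains:
        spec = lib[name]
        seq = spec.consensus
        if ancestral_divergence > 0:
            p = 1.0 - math.exp(-ancestral_divergence)
            alphabet = _TM_EVOLVE_ALPHABET if name == "TM" else AMINO_ACIDS
            seq = _substitute(rng, seq, p, frozen=set(spec.anchor_positions), alphabet=alphabet)
        for off, ch in enumerate(seq):
            residues.append(ch)
            labels.append(name)
            anchor.append(
                spec.anchor_positions.index(off) if off in spec.anchor_positions else -1
            )
        add_linker()
    return _Lineage(residues, labels, anchor)


#: TM segments evolve under strong hydrophobicity selection: substitutions
#: are drawn from the hydrophobic alphabet so the segment stays detectable.
_TM_EVOLVE_ALPHABET = "ILVFAM"


def _substitute(rng, seq: str, p: float, frozen: set[int], alphabet: str = AMINO_ACIDS) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < p)
    for i in hits:
        if int(i) in frozen:
            continue
        alt = [a for a in alphabet if a != out[i]] or list(alphabet)
        out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def _evolve(
    lin: _Lineage,
    rng: np.random.Generator,
    distance: float,
    rate_multipliers: dict[str, float],
    indel_rate: float,
) -> None:
    if distance < 0:
        raise ValueError("negative branch length")
    n = len(lin.residues)
    if n == 0 or distance == 0:
        pass
    else:
        mult = np.ones(n)
        for i, lab in enumerate(lin.labels):
            if lab is None:
                mult[i] = LINKER_MULTIPLIER
            else:
                mult[i] = rate_multipliers.get(lab, 1.0)
        p = 1.0 - np.exp(-distance * mult)
        hits = np.flatnonzero(rng.random(n) < p)
        for i in hits:
            if lin.anchor[i] >= 0:
                continue  # planted calcium-anchor states are never mutated
            cur = lin.residues[i]
            pool = _TM_EVOLVE_ALPHABET if lin.labels[i] == "TM" else AMINO_ACIDS
            alt = [a for a in pool if a != cur] or list(pool)
            lin.residues[i] = alt[rng.integers(len(alt))]
    if indel_rate > 0 and distance > 0:
        n_events = rng.poisson(indel_rate * distance * len(lin.residues))
        for _ in range(n_events):
            linker_pos = [i for i, lab in enumerate(lin.labels) if lab is None]
            if not linker_pos:
                break
            pos = linker_pos[rng.integers(len(linker_pos))]
            length = int(min(rng.geometric(0.5), 8))
            if rng.random() < 0.5:  # deletion of linker residues only
                run = [
                    i for i in range(pos, min(pos + length, len(lin.residues)))
                    if lin.labels[i] is None
                ]
                for i in reversed(run):
                    del lin.residues[i], lin.labels[i], lin.anchor[i]
            else:  # insertion of fresh linker residues
                ins = [AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] for _ in range(length)]
                lin.residues[pos:pos] = ins
                lin.labels[pos:pos] = [None] * length
                lin.anchor[pos:pos] = [-1] * length


def _lineage_to_protein(lin: _Lineage, species: str, paralog: str) -> SimulatedProtein:
    arch: list[tuple[str, int, int]] = []
    anchors: dict[str, list[int]] = {}
    start = None
    current = None
    for i, lab in enumerate(lin.labels + [None]):
        real = lab if i < len(lin.labels) else None
        if real != current:
            if current is not None:
                arch.append((current, start, i))
            current = real
            start = i
        if i < len(lin.labels) and lin.anchor[i] >= 0 and real is not None:
            anchors.setdefault(real, []).append(i)
    seq = "".join(lin.residues)
    states = {
        name: "".join(seq[p] for p in pos) for name, pos in anchors.items()
    }
    return SimulatedProtein(
        id=f"{species}|{paralog}",
        sequence=seq,
        truth_architecture=tuple(arch),
        truth_calcium_states=states,
        truth_anchor_positions={k: tuple(v) for k, v in anchors.items()},
        paralog_label=paralog,
        species_label=species,
    )


def _edge_ids(node) -> set[str]:
    ids = set()
    if node.taxon is not None and node.taxon.label:
        ids.add(node.taxon.label)
    if node.label:
        ids.add(node.label)
    leaves = sorted(
        lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
    )
    ids.add(",".join(leaves))
    return ids


def simulate_family(
    template_type1: ArchitectureTemplate,
    template_type2: ArchitectureTemplate,
    phylo: PhylogenySpec,
    rate_scale: float = 1.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    *,
    ancestral_divergence: float = 0.3,
    rate_multipliers: dict[str, float] | None = None,
    library: list[DomainSpec] | None = None,
) -> list[SimulatedProtein]:
    """Evolve one Type 1 and one Type 2 ancestral ferlin along a species tree.

    Returns one protein per (leaf species x surviving paralog lineage).
    ``rate_scale`` multiplies every branch length; ``ancestral_divergence``
    sets how far each paralog's ancestral domains sit from the library
    consensus (0.3 substitutions/site by default, so the two paralog
    ancestors are clearly distinct yet recognisable).
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be >= 0")
    if indel_rate < 0:
        raise ValueError("indel_rate must be >= 0")
    template_type1.validate()
    template_type2.validate()
    mults = DEFAULT_RATE_MULTIPLIERS if rate_multipliers is None else rate_multipliers
    lib = library_by_name(library)
    rng = np.random.default_rng(seed)
    tree = phylo.tree()

    anc1 = _assemble_ancestor(template_type1, lib, rng, ancestral_divergence)
    anc2 = _assemble_ancestor(template_type2, lib, rng, ancestral_divergence)
    events = {eid: m for eid, m in phylo.duplication_events}

    lineage_map = {tree.seed_node: [("F1", anc1), ("F2", anc2)]}
    out: list[SimulatedProtein] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_lin = lineage_map[node]
        else:
            parent_lin = lineage_map[node.parent_node]
            ids = _edge_ids(node)
            mult = next((events[i] for i in ids if i in events), 1)
            bl = (node.edge.length or 0.0) * rate_scale
            here = []
            for label, lin in parent_lin:
                copies = (
                    [label] if mult == 1
                    else [label + chr(ord("a") + k) for k in range(mult)]
                )
                for sub in copies:
                    child = lin.clone()
                    _evolve(child, rng, bl, mults, indel_rate)
                    here.append((sub, child))
            lineage_map[node] = here
        if node.is_leaf():
            species = node.taxon.label if node.taxon else (node.label or "leaf")
            for label, lin in lineage_map[node]:
                out.append(_lineage_to_protein(lin, species, label))
    return out


INACTIVATING = "SN"


def plant_calcium_states(
    protein: SimulatedProtein,
    per_domain_states: dict[str, str | None],
    seed: int = 0,
) -> SimulatedProtein:
    """Set the five calcium-anchor residues of named C2 domains.

    A value of ``None`` draws each anchor uniformly from {D, E, S, N, other}
    with the given seed.  Raises ``KeyError`` when the named domain is absent
    from the protein's planted architecture.
    """
    rng = np.random.default_rng(seed)
    seq = list(protein.sequence)
    states = dict(protein.truth_calcium_states)
    present = {d for d, _, _ in protein.truth_architecture}
    for name, requested in per_domain_states.items():
        if name not in present:
            raise KeyError(f"domain {name} absent from truth architecture")
        positions = protein.truth_anchor_positions[name]
        if requested is None:
            other = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
            requested = "".join(
                ("D", "E", "S", "N", other)[rng.integers(5)] for _ in positions
            )
        if len(requested) != len(positions):
            raise ValueError(f"{name}: need {len(positions)} anchor states")
        for pos, res in zip(positions, requested):
            seq[pos] = res
        states[name] = requested
    return replace(
        protein, sequence="".join(seq), truth_calcium_states=states
    )


# ---------------------------------------------------------------------------
# genomic loci

_CODONS_FOR = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()


def _random_dna(rng, n: int) -> str:
    letters = np.frombuffer(DNA.encode(), dtype="S1")
    return b"".join(rng.choice(letters, size=n)).decode()


def back_translate(protein_seq: str, rng: np.random.Generator) -> str:
    """Uniform choice over synonymous codons (standard code)."""
    return "".join(
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein_seq
    )


def generate_locus(
    protein: SimulatedProtein,
    n_exons: int,
    intron_length_range: tuple[int, int] = (80, 400),
    flank_length: int = 300,
    strand: str = "+",
    seed: int = 0,
    *,
    min_exon_nt: int = 90,
) -> SimulatedLocus:
    """Plant the back-translated CDS on a synthetic contig with GT..AG introns."""
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    if intron_length_range[0] < 4:
        raise ValueError("introns must be long enough to carry GT..AG")
    if strand not in "+-":
        raise ValueError("strand must be + or -")
    min_exon_nt = max(min_exon_nt, 30)
    rng = np.random.default_rng(seed)
    cds = back_translate(protein.sequence, rng)
    L = len(cds)
    if L < n_exons * min_exon_nt:
        raise ValueError(f"protein too short for {n_exons} exons")
    # stick-breaking: uniform cuts with guaranteed min exon length
    slack = L - n_exons * min_exon_nt
    offsets = np.sort(rng.integers(0, slack + 1, size=n_exons - 1))
    cuts = [int(offsets[i]) + min_exon_nt * (i + 1) for i in range(n_exons - 1)]
    pieces = []
    prev = 0
    for c in list(cuts) + [L]:
        pieces.append(cds[prev:c])
        prev = c

    lo, hi = intron_length_range
    contig_parts = [_random_dna(rng, flank_length)]
    exons = []
    pos = flank_length
    for i, piece in enumerate(pieces):
        exons.append((pos, pos + len(piece)))
        contig_parts.append(piece)
        pos += len(piece)
        if i < len(pieces) - 1:
            ilen = int(rng.integers(lo, hi + 1))
            intron = "GT" + _random_dna(rng, ilen - 4) + "AG"
            contig_parts.append(intron)
            pos += ilen
    contig_parts.append(_random_dna(rng, flank_length))
    contig = "".join(contig_parts)

    if strand == "-":
        Lc = len(contig)
        contig = str(Seq(contig).reverse_complement())
        exons = sorted((Lc - e, Lc - s) for s, e in exons)

    return SimulatedLocus(
        contig_id=f"locus|{protein.id}",
        contig_sequence=contig,
        gene_strand=strand,
        truth_exons=tuple(exons),
        encoded_protein_id=protein.id,
    )


def validate_locus(locus: SimulatedLocus, protein_seq: str) -> None:
    """Hard check of the locus invariants (GT..AG, exon length, translation)."""
    for s, e in locus.truth_exons:
        if e - s < 30:
            raise AssertionError("exon shorter than 30 nt")
    for intron in locus.intron_sequences():
        if not (intron.startswith("GT") and intron.endswith("AG")):
            raise AssertionError("non-canonical intron boundary")
    translated = str(Seq(locus.coding_sequence()).translate())
    if translated != protein_seq:
        raise AssertionError("exons do not translate back to the protein")


# ---------------------------------------------------------------------------
# truth serialization

_PROT_TSV_HEADER = (
    "protein_id\tspecies\tparalog\tdomain\tstart\tend\tanchor_positions\tcalcium_states\n"
)


def write_truth(
    proteins: list[SimulatedProtein],
    loci: list[SimulatedLocus],
    path: str | Path,
) -> None:
    """Serialize planted truth to FASTA + TSV + GFF3 under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "proteins.fasta", "w") as fh:
        for p in proteins:
            fh.write(f">{p.id} species={p.species_label} paralog={p.paralog_label}\n")
            fh.write(p.sequence + "\n")
    with open(path / "proteins.tsv", "w") as fh:
        fh.write(_PROT_TSV_HEADER)
        for p in proteins:
            for dom, s, e in p.truth_architecture:
                anch = ",".join(map(str, p.truth_anchor_positions.get(dom, ())))
                states = p.truth_calcium_states.get(dom, "")
                fh.write(
                    f"{p.id}\t{p.species_label}\t{p.paralog_label}\t"
                    f"{dom}\t{s}\t{e}\t{anch}\t{states}\n"
                )

    with open(path / "loci.fasta", "w") as fh:
        for lc in loci:
            fh.write(f">{lc.contig_id}\n{lc.contig_sequence}\n")
    with open(path / "loci.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for lc in loci:
            s0 = min(s for s, _ in lc.truth_exons) + 1
            e0 = max(e for _, e in lc.truth_exons)
            attrs = f"ID=gene:{lc.contig_id};protein_id={lc.encoded_protein_id}"
            fh.write(
                f"{lc.contig_id}\tferlinkit\tgene\t{s0}\t{e0}\t.\t{lc.gene_strand}\t.\t{attrs}\n"
            )
            for k, (s, e) in enumerate(sorted(lc.truth_exons)):
                fh.write(
                    f"{lc.contig_id}\tferlinkit\texon\t{s + 1}\t{e}\t.\t{lc.gene_strand}\t.\t"
                    f"ID=exon:{lc.contig_id}.{k};Parent=gene:{lc.contig_id}\n"
                )


def read_truth(path: str | Path) -> tuple[list[SimulatedProtein], list[SimulatedLocus]]:
    """Inverse of :func:`write_truth` (lossless round-trip)."""
    path = Path(path)
    seqs = {}
    meta = {}
    for rec in SeqIO.parse(str(path / "proteins.fasta"), "fasta"):
        seqs[rec.id] = str(rec.seq)
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        meta[rec.id] = fields

    arch: dict[str, list] = {}
    anchors: dict[str, dict] = {}
    states: dict[str, dict] = {}
    with open(path / "proteins.tsv") as fh:
        header = fh.readline()
        assert header == _PROT_TSV_HEADER
        for line in fh:
            pid, _, _, dom, s, e, anch, st = line.rstrip("\n").split("\t")
            arch.setdefault(pid, []).append((dom, int(s), int(e)))
            if anch:
                anchors.setdefault(pid, {})[dom] = tuple(map(int, anch.split(",")))
            if st:
                states.setdefault(pid, {})[dom] = st
    proteins = [
        SimulatedProtein(
            id=pid,
            sequence=seqs[pid],
            truth_architecture=tuple(arch.get(pid, [])),
            truth_calcium_states=states.get(pid, {}),
            truth_anchor_positions=anchors.get(pid, {}),
            paralog_label=meta[pid].get("paralog", ""),
            species_label=meta[pid].get("species", ""),
        )
        for pid in seqs
    ]

    contigs = {}
    loci_path = path / "loci.fasta"
    if loci_path.exists():
        for rec in SeqIO.parse(str(loci_path), "fasta"):
            contigs[rec.id] = str(rec.seq)
    loci_meta: dict[str, dict] = {}
    gff = path / "loci.gff3"
    if gff.exists():
        with open(gff) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cid, _, kind, s, e, _, strand, _, attrs = line.rstrip("\n").split("\t")
                info = loci_meta.setdefault(cid, {"exons": [], "strand": strand})
                attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                if kind == "gene":
                    info["protein_id"] = attr.get("protein_id", "")
                elif kind == "exon":
                    info["exons"].append((int(s) - 1, int(e)))
    loci = [
        SimulatedLocus(
            contig_id=cid,
            contig_sequence=contigs[cid],
            gene_strand=info["strand"],
            truth_exons=tuple(sorted(info["exons"])),
            encoded_protein_id=info.get("protein_id", ""),
        )
        for cid, info in loci_meta.items()
    ]
    return proteins, loci
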