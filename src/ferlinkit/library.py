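"""Reference domain library for ferlin annotation.

Ferlins are defined by a characteristic set of modules: up to seven tandem
C2 domains (labelled C2A..C2F plus C2DE by position), the ferlin-specific
FerI / FerA / FerB motifs, a nested DysF repeat (outer domain interrupted by
an inner copy), and a single C-terminal transmembrane (TM) segment.  The
bundled library carries one consensus sequence per module.  Consensus
strings are synthetic: they are generated once from a fixed seed so the
library is bit-identical across runs, and the seven C2 consensi are derived
from a common scaffold so that they are mutually alignable homologs, as the
real C2 repeats are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy values, used for TM detection.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

C2_NAMES = ("C2A", "C2B", "C2C", "C2D", "C2DE", "C2E", "C2F")
DYSF_NAMES = ("DysF_outer_N", "DysF_inner_N", "DysF_inner_C", "DysF_outer_C")
DOMAIN_NAMES = C2_NAMES + ("FerI", "FerA", "FerB") + DYSF_NAMES + ("TM",)

#: C2 consensus geometry: length and the five calcium-anchor offsets
#: (top-loop positions of the beta-sandwich, 0-based within the consensus).
C2_LENGTH = 105
C2_ANCHOR_OFFSETS = (32, 38, 90, 92, 98)

_LIBRARY_SEED = 714025

_NON_C2_LENGTHS = {
    "FerI": 60,
    "FerA": 66,   # ferlin-specific helical motif, Type 1 only
    "FerB": 76,   # near-universal ferlin motif
    "DysF_outer_N": 40,
    "DysF_inner_N": 52,
    "DysF_inner_C": 52,
    "DysF_outer_C": 40,
}

_TM_LENGTH = 23
_TM_ALPHABET = "ILVFAM"  # strongly hydrophobic residues


def is_c2_name(name: str) -> bool:
    """True for any C2 label, positional (C2_1) or anchored (C2A..C2F, C2DE)."""
    return name.startswith("C2")


@dataclass(frozen=True)
class DomainSpec:
    """A named reference domain with consensus sequence.

    ``anchor_positions`` holds the five calcium-anchor consensus indices for
    C2-type specs (strictly increasing, all < ``length``); it is empty for
    every non-C2 module.
    """

    name: str
    length: int
    consensus: str
    anchor_positions: tuple[int, ...] = field(default=())

    def __post_init__(self):
        if self.length != len(self.consensus):
            raise ValueError(f"{self.name}: length != len(consensus)")
        if list(self.anchor_positions) != sorted(set(self.anchor_positions)):
            raise ValueError(f"{self.name}: anchor positions must strictly increase")
        if self.anchor_positions and max(self.anchor_positions) >= self.length:
            raise ValueError(f"{self.name}: anchor position beyond domain")
        if is_c2_name(self.name):
            if len(self.anchor_positions) != 5:
                raise ValueError(f"{self.name}: C2 specs carry exactly 5 anchors")
        elif self.anchor_positions:
            raise ValueError(f"{self.name}: only C2 specs carry anchors")

    @property
    def is_c2(self) -> bool:
        return is_c2_name(self.name)


def random_protein(rng: np.random.Generator, n: int, alphabet: str = AMINO_ACIDS) -> str:
    letters = np.frombuffer(alphabet.encode(), dtype="S1")
    return b"".join(rng.choice(letters, size=n)).decode()


def mutate_sequence(
    rng: np.random.Generator,
    seq: str,
    p: float,
    frozen: tuple[int, ...] = (),
) -> str:
    """Per-site substitution with probability ``p`` to a uniform different residue.

    Positions listed in ``frozen`` are never touched.
    """
    out = list(seq)
    hit = rng.random(len(seq)) < p
    for i in np.flatnonzero(hit):
        if i in frozen:
            continue
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def build_default_library() -> list[DomainSpec]:
    """Bundled domain library; deterministic (bit-identical across calls).

    The seven C2 consensi are drawn as diverged copies of one scaffold
    (35% substitutions each, anchors frozen to aspartate), so that any C2
    instance remains alignable to the Synaptotagmin-style anchor reference
    (see :func:`anchor_reference_sequence`).  The remaining ferlin modules
    are mutually unrelated consensus sequences.
    """
    rng = np.random.default_rng(_LIBRARY_SEED)
    scaffold = list(random_protein(rng, C2_LENGTH))
    for pos in C2_ANCHOR_OFFSETS:
        scaffold[pos] = "D"
    scaffold = "".join(scaffold)

    specs = []
    for name in C2_NAMES:
        cons = mutate_sequence(rng, scaffold, 0.35, frozen=C2_ANCHOR_OFFSETS)
        specs.append(DomainSpec(name, C2_LENGTH, cons, C2_ANCHOR_OFFSETS))
    for name, length in _NON_C2_LENGTHS.items():
        specs.append(DomainSpec(name, length, random_protein(rng, length)))
    tm_letters = np.frombuffer(_TM_ALPHABET.encode(), dtype="S1")
    tm = b"".join(rng.choice(tm_letters, size=_TM_LENGTH)).decode()
    specs.append(DomainSpec("TM", _TM_LENGTH, tm))
    return specs


def library_by_name(library: list[DomainSpec] | None = None) -> dict[str, DomainSpec]:
    return {s.name: s for s in (library or build_default_library())}


def anchor_reference_sequence() -> str:
    """Synthetic stand-in for the Synaptotagmin I C2A calcium-anchor reference.

    It is the undiverged C2 scaffold with canonical aspartates at the five
    anchor loop positions, so every library C2 aligns to it at ~65% identity.
    """
    rng = np.random.default_rng(_LIBRARY_SEED)
    scaffold = list(random_protein(rng, C2_LENGTH))
    for pos in C2_ANCHOR_OFFSETS:
        scaffold[pos] = "D"
    return "".join(scaffold)
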