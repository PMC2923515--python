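"""Pairwise protein alignment with affine gaps.

Thin, deterministic wrapper around Biopython's ``PairwiseAligner`` exposing
the three operations the rest of the package builds on: optimal global and
local alignment under BLOSUM-style scoring, percent identity (EMBOSS
needle-style: matches over all alignment columns, end gaps penalized by
default), and alignment-mediated position mapping.

Scoring conventions: a gap of length k costs ``gap_open + (k-1)*gap_extend``;
``X`` scores 0 against everything; stop codons (``*``, arising from translated
genomic frames) are strongly penalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"
#: sentinel residue used by scanners to mask already-claimed regions;
#: scores so badly no optimal alignment crosses it.
MASK = "J"


class AlignmentError(ValueError):
    pass


@lru_cache(maxsize=None)
def scoring_matrix(name: str = "BLOSUM62"):
    """Load a substitution matrix, adjusted for this package's conventions."""
    try:
        base = substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise AlignmentError(f"unknown matrix name: {name!r}") from exc
    alphabet = str(base.alphabet)
    if MASK not in alphabet:
        alphabet += MASK
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in base.alphabet:
        for b in base.alphabet:
            mat[a, b] = base[a, b]
    for a in alphabet:
        if "X" in alphabet:
            mat["X", a] = mat[a, "X"] = 0.0
        if "*" in alphabet:
            mat["*", a] = mat[a, "*"] = -10.0
        mat[MASK, a] = mat[a, MASK] = -1000.0
    if "*" in alphabet:
        mat["*", "*"] = 1.0
    return mat


@dataclass(frozen=True)
class AlignParams:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    mode: str = "global"
    free_end_gaps: bool = False  # global mode only; for domain-vs-fragment use

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def replace(self, **kw) -> "AlignParams":
        d = self.__dict__ | kw
        return AlignParams(**d)


@dataclass
class AlignmentResult:
    """A pairwise alignment.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings covering the
    aligned region only (the full sequences in global mode).  ``a_start`` etc.
    give the region's coordinates in the ungapped inputs (0-based half-open).
    """

    aligned_a: str
    aligned_b: str
    score: float
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned strings differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(
            x == y and x != GAP for x, y in zip(self.aligned_a, self.aligned_b)
        )

    @property
    def identity(self) -> float:
        """Percent identity: 100 * matches / alignment_length (gaps included)."""
        if self.length == 0:
            return 0.0
        return 100.0 * self.matches / self.length

    @property
    def column_map(self) -> list[tuple[int | None, int | None]]:
        """Per column: (index in a | None, index in b | None)."""
        out = []
        i, j = self.a_start, self.b_start
        for x, y in zip(self.aligned_a, self.aligned_b):
            ia = i if x != GAP else None
            ib = j if y != GAP else None
            out.append((ia, ib))
            if x != GAP:
                i += 1
            if y != GAP:
                j += 1
        return out

    def identity_core(self) -> float:
        """Percent identity over columns between the first and last match
        (terminal gap runs excluded); used for unalignability checks."""
        cols = [
            (x, y)
            for x, y in zip(self.aligned_a, self.aligned_b)
            if not (x == GAP or y == GAP)
        ]
        if not cols:
            return 0.0
        return 100.0 * sum(x == y for x, y in cols) / len(cols)


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = scoring_matrix(params.matrix_name)
    al.open_gap_score = -params.gap_open
    al.extend_gap_score = -params.gap_extend
    al.mode = params.mode
    if params.mode == "global" and params.free_end_gaps:
        for kind in ("insertion", "deletion"):
            for side in ("left", "right"):
                setattr(al, f"open_{side}_{kind}_score", 0.0)
                setattr(al, f"extend_{side}_{kind}_score", 0.0)
    return al


def _check_inputs(a: str, b: str, params: AlignParams) -> None:
    if not a or not b:
        raise AlignmentError("empty sequence")
    alphabet = set(str(scoring_matrix(params.matrix_name).alphabet))
    bad = (set(a) | set(b)) - alphabet
    if bad:
        raise AlignmentError(f"residues outside matrix alphabet: {sorted(bad)}")


def global_align(a: str, b: str, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal affine-gap global alignment of ``a`` vs ``b``."""
    params = (params or AlignParams()).replace(mode="global")
    _check_inputs(a, b, params)
    aln = _aligner(params).align(a, b)
    best = aln[0]
    return AlignmentResult(
        aligned_a=str(best[0]),
        aligned_b=str(best[1]),
        score=float(aln.score),
        a_start=0,
        a_end=len(a),
        b_start=0,
        b_end=len(b),
    )


def local_align(a: str, b: str, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal local alignment; empty result (score 0) when nothing scores > 0."""
    params = (params or AlignParams()).replace(mode="local")
    _check_inputs(a, b, params)
    aln = _aligner(params).align(a, b)
    if aln.score <= 0 or len(aln) == 0:
        return AlignmentResult("", "", 0.0)
    best = aln[0]
    a0 = int(best.coordinates[0][0])
    a1 = int(best.coordinates[0][-1])
    b0 = int(best.coordinates[1][0])
    b1 = int(best.coordinates[1][-1])
    return AlignmentResult(
        aligned_a=str(best[0]),
        aligned_b=str(best[1]),
        score=float(aln.score),
        a_start=a0,
        a_end=a1,
        b_start=b0,
        b_end=b1,
    )


def percent_identity(a: str, b: str, params: AlignParams | None = None) -> float:
    """Identity of the optimal global alignment, to one decimal place."""
    return round(global_align(a, b, params).identity, 1)


def map_positions(
    result: AlignmentResult, positions_in_a: list[int]
) -> list[int | None]:
    """Map residue indices of ``a`` to the aligned indices in ``b`` (or None)."""
    lookup: dict[int, int | None] = {}
    for ia, ib in result.column_map:
        if ia is not None:
            lookup[ia] = ib
    out = []
    for p in positions_in_a:
        if p not in lookup:
            raise AlignmentError(f"position {p} outside aligned sequence a")
        out.append(lookup[p])
    return out


def self_score(seq: str, params: AlignParams | None = None) -> float:
    """Ungapped self-alignment score (sum of diagonal matrix entries)."""
    mat = scoring_matrix((params or AlignParams()).matrix_name)
    return float(sum(mat[c, c] for c in seq))
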