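"""Calcium-binding competence calls for C2 domains.

Classical calcium-sensitive C2 domains coordinate calcium ions through five
acidic loop residues (aspartates, with glutamate as a conservative
replacement).  Each extracted C2 domain is globally aligned (free end gaps,
so boundary wobble cannot masquerade as anchor loss) to an anchor reference
— a Synaptotagmin-I-C2A-style sequence whose five anchor positions are
known — and each anchor is mapped through the alignment and classified:

* ``canonical_D`` / ``conservative_E`` — competent (both count as conserved);
* ``inactivating_S_or_N`` — the substitutions repeatedly observed to ablate
  calcium-dependent phospholipid binding;
* ``other`` — any other residue; ``unaligned`` — anchor maps to a gap.

A domain is called ``conserved`` only when all five anchors are D or E.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .align import AlignParams, global_align, map_positions
from .library import C2_ANCHOR_OFFSETS, anchor_reference_sequence, is_c2_name

FREE_END_PARAMS = AlignParams(free_end_gaps=True)
MIN_ALIGN_IDENTITY = 15.0

STATUS_CANONICAL = "canonical_D"
STATUS_CONSERVATIVE = "conservative_E"
STATUS_INACTIVATING = "inactivating_S_or_N"
STATUS_OTHER = "other"
STATUS_UNALIGNED = "unaligned"


class AnchorSetError(ValueError):
    pass


class UnalignableDomainError(ValueError):
    """Domain shares too little similarity with the reference to call."""


@dataclass(frozen=True)
class AnchorSet:
    reference_id: str
    reference_sequence: str
    anchor_positions: tuple[int, ...]
    provenance: str = ""

    def __post_init__(self):
        if len(self.anchor_positions) != 5:
            raise AnchorSetError("anchor set must list exactly 5 positions")
        if list(self.anchor_positions) != sorted(set(self.anchor_positions)):
            raise AnchorSetError("anchor positions must strictly increase")
        for p in self.anchor_positions:
            if not 0 <= p < len(self.reference_sequence):
                raise AnchorSetError(f"anchor position {p} outside reference")
            if self.reference_sequence[p] not in "DE":
                raise AnchorSetError(
                    f"reference residue at anchor {p} is "
                    f"{self.reference_sequence[p]!r}, expected D or E"
                )


@dataclass(frozen=True)
class CalciumCall:
    domain_id: str
    residues: tuple[str, ...]   # mapped residue or "-" when unaligned
    statuses: tuple[str, ...]

    @property
    def n_conserved(self) -> int:
        return sum(s in (STATUS_CANONICAL, STATUS_CONSERVATIVE) for s in self.statuses)

    @property
    def overall(self) -> str:
        return "conserved" if self.n_conserved == 5 else "not_conserved"


def default_anchor_set() -> AnchorSet:
    """Bundled synthetic anchor reference (Synaptotagmin I C2A stand-in)."""
    return AnchorSet(
        reference_id="SYT1_C2A_synthetic",
        reference_sequence=anchor_reference_sequence(),
        anchor_positions=C2_ANCHOR_OFFSETS,
        provenance="synthetic reference generated with the bundled library",
    )


def load_anchor_set(reference_fasta: str | Path, annotation_tsv: str | Path) -> AnchorSet:
    """Load reference FASTA + 2-column anchor annotation.

    The annotation file holds ``reference_id<TAB>comma-separated 1-based
    positions``; validation enforces exactly five acidic anchor residues.
    """
    records = list(SeqIO.parse(str(reference_fasta), "fasta"))
    if not records:
        raise AnchorSetError("reference FASTA is empty")
    by_id = {r.id: str(r.seq) for r in records}
    with open(annotation_tsv) as fh:
        rows = [
            line.rstrip("\n").split("\t")
            for line in fh
            if line.strip() and not line.startswith("#")
        ]
    if not rows:
        raise AnchorSetError("anchor annotation is empty")
    ref_id, positions = rows[0][0], rows[0][1]
    if ref_id not in by_id:
        raise AnchorSetError(f"reference id {ref_id!r} not in FASTA")
    anchors = tuple(int(x) - 1 for x in positions.split(","))
    return AnchorSet(
        reference_id=ref_id,
        reference_sequence=by_id[ref_id],
        anchor_positions=anchors,
        provenance=f"loaded from {annotation_tsv}",
    )


def call_calcium_residues(
    c2_sequence: str,
    anchors: AnchorSet | None = None,
    params: AlignParams | None = None,
    domain_id: str = "",
) -> CalciumCall:
    """Map the five anchors onto one extracted C2 domain and call each."""
    anchors = anchors or default_anchor_set()
    params = params or FREE_END_PARAMS
    res = global_align(anchors.reference_sequence, c2_sequence, params)
    if res.identity_core() < MIN_ALIGN_IDENTITY:
        raise UnalignableDomainError(
            f"{domain_id or 'domain'}: alignment identity below "
            f"{MIN_ALIGN_IDENTITY}% — unalignable domain"
        )
    mapped = map_positions(res, list(anchors.anchor_positions))
    residues = []
    statuses = []
    for m in mapped:
        if m is None:
            residues.append("-")
            statuses.append(STATUS_UNALIGNED)
            continue
        r = c2_sequence[m]
        residues.append(r)
        if r == "D":
            statuses.append(STATUS_CANONICAL)
        elif r == "E":
            statuses.append(STATUS_CONSERVATIVE)
        elif r in "SN":
            statuses.append(STATUS_INACTIVATING)
        else:
            statuses.append(STATUS_OTHER)
    return CalciumCall(domain_id=domain_id, residues=tuple(residues), statuses=tuple(statuses))


C2_ROW_ORDER = ("C2A", "C2B", "C2C", "C2D", "C2DE", "C2E", "C2F")


def conservation_table(
    proteins: dict[str, str],
    architectures: dict[str, "object"],
    anchors: AnchorSet | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-protein calcium-conservation grid (rows = C2 labels).

    Cells read ``Yes (5/5)`` / ``No (n/5)``; blank where the protein lacks
    that C2.  When ``groups`` maps protein ids to group names, one summary
    column per group is appended, "Yes" only when every member is conserved.
    """
    anchors = anchors or default_anchor_set()
    cols: dict[str, dict[str, str]] = {}
    conserved: dict[str, dict[str, bool]] = {}
    for pid, seq in proteins.items():
        arch = architectures[pid]
        col: dict[str, str] = {}
        ok: dict[str, bool] = {}
        for hit in arch.hits:
            name = hit.domain_name
            if not is_c2_name(name) or name not in C2_ROW_ORDER:
                continue
            try:
                call = call_calcium_residues(
                    seq[hit.start : hit.end], anchors, domain_id=f"{pid}:{name}"
                )
            except UnalignableDomainError:
                col[name] = "unalignable"
                ok[name] = False
                continue
            word = "Yes" if call.overall == "conserved" else "No"
            col[name] = f"{word} ({call.n_conserved}/5)"
            ok[name] = call.overall == "conserved"
        cols[pid] = col
        conserved[pid] = ok
    table = pd.DataFrame(
        {pid: [cols[pid].get(row, "") for row in C2_ROW_ORDER] for pid in proteins},
        index=list(C2_ROW_ORDER),
    )
    if groups:
        for gname in sorted(set(groups.values())):
            members = [p for p, g in groups.items() if g == gname and p in conserved]
            summary = []
            for row in C2_ROW_ORDER:
                calls = [conserved[m][row] for m in members if row in conserved[m]]
                summary.append("" if not calls else ("Yes" if all(calls) else "No"))
            table[f"group:{gname}"] = summary
    return table
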