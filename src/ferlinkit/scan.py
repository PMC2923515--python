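"""Domain scanning and ferlin architecture classification.

A protein is scanned against the reference domain library by iterated local
alignment: each consensus is aligned, the best hit recorded, its span masked,
and the scan repeated until the score drops below the relaxed threshold.
Scores are normalized by the consensus self-score, and hits are two-tier:
``confident`` (normalized score >= 0.45) or ``marginal`` (>= 0.30), with
marginal hits reported rather than dropped — diverged domains should be
flagged, never silently lost.  The transmembrane segment gets a dedicated
hydrophobicity detector (19-residue Kyte-Doolittle window over the final 60
residues) because short hydrophobic stretches align poorly.

C2 domains are then named positionally: the two C2s flanking FerI are C2B and
C2C, the two C2s adjacent to the C-terminal TM are C2E and C2F, anything
N-terminal of C2B is C2A, and the one or two C2s between C2C and C2E are C2D
and C2DE.  Architectures are classified into Type 1 (DysF-bearing) vs Type 2
(non-DysF) and topology subtypes A-F by their presence/absence grammar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .align import MASK, AlignParams, local_align, self_score
from .library import (
    DYSF_NAMES,
    KYTE_DOOLITTLE,
    DomainSpec,
    build_default_library,
    is_c2_name,
)
from .simulate import SUBTYPE_ABSENT

logger = logging.getLogger("ferlinkit")

PRIMARY_THRESHOLD = 0.45
RELAXED_THRESHOLD = 0.30
TM_WINDOW = 19
TM_KD_CUTOFF = 1.6
TM_SEARCH_TAIL = 60

C2_POSITIONAL_ORDER = ("C2A", "C2B", "C2C", "C2D", "C2DE", "C2E", "C2F")


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHit:
    domain_name: str
    start: int
    end: int
    score: float
    normalized_score: float
    confident: bool

    def __post_init__(self):
        if not self.start < self.end:
            raise ScanError("hit start must precede end")
        if not (0 < self.normalized_score <= 1):
            raise ScanError("normalized score must lie in (0, 1]")

    @property
    def marginal(self) -> bool:
        return not self.confident

    def overlap(self, other: "DomainHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Architecture:
    protein_id: str
    hits: list[DomainHit]
    ferlin_type: int | None = None
    subtype: str | None = None
    is_minimal_ferlin: bool = False
    partial_dysf: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def domain_names(self) -> list[str]:
        return [h.domain_name for h in self.hits]

    def topology_string(self) -> str:
        parts: list[str] = []
        i = 0
        names = self.domain_names
        while i < len(names):
            if names[i] == "DysF_outer_N" and tuple(names[i : i + 4]) == DYSF_NAMES:
                parts.append("DysF[n]")
                i += 4
            elif names[i] in DYSF_NAMES:
                parts.append("DysF[partial]")
                while i < len(names) and names[i] in DYSF_NAMES:
                    i += 1
            else:
                parts.append(names[i])
                i += 1
        return "-".join(parts)


def _kd_profile(seq: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])


def detect_tm(seq: str) -> DomainHit | None:
    """Best 19-residue Kyte-Doolittle window within the last 60 residues."""
    tail_from = max(0, len(seq) - TM_SEARCH_TAIL)
    kd = _kd_profile(seq[tail_from:])
    if len(kd) < TM_WINDOW:
        return None
    means = np.convolve(kd, np.ones(TM_WINDOW) / TM_WINDOW, mode="valid")
    best = int(np.argmax(means))
    mean = float(means[best])
    if mean <= 0:
        return None
    start = tail_from + best
    return DomainHit(
        domain_name="TM",
        start=start,
        end=start + TM_WINDOW,
        score=mean,
        normalized_score=min(1.0, mean / 4.5),
        confident=mean > TM_KD_CUTOFF,
    )


def scan_domains(
    protein: str,
    library: list[DomainSpec] | None = None,
    params: AlignParams | None = None,
    primary: float = PRIMARY_THRESHOLD,
    relaxed: float = RELAXED_THRESHOLD,
    max_hits_per_domain: int = 10,
) -> list[DomainHit]:
    """Locate library domains in ``protein``; overlaps resolved greedily.

    Returns confident and marginal hits, sorted by start coordinate.
    """
    if not protein:
        raise ScanError("empty protein")
    library = library or build_default_library()
    params = params or AlignParams()
    raw: list[DomainHit] = []
    for spec in library:
        if spec.name == "TM":
            continue
        ref_score = self_score(spec.consensus, params)
        if ref_score <= 0:
            raise ScanError(f"{spec.name}: non-positive self-score")
        work = list(protein)
        for _ in range(max_hits_per_domain):
            res = local_align(spec.consensus, "".join(work), params)
            norm = res.score / ref_score
            if norm < relaxed or res.length == 0:
                break
            span = (res.b_start, res.b_end)
            if span[1] - span[0] >= 0.4 * spec.length:
                raw.append(
                    DomainHit(
                        domain_name=spec.name,
                        start=span[0],
                        end=span[1],
                        score=res.score,
                        normalized_score=min(1.0, norm),
                        confident=norm >= primary,
                    )
                )
            for i in range(*span):
                work[i] = MASK
    tm_specs = [s for s in library if s.name == "TM"]
    if tm_specs:
        spec = tm_specs[0]
        ref_score = self_score(spec.consensus, params)
        res = local_align(spec.consensus, protein, params)
        norm = res.score / ref_score if ref_score > 0 else 0.0
        if norm >= primary and res.length > 0:
            raw.append(
                DomainHit(
                    "TM", res.b_start, res.b_end, res.score,
                    min(1.0, norm), True,
                )
            )
        else:
            tm = detect_tm(protein)
            if tm is not None and tm.confident:
                raw.append(tm)
    return resolve_overlaps(raw)


def resolve_overlaps(hits: list[DomainHit], tolerance: int = 5) -> list[DomainHit]:
    """Greedy resolution by descending normalized score.

    Hits overlapping a kept hit by more than ``tolerance`` residues are
    dropped; smaller overlaps are trimmed off the lower-scoring hit.
    """
    kept: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (-h.normalized_score, h.start, h.domain_name)):
        trimmed = h
        ok = True
        for k in kept:
            ov = trimmed.overlap(k)
            if ov == 0:
                continue
            if ov > tolerance:
                ok = False
                break
            if trimmed.start < k.start:
                trimmed = replace(trimmed, end=k.start)
            else:
                trimmed = replace(trimmed, start=k.end)
            if trimmed.end - trimmed.start < 5:
                ok = False
                break
        if ok:
            kept.append(trimmed)
    return sorted(kept, key=lambda h: h.start)


def name_c2_domains(hits: list[DomainHit]) -> tuple[list[DomainHit], list[str]]:
    """Relabel C2 hits positionally (A..F, DE) using FerI and TM as anchors.

    Without either anchor the C2s keep positional labels C2_1, C2_2, ... and
    a warning is issued.
    """
    hits = sorted(hits, key=lambda h: h.start)
    warnings: list[str] = []
    c2s = [h for h in hits if is_c2_name(h.domain_name)]
    feri = next((h for h in hits if h.domain_name == "FerI"), None)
    tms = [h for h in hits if h.domain_name == "TM"]
    tm = tms[-1] if tms else None

    labels: dict[int, str] = {}  # index into c2s -> label
    if feri is None and tm is None:
        for i in range(len(c2s)):
            labels[i] = f"C2_{i + 1}"
        if c2s:
            warnings.append("W_C2_NAMES: no FerI or TM anchor; positional labels used")
        return _apply_c2_labels(hits, c2s, labels), warnings

    idx_b = idx_c = None
    if feri is not None:
        before = [i for i, h in enumerate(c2s) if h.end <= feri.start]
        after = [i for i, h in enumerate(c2s) if h.start >= feri.end]
        if before:
            idx_b = before[-1]
            labels[idx_b] = "C2B"
        if after:
            idx_c = after[0]
            labels[idx_c] = "C2C"
        if idx_b is not None and before[:-1]:
            labels[before[-2]] = "C2A"
            for extra in before[:-2]:
                labels[extra] = f"C2_{extra + 1}"
    idx_e = idx_f = None
    if tm is not None:
        tail = [i for i, h in enumerate(c2s) if h.end <= tm.start and i not in labels]
        if tail:
            idx_f = tail[-1]
            labels[idx_f] = "C2F"
        if len(tail) >= 2:
            idx_e = tail[-2]
            labels[idx_e] = "C2E"
    lo = idx_c if idx_c is not None else idx_b
    hi = idx_e if idx_e is not None else (idx_f if idx_f is not None else len(c2s))
    middle = [
        i for i in range(len(c2s))
        if i not in labels and (lo is None or i > lo) and i < (hi if hi is not None else len(c2s))
    ]
    if middle:
        labels[middle[0]] = "C2D"
    if len(middle) >= 2:
        labels[middle[1]] = "C2DE"
    for extra in middle[2:]:
        labels[extra] = f"C2_{extra + 1}"
        warnings.append("W_C2_NAMES: surplus C2 between C2DE and C2E left positional")
    for i in range(len(c2s)):
        if i not in labels:
            labels[i] = f"C2_{i + 1}"
            warnings.append("W_C2_NAMES: unanchored C2 left positional")
    return _apply_c2_labels(hits, c2s, labels), warnings


def _apply_c2_labels(hits, c2s, labels) -> list[DomainHit]:
    relabeled = {id(c2s[i]): lab for i, lab in labels.items()}
    return [
        replace(h, domain_name=relabeled[id(h)]) if id(h) in relabeled else h
        for h in hits
    ]


def validate_ferlin(hits: list[DomainHit]) -> tuple[bool, list[str]]:
    """Check the two defining ferlin features.

    1. an N-terminal FerI sandwiched between two C2 domains (C2B-FerI-C2C);
    2. two C2 domains adjacent to a TM at the extreme C-terminus.
    """
    reasons: list[str] = []
    names = [h.domain_name for h in sorted(hits, key=lambda h: h.start)]
    sandwich = any(
        is_c2_name(names[i]) and names[i + 1] == "FerI" and is_c2_name(names[i + 2])
        for i in range(len(names) - 2)
    )
    if not sandwich:
        reasons.append("FerI not sandwiched between two C2 domains")
    tail = (
        len(names) >= 3
        and names[-1] == "TM"
        and is_c2_name(names[-2])
        and is_c2_name(names[-3])
    )
    if not tail:
        reasons.append("no C-terminal C2-C2-TM")
    return not reasons, reasons


def classify_type(hits: list[DomainHit]) -> tuple[int | None, bool]:
    """Type 1 iff any confident DysF component; Type 2 iff ferlin-valid
    without DysF.  Returns (type, partial_dysf flag)."""
    dysf = [h for h in hits if h.domain_name in DYSF_NAMES and h.confident]
    if dysf:
        present = {h.domain_name for h in dysf}
        nested = _dysf_nested(hits)
        partial = present != set(DYSF_NAMES) or not nested
        return 1, partial
    valid, _ = validate_ferlin(hits)
    return (2, False) if valid else (None, False)


def _dysf_nested(hits: list[DomainHit]) -> bool:
    pos = {h.domain_name: h.start for h in hits if h.domain_name in DYSF_NAMES}
    if set(pos) != set(DYSF_NAMES):
        return False
    return (
        pos["DysF_outer_N"] < pos["DysF_inner_N"]
        < pos["DysF_inner_C"] < pos["DysF_outer_C"]
    )


def classify_subtype(hits: list[DomainHit]) -> str:
    """Match the presence/absence grammar of topology subtypes A-F.

    Marginal hits count as present.  Requires named C2 hits (after
    :func:`name_c2_domains`); returns "unclassified" when no subtype's
    absent-domain set matches exactly.
    """
    present = {h.domain_name for h in hits}
    if "C2B" not in present or "C2C" not in present:
        return "unclassified"
    optional = {"C2A", "C2D", "C2DE", "C2E", "C2F", "FerB"}
    absent = frozenset(optional - present)
    for subtype, spec_absent in SUBTYPE_ABSENT.items():
        if absent == spec_absent:
            return subtype
    return "unclassified"


def classify_architecture(
    protein_id: str,
    protein: str,
    library: list[DomainSpec] | None = None,
    params: AlignParams | None = None,
) -> Architecture:
    """Scan, name, and classify one protein end to end."""
    hits = scan_domains(protein, library, params)
    named, warnings = name_c2_domains(hits)
    ferlin_type, partial = classify_type(named)
    subtype = classify_subtype(named)
    minimal, reasons = validate_ferlin(named)
    for w in warnings:
        logger.warning(w)
    return Architecture(
        protein_id=protein_id,
        hits=named,
        ferlin_type=ferlin_type,
        subtype=subtype,
        is_minimal_ferlin=minimal,
        partial_dysf=partial,
        warnings=warnings + [f"W_NOT_FERLIN: {r}" for r in reasons],
    )
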