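"""Gene-model assembly from translated-search hits on genomic contigs.

The pipeline mirrors how unannotated ferlin genes are lifted out of draft
genomes: a protein query is searched against all six translation frames of a
contig; high-scoring segment pairs (HSPs) are chained under strand, ordering
and maximum-intron constraints; and each exon-exon junction is refined by a
deterministic window search for canonical GT..AG splice sites that keeps the
spliced CDS in frame and maximizes the re-aligned protein score.  Junctions
where no in-frame GT..AG pair exists in the window are flagged ``raw`` and
logged, never silently accepted.

Coordinates are 0-based half-open on the forward strand throughout; GFF3
output is 1-based closed per the format.  An HSP's ``frame`` field is a
coordinate convention, ``s_start % 3`` on "+" and ``s_end % 3`` on "-", so it
survives a round trip through 12-column tabular files that do not record the
contig length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .align import GAP, AlignParams, AlignmentResult, global_align, local_align, scoring_matrix

logger = logging.getLogger("ferlinkit")

#: default per-HSP acceptance score; calibrated so random contigs with no
#: planted gene yield zero HSPs (see the null-calibration test).
DEFAULT_MIN_HSP_SCORE = 60.0
#: alignment blocks separated by a gap of at least this many residues are
#: split into separate HSPs (an in-frame intron shows up as such a gap).
SPLIT_GAP_AA = 10
DEFAULT_MAX_INTRON = 50_000
DEFAULT_MAX_Q_OVERLAP = 10
DEFAULT_CONTIG_CAP = 2_000_000
MIN_INTRON = 4

FREE_END = AlignParams(free_end_gaps=True)


class AssemblyError(ValueError):
    pass


class ContigTooLargeError(AssemblyError):
    """Contig exceeds the configured cap; supply external tabular hits."""


@dataclass(frozen=True)
class HSP:
    """A high-scoring segment pair: protein query vs translated contig frame.

    ``q_*`` are protein residue coordinates; ``s_*`` are forward-strand
    nucleotide coordinates (0-based half-open in both systems).
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    frame: int
    score: float

    def __post_init__(self):
        if not self.q_start < self.q_end:
            raise AssemblyError("q_start must precede q_end")
        if not self.s_start < self.s_end:
            raise AssemblyError("s_start must precede s_end")
        if self.strand not in "+-":
            raise AssemblyError("strand must be + or -")
        if abs((self.s_end - self.s_start) - 3 * (self.q_end - self.q_start)) > 3:
            raise AssemblyError("subject span must be ~3x query span (gapless HSP)")


@dataclass
class GeneModel:
    contig_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # ascending forward-strand coordinates
    cds_sequence: str                   # coding orientation
    protein_sequence: str
    exon_confidence: tuple[str, ...]    # "refined" | "raw" per exon
    junction_refined: tuple[bool, ...] = ()
    query_id: str = ""

    def __post_init__(self):
        prev = 0
        for s, e in self.exons:
            if not (prev <= s < e):
                raise AssemblyError("exons must be ordered and non-overlapping")
            prev = e
        if len(self.exon_confidence) != len(self.exons):
            raise AssemblyError("one confidence flag per exon required")
        translated = str(Seq(self.cds_sequence[: 3 * (len(self.cds_sequence) // 3)]).translate())
        if translated != self.protein_sequence:
            raise AssemblyError("CDS does not translate to the stated protein")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _frame_field(s_start: int, s_end: int, strand: str) -> int:
    return s_start % 3 if strand == "+" else s_end % 3


#: weakly scoring block edges (chance extension of a local alignment into
#: translated intron) are trimmed: the longest prefix/suffix whose mean
#: column score stays below this is removed.  Every exact-match column
#: scores >= 4 under BLOSUM62, so true exon cores are never touched.
EDGE_TRIM_MEAN = 1.0


def _trim_block(cols: list[float]) -> tuple[int, int]:
    """Return (lo, hi) keeping the block core after edge trimming."""
    lo, hi = 0, len(cols)
    acc = 0.0
    for i, c in enumerate(cols):
        acc += c
        if acc < EDGE_TRIM_MEAN * (i + 1):
            lo = i + 1
    acc = 0.0
    n = 0
    for i in range(len(cols) - 1, lo - 1, -1):
        acc += cols[i]
        n += 1
        if acc < EDGE_TRIM_MEAN * n:
            hi = i
    return lo, hi


def _gapless_blocks(res: AlignmentResult, matrix) -> list[tuple[int, int, int, int, float]]:
    """Split an alignment into strictly gapless blocks with trimmed edges.

    Returns (qs, qe, ts, te, score); an in-frame intron appears as a long
    gap and therefore always separates blocks."""
    blocks = []
    qi, ti = res.a_start, res.b_start
    qs = ts = None
    cols: list[float] = []

    def flush(q_end, t_end):
        nonlocal qs, ts, cols
        if qs is not None and cols:
            lo, hi = _trim_block(cols)
            if hi > lo:
                blocks.append((qs + lo, qs + hi, ts + lo, ts + hi, sum(cols[lo:hi])))
        qs = ts = None
        cols = []

    for x, y in zip(res.aligned_a, res.aligned_b):
        if x != GAP and y != GAP:
            if qs is None:
                qs, ts = qi, ti
            cols.append(float(matrix[x, y]))
        else:
            flush(qi, ti)
        if x != GAP:
            qi += 1
        if y != GAP:
            ti += 1
    flush(qi, ti)
    return blocks


def translated_search(
    query_protein: str,
    contig: str,
    params: AlignParams | None = None,
    min_score: float = DEFAULT_MIN_HSP_SCORE,
    max_contig: int = DEFAULT_CONTIG_CAP,
    query_id: str = "query",
    subject_id: str = "contig",
    max_hits_per_frame: int = 20,
    min_block_score: float = 40.0,
) -> list[HSP]:
    """Local-align the query against all six frame translations of ``contig``.

    Iterated with masking so multiple exons (and multiple loci) per frame are
    found; every returned HSP is a gapless block in forward-strand coords.
    """
    if len(contig) > max_contig:
        raise ContigTooLargeError(
            f"contig is {len(contig)} nt (cap {max_contig}); "
            "supply external tabular hits instead"
        )
    params = params or AlignParams()
    matrix = scoring_matrix(params.matrix_name)
    L = len(contig)
    hsps: list[HSP] = []
    for strand in "+-":
        dna = contig if strand == "+" else _revcomp(contig)
        for f in range(3):
            sub = dna[f : f + 3 * ((L - f) // 3)]
            if len(sub) < 3:
                continue
            prot = str(Seq(sub).translate())
            work = list(prot)
            for _ in range(max_hits_per_frame):
                res = local_align(query_protein, "".join(work), params)
                if res.score < min_score or res.length == 0:
                    break
                for qs, qe, ts, te, bscore in _gapless_blocks(res, matrix):
                    if bscore < min_block_score or qe - qs < 5:
                        continue
                    if strand == "+":
                        s0, s1 = f + 3 * ts, f + 3 * te
                    else:
                        s0, s1 = L - (f + 3 * te), L - (f + 3 * ts)
                    hsps.append(
                        HSP(
                            query_id=query_id,
                            subject_id=subject_id,
                            q_start=qs,
                            q_end=qe,
                            s_start=s0,
                            s_end=s1,
                            strand=strand,
                            frame=_frame_field(s0, s1, strand),
                            score=bscore,
                        )
                    )
                for i in range(res.b_start, res.b_end):
                    work[i] = "J"
    hsps.sort(key=lambda h: (h.s_start, h.s_end, h.strand, -h.score))
    return hsps


# ---------------------------------------------------------------------------
# tabular interchange (12-column search output)

_TAB_COLS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(path: str | Path) -> list[HSP]:
    """Read standard 12-column tabular hits (1-based inclusive coordinates).

    Reversed subject coordinates (sstart > send) encode the minus strand.
    """
    hsps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 12:
                raise AssemblyError(f"line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                qid, sid = parts[0], parts[1]
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                bits = float(parts[11])
            except ValueError as exc:
                raise AssemblyError(f"line {lineno}: malformed field ({exc})") from exc
            if sstart <= send:
                strand, s0, s1 = "+", sstart - 1, send
            else:
                strand, s0, s1 = "-", send - 1, sstart
            hsps.append(
                HSP(
                    query_id=qid,
                    subject_id=sid,
                    q_start=qstart - 1,
                    q_end=qend,
                    s_start=s0,
                    s_end=s1,
                    strand=strand,
                    frame=_frame_field(s0, s1, strand),
                    score=bits,
                )
            )
    return hsps


def write_tabular_hits(hsps: list[HSP], path: str | Path) -> None:
    """Inverse of :func:`read_tabular_hits` (coordinates and strand round-trip)."""
    with open(path, "w") as fh:
        for h in hsps:
            if h.strand == "+":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            row = [
                h.query_id, h.subject_id, "0.0", str(h.q_end - h.q_start), "0", "0",
                str(h.q_start + 1), str(h.q_end), str(sstart), str(send),
                "0.0", f"{h.score:g}",
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# chaining

def _chain_feasible(a: HSP, b: HSP, max_intron: int, max_q_overlap: int) -> bool:
    """Can HSP ``b`` follow ``a`` in one gene model (coding order)?"""
    if a.strand != b.strand:
        return False
    if not (b.q_start >= a.q_end - max_q_overlap and b.q_end > a.q_end and b.q_start >= a.q_start):
        return False
    if a.strand == "+":
        gap = b.s_start - a.s_end
    else:
        gap = a.s_start - b.s_end
    return 0 <= gap <= max_intron


def chain_hsps(
    hsps: list[HSP],
    max_intron: int = DEFAULT_MAX_INTRON,
    max_q_overlap: int = DEFAULT_MAX_Q_OVERLAP,
) -> list[list[HSP]]:
    """Highest-total-score chains of colinear HSPs (dynamic program).

    All HSPs must share one query and one subject.  Chains are extracted
    greedily by score; chains whose subject spans are disjoint from every
    earlier chain are reported too (candidate additional loci/paralogs).
    """
    if not hsps:
        raise AssemblyError("no HSPs to chain")
    if len({(h.query_id, h.subject_id) for h in hsps}) > 1:
        raise AssemblyError("chain_hsps requires a single query/subject pair")
    chains: list[list[HSP]] = []
    remaining = list(hsps)
    while remaining:
        best_chain = _best_chain(remaining, max_intron, max_q_overlap)
        if best_chain is None:
            break
        chains.append(best_chain)
        span = (
            min(h.s_start for h in best_chain),
            max(h.s_end for h in best_chain),
        )
        remaining = [
            h for h in remaining
            if h.s_end <= span[0] or h.s_start >= span[1]
        ]
    return chains


def _best_chain(
    hsps: list[HSP], max_intron: int, max_q_overlap: int
) -> list[HSP] | None:
    order = sorted(range(len(hsps)), key=lambda i: (hsps[i].s_start, hsps[i].s_end))
    best_score = [hsps[i].score for i in order]
    back: list[int | None] = [None] * len(order)
    for j in range(len(order)):
        hj = hsps[order[j]]
        for i in range(j):
            hi = hsps[order[i]]
            prev, nxt = (hi, hj) if hi.strand == "+" else (hj, hi)
            if _chain_feasible(prev, nxt, max_intron, max_q_overlap):
                cand = best_score[i] + hj.score
                if cand > best_score[j]:
                    best_score[j] = cand
                    back[j] = i
    end = max(range(len(order)), key=lambda j: best_score[j])
    idx: list[int] = []
    k: int | None = end
    while k is not None:
        idx.append(order[k])
        k = back[k]
    chain = [hsps[i] for i in reversed(idx)]
    # return in coding order: ascending subject on +, descending on -
    chain.sort(key=lambda h: h.s_start, reverse=(chain[0].strand == "-"))
    return chain


def _drop_redundant(chain: list[HSP]) -> list[HSP]:
    """Drop internal members whose query span adds nothing beyond their
    neighbours (spurious intron-translation blocks that slot into a chain)."""
    changed = True
    while changed and len(chain) > 2:
        changed = False
        scored = sorted(range(1, len(chain) - 1), key=lambda i: chain[i].score)
        for i in scored:
            prev, cur, nxt = chain[i - 1], chain[i], chain[i + 1]
            covered = (
                cur.q_end <= prev.q_end
                or cur.q_start >= nxt.q_start
                or (
                    cur.q_start >= prev.q_start
                    and cur.q_end <= nxt.q_end
                    and prev.q_end >= nxt.q_start
                )
            )
            if covered:
                del chain[i]
                changed = True
                break
    return chain


# ---------------------------------------------------------------------------
# splice-boundary refinement


def refine_boundaries(
    chain: list[HSP],
    contig: str,
    query_protein: str,
    window: int = 30,
    params: AlignParams | None = None,
    contig_id: str = "contig",
) -> GeneModel:
    """Turn one HSP chain into a gene model with GT..AG-refined junctions.

    For each adjacent exon pair, donor GT and acceptor AG positions within
    ``window`` nt of the HSP ends are enumerated; pairs that keep the spliced
    CDS in frame are scored by re-aligning the translated junction
    neighbourhood to the query, and the best pair wins.  ``window == 0``
    disables the search (every junction stays raw).  Terminal exon ends are
    extended to cover the query's full span.
    """
    if not chain:
        raise AssemblyError("empty chain")
    chain = _drop_redundant(list(chain))
    params = params or FREE_END
    strand = chain[0].strand
    L = len(contig)
    if strand == "-":
        work = _revcomp(contig)
        segs = [
            {"ws": L - h.s_end, "we": L - h.s_start, "qs": h.q_start, "qe": h.q_end}
            for h in chain
        ]
    else:
        work = contig
        segs = [
            {"ws": h.s_start, "we": h.s_end, "qs": h.q_start, "qe": h.q_end}
            for h in chain
        ]
    segs.sort(key=lambda s: s["ws"])
    # merge segments separated by a tiny subject gap: same exon
    merged = [dict(segs[0], anchor=segs[0]["ws"])]
    for s in segs[1:]:
        prev = merged[-1]
        if s["ws"] - prev["we"] <= 12:
            prev["we"] = max(prev["we"], s["we"])
            prev["qe"] = max(prev["qe"], s["qe"])
        else:
            merged.append(dict(s, anchor=s["ws"]))
    exons = [[m["ws"], m["we"]] for m in merged]
    anchors = [m["anchor"] for m in merged]
    # extend terminal exons to the query's span
    exons[0][0] = max(0, exons[0][0] - 3 * merged[0]["qs"])
    exons[-1][1] = min(len(work), exons[-1][1] + 3 * (len(query_protein) - merged[-1]["qe"]))

    refined_flags: list[bool] = []
    cum = 0  # CDS length accumulated over refined exons
    for i in range(len(exons) - 1):
        choice = None
        if window > 0:
            choice = _refine_junction(
                work, query_protein, exons[i], exons[i + 1],
                anchors[i + 1], cum, window, params,
            )
        if choice is None:
            refined_flags.append(False)
            logger.warning(
                "W_RAW_JUNCTION: %s junction %d kept raw (no in-frame GT..AG in window)",
                contig_id, i,
            )
        else:
            d, a = choice
            exons[i][1] = d
            exons[i + 1][0] = a
            refined_flags.append(True)
        cum += exons[i][1] - exons[i][0]

    cds = "".join(work[s:e] for s, e in exons)
    cds = cds[: 3 * (len(cds) // 3)]
    protein = str(Seq(cds).translate())
    if strand == "-":
        fwd_exons = tuple(sorted((L - e, L - s) for s, e in exons))
    else:
        fwd_exons = tuple(tuple(e) for e in exons)
    conf = _exon_confidence(len(exons), refined_flags)
    return GeneModel(
        contig_id=contig_id,
        strand=strand,
        exons=fwd_exons,
        cds_sequence=cds,
        protein_sequence=protein,
        exon_confidence=conf,
        junction_refined=tuple(refined_flags),
        query_id=chain[0].query_id,
    )


def _exon_confidence(n_exons: int, flags: list[bool]) -> tuple[str, ...]:
    """Exon is 'refined' when every junction it touches was refined."""
    conf = []
    for i in range(n_exons):
        left = flags[i - 1] if i > 0 else True
        right = flags[i] if i < n_exons - 1 else True
        conf.append("refined" if left and right else "raw")
    return tuple(conf)


def _refine_junction(
    work: str,
    query: str,
    exon_a: list[int],
    exon_b: list[int],
    anchor_b: int,
    cum: int,
    window: int,
    params: AlignParams,
) -> tuple[int, int] | None:
    approx_d, approx_a = exon_a[1], exon_b[0]
    donors = [
        d for d in range(max(exon_a[0] + 3, approx_d - window), min(len(work) - 1, approx_d + window) + 1)
        if work[d : d + 2] == "GT"
    ]
    acceptors = [
        a for a in range(max(2, approx_a - window), min(exon_b[1] - 3, approx_a + window) + 1)
        if work[a - 2 : a] == "AG"
    ]
    best = None
    best_key = None
    for d in donors:
        prefix_len = cum + (d - exon_a[0])
        for a in acceptors:
            if a - d < MIN_INTRON:
                continue
            if (prefix_len + anchor_b - a) % 3 != 0:
                continue
            score = _junction_score(
                work, query, exon_a, exon_b, d, a, cum, params,
                approx_d, approx_a, window,
            )
            key = (score, -(abs(d - approx_d) + abs(a - approx_a)), -d)
            if best_key is None or key > best_key:
                best_key = key
                best = (d, a)
    return best


def _junction_score(
    work: str,
    query: str,
    exon_a: list[int],
    exon_b: list[int],
    d: int,
    a: int,
    cum: int,
    params: AlignParams,
    approx_d: int,
    approx_a: int,
    window: int,
) -> float:
    """Score one candidate (donor, acceptor) pair.

    All candidates of a junction share a common codon-aligned subject start
    and a common subject end plus one fixed query window, so a shifted decoy
    can only lose alignment score relative to the true junction — it never
    gains by dragging differently composed residues into view."""
    phase = (-cum) % 3  # offset of the first full codon within exon_a
    tail_start = max(exon_a[0] + phase, approx_d - 48 - window)
    tail_start += (-(cum + tail_start - exon_a[0])) % 3
    head_end = min(exon_b[1], approx_a + 48 + window)
    junc_nt = work[tail_start:d] + work[a:head_end]
    junc_nt = junc_nt[: 3 * (len(junc_nt) // 3)]
    if not junc_nt:
        return float("-inf")
    prot = str(Seq(junc_nt).translate())
    qj = (cum + approx_d - exon_a[0]) // 3
    span = (head_end - tail_start) // 3 // 2 + 6
    q_lo = max(0, qj - span)
    q_hi = min(len(query), qj + span)
    if q_lo >= q_hi:
        return float("-inf")
    return global_align(prot, query[q_lo:q_hi], params).score


# ---------------------------------------------------------------------------
# GFF3 / FASTA emission


def emit_gene_model(model: GeneModel, gene_id: str | None = None) -> tuple[str, str]:
    """Render a gene model as (GFF3 text, protein FASTA text).

    GFF3 rows are gene/mRNA/exon/CDS, 1-based closed, coordinates ascending
    regardless of strand; exon confidence flags travel in the attributes.
    """
    gid = gene_id or f"{model.contig_id}.gene"
    s0 = min(s for s, _ in model.exons) + 1
    e0 = max(e for _, e in model.exons)
    lines = ["##gff-version 3"]
    lines.append(
        f"{model.contig_id}\tferlinkit\tgene\t{s0}\t{e0}\t.\t{model.strand}\t.\t"
        f"ID={gid};query_id={model.query_id}"
    )
    junc = ",".join("1" if f else "0" for f in model.junction_refined)
    lines.append(
        f"{model.contig_id}\tferlinkit\tmRNA\t{s0}\t{e0}\t.\t{model.strand}\t.\t"
        f"ID={gid}.t1;Parent={gid};junctions_refined={junc}"
    )
    for k, ((s, e), conf) in enumerate(zip(model.exons, model.exon_confidence)):
        lines.append(
            f"{model.contig_id}\tferlinkit\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t"
            f"ID={gid}.exon{k};Parent={gid}.t1;confidence={conf}"
        )
    phase = 0
    cds_exons = list(model.exons) if model.strand == "+" else list(model.exons)[::-1]
    for k, (s, e) in enumerate(cds_exons):
        lines.append(
            f"{model.contig_id}\tferlinkit\tCDS\t{s + 1}\t{e}\t.\t{model.strand}\t{phase}\t"
            f"ID={gid}.cds;Parent={gid}.t1"
        )
        phase = (3 - ((e - s) - phase) % 3) % 3
    gff = "\n".join(lines) + "\n"
    fasta = f">{gid} contig={model.contig_id} strand={model.strand} query={model.query_id}\n{model.protein_sequence}\n"
    return gff, fasta


def read_gene_model(gff_text: str, contig: str) -> GeneModel:
    """Parse :func:`emit_gene_model` GFF3 back into an equal GeneModel."""
    contig_id = strand = None
    query_id = ""
    junctions: tuple[bool, ...] = ()
    exons: list[tuple[int, int]] = []
    conf: list[str] = []
    for line in gff_text.splitlines():
        if not line or line.startswith("#"):
            continue
        cid, _, kind, s, e, _, st, _, attrs = line.split("\t")
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if kind == "gene":
            contig_id, strand = cid, st
            query_id = attr.get("query_id", "")
        elif kind == "mRNA":
            j = attr.get("junctions_refined", "")
            junctions = tuple(x == "1" for x in j.split(",")) if j else ()
        elif kind == "exon":
            exons.append((int(s) - 1, int(e)))
            conf.append(attr.get("confidence", "raw"))
    pairs = sorted(zip(exons, conf))
    exons = [p[0] for p in pairs]
    conf = [p[1] for p in pairs]
    cds = "".join(contig[s:e] for s, e in exons)
    if strand == "-":
        cds = _revcomp(cds)
    cds = cds[: 3 * (len(cds) // 3)]
    protein = str(Seq(cds).translate())
    return GeneModel(
        contig_id=contig_id,
        strand=strand,
        exons=tuple(exons),
        cds_sequence=cds,
        protein_sequence=protein,
        exon_confidence=tuple(conf),
        junction_refined=junctions,
        query_id=query_id,
    )
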