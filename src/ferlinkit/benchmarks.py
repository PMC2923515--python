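"""Planted-truth recovery experiments.

Each function simulates data with known ground truth under the package's
study conditions, runs the corresponding analysis stage, and returns a
summary statistic.  The experiments double as the package's acceptance
checks and as worked examples of the intended analysis scale.

The exhaustive alignment enumerator here is an independent oracle: it
scores every possible gapped pairing of two short sequences by direct
recursion (affine gap cost ``open + (k-1)*extend``), without touching the
production aligner's dynamic program.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .align import AlignParams, global_align, local_align, scoring_matrix
from .assembly import chain_hsps, refine_boundaries, translated_search
from .calcium import call_calcium_residues, default_anchor_set
from .library import C2_ANCHOR_OFFSETS, anchor_reference_sequence, build_default_library
from .phylo import (
    DistanceMatrix,
    Tree,
    TreeNode,
    assign_fragment,
    bootstrap,
    nj_tree,
    partition_types,
    progressive_msa,
)
from .scan import classify_architecture
from .simulate import (
    PhylogenySpec,
    _substitute,
    default_template,
    generate_locus,
    plant_calcium_states,
    simulate_family,
)

REDUCED_ALPHABET = "ACDE"


# ---------------------------------------------------------------------------
# 1. alignment oracle


def enumerate_best_global(a: str, b: str, params: AlignParams) -> float:
    """Best global alignment score by exhaustive recursion over all
    monotone alignments with affine gap state."""
    mat = scoring_matrix(params.matrix_name)
    go, ge = params.gap_open, params.gap_extend

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # state: 0 = diagonal/start, 1 = in gap consuming a, 2 = in gap consuming b
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, float(mat[a[i], b[j]]) + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = ge if state == 1 else go
            best = max(best, -cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = ge if state == 2 else go
            best = max(best, -cost + rec(i, j + 1, 2))
        return best

    out = rec(0, 0, 0)
    rec.cache_clear()
    return out


def enumerate_best_local(a: str, b: str, params: AlignParams) -> float:
    """Best local alignment score: max over all substring pairs of the
    best *end-anchored* gapped alignment, never below the empty alignment."""
    mat = scoring_matrix(params.matrix_name)
    go, ge = params.gap_open, params.gap_extend

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # best score of an alignment ending exactly at (i, j)
        best = -math.inf
        if i > 0 and j > 0:
            sub = float(mat[a[i - 1], b[j - 1]])
            prev = max(rec(i - 1, j - 1, 0), rec(i - 1, j - 1, 1), rec(i - 1, j - 1, 2), 0.0) \
                if state == 0 else -math.inf
            if state == 0:
                best = max(best, sub + prev)
        if state == 1 and i > 0:
            for prev_state in (0, 1, 2):
                cost = ge if prev_state == 1 else go
                p = rec(i - 1, j, prev_state)
                if p > -math.inf:
                    best = max(best, p - cost)
        if state == 2 and j > 0:
            for prev_state in (0, 1, 2):
                cost = ge if prev_state == 2 else go
                p = rec(i, j - 1, prev_state)
                if p > -math.inf:
                    best = max(best, p - cost)
        return best

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            best = max(best, rec(i, j, 0))
    rec.cache_clear()
    return best


def alignment_oracle_agreement(seed: int, n_pairs: int = 150, max_len: int = 6) -> float:
    """Percent of random short pairs where the production aligner's global
    and local scores both equal the exhaustive enumeration oracle."""
    rng = np.random.default_rng(seed)
    params = AlignParams()
    letters = list(REDUCED_ALPHABET)
    agree = 0
    for _ in range(n_pairs):
        la = int(rng.integers(1, max_len + 1))
        lb = int(rng.integers(1, max_len + 1))
        a = "".join(rng.choice(letters, la))
        b = "".join(rng.choice(letters, lb))
        ok_g = global_align(a, b, params).score == enumerate_best_global(a, b, params)
        ok_l = local_align(a, b, params).score == enumerate_best_local(a, b, params)
        agree += ok_g and ok_l
    return 100.0 * agree / n_pairs


# ---------------------------------------------------------------------------
# 2. NJ consistency on additive matrices


def random_tree(n_leaves: int, rng: np.random.Generator) -> Tree:
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.05, 1.0))) for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        new = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        new.children = [nodes[i], nodes[j]]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [new]
    root = TreeNode()
    root.children = nodes
    return Tree(root)


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Additive leaf-to-leaf path-length matrix of a tree."""
    paths: dict[str, dict[int, float]] = {}

    def walk(node, depth, anc):
        anc = dict(anc)
        anc[id(node)] = depth
        if node.is_leaf:
            paths[node.name] = anc
        for c in node.children:
            walk(c, depth + c.length, anc)

    walk(tree.root, 0.0, {})
    labels = tree.leaf_labels
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[labels[i]], paths[labels[j]]
            da = max(pa.values())
            db = max(pb.values())
            dc = max(min(pa[k], pb[k]) for k in pa if k in pb)
            d[i, j] = d[j, i] = da + db - 2 * dc
    return DistanceMatrix(labels, d)


def nj_additive_recovery(seed: int, n_matrices: int = 100) -> float:
    """Percent of random additive matrices (5-10 leaves) whose generating
    topology neighbor joining recovers exactly."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_matrices):
        t = random_tree(int(rng.integers(5, 11)), rng)
        est = nj_tree(tree_distance_matrix(t))
        ok += est.bipartitions() == t.bipartitions()
    return 100.0 * ok / n_matrices


# ---------------------------------------------------------------------------
# 3. Type 1 / Type 2 partition with bootstrap

TWO_CLADE_NEWICK = "((s1:0.08,s2:0.08):0.05,(s3:0.08,s4:0.08):0.05);"


def two_type_partition_replicates(
    seed: int, n_replicates: int = 20, n_bootstrap: int = 100, min_support: float = 95.0
) -> int:
    """Number of seeded replicates (out of ``n_replicates``) in which the
    Type 1 / Type 2 split is a clean bipartition with bootstrap support
    >= ``min_support``."""
    t1 = default_template(1, "A")
    t2 = default_template(2, "A")
    hits = 0
    for rep in range(n_replicates):
        fam = simulate_family(
            t1, t2, PhylogenySpec(TWO_CLADE_NEWICK), seed=seed + rep,
            ancestral_divergence=0.4,
        )
        msa = progressive_msa([(p.id, p.sequence) for p in fam])
        tree = bootstrap(msa, n_replicates=n_bootstrap, seed=seed + rep)
        types = {p.id: (1 if p.paralog_label.startswith("F1") else 2) for p in fam}
        rep_out = partition_types(tree, types)
        if rep_out["clean"] and (rep_out["support"] or 0.0) >= min_support:
            hits += 1
    return hits


# ---------------------------------------------------------------------------
# 4. subtype grammar recovery


def subtype_recovery(seed: int, n_proteins: int = 200, divergence: float = 0.3) -> float:
    """Percent of simulated proteins whose topology subtype is recovered
    exactly at <= ``divergence`` substitutions/site."""
    library = build_default_library()
    newick = f"(sp1:{divergence},sp2:{divergence});"
    n = ok = 0
    rep = 0
    while n < n_proteins:
        for ftype in (1, 2):
            for st in "ABCDEF":
                tpl = default_template(ftype, st)
                other = default_template(2 if ftype == 1 else 1, "A")
                fam = simulate_family(
                    tpl if ftype == 1 else other,
                    tpl if ftype == 2 else other,
                    PhylogenySpec(newick),
                    seed=seed + 1000 * rep + 10 * ord(st) + ftype,
                    ancestral_divergence=0.0,
                )
                for p in fam:
                    focal = p.paralog_label == ("F1" if ftype == 1 else "F2")
                    want = tpl.subtype if focal else "A"
                    arch = classify_architecture(p.id, p.sequence, library)
                    n += 1
                    ok += arch.subtype == want
                    if n >= n_proteins:
                        break
                if n >= n_proteins:
                    break
            if n >= n_proteins:
                break
        rep += 1
    return 100.0 * ok / n


# ---------------------------------------------------------------------------
# 5. calcium anchor status recovery


def calcium_recovery(seed: int, n_anchors: int = 500, divergence: float = 0.2) -> dict:
    """Per-anchor status recovery on planted anchors, plus a check that
    D->E substitutions never flip the overall call."""
    rng = np.random.default_rng(seed)
    ref = anchor_reference_sequence()
    anchors = default_anchor_set()
    p = 1.0 - math.exp(-divergence)
    n = ok = 0
    de_flips = 0
    while n < n_anchors:
        seq = _substitute(rng, ref, p, frozen=set(C2_ANCHOR_OFFSETS))
        states = "".join(rng.choice(list("DESNK")) for _ in range(5))
        planted = list(seq)
        for pos, r in zip(C2_ANCHOR_OFFSETS, states):
            planted[pos] = r
        call = call_calcium_residues("".join(planted), anchors)
        for want, got in zip(states, call.residues):
            n += 1
            ok += want == got
        # D->E at every D anchor must not change `overall`
        if "D" in states:
            swapped = list(planted)
            for pos, r in zip(C2_ANCHOR_OFFSETS, states):
                if r == "D":
                    swapped[pos] = "E"
            call2 = call_calcium_residues("".join(swapped), anchors)
            de_flips += call.overall != call2.overall
    return {"recovery_pct": 100.0 * ok / n, "d_to_e_flips": de_flips, "n": n}


# ---------------------------------------------------------------------------
# 6. gene assembly exon-boundary recovery


def assembly_recovery(
    seed: int,
    n_loci: int = 50,
    query_divergence: float = 0.3,
    min_exons: int = 3,
    max_exons: int = 15,
) -> dict:
    """Fraction of true exon boundaries recovered exactly over synthetic
    loci; ``query_divergence`` 0.3 gives ~74% query identity."""
    t1 = default_template(1, "A")
    t2 = default_template(2, "A")
    fam = simulate_family(
        t1, t2, PhylogenySpec("(s1:0.0,s2:0.0);"), rate_scale=0.0, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    protein = fam[0]
    if query_divergence > 0:
        query = _substitute(
            rng, protein.sequence, 1.0 - math.exp(-query_divergence), frozen=set()
        )
    else:
        query = protein.sequence
    identity = 100.0 * sum(a == b for a, b in zip(query, protein.sequence)) / len(query)
    total = found = 0
    for i in range(n_loci):
        n_exons = min_exons + int(rng.integers(0, max_exons - min_exons + 1))
        strand = "+" if i % 2 == 0 else "-"
        locus = generate_locus(protein, n_exons, strand=strand, seed=seed + 50 + i)
        hsps = translated_search(
            query, locus.contig_sequence, query_id="q", subject_id=locus.contig_id
        )
        truth = {("s", s) for s, _ in locus.truth_exons} | {
            ("e", e) for _, e in locus.truth_exons
        }
        total += len(truth)
        if not hsps:
            continue
        chain = chain_hsps(hsps)[0]
        model = refine_boundaries(chain, locus.contig_sequence, query, contig_id=locus.contig_id)
        got = {("s", s) for s, _ in model.exons} | {("e", e) for _, e in model.exons}
        found += len(truth & got)
    return {
        "boundary_recovery_pct": 100.0 * found / total,
        "query_identity_pct": identity,
        "n_loci": n_loci,
    }


# ---------------------------------------------------------------------------
# 7. fragment-to-paralog assignment

SIX_PARALOG_NEWICK = (
    "((v1:0.15,v2:0.15)vert:0.25,(v3:0.15,v4:0.15)vert2:0.25);"
)
SIX_PARALOG_EVENTS = (("vert", 3), ("vert2", 3))


def fragment_assignment_accuracy(
    seed: int, n_fragments: int = 200, divergence: float = 0.2
) -> float:
    """Percent of C2F fragments (at ``divergence`` substitutions/site from
    a leaf of a six-paralog family) assigned to the correct paralog."""
    t1 = default_template(1, "A")
    t2 = default_template(2, "A")
    fam = simulate_family(
        t1, t2, PhylogenySpec(SIX_PARALOG_NEWICK, SIX_PARALOG_EVENTS),
        seed=seed, ancestral_divergence=0.4,
    )
    refs = [
        (p.paralog_label, p.domain_sequence("C2F"))
        for p in fam
        if p.species_label in ("v1", "v3")
    ]
    sources = [p for p in fam if p.species_label in ("v2", "v4")]
    rng = np.random.default_rng(seed + 1)
    p_mut = 1.0 - math.exp(-divergence)
    n = ok = 0
    while n < n_fragments:
        src = sources[int(rng.integers(len(sources)))]
        frag = _substitute(rng, src.domain_sequence("C2F"), p_mut, frozen=set())
        result = assign_fragment(frag, refs)
        n += 1
        ok += result["label"] == src.paralog_label
    return 100.0 * ok / n
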