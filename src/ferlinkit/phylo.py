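"""Distance trees for ferlin families: progressive MSA, neighbor joining,
column bootstrap, Type 1/Type 2 partition checks, and fragment assignment.

Trees are inferred by canonical neighbor joining on corrected protein
distances: with p the per-column mismatch proportion over shared ungapped
columns, d = -ln(1 - p - p^2/5) — a standard one-parameter correction for
multiple substitutions at protein scale.  Branch support comes from a column
bootstrap: alignment columns are resampled with replacement, a replicate
tree is built per resample, and each internal bipartition of the base tree
is annotated with the percentage of replicates containing it.

The bundled multiple aligner is a guide-tree progressive scheme (3-mer
distance guide, UPGMA merge order, affine profile-profile global steps);
it stands in for external MSA tools at desk scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .align import AlignParams, global_align, scoring_matrix
from .library import AMINO_ACIDS

logger = logging.getLogger("ferlinkit")

GAP = "-"
SATURATION_P = 0.80


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances


def correct_distance(p: float) -> float:
    """Corrected distance d = -ln(1 - p - p^2/5); monotone on [0, 0.8)."""
    if p < 0:
        raise PhyloError("negative p-distance")
    p = min(p, SATURATION_P - 1e-6)
    return -math.log(1.0 - p - p * p / 5.0)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhyloError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise PhyloError("diagonal must be zero")
        if np.any(self.d < 0):
            raise PhyloError("distances must be non-negative")

    @classmethod
    def from_alignment(cls, alignment: list[tuple[str, str]]) -> "DistanceMatrix":
        """Corrected distances from a gapped alignment.

        Gap-containing columns are excluded pairwise (not listwise), so
        fragments contribute over their aligned extent only.
        """
        labels = [lab for lab, _ in alignment]
        rows = np.array([list(seq) for _, seq in alignment])
        n = len(labels)
        d = np.zeros((n, n))
        saturated = set()
        for i in range(n):
            for j in range(i + 1, n):
                shared = (rows[i] != GAP) & (rows[j] != GAP)
                m = int(shared.sum())
                if m == 0:
                    p = SATURATION_P
                else:
                    p = float((rows[i][shared] != rows[j][shared]).sum() / m)
                if p >= SATURATION_P:
                    saturated.add((labels[i], labels[j]))
                    logger.warning(
                        "W_SATURATED: %s vs %s p=%.2f at saturation",
                        labels[i], labels[j], p,
                    )
                d[i, j] = d[j, i] = correct_distance(p)
        return cls(labels, d, saturated)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal root."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each normalized to the side not
        containing the lexicographically first leaf; trivial splits excluded."""
        all_leaves = set(self.root.leaves())
        ref = min(all_leaves)
        out = set()
        for node in self._walk(self.root):
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaves())
            if ref in side:
                side = frozenset(all_leaves - side)
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def _walk(self, node):
        yield node
        for c in node.children:
            yield from self._walk(c)

    def annotate_supports(self, support: dict[frozenset[str], float]) -> None:
        all_leaves = set(self.root.leaves())
        ref = min(all_leaves)
        for node in self._walk(self.root):
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaves())
            if ref in side:
                side = frozenset(all_leaves - side)
            if side in support:
                node.support = support[side]

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = node.name
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def rooted_at(self, outgroup: str) -> "Tree":
        """Re-root on the pendant edge of ``outgroup`` (a leaf label)."""
        parent: dict[int, TreeNode | None] = {}

        def walk(node, par):
            parent[id(node)] = par
            for c in node.children:
                walk(c, node)

        walk(self.root, None)
        target = next(
            (n for n in self._walk(self.root) if n.is_leaf and n.name == outgroup),
            None,
        )
        if target is None:
            raise PhyloError(f"outgroup {outgroup!r} is not a leaf")
        # walk from target up to root, reversing edges
        path = []
        node = target
        while node is not None:
            path.append(node)
            node = parent[id(node)]
        new_root = TreeNode(name="", length=0.0)
        half = target.length / 2.0
        og = TreeNode(name=target.name, length=half)
        rest = _invert_path(path, 1)
        rest.length = half
        new_root.children = [og, rest]
        return Tree(new_root)


def _invert_path(path: list[TreeNode], i: int) -> TreeNode:
    node = path[i]
    clone = TreeNode(name=node.name, length=path[i - 1].length, support=node.support)
    clone.children = [c for c in node.children if c is not path[i - 1]]
    if i + 1 < len(path):
        clone.children.append(_invert_path(path, i + 1))
    return clone


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Canonical neighbor joining with deterministic lexicographic tie-break.

    Consistent: recovers the generating topology on any additive matrix.
    Negative branch lengths are clamped to zero with a warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("need >= 3 labels")
    nodes = [TreeNode(name=lab) for lab in dm.labels]
    tags = list(dm.labels)  # lexicographic tie-break tag per cluster
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp(x, a, b):
        if x < 0:
            logger.warning("W_NEG_BRANCH: negative branch length %.4g (%s,%s) clamped", x, a, b)
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_key = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_tag = tuple(sorted((tags[i], tags[j])))
                key = (q, pair_tag)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li = clamp(li, tags[i], tags[j])
        lj = clamp(lj, tags[j], tags[i])
        new = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        new.children = [a, b]
        nodes.append(new)
        tags.append(min(tags[i], tags[j]))
        k = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - dij)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j = active
    # attach the last edge into an internal node: standard unrooted NJ
    # representation with a trifurcating root
    if not nodes[j].is_leaf:
        i, j = j, i
    if nodes[i].is_leaf:
        root = TreeNode()
        nodes[i].length = clamp(d[i, j] / 2, tags[i], tags[j])
        nodes[j].length = clamp(d[i, j] / 2, tags[j], tags[i])
        root.children = [nodes[i], nodes[j]]
        return Tree(root)
    root = nodes[i]
    nodes[j].length = clamp(d[i, j], tags[i], tags[j])
    root.children.append(nodes[j])
    return Tree(root)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap(
    alignment: list[tuple[str, str]],
    n_replicates: int = 100,
    seed: int = 0,
) -> Tree:
    """NJ tree with column-bootstrap supports (percent of replicates
    containing each internal bipartition of the base tree)."""
    if n_replicates < 1:
        raise PhyloError("n_replicates must be >= 1")
    ncol = len(alignment[0][1])
    if ncol < 2:
        raise PhyloError("alignment needs >= 2 columns")
    labels = [lab for lab, _ in alignment]
    base = nj_tree(DistanceMatrix.from_alignment(alignment))
    target = base.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    rows = np.array([list(seq) for _, seq in alignment])
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = [(lab, "".join(rows[i, cols])) for i, lab in enumerate(labels)]
        rep_tree = nj_tree(DistanceMatrix.from_alignment(rep))
        found = rep_tree.bipartitions()
        for bp in target:
            if bp in found:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    base.annotate_supports(support)
    return base


# ---------------------------------------------------------------------------
# type partition


def partition_types(tree: Tree, type_labels: dict[str, int]) -> dict:
    """Does one internal edge separate all Type 1 from all Type 2 leaves?

    Returns a report with ``clean`` (bool), ``outliers`` (the minimal leaf
    set breaking monophyly at the best edge), and the ``support`` of the
    partition edge when annotated.
    """
    leaves = tree.leaf_labels
    missing = [l for l in leaves if l not in type_labels]
    if missing:
        raise PhyloError(f"unlabeled leaves: {missing}")
    t1 = frozenset(l for l in leaves if type_labels[l] == 1)
    t2 = frozenset(l for l in leaves if type_labels[l] == 2)
    if not t1 or not t2:
        return {"clean": True, "outliers": [], "support": None, "edge": None}
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    target = t1 if ref not in t1 else t2

    support_map = {}
    for node in tree._walk(tree.root):
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(node.leaves())
        if ref in side:
            side = frozenset(all_leaves - side)
        support_map[side] = node.support

    if target in support_map or len(t1) == 1 or len(t2) == 1:
        return {
            "clean": True,
            "outliers": [],
            "support": support_map.get(target),
            "edge": target,
        }
    best_edge = None
    best_out: frozenset[str] | None = None
    for side in support_map:
        for cand in (side, all_leaves - side):
            mism = (cand - t1) | (t1 - cand)
            if best_out is None or len(mism) < len(best_out):
                best_out = frozenset(mism)
                best_edge = side
    return {
        "clean": False,
        "outliers": sorted(best_out or ()),
        "support": support_map.get(best_edge),
        "edge": best_edge,
    }


# ---------------------------------------------------------------------------
# fragment assignment

ASSIGN_MARGIN = 0.05


def assign_fragment(
    fragment: str,
    references: list[tuple[str, str]],
    params: AlignParams | None = None,
) -> dict:
    """Nearest-reference paralog assignment for a fragmentary domain.

    Aligns the fragment to each labeled reference with free end gaps,
    computes corrected distances over shared columns, and returns the best
    paralog label with the margin to the runner-up label; margins below
    0.05 are flagged ambiguous.
    """
    if len({lab for lab, _ in references}) < 2:
        raise PhyloError("references must span >= 2 paralog labels")
    params = params or AlignParams(free_end_gaps=True)
    dists: dict[str, float] = {}
    alignable = False
    for lab, ref in references:
        res = global_align(fragment, ref, params)
        if res.identity_core() >= 15.0:
            alignable = True
        cols = [
            (x, y)
            for x, y in zip(res.aligned_a, res.aligned_b)
            if x != GAP and y != GAP
        ]
        p = (
            sum(x != y for x, y in cols) / len(cols)
            if cols
            else SATURATION_P
        )
        dist = correct_distance(p)
        dists[lab] = min(dists.get(lab, math.inf), dist)
    if not alignable:
        raise PhyloError("fragment unalignable to all references (identity < 15%)")
    ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    best_label, best_d = ranked[0]
    margin = (ranked[1][1] - best_d) if len(ranked) > 1 else math.inf
    return {
        "label": best_label,
        "distance": best_d,
        "margin": margin,
        "ambiguous": margin < ASSIGN_MARGIN,
        "distances": dists,
    }


# ---------------------------------------------------------------------------
# progressive multiple alignment

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@njit(cache=True)
def _profile_dp(S, gap_open, gap_extend):  # pragma: no cover - numba kernel
    m, n = S.shape
    NEG = -1e30
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in B (consume A)
    Y = np.full((m + 1, n + 1), NEG)  # gap in A (consume B)
    PM = np.zeros((m + 1, n + 1), dtype=np.int8)
    PX = np.zeros((m + 1, n + 1), dtype=np.int8)
    PY = np.zeros((m + 1, n + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
        PX[i, 0] = 1
    for j in range(1, n + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
        PY[0, j] = 2
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # M
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + S[i - 1, j - 1]
            PM[i, j] = ptr
            # X: consume column of A
            best = M[i - 1, j] - gap_open
            ptr = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                ptr = 1
            if Y[i - 1, j] - gap_open > best:
                best = Y[i - 1, j] - gap_open
                ptr = 2
            X[i, j] = best
            PX[i, j] = ptr
            # Y: consume column of B
            best = M[i, j - 1] - gap_open
            ptr = 0
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                ptr = 1
            if X[i, j - 1] - gap_open > best:
                best = X[i, j - 1] - gap_open
                ptr = 2
            Y[i, j] = best
            PY[i, j] = ptr
    # traceback
    path = np.empty(m + n, dtype=np.int8)
    k = 0
    i, j = m, n
    state = 0
    if X[m, n] > M[m, n] and X[m, n] >= Y[m, n]:
        state = 1
    elif Y[m, n] > M[m, n]:
        state = 2
    while i > 0 or j > 0:
        if state == 0:
            path[k] = 0
            prev = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            path[k] = 1
            prev = PX[i, j]
            i -= 1
        else:
            path[k] = 2
            prev = PY[i, j]
            j -= 1
        k += 1
        if i == 0 and j > 0 and state != 2:
            state = 2
            continue
        if j == 0 and i > 0 and state != 1:
            state = 1
            continue
        state = prev
    return path[:k][::-1]


def _profile_freqs(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    F = np.zeros((L, len(AMINO_ACIDS)))
    for row in rows:
        for i, c in enumerate(row):
            k = _AA_INDEX.get(c, -1)
            if k >= 0:
                F[i, k] += 1
    return F / len(rows)


def _merge_profiles(
    rows_a: list[str],
    rows_b: list[str],
    M20: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    FA = _profile_freqs(rows_a)
    FB = _profile_freqs(rows_b)
    S = FA @ M20 @ FB.T
    path = _profile_dp(S, gap_open, gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for move in path:
        if move == 0:
            for r, row in zip(out_a, rows_a):
                r.append(row[i])
            for r, row in zip(out_b, rows_b):
                r.append(row[j])
            i += 1
            j += 1
        elif move == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[i])
            for r in out_b:
                r.append(GAP)
            i += 1
        else:
            for r in out_a:
                r.append(GAP)
            for r, row in zip(out_b, rows_b):
                r.append(row[j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_msa(
    sequences: list[tuple[str, str]],
    params: AlignParams | None = None,
) -> list[tuple[str, str]]:
    """Guide-tree progressive alignment (UPGMA on 3-mer distances, affine
    profile-profile merges).  Output row order matches the input order."""
    if len(sequences) < 2:
        raise PhyloError("need >= 2 sequences")
    params = params or AlignParams()
    mat = scoring_matrix(params.matrix_name)
    M20 = np.array(
        [[float(mat[a, b]) for b in AMINO_ACIDS] for a in AMINO_ACIDS]
    )
    order = sorted(range(len(sequences)), key=lambda i: sequences[i][0])
    labels = [sequences[i][0] for i in order]
    seqs = [sequences[i][1] for i in order]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i], seqs[j])
    # deterministic UPGMA merge order (ties by cluster tag)
    clusters: dict[int, dict] = {
        i: {"members": [i], "rows": [seqs[i]], "tag": labels[i]} for i in range(n)
    }
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best_key = None
        best_pair = None
        for (i, j), dij in dist.items():
            if i not in clusters or j not in clusters:
                continue
            tag = tuple(sorted((clusters[i]["tag"], clusters[j]["tag"])))
            key = (dij, tag)
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (i, j)
        i, j = best_pair
        rows_a, rows_b = _merge_profiles(
            clusters[i]["rows"], clusters[j]["rows"], M20,
            params.gap_open, params.gap_extend,
        )
        merged = {
            "members": clusters[i]["members"] + clusters[j]["members"],
            "rows": rows_a + rows_b,
            "tag": min(clusters[i]["tag"], clusters[j]["tag"]),
        }
        na, nb = len(clusters[i]["members"]), len(clusters[j]["members"])
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.get((min(i, k), max(i, k)), 0.0)
            djk = dist.get((min(j, k), max(j, k)), 0.0)
            dist[(min(k, next_id), max(k, next_id))] = (na * dik + nb * djk) / (na + nb)
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        next_id += 1
    final = clusters[next_id - 1]
    by_orig = {
        order[member]: row for member, row in zip(final["members"], final["rows"])
    }
    return [(sequences[i][0], by_orig[i]) for i in range(len(sequences))]
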