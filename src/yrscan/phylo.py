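"""Representative-element tree: alignment, trimming, distances, NJ.

The tree stage summarizes family representatives with a distance-based
neighbor-joining tree over concatenated, gap-trimmed RT/RH/YR domain
alignments (MT is restricted to DIRS elements, so including it would
structure the tree by superfamily membership alone). This is deliberately
a distance method: the claims it supports are clade separations, which are
testable at distance level without maximum-likelihood machinery.
"""

from __future__ import annotations

import logging
import math
from collections import Counter

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

from ._align import AA_ORDER
from .seqio import Alignment

log = logging.getLogger("yrscan")

_GAP = 20  # index of '-' in profile frequency vectors


def _b62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = m[a, b]
    return out


def _encode_rows(rows: list[str]) -> list[np.ndarray]:
    lut = {a: i for i, a in enumerate(AA_ORDER)}
    lut["-"] = _GAP
    return [np.array([lut.get(c, _GAP) for c in r], dtype=np.int64) for r in rows]


# ---------------------------------------------------------------------------
# progressive alignment

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    wa = Counter(a[i : i + k] for i in range(max(0, len(a) - k + 1)))
    wb = Counter(b[i : i + k] for i in range(max(0, len(b) - k + 1)))
    shared = sum((wa & wb).values())
    denom = min(sum(wa.values()), sum(wb.values()))
    return 1.0 - shared / denom if denom else 1.0


def _guide_order(seqs: list[str]) -> list[tuple[int, int]]:
    """UPGMA merge order on k-mer distances; returns (i, j) node-index pairs."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i], seqs[j])
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j), _ = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((i, j))
        members = active[i] + active[j]
        del active[i], active[j]
        newd = {}
        for k_ in active:
            pij = [d[x, y] for x in members for y in active[k_]]
            newd[(min(k_, nxt), max(k_, nxt))] = float(np.mean(pij))
        dist = {
            (a, b): v for (a, b), v in dist.items() if a in active and b in active
        }
        dist.update(newd)
        active[nxt] = members
        nxt += 1
    return merges


def _profile_nw(pa: np.ndarray, pb: np.ndarray, sub: np.ndarray,
                go: float = -11.0, ge: float = -1.0) -> list[str]:
    """Global profile-profile alignment; returns the operation path.

    Columns are frequency vectors over 20 aa + gap; gap frequencies
    contribute zero substitution score. Ops: 'D' diagonal, 'U' gap in b,
    'L' gap in a.
    """
    na, nb = pa.shape[0], pb.shape[0]
    S = pa[:, :20] @ sub[:20, :20] @ pb[:, :20].T  # (na, nb) expected scores
    NEG = -1e30
    H = np.full((na + 1, nb + 1), NEG)
    E = np.full((na + 1, nb + 1), NEG)  # gap in a (consumes b)
    F = np.full((na + 1, nb + 1), NEG)  # gap in b (consumes a)
    H[0, 0] = 0.0
    for j in range(1, nb + 1):
        E[0, j] = go + (j - 1) * ge
        H[0, j] = E[0, j]
    for i in range(1, na + 1):
        F[i, 0] = go + (i - 1) * ge
        H[i, 0] = F[i, 0]
        for j in range(1, nb + 1):
            E[i, j] = max(H[i, j - 1] + go, E[i, j - 1] + ge)
            F[i, j] = max(H[i - 1, j] + go, F[i - 1, j] + ge)
            H[i, j] = max(H[i - 1, j - 1] + S[i - 1, j - 1], E[i, j], F[i, j])
    ops: list[str] = []
    i, j = na, nb
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                ops.append("D")
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ops.append("U")
            if F[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
        else:
            ops.append("L")
            if E[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
    ops.reverse()
    return ops


def _apply_ops(rows_a: list[str], rows_b: list[str], ops: list[str]) -> list[str]:
    out = []
    for row in rows_a:
        s, i = [], 0
        for op in ops:
            if op in ("D", "U"):
                s.append(row[i])
                i += 1
            else:
                s.append("-")
        out.append("".join(s))
    for row in rows_b:
        s, j = [], 0
        for op in ops:
            if op in ("D", "L"):
                s.append(row[j])
                j += 1
            else:
                s.append("-")
        out.append("".join(s))
    return out


def _freq_profile(rows: list[str]) -> np.ndarray:
    enc = _encode_rows(rows)
    n = len(rows)
    ncol = len(rows[0])
    out = np.zeros((ncol, 21))
    for r in enc:
        out[np.arange(ncol), r] += 1.0
    return out / n


def progressive_align(seqs: list[str], ids: list[str] | None = None) -> Alignment:
    """Progressive multiple alignment along a k-mer-distance UPGMA guide tree.

    Pairwise and profile merges use global alignment with affine gaps and
    BLOSUM62 expected-score columns. Deterministic.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = ids if ids is not None else [f"s{i}" for i in range(len(seqs))]
    sub = _b62()
    nodes: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(len(seqs))
    }
    nxt = len(seqs)
    for i, j in _guide_order(seqs):
        ids_a, rows_a = nodes.pop(i)
        ids_b, rows_b = nodes.pop(j)
        ops = _profile_nw(_freq_profile(rows_a), _freq_profile(rows_b), sub)
        nodes[nxt] = (ids_a + ids_b, _apply_ops(rows_a, rows_b, ops))
        nxt += 1
    final_ids, final_rows = nodes.popitem()[1]
    order = {rid: k for k, rid in enumerate(ids)}
    pairs = sorted(zip(final_ids, final_rows), key=lambda t: order[t[0]])
    return Alignment(ids=[p[0] for p in pairs], rows=[p[1] for p in pairs])


# ---------------------------------------------------------------------------
# trimming / concatenation / distances

def trim_columns(a: Alignment, max_gap_fraction: float = 0.05) -> Alignment:
    """Remove columns whose gap fraction exceeds ``max_gap_fraction``."""
    n = len(a.rows)
    keep = [
        j for j in range(a.n_cols)
        if sum(1 for r in a.rows if r[j] == "-") / n <= max_gap_fraction
    ]
    if not keep:
        raise ValueError("all alignment columns removed by trimming")
    rows = ["".join(r[j] for j in keep) for r in a.rows]
    partitions = {}
    if a.partitions:
        for name, (lo, hi) in a.partitions.items():
            kept_before = sum(1 for j in keep if j < lo)
            kept_in = sum(1 for j in keep if lo <= j < hi)
            partitions[name] = (kept_before, kept_before + kept_in)
    return Alignment(ids=list(a.ids), rows=rows, partitions=partitions)


def concat_partitions(alignments: dict[str, Alignment]) -> Alignment:
    """Concatenate per-domain alignments; missing rows are padded with gaps."""
    all_ids = sorted(set().union(*[set(a.ids) for a in alignments.values()]))
    if not all_ids:
        raise ValueError("no rows to concatenate")
    for name, a in alignments.items():
        if not set(a.ids) & set(all_ids):
            raise ValueError(f"partition {name} shares no row ids")
    rows = {rid: [] for rid in all_ids}
    partitions = {}
    pos = 0
    for name in sorted(alignments):
        a = alignments[name]
        width = a.n_cols
        lookup = dict(zip(a.ids, a.rows))
        for rid in all_ids:
            rows[rid].append(lookup.get(rid, "-" * width))
        partitions[name] = (pos, pos + width)
        pos += width
    return Alignment(ids=all_ids, rows=["".join(rows[r]) for r in all_ids],
                     partitions=partitions)


def distance_matrix(a: Alignment, model: str = "p-distance") -> np.ndarray:
    """Pairwise distances over columns where both rows are ungapped.

    ``p-distance`` is mismatches/compared; ``poisson`` is -ln(1 - p).
    A pair with no comparable columns, or p = 1 under poisson, is an error.
    """
    if len(a.rows) < 2:
        raise ValueError("need >= 2 rows")
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    enc = np.array([list(r) for r in a.rows])
    n = len(a.rows)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (enc[i] != "-") & (enc[j] != "-")
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(f"rows {a.ids[i]} and {a.ids[j]} share no ungapped columns")
            p = float((enc[i][both] != enc[j][both]).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(f"poisson distance undefined at p=1 ({a.ids[i]}, {a.ids[j]})")
                p = -math.log(1.0 - p)
            out[i, j] = out[j, i] = p
    return out


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(d: np.ndarray, ids: list[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties pick the smallest active index pair; negative branch lengths are
    clamped to zero with a warning. Returns an unrooted tree (trifurcating
    seed node).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n0 = d.shape[0]
    if n0 < 3:
        raise ValueError("need at least 3 taxa")
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {}
    for k, name in enumerate(ids):
        node = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes[k] = node
    dist = {(i, j): d[i, j] for i in range(n0) for j in range(n0) if i < j}
    active = list(range(n0))
    nxt = n0

    def D(i, j):
        return dist[(min(i, j), max(i, j))]

    def clamp(x):
        if x < 0:
            log.warning("negative branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * D(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = 0.5 * D(i, j) + (r[i] - r[j]) / (2 * (n - 2))
        lj = D(i, j) - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj)
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, nxt), max(k, nxt))] = 0.5 * (D(i, k) + D(j, k) - D(i, j))
        active = [k for k in active if k not in (i, j)] + [nxt]
        nodes[nxt] = parent
        nxt += 1
    a, b, c = active
    la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
    lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
    lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
    root = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = clamp(lk)
    tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_ids: list[str]) -> dendropy.Tree:
    """Root on the branch separating a monophyletic outgroup, at its midpoint."""
    t = tree.clone(depth=1)
    all_leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    og = set(outgroup_ids)
    missing = og - all_leaves
    if missing:
        raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
    target = None
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == og or below == all_leaves - og:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup is not monophyletic on the tree: {sorted(og)}"
        )
    length = target.edge.length or 0.0
    t.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0,
                     update_bipartitions=True, suppress_unifurcations=True)
    return t


def tree_to_newick(tree: dendropy.Tree, decimals: int = 6) -> str:
    def fmt(node) -> str:
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_")
        else:
            label = "(" + ",".join(fmt(c) for c in node.child_nodes()) + ")"
        if node.edge.length is not None and node.parent_node is not None:
            return f"{label}:{node.edge.length:.{decimals}f}"
        return label

    return fmt(tree.seed_node) + ";"
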