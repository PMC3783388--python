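"""Family assignment by greedy identity clustering and similarity graphs.

Families are clusters of concatenated domain peptides at a sequence
identity threshold (default 60%), built with a CD-HIT-style greedy
incremental scheme: sequences are processed longest-first and join the
first representative they match, using a short-word count filter before
the exact alignment. Higher-level groups come from an all-vs-all local
alignment similarity graph whose edges keep pairs with an empirical
Gumbel p-value below a threshold (default 1e-06); group identity is
connected-component membership.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import edlib
import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

DOMAIN_ORDER = ("RT", "RH", "YR", "MT")
_EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class ConcatenatedDomains:
    """Best-hit peptides of one element concatenated in RT,RH,YR,MT order."""

    element_id: str
    peptide: str
    parts: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError(f"{self.element_id}: empty concatenated peptide")


def concatenate_domains(element, element_id: str) -> ConcatenatedDomains:
    """Extract and concatenate the best hit peptide per domain class."""
    parts: dict[str, tuple[int, int]] = {}
    pieces: list[str] = []
    pos = 0
    for dclass in DOMAIN_ORDER:
        hit = element.core.best_hit(dclass)
        if hit is None or not hit.peptide:
            continue
        parts[dclass] = (pos, pos + len(hit.peptide))
        pieces.append(hit.peptide)
        pos += len(hit.peptide)
    return ConcatenatedDomains(element_id=element_id, peptide="".join(pieces), parts=parts)


# ---------------------------------------------------------------------------
# identity and greedy clustering

def global_identity(a: str, b: str) -> float:
    """Identical positions in a minimum-edit global alignment / shorter length."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    i = j = matches = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in ("=", "X", "M"):
            if ch == "=":
                matches += n
            elif ch == "M":  # ambiguous op: compare explicitly
                matches += sum(1 for k in range(n) if a[i + k] == b[j + k])
            i += n
            j += n
        elif ch == "I":
            j += n
        elif ch == "D":
            i += n
    return matches / min(len(a), len(b))


def meets_identity(a: str, b: str, threshold: float) -> bool:
    """identity(a, b) >= threshold, compared with a small tolerance."""
    return global_identity(a, b) >= threshold - 1e-9


def _word_counter(seq: str, word_len: int) -> Counter:
    return Counter(seq[i : i + word_len] for i in range(len(seq) - word_len + 1))


def min_common_words(short_len: int, threshold: float, word_len: int) -> int:
    """Lower bound on shared words for a pair at >= threshold identity.

    Each of the at most (1-threshold)*L mismatches destroys at most
    word_len words of the shorter sequence, hence the bound; it can be
    non-positive at low thresholds, in which case the filter passes
    everything (the CD-HIT behavior for permissive thresholds).
    """
    n_words = short_len - word_len + 1
    return max(0, n_words - math.ceil((1.0 - threshold) * short_len) * word_len)


@dataclass
class FamilyCluster:
    representative_id: str
    member_ids: list[str]
    threshold: float


def greedy_identity_cluster(seqs: list[ConcatenatedDomains], threshold: float = 0.60,
                            word_len: int = 4) -> list[FamilyCluster]:
    """Greedy incremental clustering at a global-identity threshold.

    Sequences are sorted by length descending (ties: lexicographic id) and
    each joins the first existing representative that passes the word
    filter and then the exact identity test; otherwise it founds a new
    cluster. Deterministic.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if word_len < 2:
        raise ValueError("word_len must be >= 2")
    ordered = sorted(seqs, key=lambda s: (-len(s.peptide), s.element_id))
    clusters: list[FamilyCluster] = []
    rep_seqs: list[ConcatenatedDomains] = []
    rep_words: list[Counter] = []
    for s in ordered:
        words = _word_counter(s.peptide, word_len)
        placed = False
        for cl, rep, rwords in zip(clusters, rep_seqs, rep_words):
            short = min(len(s.peptide), len(rep.peptide))
            need = min_common_words(short, threshold, word_len)
            if need > 0:
                common = sum((words & rwords).values())
                if common < need:
                    continue
            if meets_identity(s.peptide, rep.peptide, threshold):
                cl.member_ids.append(s.element_id)
                placed = True
                break
        if not placed:
            clusters.append(FamilyCluster(representative_id=s.element_id,
                                          member_ids=[s.element_id], threshold=threshold))
            rep_seqs.append(s)
            rep_words.append(words)
    return clusters


# ---------------------------------------------------------------------------
# similarity graph

@dataclass
class SimilarityGraph:
    nodes: list[str]
    edges: list[tuple[str, str, float]]
    p_threshold: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, p in self.edges:
            g.add_edge(u, v, p_value=p)
        return g


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def shuffle_pvalue(obs: float, null_scores: np.ndarray) -> float:
    """Right-tail Gumbel p-value, location/scale by method of moments."""
    m = float(null_scores.mean())
    s = float(null_scores.std(ddof=1)) if null_scores.size > 1 else 0.0
    if s == 0.0:
        return np.nextafter(0, 1) if obs > m else 1.0
    beta = s * math.sqrt(6.0) / math.pi
    mu = m - _EULER_GAMMA * beta
    z = (obs - mu) / beta
    if z > 700.0:
        return float(np.nextafter(0, 1))
    p = -math.expm1(-math.exp(-z))
    return float(min(1.0, max(p, np.nextafter(0, 1))))


def build_similarity_graph(seqs: dict[str, str], p_threshold: float = 1e-06,
                           n_shuffles: int = 50, seed: int = 0) -> SimilarityGraph:
    """All-vs-all local alignment graph with empirical Gumbel p-values.

    For each pair the null is the local alignment score of ``n_shuffles``
    shuffles of the shorter sequence against the longer; edges keep pairs
    at p <= p_threshold. Deterministic given the seed.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if n_shuffles < 50:
        raise ValueError("n_shuffles must be >= 50")
    aligner = _make_aligner()
    ids = sorted(seqs)
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str, float]] = []
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            a, b = seqs[u], seqs[v]
            short, longer = (a, b) if len(a) <= len(b) else (b, a)
            obs = float(aligner.score(longer, short))
            chars = np.array(list(short))
            null = np.empty(n_shuffles)
            for k in range(n_shuffles):
                null[k] = aligner.score(longer, "".join(rng.permutation(chars)))
            p = shuffle_pvalue(obs, null)
            if p <= p_threshold:
                edges.append((u, v, p))
    return SimilarityGraph(nodes=ids, edges=edges, p_threshold=p_threshold)


def connected_components(g: SimilarityGraph) -> list[list[str]]:
    """Components as sorted id lists, ordered by their smallest member."""
    comps = [sorted(c) for c in nx.connected_components(g.to_networkx())]
    return sorted(comps, key=lambda c: c[0])


def layout_2d(g: SimilarityGraph, iterations: int = 200, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Seeded force-directed 2D embedding (visualization only).

    Edge attraction is proportional to -log10(p); all pairs repel with an
    inverse-square term; the step size decays linearly. No classification
    decision may read these coordinates.
    """
    ids = list(g.nodes)
    n = len(ids)
    if n == 0:
        raise ValueError("empty graph")
    if n == 1:
        return {ids[0]: (0.0, 0.0)}
    idx = {u: i for i, u in enumerate(ids)}
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((n, 2))
    w = np.zeros((n, n))
    for u, v, p in g.edges:
        weight = -math.log10(max(p, 1e-300))
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = weight
    w_max = w.max() if w.max() > 0 else 1.0
    w /= w_max
    for it in range(iterations):
        step = 0.1 * (1.0 - it / iterations) + 1e-3
        delta = pos[:, None, :] - pos[None, :, :]
        dist2 = (delta ** 2).sum(axis=2) + 1e-9
        rep = delta / dist2[:, :, None]
        att = -delta * w[:, :, None]
        force = (0.05 * rep + att).sum(axis=1)
        pos += step * force
    return {u: (float(pos[i, 0]), float(pos[i, 1])) for u, i in idx.items()}
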