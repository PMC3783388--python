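"""Terminal-repeat architecture detection around element cores.

Two diagnostic layouts delimit tyrosine-recombinase retrotransposons:

* DIRS: inverted terminal repeats (ITR) — the left terminus matches the
  reverse complement of the right terminus, optionally supported by an
  internal complementary region (ICR);
* Ngaro: split direct repeats in A1 - core - B1 - A2 - B2 order.

Repeats are modeled as ungapped copies: candidate diagonals come from
exact k-mer seeds and the optimal interval on each diagonal — maximum
match/mismatch score (+1/-3) subject to a minimum length and identity —
is computed exactly, so on seeded diagonals the result equals exhaustive
substring-pair enumeration. The mismatch penalty keeps reported copy
boundaries at the repeat edges instead of drifting into flanking sequence
(chance matches in random flank would keep inflating a pure match count).
N never matches anything, including another N.

Repeat copies may reach at most 30 nt into the core's domain envelope,
which prevents coding sequence from being reused as "repeat" evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .seqio import GenomeRecord, Interval, revcomp

CORE_OVERLAP_TOLERANCE_NT = 30


@dataclass(frozen=True)
class RepeatCopy:
    interval: Interval
    sequence: str


@dataclass(frozen=True)
class RepeatStructure:
    """Evidence of ITR (DIRS) or split direct repeats (Ngaro).

    ``copies`` are in architectural order — (left, right) for ITR,
    (A1, B1, A2, B2) for SPLIT_DIRECT — with genomic forward-strand
    coordinates. ``score`` is total matched bases (length x identity,
    summed over the A and B pairs).
    """

    kind: str  # ITR | SPLIT_DIRECT | none
    copies: tuple[RepeatCopy, ...]
    identity_a: float
    identity_b: float | None = None
    icr: Optional[RepeatCopy] = None
    score: float = 0.0

    def with_icr(self, icr: RepeatCopy | None) -> "RepeatStructure":
        return RepeatStructure(self.kind, self.copies, self.identity_a,
                               self.identity_b, icr, self.score)


NO_REPEATS = RepeatStructure(kind="none", copies=(), identity_a=0.0)


# ---------------------------------------------------------------------------
# ungapped pair finding

MISMATCH_PENALTY = 3


@dataclass(frozen=True)
class _Pair:
    score: int  # matches - MISMATCH_PENALTY * mismatches
    matches: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    @property
    def identity(self) -> float:
        return self.matches / self.length

    def sort_key(self):
        # higher score, then shortest (ties at equal score extend into flank
        # by break-even excursions, so shorter = tighter boundaries), then
        # leftmost a, then leftmost b
        return (-self.score, self.length, self.a_start, self.b_start)


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    return codes


def seed_diagonals(a: str, b: str, k: int) -> list[int]:
    """Diagonals (b_index - a_index) sharing an exact k-mer (N-free)."""
    if len(a) < k or len(b) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        w = a[i : i + k]
        if "N" not in w:
            index.setdefault(w, []).append(i)
    diags: set[int] = set()
    for j in range(len(b) - k + 1):
        w = b[j : j + k]
        for i in index.get(w, ()):
            diags.add(j - i)
    return sorted(diags)


class _MinSegmentTree:
    """Point-update / range-min segment tree over (value, index) pairs."""

    _INF = (1 << 60, 1 << 60)

    def __init__(self, n: int):
        self.n = 1
        while self.n < n:
            self.n *= 2
        self.data = [self._INF] * (2 * self.n)

    def update(self, i: int, item: tuple[int, int]) -> None:
        i += self.n
        if item < self.data[i]:
            self.data[i] = item
            i //= 2
            while i:
                new = min(self.data[2 * i], self.data[2 * i + 1])
                if new == self.data[i]:
                    break
                self.data[i] = new
                i //= 2

    def query(self, lo: int, hi: int) -> tuple[int, int]:
        """min over [lo, hi)."""
        res = self._INF
        lo += self.n
        hi += self.n
        while lo < hi:
            if lo & 1:
                if self.data[lo] < res:
                    res = self.data[lo]
                lo += 1
            if hi & 1:
                hi -= 1
                if self.data[hi] < res:
                    res = self.data[hi]
            lo //= 2
            hi //= 2
        return res


def best_interval_on_diagonal(match: np.ndarray, min_len: int, min_id: float,
                              max_len: int | None = None):
    """Exact best interval on one diagonal's boolean match vector.

    Maximizes score = matches - MISMATCH_PENALTY * mismatches subject to
    length >= min_len, identity >= min_id and optionally length <= max_len.
    Identity feasibility is compared in scaled-integer arithmetic
    (per-mille), so there are no float boundary effects. Ties: shortest,
    then leftmost start (an equal-score longer interval only adds
    break-even flank noise). Returns (score, matches, start, end) or None.

    With M the match prefix sum, score(s, e) = G[e] - G[s] for
    G[x] = (1+P)*M[x] - P*x, and identity feasibility is D[s] <= D[e] for
    D[x] = 1000*M[x] - p*x. Processing ends in increasing D order while
    activating starts with D[s] <= D[e] in a segment tree keyed by
    position makes every query an exact range-min of G over the allowed
    start window.
    """
    L = int(match.shape[0])
    if L < min_len:
        return None
    p = int(round(min_id * 1000))
    P = MISMATCH_PENALTY
    M = np.concatenate([[0], np.cumsum(match.astype(np.int64))])
    idx = np.arange(L + 1, dtype=np.int64)
    D = 1000 * M - p * idx
    G = (1 + P) * M - P * idx
    order = np.argsort(D, kind="stable")  # positions by increasing D
    tree = _MinSegmentTree(L + 1)
    ptr = 0
    best = None  # key (-score, length, s); value (score, matches, s, e)
    for e in order:
        e = int(e)
        # activate all starts with D[s] <= D[e]
        while ptr <= L and D[order[ptr]] <= D[e]:
            s = int(order[ptr])
            # min G first; among equal G prefer the largest s (shortest)
            tree.update(s, (int(G[s]), -s))
            ptr += 1
        hi = e - min_len + 1
        lo = 0 if max_len is None else max(0, e - max_len)
        if hi <= lo:
            continue
        g_s, neg_s = tree.query(lo, hi)
        if g_s >= 1 << 59:
            continue
        s = -neg_s
        score = int(G[e]) - g_s
        key = (-score, e - s, s)
        if best is None or key < best[0]:
            best = (key, (score, int(M[e] - M[s]), s, e))
    return None if best is None else best[1]


def best_direct_pair(a: str, b: str, k: int, min_len: int, min_id: float,
                     self_mode: bool = False) -> _Pair | None:
    """Best ungapped pair between ``a`` and ``b`` on k-mer-seeded diagonals.

    With ``self_mode`` (a is b), only forward diagonals d >= min_len are
    considered and copies may not overlap (length <= d).
    """
    ca, cb = _encode(a), _encode(b)
    best: _Pair | None = None
    for d in seed_diagonals(a, b, k):
        if self_mode and d < min_len:
            continue
        lo_a = max(0, -d)
        hi_a = min(len(a), len(b) - d)
        if hi_a - lo_a < min_len:
            continue
        seg_a = ca[lo_a:hi_a]
        seg_b = cb[lo_a + d : hi_a + d]
        match = (seg_a == seg_b) & (seg_a != ord("N"))
        cap = d if self_mode else None
        res = best_interval_on_diagonal(match, min_len, min_id, max_len=cap)
        if res is None:
            continue
        score, m, s, e = res
        cand = _Pair(score=score, matches=m, a_start=lo_a + s, a_end=lo_a + e,
                     b_start=lo_a + d + s, b_end=lo_a + d + e)
        if best is None or cand.sort_key() < best.sort_key():
            best = cand
    return best


# ---------------------------------------------------------------------------
# ITR (DIRS)

def find_itr(record: GenomeRecord, core: Interval, flank_nt: int = 2000,
             k: int = 13, min_len: int = 20, min_identity: float = 0.80) -> RepeatStructure | None:
    """Best inverted-terminal-repeat pair flanking ``core``, or None.

    The left flank is compared with the reverse complement of the right
    flank; flanks are clipped at sequence ends and may reach at most 30 nt
    into the core. Both copies are reported on the forward strand.
    """
    L = record.length
    tol = CORE_OVERLAP_TOLERANCE_NT
    a_lo = max(0, core.start - flank_nt)
    a_hi = min(L, min(core.start + tol, core.end))
    b_lo = max(0, max(core.end - tol, core.start))
    b_hi = min(L, core.end + flank_nt)
    if a_hi - a_lo < min_len or b_hi - b_lo < min_len:
        return None
    a = record.residues[a_lo:a_hi]
    b_fwd = record.residues[b_lo:b_hi]
    b = revcomp(b_fwd)
    pair = best_direct_pair(a, b, k, min_len, min_identity)
    if pair is None:
        return None
    left_iv = Interval(record.id, a_lo + pair.a_start, a_lo + pair.a_end, "+")
    # b index ib maps to forward coordinate b_hi - 1 - ib
    right_iv = Interval(record.id, b_hi - pair.b_end, b_hi - pair.b_start, "+")
    left = RepeatCopy(left_iv, record.residues[left_iv.start : left_iv.end])
    right = RepeatCopy(right_iv, record.residues[right_iv.start : right_iv.end])
    return RepeatStructure(kind="ITR", copies=(left, right),
                           identity_a=pair.identity, score=float(pair.score))


def find_icr(record: GenomeRecord, element: Interval, itr: RepeatStructure,
             k: int = 13, min_len: int = 15, min_identity: float = 0.80) -> RepeatCopy | None:
    """Interior segment matching the reverse complement of the left ITR copy.

    Supporting evidence for the DIRS replication model only; never required
    for classification.
    """
    if itr.kind != "ITR":
        raise ValueError("find_icr requires an ITR structure")
    left, right = itr.copies
    lo = left.interval.end
    hi = right.interval.start
    if hi - lo < min_len:
        return None
    interior = record.residues[lo:hi]
    target = revcomp(left.sequence)
    pair = best_direct_pair(target, interior, k, min_len, min_identity)
    if pair is None:
        return None
    iv = Interval(record.id, lo + pair.b_start, lo + pair.b_end, "+")
    return RepeatCopy(iv, record.residues[iv.start : iv.end])


# ---------------------------------------------------------------------------
# split direct repeats (Ngaro)

def _find_split_direct_fwd(seq: str, seq_id: str, offset: int, core: Interval,
                           flank_nt: int, k: int, min_len: int,
                           min_identity: float) -> RepeatStructure | None:
    """Forward-strand A1-core-B1-A2-B2 search on ``seq`` (genomic offset given)."""
    L = len(seq)
    tol = CORE_OVERLAP_TOLERANCE_NT
    c_start, c_end = core.start - offset, core.end - offset
    a_lo = max(0, c_start - flank_nt)
    a_hi = min(L, min(c_start + tol, c_end))
    d_lo = max(0, max(c_end - tol, c_start))
    d_hi = min(L, c_end + 2 * flank_nt)
    if a_hi - a_lo < min_len or d_hi - d_lo < 2 * min_len:
        return None
    left = seq[a_lo:a_hi]
    down = seq[d_lo:d_hi]
    a_pair = best_direct_pair(left, down, k, min_len, min_identity)
    if a_pair is None:
        return None
    b_pair = best_direct_pair(down, down, k, min_len, min_identity, self_mode=True)
    if b_pair is None:
        return None
    a1 = (a_lo + a_pair.a_start, a_lo + a_pair.a_end)
    a2 = (d_lo + a_pair.b_start, d_lo + a_pair.b_end)
    b1 = (d_lo + b_pair.a_start, d_lo + b_pair.a_end)
    b2 = (d_lo + b_pair.b_start, d_lo + b_pair.b_end)
    # architectural order: A1 before the core; B1, A2, B2 downstream with
    # start(B1) < start(A2) < start(B2)
    if a1[0] >= c_start + tol:
        return None
    if not (b1[0] < a2[0] < b2[0]):
        return None
    copies = tuple(
        RepeatCopy(Interval(seq_id, offset + s, offset + e, "+"), seq[s:e])
        for s, e in (a1, b1, a2, b2)
    )
    return RepeatStructure(
        kind="SPLIT_DIRECT", copies=copies,
        identity_a=a_pair.identity, identity_b=b_pair.identity,
        score=float(a_pair.score + b_pair.score),
    )


def find_split_direct(record: GenomeRecord, core: Interval, flank_nt: int = 2000,
                      k: int = 13, min_len: int = 20, min_identity: float = 0.80,
                      strand: str = "+") -> RepeatStructure | None:
    """Best split-direct-repeat layout around ``core``, or None.

    The A pair links the left flank with the downstream region; the B pair
    lies entirely downstream; all (A, B) combinations honoring the start
    ordering are scored by summed matches and the best is returned. For
    minus-strand cores the search runs on the reverse complement of the
    region and coordinates are mapped back; copies are reported in
    architectural (element-strand) order.
    """
    if strand == "+":
        return _find_split_direct_fwd(record.residues, record.id, 0, core,
                                      flank_nt, k, min_len, min_identity)
    g0 = max(0, core.start - 2 * flank_nt - 100)
    g1 = min(record.length, core.end + 2 * flank_nt + 100)
    region_rc = revcomp(record.residues[g0:g1])
    mirrored_core = Interval(record.id, g1 - core.end, g1 - core.start, "+")
    res = _find_split_direct_fwd(region_rc, record.id, 0, mirrored_core,
                                 flank_nt, k, min_len, min_identity)
    if res is None:
        return None
    n = g1 - g0

    def back(iv: Interval) -> Interval:
        return Interval(record.id, g0 + (n - iv.end), g0 + (n - iv.start), "+")

    copies = tuple(
        RepeatCopy(back(c.interval), revcomp(c.sequence)) for c in res.copies
    )
    return RepeatStructure(kind="SPLIT_DIRECT", copies=copies,
                           identity_a=res.identity_a, identity_b=res.identity_b,
                           score=res.score)
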