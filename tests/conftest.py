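"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by exhaustive computation
(full-matrix dynamic programming, all-substring-pair enumeration,
union-find) so the package's optimized implementations are checked against
structurally independent code.
"""

from __future__ import annotations

import numpy as np
import pytest

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20130925)


def random_peptide(rng, n: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, n))


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate_peptide(rng, pep: str, frac: float) -> str:
    pep = list(pep)
    k = int(round(frac * len(pep)))
    for i in rng.choice(len(pep), size=k, replace=False):
        options = AA.replace(pep[i], "")
        pep[i] = options[rng.integers(0, 19)]
    return "".join(pep)


def mutate_dna(rng, seq: str, frac: float) -> str:
    seq = list(seq)
    k = int(round(frac * len(seq)))
    for i in rng.choice(len(seq), size=k, replace=False):
        options = "ACGT".replace(seq[i], "")
        seq[i] = options[rng.integers(0, 3)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# naive local profile alignment oracle (full-matrix affine DP, no windowing)

def _score(columns, aa_code, i):
    if aa_code == 20:  # stop
        return -8.0
    if aa_code >= 21:  # X or masked
        return 0.0 if aa_code == 21 else -1e6
    return columns[i, aa_code]


def naive_local_dp(columns, codes, go, ge):
    """Full H/E/F float64 matrices of local profile-peptide alignment."""
    Lp, n = columns.shape[0], len(codes)
    NEG = -1e18
    H = np.zeros((Lp + 1, n + 1))
    E = np.full((Lp + 1, n + 1), NEG)
    F = np.full((Lp + 1, n + 1), NEG)
    for i in range(1, Lp + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + go, E[i, j - 1] + ge)
            F[i, j] = max(H[i - 1, j] + go, F[i - 1, j] + ge)
            diag = H[i - 1, j - 1] + _score(columns, codes[j - 1], i - 1)
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
    return H, E, F


def naive_greedy_hits(columns, pep_codes, go, ge, threshold):
    """Greedy best-score extraction with aligned-region masking (scores only)."""
    codes = list(pep_codes)
    scores = []
    while True:
        H, E, F = naive_local_dp(columns, codes, go, ge)
        best = H.max()
        if best < threshold:
            return sorted(scores, reverse=True)
        # locate the aligned peptide region of one best-ending cell
        ends = np.argwhere(H == best)
        ends = ends[np.lexsort((ends[:, 0], ends[:, 1]))]
        i, j = map(int, ends[0])
        scores.append(best)
        # traceback to find peptide span
        state = "H"
        j_end = j
        while True:
            if state == "H":
                if H[i, j] == 0.0:
                    break
                diag = H[i - 1, j - 1] + _score(columns, codes[j - 1], i - 1)
                if i >= 1 and j >= 1 and H[i, j] == diag:
                    i, j = i - 1, j - 1
                    if H[i, j] == 0.0:
                        break
                    continue
                state = "F" if H[i, j] == F[i, j] else "E"
            elif state == "F":
                state = "H" if F[i, j] == H[i - 1, j] + go else "F"
                i -= 1
            else:
                state = "H" if E[i, j] == H[i, j - 1] + go else "E"
                j -= 1
        for k in range(j, j_end):
            codes[k] = 22  # mask


# ---------------------------------------------------------------------------
# exhaustive ungapped substring-pair oracle

def oracle_best_pair(a: str, b: str, min_len: int, min_id: float,
                     self_mode: bool = False, penalty: int = 3):
    """Best ungapped pair by exhaustive enumeration of every diagonal and
    every (start, end) — no seeding, no sweep; same scoring/tie-breaks as
    the package (score = matches - penalty*mismatches; ties shortest, then
    leftmost). Vectorized over the full (start, end) grid per diagonal."""
    best = None
    ca = np.frombuffer(a.encode(), dtype=np.uint8)
    cb = np.frombuffer(b.encode(), dtype=np.uint8)
    p = int(round(min_id * 1000))
    for d in range(-(len(a) - min_len), len(b) - min_len + 1):
        if self_mode and d < min_len:
            continue
        lo = max(0, -d)
        hi = min(len(a), len(b) - d)
        L = hi - lo
        if L < min_len:
            continue
        seg = (ca[lo:hi] == cb[lo + d : hi + d]) & (ca[lo:hi] != ord("N"))
        M = np.concatenate([[0], np.cumsum(seg.astype(np.int64))])
        S = np.arange(L + 1)[:, None]
        E = np.arange(L + 1)[None, :]
        length = E - S
        m = M[E] - M[S]
        ok = (length >= min_len) & (1000 * m >= p * length)
        if self_mode:
            ok &= length <= d
        if not ok.any():
            continue
        score = m - penalty * (length - m)
        # maximize score, then shortest, then leftmost start
        key = ((score + 4 * (L + 1)) * 4096 + (L - length)) * 4096 + (L - S)
        key = np.where(ok, key, -1)
        flat = int(np.argmax(key))
        s, e = flat // (L + 1), flat % (L + 1)
        cand_key = (-int(score[s, e]), int(length[s, e]), lo + int(s), lo + d + int(s))
        cand = (int(score[s, e]), int(m[s, e]), lo + int(s), lo + int(e),
                lo + d + int(s), lo + d + int(e))
        if best is None or cand_key < best[0]:
            best = (cand_key, cand)
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# union-find component oracle

def union_find_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), []).append(n)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
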