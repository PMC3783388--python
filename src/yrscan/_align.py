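"""Local profile-to-peptide alignment with affine gaps.

The scanner aligns a position score matrix (one score vector per profile
column) against long six-frame peptides. The forward pass is vectorized
along the peptide axis: for each profile row the insertion state is a
running-maximum scan, so the full Smith-Waterman recurrence is computed
exactly without per-cell Python loops. Candidate regions found by the
forward pass are then re-solved in small windows with a traceback to
recover exact hit boundaries; non-overlapping local optima are extracted
greedily from the best score with aligned-region masking.

Scoring conventions used throughout the package: ``*`` (stop codon read
through) costs a fixed -8 against every column, ``X`` (codon containing N)
scores 0, and gap_open <= gap_extend < 0 (cost of a gap of length g is
gap_open + (g-1)*gap_extend).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODE = 20
X_CODE = 21
_MASK_CODE = 22
STOP_SCORE = -8.0

_PEP_CODE = np.full(256, X_CODE, dtype=np.int8)
for _i, _a in enumerate(AA_ORDER):
    _PEP_CODE[ord(_a)] = _i
    _PEP_CODE[ord(_a.lower())] = _i
_PEP_CODE[ord("*")] = STOP_CODE

_NEG = -1.0e6  # effectively forbidden, but keeps arithmetic finite


def encode_peptide(pep: str) -> np.ndarray:
    """Encode amino acids to 0..19, '*' to 20, anything else to 21 (X)."""
    return _PEP_CODE[np.frombuffer(pep.encode(), dtype=np.uint8)].copy()


def expand_score_matrix(columns: np.ndarray) -> np.ndarray:
    """(Lp, 20) column scores -> (Lp, 23) with stop / X / mask codes appended."""
    Lp = columns.shape[0]
    out = np.empty((Lp, 23), dtype=np.float64)
    out[:, :20] = columns
    out[:, STOP_CODE] = STOP_SCORE
    out[:, X_CODE] = 0.0
    out[:, _MASK_CODE] = _NEG
    return out


@dataclass(frozen=True)
class LocalHit:
    """One local alignment of a profile against a peptide."""

    score: float
    pep_start: int  # 0-based half-open peptide window
    pep_end: int
    prof_start: int  # 0-based half-open profile-column window
    prof_end: int


def _forward_colmax(smat: np.ndarray, codes: np.ndarray, go: float, ge: float) -> np.ndarray:
    """Best alignment score ending at each peptide position (max over profile rows)."""
    n = codes.shape[0]
    Lp = smat.shape[0]
    jrange = np.arange(n, dtype=np.float64)
    c_t = go - ge * jrange           # added to base before the running max
    c_e = ge * (jrange - 1.0)        # added after, shifted by one
    colmax = np.zeros(n, dtype=np.float64)
    h_prev = np.zeros(n, dtype=np.float64)
    f_prev = np.full(n, _NEG, dtype=np.float64)
    h_row = np.empty(n, dtype=np.float64)
    f_row = np.empty(n, dtype=np.float64)
    base = np.empty(n, dtype=np.float64)
    t = np.empty(n, dtype=np.float64)
    tmp = np.empty(n, dtype=np.float64)
    for i in range(Lp):
        # F: deletion of profile column i
        np.add(h_prev, go, out=f_row)
        np.add(f_prev, ge, out=tmp)
        np.maximum(f_row, tmp, out=f_row)
        # base: fresh start / diagonal / deletion
        base[0] = smat[i, codes[0]]
        np.add(smat[i][codes[1:]], h_prev[:-1], out=base[1:])
        np.maximum(base, f_row, out=base)
        np.maximum(base, 0.0, out=base)
        # E (insertion) as a running-max scan: E[j] = max_{k<j} base[k]+go+ge*(j-1-k)
        np.add(base, c_t, out=t)
        np.maximum.accumulate(t, out=t)
        h_row[0] = base[0]
        np.add(t[:-1], c_e[1:], out=tmp[1:])
        np.maximum(base[1:], tmp[1:], out=h_row[1:])
        np.maximum(colmax, h_row, out=colmax)
        h_prev, h_row = h_row, h_prev
        f_prev, f_row = f_row, f_prev
    return colmax


MASK_CODE = _MASK_CODE


def forward_colmax(columns: np.ndarray, codes: np.ndarray, go: float, ge: float) -> np.ndarray:
    """Per-position best-alignment-ending-here scores (vectorized forward pass)."""
    return _forward_colmax(expand_score_matrix(columns), codes, go, ge)


def max_local_score(columns: np.ndarray, codes: np.ndarray, go: float, ge: float) -> float:
    smat = expand_score_matrix(columns)
    return float(_forward_colmax(smat, codes, go, ge).max(initial=0.0))


def _window_dp(smat, codes, go, ge):
    """Full H/E/F matrices for a (small) window; rows 0..Lp, cols 0..n."""
    Lp = smat.shape[0]
    n = codes.shape[0]
    H = np.zeros((Lp + 1, n + 1), dtype=np.float64)
    E = np.full((Lp + 1, n + 1), _NEG, dtype=np.float64)
    F = np.full((Lp + 1, n + 1), _NEG, dtype=np.float64)
    jrange = np.arange(n, dtype=np.float64)
    for i in range(1, Lp + 1):
        s = smat[i - 1][codes]
        F[i, 1:] = np.maximum(H[i - 1, 1:] + go, F[i - 1, 1:] + ge)
        base = np.maximum(np.maximum(F[i, 1:], 0.0), H[i - 1, :-1] + s)
        t = base + go - ge * (jrange + 1.0)
        cm = np.maximum.accumulate(t)
        E[i, 2:] = cm[:-1] + ge * jrange[1:]
        H[i, 1:] = np.maximum(base, E[i, 1:])
    return H, E, F


def _traceback(H, E, F, smat, codes, go, ge, i, j):
    """Walk back from H[i, j]; returns (pep_start, prof_start) (0-based)."""
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0.0:
                return j, i
            s = smat[i - 1][codes[j - 1]]
            if i >= 1 and j >= 1 and h == H[i - 1, j - 1] + s:
                i, j = i - 1, j - 1
                if H[i, j] == 0.0:
                    return j, i
                continue
            if h == F[i, j]:
                state = "F"
                continue
            if h == E[i, j]:
                state = "E"
                continue
            raise AssertionError("traceback: inconsistent H cell")
        elif state == "F":
            if F[i, j] == H[i - 1, j] + go:
                i, state = i - 1, "H"
            else:
                i = i - 1
        else:  # E
            if E[i, j] == H[i, j - 1] + go:
                j, state = j - 1, "H"
            else:
                j = j - 1


def _extract_window_hits(smat, codes, go, ge, threshold):
    """Greedy non-overlapping local optima within one window."""
    codes = codes.copy()
    hits = []
    while True:
        H, E, F = _window_dp(smat, codes, go, ge)
        best = H.max()
        if best < threshold:
            break
        # deterministic tie-break: best score, then leftmost end, then
        # smallest profile end row
        ends = np.argwhere(H == best)
        ends = ends[np.lexsort((ends[:, 0], ends[:, 1]))]
        i_end, j_end = int(ends[0][0]), int(ends[0][1])
        j_start, i_start = _traceback(H, E, F, smat, codes, go, ge, i_end, j_end)
        hits.append(
            LocalHit(score=float(best), pep_start=j_start, pep_end=j_end,
                     prof_start=i_start, prof_end=i_end)
        )
        codes[j_start:j_end] = _MASK_CODE
    hits.sort(key=lambda h: (h.pep_start, h.pep_end))
    return hits


def scan_local(columns: np.ndarray, codes: np.ndarray, go: float, ge: float,
               threshold: float) -> list[LocalHit]:
    """All non-overlapping local alignments with score >= threshold.

    Exact: the windowing around forward-pass candidates is sized from an
    upper bound on alignment extent, so results equal a full-matrix greedy
    extraction.
    """
    n = codes.shape[0]
    if n == 0:
        return []
    smat = expand_score_matrix(columns)
    colmax = _forward_colmax(smat, codes, go, ge)
    cand = np.flatnonzero(colmax >= threshold)
    if cand.size == 0:
        return []
    # any alignment scoring >= threshold spans at most W peptide residues
    upper = float(np.maximum(columns.max(axis=1), 0.0).sum())
    W = columns.shape[0] + int(np.ceil(max(upper + go, 0.0) / abs(ge))) + 4
    # overlapping alignments always land in one merged window
    windows = []
    lo = hi = int(cand[0])
    for j in cand[1:]:
        if j - hi <= 2 * W:
            hi = int(j)
        else:
            windows.append((lo, hi))
            lo = hi = int(j)
    windows.append((lo, hi))
    hits: list[LocalHit] = []
    for lo, hi in windows:
        w0 = max(0, lo - W)
        w1 = min(n, hi + 1)
        for h in _extract_window_hits(smat, codes[w0:w1], go, ge, threshold):
            hits.append(
                LocalHit(score=h.score, pep_start=h.pep_start + w0, pep_end=h.pep_end + w0,
                         prof_start=h.prof_start, prof_end=h.prof_end)
            )
    hits.sort(key=lambda h: (h.pep_start, h.pep_end))
    return hits
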